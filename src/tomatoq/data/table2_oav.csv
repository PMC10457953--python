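compound,cas,aroma_type,P1,P2,P3,P4,P5,T1,T2,T3,T4,T5,Y1,Y2,Y3,Y4,Y5,odor_threshold_ug_per_kg
1-Hexanol,111-27-3,"Fruity, sweet, green",12.51,0.00,0.00,0.00,0.00,14.33,12.60,14.34,10.53,19.63,8.51,9.72,17.47,20.91,14.87,5.7
(Z)-3-Hexen-1-ol,928-96-1,"Fresh, green",2.26,0.68,2.54,1.76,3.44,1.56,2.68,3.65,3.38,3.68,0.83,1.85,1.15,2.06,2.34,200
1-Octen-3-ol,3391-86-4,"Mushroom, earthy, green",3.81,2.41,6.16,16.22,0.00,7.73,5.16,6.23,12.78,8.48,1.50,4.82,14.61,5.42,4.84,1
Linalool,78-70-6,"Citrus, floral, sweet",1.94,1.81,2.96,3.55,2.29,2.92,2.13,2.30,3.46,0.00,2.36,2.47,0.00,0.00,3.57,1.5
1-Octanol,111-87-5,"Waxy, green, citrus",0.00,0.00,471.45,1017.08,314.78,244.55,200.02,580.71,1054.24,919.37,389.87,224.69,0.00,286.38,0.00,0.023
1-Nonanol,143-08-8,"Fresh, fatty, floral",1.26,0.00,2.34,5.44,0.00,1.77,1.39,4.26,6.57,5.21,1.93,0.00,2.57,0.00,0.00,2
3-methylbutanal,590-86-3,"Fruity, fatty",17.41,31.66,37.71,32.56,25.19,50.50,21.14,16.13,26.04,23.36,31.00,0.00,49.45,14.66,22.97,0.25
Hexanal,66-25-1,"Fresh, green, fruity",30.34,14.30,28.52,36.39,22.55,24.41,54.35,29.02,55.99,57.52,49.46,58.77,30.72,48.27,47.15,4.5
(Z)-3-Hexenal,6789-80-6,"Green, fatty, fruity",24.27,46.05,141.86,40.52,108.54,161.84,104.91,97.07,70.27,133.75,102.18,106.87,48.92,0.00,124.17,0.25
Heptanal,111-71-7,"Fresh, green, herbal",1.48,0.00,0.00,0.00,0.00,1.80,1.83,0.00,0.00,2.01,0.00,1.69,2.69,1.65,1.75,2.9
(E)-2-Hexenal,6728-26-3,"Green, banana",5.02,10.30,7.50,10.05,5.20,10.05,7.27,7.02,10.61,15.01,8.50,10.19,9.00,8.51,8.34,40
2-Hexenal,505-57-7,"Sweet, fruity, green",20.95,0.00,16.41,12.80,21.20,28.34,19.40,29.97,18.87,22.37,29.51,30.46,32.99,34.03,36.89,17
Octanal,124-13-0,"Citrus, green, waxy",3.16,0.00,0.00,23.15,0.00,0.00,0.00,0.00,8.10,0.00,0.00,2.59,0.00,12.20,0.00,0.7
(E)-2-Heptenal,18829-55-5,"Pungent, green, fresh",1.49,1.11,1.56,0.49,0.98,5.35,2.34,0.92,1.53,1.40,1.92,3.68,2.94,4.79,3.89,13
Nonanal,124-19-6,"Waxy, fresh, citrus",13.70,0.00,11.28,0.00,5.84,18.26,11.72,0.00,15.25,17.38,0.00,11.72,0.00,9.13,10.00,1
(E)-2-Octenal,2548-87-0,"Fresh, green, herbal",2.77,2.84,1.60,13.09,3.10,14.30,10.35,5.08,2.87,2.54,14.96,6.33,6.28,11.09,10.21,3
"(E,E)-2,4-Heptadienal",4313-03-5,"Fatty, green, vegetable",46.26,95.31,0.00,72.99,266.39,141.03,217.30,193.93,0.00,51.55,0.00,0.00,31.82,203.56,118.01,0.08
Decanal,112-31-2,"Sweet, waxy, citrus",73.32,76.22,72.04,53.73,90.50,90.78,68.85,125.75,159.20,133.00,0.00,47.72,0.00,95.87,82.31,0.1
(E)-2-Nonenal,18829-56-6,"Fatty, green, citrus",0.00,0.00,0.00,0.00,0.00,0.00,0.00,0.00,11.31,0.00,7.51,0.00,9.33,16.67,12.63,0.4
β-Cyclocitral,432-25-7,"Herbal, rose, sweet",0.82,0.00,0.44,8.18,0.53,0.56,0.41,7.06,11.28,7.67,2.00,0.33,2.55,1.39,0.58,5
(E)-2-Decenal,3913-81-3,"Waxy, green, earthy",9.81,0.00,12.44,27.79,0.00,10.49,9.79,23.60,32.67,28.70,14.11,7.67,31.88,19.82,0.00,0.3
Citral,5392-40-5,"Citral, sweet",0.60,0.30,1.39,0.00,0.00,0.52,0.48,0.72,0.63,0.59,0.46,0.00,0.00,0.00,1.44,5
"(E,E)-2,4-Nonadienal",5910-87-2,"Melon, waxy, green",0.00,0.00,0.00,0.00,0.00,0.00,65.06,0.00,58.39,0.00,0.00,0.00,45.38,0.00,0.00,0.09
"2,4-Decadienal",2363-88-4,"Sweet, fresh, citrus",49.13,0.00,81.92,0.00,101.69,162.93,121.52,75.07,175.65,132.02,0.00,47.04,0.00,0.00,79.59,0.07
"(E,E)-2,4-Decadienal",25152-84-5,"Fatty, melon, citrus",0.00,0.00,80.00,53.57,81.00,138.57,155.86,131.43,448.43,80.43,0.00,66.00,175.43,111.71,116.86,0.07
1-Penten-3-one,1629-58-9,"Pungent",16.41,35.56,39.79,33.08,26.14,49.92,9.75,11.20,26.39,39.80,30.74,9.34,41.20,7.18,17.71,1
1-Octen-3-one,4312-99-6,"Herbal, mushroom, earthy",62.46,88.42,449.91,206.16,307.47,231.10,193.40,367.06,630.53,553.93,0.00,111.45,200.29,322.79,0.00,0.003
Methylheptenone,110-93-0,"Citrus, green",1.51,1.12,1.41,0.52,1.03,1.60,1.32,0.55,0.93,1.21,1.32,1.10,1.88,2.23,1.60,50
Geranylacetone,3796-70-1,"Foral, fruity, green",0.00,0.00,1.34,0.48,1.00,0.00,2.05,0.53,1.77,1.77,1.00,0.36,1.64,2.07,0.79,60
β-ionone,79-77-6,"Floral, woody",326.92,39.84,182.03,267.40,328.76,707.44,621.99,394.14,718.24,763.47,432.38,542.18,635.60,530.22,825.26,0.007
Ethyl ethanoate,141-78-6,"Fruity sweet",0.00,4.63,2.08,1.14,1.14,26.02,18.94,8.98,7.61,20.72,0.34,0.16,1.23,5.16,0.45,10
Guaiacol,90-05-1,"Woody",0.00,3.35,4.11,2.99,2.02,0.00,1.66,0.00,2.12,3.76,2.76,0.00,0.00,0.00,0.00,2
2-Amylfuran,3777-69-3,"Fruity, green, earthy",0.82,0.99,0.00,0.00,0.00,1.77,1.67,1.48,2.18,2.13,0.00,0.54,1.42,0.00,0.39,4.8
2-Isobutylthiazole,18640-74-9,"Green, earthy, vegetable",5.72,5.62,9.05,4.02,5.07,7.91,12.10,8.16,10.73,12.59,9.24,2.85,2.49,2.44,6.23,3
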