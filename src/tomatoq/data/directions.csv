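indicator,direction
moisture,negative
firmness_with_peel,negative
firmness_without_peel,negative
oxalic_acid,negative
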