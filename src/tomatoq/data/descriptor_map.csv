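descriptor,canonical_type
fruity,fruity
sweet,sweet
floral,floral
fresh,fresh
mushroom-like,mushroom-like
earthy,earthy
green,green
waxy,waxy
fatty,fatty
herbal,herbal
vegetable,vegetable
woody,woody
pungent,pungent
citrus,fruity
banana,fruity
melon,fruity
citral,fruity
rose,floral
mushroom,mushroom-like
foral,floral
fruity sweet,fruity
fruity sweet,sweet
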