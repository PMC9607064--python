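item,group,fraction
beef_mince,red_meat,1
bacon,red_meat,1
sausage,red_meat,1
chicken_breast,poultry,1
cod,fish,1
salmon,fish,1
eggs,eggs,1
whole_milk,dairy,1
cheddar,dairy,1
yogurt,dairy,1
butter,saturated_oils,1
olive_oil,unsaturated_oils,1
sunflower_oil,unsaturated_oils,1
margarine,unsaturated_oils,1
wholemeal_bread,whole_grains,1
oats,whole_grains,1
brown_rice,whole_grains,1
lentils,legumes,1
baked_beans,legumes,1
tofu,legumes,1
peas,vegetables,1
mixed_nuts,nuts,1
peanut_butter,nuts,1
apple,fruits,1
banana,fruits,1
orange,fruits,1
fruit_juice,fruits,0.5
fruit_juice,ssb,0.5
spinach,vegetables,1
carrots,vegetables,1
broccoli,vegetables,1
tomatoes,vegetables,1
cola,ssb,1
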