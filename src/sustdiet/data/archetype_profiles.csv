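item,unsustainable,balanced,restricted,sigma
beef_mince,0.413,0.55,0.01,0.5
bacon,0.338,0.3,0.005,0.6
sausage,0.338,0.35,0.005,0.6
chicken_breast,0.638,0.95,0.008,0.5
cod,0.075,0.13,0.05,0.6
salmon,0.045,0.11,0.04,0.6
eggs,0.8,0.5,0.4,0.5
whole_milk,0.4,0.5,0.7,0.4
cheddar,0.6,0.4,0.1,0.5
yogurt,0.2,0.3,0.15,0.5
butter,1.2,2.3,1.8,0.5
olive_oil,0.3,1.5,0.45,0.5
sunflower_oil,0.225,0.5,0.15,0.6
margarine,0.375,0.4,0.2,0.6
white_bread,1.95,0.4,0.5,0.4
wholemeal_bread,0.525,2.6,2.9,0.4
oats,0.15,1.0,0.8,0.5
brown_rice,0.188,1.0,1.1,0.5
pasta,0.45,0.25,0.2,0.5
potatoes,0.6,0.4,0.6,0.5
lentils,0.045,0.18,0.2,0.6
baked_beans,0.112,0.08,0.1,0.6
tofu,0.008,0.04,0.1,0.8
peas,0.225,0.5,0.35,0.5
mixed_nuts,0.045,0.2,0.18,0.7
peanut_butter,0.112,0.05,0.04,0.7
apple,0.25,0.5,0.55,0.5
banana,0.28,0.45,0.5,0.5
orange,0.112,0.15,0.2,0.6
fruit_juice,0.2,0.35,0.4,0.6
spinach,0.09,0.6,0.35,0.6
carrots,0.262,0.75,0.45,0.5
broccoli,0.15,0.7,0.4,0.5
tomatoes,0.338,0.8,0.5,0.5
cola,0.9,0.1,0.12,0.7
chocolate_bar,0.75,0.25,0.2,0.5
crisps,0.638,0.25,0.25,0.5
table_sugar,2.2,0.4,0.5,0.8
soy_milk_fortified,0.02,0.1,0.3,0.5
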