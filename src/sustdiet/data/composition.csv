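item,portion_g,energy_kcal,protein_g,iron_mg,zinc_mg,selenium_ug,folate_ug,b12_ug,calcium_mg,copper_mg,magnesium_mg,iodine_ug,sfa_g,pufa_g,n3_long_g,trans_g,sodium_mg,added_sugar_g
beef_mince,100,250,26.0,2.7,6.0,10.0,10,2.5,18,0.06,21,10.0,9.0,0.5,0.0,0.4,75,0.0
bacon,30,300,30.0,1.0,3.0,20.0,2,0.8,10,0.08,20,10.0,12.0,1.5,0.0,0.3,1800,0.0
sausage,50,300,14.0,1.2,1.8,12.0,4,1.0,60,0.06,15,8.0,10.0,1.5,0.0,0.5,800,0.0
chicken_breast,120,165,31.0,0.4,1.0,16.0,8,0.4,6,0.05,28,7.0,1.0,0.8,0.02,0.05,65,0.0
cod,120,96,20.0,0.2,0.5,30.0,10,1.0,15,0.03,25,110.0,0.2,0.3,0.25,0.0,70,0.0
salmon,110,200,22.0,0.4,0.5,25.0,25,3.0,12,0.06,28,30.0,2.5,3.5,2.2,0.0,50,0.0
eggs,60,150,13.0,1.9,1.3,23.0,47,1.1,55,0.07,12,50.0,3.1,1.8,0.07,0.04,140,0.0
whole_milk,200,64,3.4,0.03,0.4,1.5,6,0.9,120,0.02,11,30.0,2.3,0.1,0.0,0.05,42,0.0
cheddar,30,416,25.0,0.7,4.0,12.0,30,1.1,740,0.03,28,40.0,21.0,0.9,0.0,0.8,650,0.0
yogurt,125,80,4.8,0.1,0.6,2.0,8,0.3,160,0.02,15,35.0,2.9,0.1,0.0,0.0,60,5.0
butter,10,740,0.6,0.02,0.1,1.0,1,0.1,15,0.01,2,40.0,52.0,2.8,0.0,2.0,600,0.0
olive_oil,11,884,0.0,0.3,0.0,0.0,0,0.0,1,0.02,0,0.0,14.0,10.0,0.0,0.0,0,0.0
sunflower_oil,11,884,0.0,0.0,0.0,0.0,0,0.0,0,0.0,0,0.0,11.0,63.0,0.0,0.0,0,0.0
margarine,10,720,0.2,0.0,0.0,0.0,0,0.0,10,0.0,2,0.0,18.0,24.0,0.0,1.5,700,0.0
white_bread,36,240,9.0,1.1,0.7,6.0,20,0.0,110,0.12,25,10.0,0.4,1.1,0.0,0.05,430,3.0
wholemeal_bread,36,230,11.0,2.4,1.8,20.0,25,0.0,106,0.23,76,5.0,0.5,1.6,0.0,0.05,400,2.0
oats,40,379,11.0,3.8,2.3,3.0,20,0.0,52,0.36,130,0.0,1.4,2.2,0.0,0.0,5,0.0
brown_rice,80,123,2.6,0.5,0.6,10.0,4,0.0,3,0.1,43,0.0,0.2,0.3,0.0,0.0,1,0.0
pasta,180,158,5.0,0.6,0.7,15.0,7,0.0,7,0.1,18,0.0,0.1,0.3,0.0,0.0,1,0.0
potatoes,180,87,2.0,0.4,0.3,0.5,10,0.0,5,0.1,21,2.0,0.1,0.1,0.0,0.0,7,0.0
lentils,120,116,9.0,3.3,1.3,3.0,20,0.0,19,0.25,36,0.0,0.1,0.2,0.0,0.0,2,0.0
baked_beans,200,81,5.0,1.4,0.7,2.0,15,0.0,48,0.14,31,2.0,0.1,0.3,0.0,0.0,400,2.5
tofu,100,118,12.0,1.6,0.8,9.0,19,0.0,350,0.19,58,0.0,0.7,2.7,0.0,0.0,12,0.0
peas,80,81,5.4,1.5,1.0,1.0,47,0.0,25,0.18,33,0.0,0.1,0.3,0.0,0.0,3,0.0
mixed_nuts,30,607,20.0,2.6,3.1,20.0,40,0.0,85,1.3,230,2.0,7.0,18.0,0.0,0.0,5,0.0
peanut_butter,20,588,25.0,1.7,2.7,6.0,50,0.0,49,0.6,160,0.0,10.0,12.0,0.0,0.0,400,2.0
apple,112,52,0.3,0.1,0.05,0.0,3,0.0,6,0.03,5,1.0,0.0,0.1,0.0,0.0,1,0.0
banana,100,89,1.1,0.3,0.2,1.0,15,0.0,5,0.08,27,2.0,0.1,0.1,0.0,0.0,1,0.0
orange,160,47,0.9,0.1,0.1,0.5,25,0.0,40,0.05,10,2.0,0.0,0.0,0.0,0.0,0,0.0
fruit_juice,200,44,0.5,0.2,0.05,0.1,12,0.0,9,0.03,10,1.0,0.0,0.0,0.0,0.0,2,8.0
spinach,80,23,2.9,2.7,0.5,1.0,120,0.0,99,0.13,79,2.0,0.1,0.2,0.0,0.0,79,0.0
carrots,80,41,0.9,0.3,0.2,0.1,12,0.0,33,0.05,12,2.0,0.0,0.1,0.0,0.0,69,0.0
broccoli,85,34,2.8,0.7,0.4,2.5,60,0.0,47,0.05,21,0.3,0.1,0.1,0.0,0.0,33,0.0
tomatoes,85,18,0.9,0.3,0.2,0.0,12,0.0,10,0.06,11,2.0,0.0,0.1,0.0,0.0,5,0.0
cola,330,42,0.0,0.0,0.0,0.0,0,0.0,2,0.0,1,0.0,0.0,0.0,0.0,0.0,4,10.6
chocolate_bar,45,534,7.3,2.4,2.0,4.0,10,0.6,189,0.7,63,10.0,18.0,1.4,0.0,0.1,79,47.0
crisps,25,530,6.0,1.2,0.9,3.0,28,0.0,30,0.3,50,2.0,2.5,8.0,0.0,0.1,520,0.0
table_sugar,5,400,0.0,0.0,0.0,0.0,0,0.0,0,0.0,0,0.0,0.0,0.0,0.0,0.0,0,100.0
soy_milk_fortified,200,40,3.0,0.4,0.3,2.0,15,0.4,120,0.04,14,30.0,0.3,1.1,0.0,0.0,40,1.5
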