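nutrient,male,female
protein_g,55.5,45.0
iron_mg,8.7,14.8
zinc_mg,9.5,7.0
selenium_ug,75,60
folate_ug,200,200
b12_ug,1.5,1.5
calcium_mg,700,700
copper_mg,1.2,1.2
magnesium_mg,300,270
iodine_ug,140,140
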