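group,health_class,environmental_impact,direction,anchor_0,anchor_10,ref_min,ref_opt,ref_max,units
whole_grains,protective,low,increasing,0,232,100,232,300,g/day
vegetables,protective,low,increasing,0,300,200,300,600,g/day
fruits,protective,low,increasing,0,200,100,200,300,g/day
dairy,neutral,medium,range,1000,250,250,375,500,g/day
red_meat,limited,high,decreasing,100,28,0,14,28,g/day
fish,protective,medium,increasing,0,28,0,28,100,g/day
eggs,neutral,medium,decreasing,75,25,0,13,25,g/day
poultry,neutral,high,decreasing,116,58,0,29,58,g/day
legumes,protective,low,increasing,0,75,0,75,100,g/day
nuts,protective,low,increasing,0,50,25,50,75,g/day
unsaturated_oils,protective,medium,increasing,0,40,20,40,80,g/day
saturated_oils,limited,high,decreasing,47,11.8,0,5.9,11.8,g/day
added_sugars,limited,low,decreasing,124,31,0,15.5,31,g/day
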