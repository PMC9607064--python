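component,direction,anchor_0,anchor_10,units
vegetables,increasing,0,5,servings/day
fruit,increasing,0,4,servings/day
whole_grains,increasing,0,75,g/day
nuts_legumes,increasing,0,1,servings/day
n3_long,increasing,0,250,mg/day
pufa_pct_energy,increasing,2,10,pct_energy
ssb,decreasing,1,0,servings/day
red_processed_meat,decreasing,1.5,0,servings/day
trans_pct_energy,decreasing,4,0.5,pct_energy
sodium,decreasing,3337,1112,mg/day
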