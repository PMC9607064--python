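code,label,multiplier
0,never or less than once per month,0
1,1-3 per month,0.067
2,once a week,0.143
3,2-4 per week,0.429
4,5-6 per week,0.786
5,once a day,1
6,2-3 per day,2.5
7,4-5 per day,4.5
8,6+ per day,6
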