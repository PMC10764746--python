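level,material,class,value,stars,ee1,ee1_stars,ee2,ee2_stars,ee3,ee3_stars
additive,Ehd1-2,a,2.1,*,,,,,,
additive,OsMADS50-2,a,-6.1,**,-1.9,*,,,,
additive,Hd3a-2,a,5.6,**,,,,,,
additive,Hd1-2,a,,,,,,,,
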