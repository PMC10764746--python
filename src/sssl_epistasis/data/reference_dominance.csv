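level,material,class,value,stars,ee1,ee1_stars,ee2,ee2_stars,ee3,ee3_stars
dominance,Ehd1-1,d,2.7,**,-2.3,*,2.6,*,,
dominance,OsMADS50-1,d,-8.0,**,,,,,,
dominance,Hd3a-1,d,18.5,**,-2.4,*,,,,
dominance,Hd1-1,d,1.7,*,,,,,,
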