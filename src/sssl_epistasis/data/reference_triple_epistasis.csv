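level,material,class,value,stars,ee1,ee1_stars,ee2,ee2_stars,ee3,ee3_stars
triple_epistasis,Ehd1-1/OsMADS50-1/Hd3a-1,d-d-d,16.8,**,-5.6,*,7.5,**,,
triple_epistasis,Ehd1-1/OsMADS50-1/Hd3a-2,d-d-a,-9.7,**,7.4,**,,,,
triple_epistasis,Ehd1-1/OsMADS50-1/Hd1-1,d-d-d,,,,,,,,
triple_epistasis,Ehd1-1/OsMADS50-1/Hd1-2,d-d-a,8.9,**,,,,,,
triple_epistasis,Ehd1-1/OsMADS50-2/Hd3a-1,d-a-d,19.0,**,,,,,,
triple_epistasis,Ehd1-1/OsMADS50-2/Hd3a-2,d-a-a,-9.3,**,-6.0,*,,,,
triple_epistasis,Ehd1-1/OsMADS50-2/Hd1-1,d-a-d,4.8,**,,,,,,
triple_epistasis,Ehd1-1/OsMADS50-2/Hd1-2,d-a-a,3.3,*,,,,,,
triple_epistasis,Ehd1-1/Hd3a-1/Hd1-1,d-d-d,16.3,**,,,,,,
triple_epistasis,Ehd1-1/Hd3a-1/Hd1-2,d-d-a,,,,,,,,
triple_epistasis,Ehd1-1/Hd3a-2/Hd1-1,d-a-d,-8.8,**,-5.9,*,7.0,**,,
triple_epistasis,Ehd1-1/Hd3a-2/Hd1-2,d-a-a,-7.5,**,-5.7,*,9.0,**,,
triple_epistasis,Ehd1-2/OsMADS50-1/Hd3a-1,a-d-d,11.1,**,,,,,,
triple_epistasis,Ehd1-2/OsMADS50-1/Hd3a-2,a-d-a,-12.6,**,,,,,,
triple_epistasis,Ehd1-2/OsMADS50-1/Hd1-1,a-d-d,,,,,,,,
triple_epistasis,Ehd1-2/OsMADS50-1/Hd1-2,a-d-a,6.4,**,,,,,,
triple_epistasis,Ehd1-2/OsMADS50-2/Hd3a-1,a-a-d,14.0,**,,,,,,
triple_epistasis,Ehd1-2/OsMADS50-2/Hd3a-2,a-a-a,-8.7,**,,,,,,
triple_epistasis,Ehd1-2/OsMADS50-2/Hd1-1,a-a-d,4.5,**,,,,,,
triple_epistasis,Ehd1-2/OsMADS50-2/Hd1-2,a-a-a,,,,,,,,
triple_epistasis,Ehd1-2/Hd3a-1/Hd1-1,a-d-d,16.6,**,,,,,,
triple_epistasis,Ehd1-2/Hd3a-1/Hd1-2,a-d-a,,,,,,,,
triple_epistasis,Ehd1-2/Hd3a-2/Hd1-1,a-a-d,-10.1,**,-5.5,*,6.8,**,,
triple_epistasis,Ehd1-2/Hd3a-2/Hd1-2,a-a-a,-8.2,**,-5.3,*,9.0,**,,
triple_epistasis,OsMADS50-1/Hd3a-1/Hd1-1,d-d-d,13.1,**,,,,,,
triple_epistasis,OsMADS50-1/Hd3a-1/Hd1-2,d-d-a,8.6,**,,,,,,
triple_epistasis,OsMADS50-1/Hd3a-2/Hd1-1,d-a-d,-12.5,**,,,,,,
triple_epistasis,OsMADS50-1/Hd3a-2/Hd1-2,d-a-a,-7.0,**,10.7,**,,,,
triple_epistasis,OsMADS50-2/Hd3a-1/Hd1-1,a-d-d,20.0,**,,,,,,
triple_epistasis,OsMADS50-2/Hd3a-1/Hd1-2,a-d-a,6.1,**,,,,,,
triple_epistasis,OsMADS50-2/Hd3a-2/Hd1-1,a-a-d,-6.0,**,-5.1,*,5.7,*,,
triple_epistasis,OsMADS50-2/Hd3a-2/Hd1-2,a-a-a,-4.2,**,-10.4,**,12.6,**,,
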