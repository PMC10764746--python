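level,material,class,value,stars,ee1,ee1_stars,ee2,ee2_stars,ee3,ee3_stars
mixed_epistasis,Ehd1-1/OsMADS50-1/Hd3a-1,d-d-d,-13.4,**,-4.5,*,,,,
mixed_epistasis,Ehd1-1/OsMADS50-1/Hd3a-2,d-d-a,19.1,**,,,,,,
mixed_epistasis,Ehd1-1/OsMADS50-1/Hd1-1,d-d-d,-3.0,*,,,,,,
mixed_epistasis,Ehd1-1/OsMADS50-1/Hd1-2,d-d-a,,,,,,,,
mixed_epistasis,Ehd1-1/OsMADS50-2/Hd3a-1,d-a-d,-18.0,**,,,,,,
mixed_epistasis,Ehd1-1/OsMADS50-2/Hd3a-2,d-a-a,-5.3,**,,,,,,
mixed_epistasis,Ehd1-1/OsMADS50-2/Hd1-1,d-a-d,-3.8,**,,,,,,
mixed_epistasis,Ehd1-1/OsMADS50-2/Hd1-2,d-a-a,-6.2,**,4.8,*,-5.3,*,,
mixed_epistasis,Ehd1-1/Hd3a-1/Hd1-1,d-d-d,-17.6,**,-4.8,*,,,,
mixed_epistasis,Ehd1-1/Hd3a-1/Hd1-2,d-d-a,-16.4,**,,,,,,
mixed_epistasis,Ehd1-1/Hd3a-2/Hd1-1,d-a-d,9.9,**,4.4,*,-6.7,**,,
mixed_epistasis,Ehd1-1/Hd3a-2/Hd1-2,d-a-a,10.2,**,,,,,,
mixed_epistasis,Ehd1-2/OsMADS50-1/Hd3a-1,a-d-d,-11.8,**,-4.8,*,5.9,*,,
mixed_epistasis,Ehd1-2/OsMADS50-1/Hd3a-2,a-d-a,13.6,**,,,,,,
mixed_epistasis,Ehd1-2/OsMADS50-1/Hd1-1,a-d-d,,,,,,,,
mixed_epistasis,Ehd1-2/OsMADS50-1/Hd1-2,a-d-a,,,,,,,,
mixed_epistasis,Ehd1-2/OsMADS50-2/Hd3a-1,a-a-d,-15.6,**,,,,,,
mixed_epistasis,Ehd1-2/OsMADS50-2/Hd3a-2,a-a-a,7.6,**,,,,,,
mixed_epistasis,Ehd1-2/OsMADS50-2/Hd1-1,a-a-d,-3.1,*,,,,,,
mixed_epistasis,Ehd1-2/OsMADS50-2/Hd1-2,a-a-a,-2.7,**,-4.8,*,,,,
mixed_epistasis,Ehd1-2/Hd3a-1/Hd1-1,a-d-d,-12.8,**,,,,,,
mixed_epistasis,Ehd1-2/Hd3a-1/Hd1-2,a-d-a,-13.6,**,,,,,,
mixed_epistasis,Ehd1-2/Hd3a-2/Hd1-1,a-a-d,13.3,**,-4.6,*,,,,
mixed_epistasis,Ehd1-2/Hd3a-2/Hd1-2,a-a-a,15.1,**,,,,,,
mixed_epistasis,OsMADS50-1/Hd3a-1/Hd1-1,d-d-d,-16.0,**,,,,,,
mixed_epistasis,OsMADS50-1/Hd3a-1/Hd1-2,d-d-a,-14.2,**,4.4,*,,,,
mixed_epistasis,OsMADS50-1/Hd3a-2/Hd1-1,d-a-d,3.6,**,-4.4,*,,,,
mixed_epistasis,OsMADS50-1/Hd3a-2/Hd1-2,d-a-a,6.2,**,,,,,,
mixed_epistasis,OsMADS50-2/Hd3a-1/Hd1-1,a-d-d,-18.5,**,,,,,,
mixed_epistasis,OsMADS50-2/Hd3a-1/Hd1-2,a-d-a,-18.5,**,,,,,,
mixed_epistasis,OsMADS50-2/Hd3a-2/Hd1-1,a-a-d,8.2,**,-5.3,*,,,,
mixed_epistasis,OsMADS50-2/Hd3a-2/Hd1-2,a-a-a,4.2,*,,,,,,
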