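level,material,class,value,stars,ee1,ee1_stars,ee2,ee2_stars,ee3,ee3_stars
dual_epistasis,Ehd1-1/OsMADS50-1,d-d,3.5,*,-3.4,*,,,,
dual_epistasis,Ehd1-2/OsMADS50-1,a-d,2.7,**,,,,,,
dual_epistasis,Ehd1-1/OsMADS50-2,d-a,-3.2,**,,,,,,
dual_epistasis,Ehd1-2/OsMADS50-2,a-a,,,,,,,,
dual_epistasis,Ehd1-1/Hd3a-1,d-d,-15.2,**,,,,,,
dual_epistasis,Ehd1-2/Hd3a-1,a-d,-12.2,**,3.7,*,,,,
dual_epistasis,Ehd1-1/Hd3a-2,d-a,13.0,**,-3.5,*,,,,
dual_epistasis,Ehd1-2/Hd3a-2,a-a,16.2,**,4.1,*,,,,
dual_epistasis,Ehd1-1/Hd1-1,d-d,-3.4,**,3.3,*,-3.1,*,,
dual_epistasis,Ehd1-2/Hd1-1,a-d,,,,,,,,
dual_epistasis,Ehd1-1/Hd1-2,d-a,,,,,,,,
dual_epistasis,Ehd1-2/Hd1-2,a-a,,,,,,,,
dual_epistasis,OsMADS50-1/Hd3a-1,d-d,-13.5,**,3.5,*,,,,
dual_epistasis,OsMADS50-2/Hd3a-1,a-d,-18.6,**,,,,,,
dual_epistasis,OsMADS50-1/Hd3a-2,d-a,7.2,**,,,,,,
dual_epistasis,OsMADS50-2/Hd3a-2,a-a,6.4,**,-3.6,*,,,,
dual_epistasis,OsMADS50-1/Hd1-1,d-d,,,,,,,,
dual_epistasis,OsMADS50-2/Hd1-1,a-d,-4.6,**,,,,,,
dual_epistasis,OsMADS50-1/Hd1-2,d-a,-7.6,**,,,,,,
dual_epistasis,OsMADS50-2/Hd1-2,a-a,-4.4,**,,,,,,
dual_epistasis,Hd3a-1/Hd1-1,d-d,-15.3,**,,,,,,
dual_epistasis,Hd3a-2/Hd1-1,a-d,9.1,**,5.0,**,-7.1,**,,
dual_epistasis,Hd3a-1/Hd1-2,d-a,,,,,,,,
dual_epistasis,Hd3a-2/Hd1-2,a-a,6.6,**,7.3,**,-9.7,**,,
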