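level,material,class,value,stars,ee1,ee1_stars,ee2,ee2_stars,ee3,ee3_stars
pyramiding,Ehd1-1/OsMADS50-1,d-d,-6.8,**,3.2,*,,,,
pyramiding,Ehd1-1/OsMADS50-2,d-a,-6.6,**,,,,,,
pyramiding,Ehd1-1/Hd3a-1,d-d,6.0,**,3.2,*,,,,
pyramiding,Ehd1-1/Hd3a-2,d-a,21.3,**,,,,,,
pyramiding,Ehd1-1/Hd1-1,d-d,,,,,,,,
pyramiding,Ehd1-1/Hd1-2,d-a,1.7,*,-2.9,*,3.2,*,,
pyramiding,Ehd1-2/OsMADS50-1,a-d,-3.9,**,-3.4,**,,,,
pyramiding,Ehd1-2/OsMADS50-2,a-a,-5.9,**,-2.6,*,,,,
pyramiding,Ehd1-2/Hd3a-1,a-d,7.6,**,-2.8,*,2.5,*,,
pyramiding,Ehd1-2/Hd3a-2,a-a,23.2,**,-4.4,**,2.5,*,,
pyramiding,Ehd1-2/Hd1-1,a-d,,,,,,,,
pyramiding,Ehd1-2/Hd1-2,a-a,2.7,**,-2.9,*,2.6,*,,
pyramiding,OsMADS50-1/Hd3a-1,d-d,-3.0,**,,,,,,
pyramiding,OsMADS50-1/Hd3a-2,d-a,4.8,**,,,,,,
pyramiding,OsMADS50-1/Hd1-1,d-d,-6.6,**,,,,,,
pyramiding,OsMADS50-1/Hd1-2,d-a,-7.6,**,2.6,*,,,,
pyramiding,OsMADS50-2/Hd3a-1,a-d,-6.2,**,,,,,,
pyramiding,OsMADS50-2/Hd3a-2,a-a,3.6,**,-2.8,*,,,,
pyramiding,OsMADS50-2/Hd1-1,a-d,-9.0,**,,,,,,
pyramiding,OsMADS50-2/Hd1-2,a-a,-9.5,**,,,,,,
pyramiding,Hd3a-1/Hd1-1,d-d,4.9,**,,,,,,
pyramiding,Hd3a-1/Hd1-2,d-a,5.7,**,,,,,,
pyramiding,Hd3a-2/Hd1-1,a-d,16.4,**,2.7,*,-4.9,**,,
pyramiding,Hd3a-2/Hd1-2,a-a,13.1,**,5.7,**,-7.9,**,,
pyramiding,Ehd1-1/OsMADS50-1/Hd3a-1,d-d-d,-5.6,**,6.0,**,,,,
pyramiding,Ehd1-1/OsMADS50-1/Hd3a-2,d-d-a,9.4,**,-3.1,*,3.1,*,,
pyramiding,Ehd1-1/OsMADS50-1/Hd1-1,d-d-d,-6.6,**,,,,,,
pyramiding,Ehd1-1/OsMADS50-1/Hd1-2,d-d-a,-6.5,**,2.5,*,,,,
pyramiding,Ehd1-1/OsMADS50-2/Hd3a-1,d-a-d,-2.9,**,,,,,,
pyramiding,Ehd1-1/OsMADS50-2/Hd3a-2,d-a-a,3.9,**,,,,,,
pyramiding,Ehd1-1/OsMADS50-2/Hd1-1,d-a-d,-8.2,**,,,,,,
pyramiding,Ehd1-1/OsMADS50-2/Hd1-2,d-a-a,-8.7,**,,,,,,
pyramiding,Ehd1-1/Hd3a-1/Hd1-1,d-d-d,5.3,**,,,,,,
pyramiding,Ehd1-1/Hd3a-1/Hd1-2,d-d-a,5.7,**,,,,,,
pyramiding,Ehd1-1/Hd3a-2/Hd1-1,d-a-d,19.9,**,,,,,,
pyramiding,Ehd1-1/Hd3a-2/Hd1-2,d-a-a,19.4,**,,,,,,
pyramiding,Ehd1-2/OsMADS50-1/Hd3a-1,a-d-d,-4.7,**,2.5,*,,,,
pyramiding,Ehd1-2/OsMADS50-1/Hd3a-2,a-d-a,12.5,**,-4.2,**,2.9,*,,
pyramiding,Ehd1-2/OsMADS50-1/Hd1-1,a-d-d,-5.2,**,3.0,*,,,,
pyramiding,Ehd1-2/OsMADS50-1/Hd1-2,a-d-a,-3.8,**,,,,,,
pyramiding,Ehd1-2/OsMADS50-2/Hd3a-1,a-a-d,-1.9,*,,,,,,
pyramiding,Ehd1-2/OsMADS50-2/Hd3a-2,a-a-a,8.4,**,-3.1,*,,,,
pyramiding,Ehd1-2/OsMADS50-2/Hd1-1,a-a-d,-6.2,**,,,,,,
pyramiding,Ehd1-2/OsMADS50-2/Hd1-2,a-a-a,-6.6,**,3.0,*,,,,
pyramiding,Ehd1-2/Hd3a-1/Hd1-1,a-d-d,8.7,**,-2.9,*,2.6,*,,
pyramiding,Ehd1-2/Hd3a-1/Hd1-2,a-d-a,7.1,**,,,,,,
pyramiding,Ehd1-2/Hd3a-2/Hd1-1,a-a-d,21.9,**,,,,,,
pyramiding,Ehd1-2/Hd3a-2/Hd1-2,a-a-a,22.9,**,-2.5,*,,,,
pyramiding,OsMADS50-1/Hd3a-1/Hd1-1,d-d-d,-3.8,**,,,,,,
pyramiding,OsMADS50-1/Hd3a-1/Hd1-2,d-d-a,-2.8,**,2.7,*,,,,
pyramiding,OsMADS50-1/Hd3a-2/Hd1-1,d-a-d,2.9,**,,,,,,
pyramiding,OsMADS50-1/Hd3a-2/Hd1-2,d-a-a,4.7,**,,,,,,
pyramiding,OsMADS50-2/Hd3a-1/Hd1-1,a-d-d,-4.4,**,,,,,,
pyramiding,OsMADS50-2/Hd3a-1/Hd1-2,a-d-a,-5.2,**,,,,,,
pyramiding,OsMADS50-2/Hd3a-2/Hd1-1,a-a-d,4.0,**,-2.6,*,,,,
pyramiding,OsMADS50-2/Hd3a-2/Hd1-2,a-a-a,,,,,,,,
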