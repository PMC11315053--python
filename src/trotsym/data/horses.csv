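horse_id,sex,breed,age_years,time_in_shoes,competition_level
1000,Gelding,Dutch Warmblood,8,>12 shoeing cycles,>1.40 m
1001,Gelding,Dutch Warmblood,13,>12 shoeing cycles,>1.45 m
1002,Mare,Dutch Warmblood,7,>12 shoeing cycles,>1.40 m
1003,Gelding,Dutch Warmblood,11,>12 shoeing cycles,>1.30 m
1005,Gelding,Dutch Warmblood,11,>12 shoeing cycles,>1.30 m
1007,Gelding,Dutch Warmblood,11,6th shoeing cycle,>1.50 m
1008,Gelding,Dutch Warmblood,12,6th shoeing cycle,>1.30 m
1009,Mare,Dutch Warmblood,8,>12 shoeing cycles,>1.20 m
1010,Gelding,Dutch Warmblood,11,>12 shoeing cycles,>1.20 m
1011,Mare,Dutch Warmblood,10,>12 shoeing cycles,>1.20 m
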