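specimen_id,pre_ccn,pre_thick,post1_ccn,post1_thick,post2_ccn,post2_thick
1,795.0,3.67,758.0,3.65,799.6,3.52
2,825.4,3.73,812.6,4.15,796.0,4.14
3,860.5,4.72,806.9,4.82,855.6,4.59
4,781.8,3.63,750.9,3.57,812.6,3.55
5,819.8,3.35,773.2,3.72,797.8,3.43
6,708.0,2.61,687.5,2.31,699.5,2.38
7,815.3,3.42,747.1,3.41,788.7,3.37
8,810.3,3.51,754.8,3.50,764.5,3.42
9,866.7,3.99,821.0,4.13,821.5,4.16
10,780.3,3.12,775.7,3.01,744.8,3.19
11,800.0,4.16,804.3,3.99,805.2,4.12
12,797.4,3.55,764.8,3.40,787.1,3.45
13,823.0,4.30,812.4,3.96,795.9,4.21
14,865.9,4.47,815.0,4.23,848.8,4.17
15,772.4,3.90,798.3,3.52,829.4,3.54
16,849.9,4.45,850.3,4.29,855.0,4.25
17,781.0,2.98,726.9,2.94,783.6,2.87
18,806.3,3.44,749.8,3.48,803.2,3.42
19,846.6,4.20,815.3,4.26,840.9,4.19
20,740.2,2.85,737.7,2.65,748.9,2.71
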