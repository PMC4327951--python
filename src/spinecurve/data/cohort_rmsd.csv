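patient,sex,age_years,height_cm,weight_kg,bmi,rmsd_xy_mm,rmsd_xz_mm
1,F,42,168,83,29.4,7.68,1.34
2,F,32,156,59,24.2,2.38,0.60
3,F,34,154,53,22.3,4.36,0.51
4,M,45,173,57,19.0,4.04,0.51
5,F,52,175,70,22.9,7.48,1.54
6,F,50,170,65,22.5,4.17,1.25
7,M,18,169,65,22.8,3.32,0.53
8,F,62,154,64,27.0,4.30,2.31
9,F,69,159,69,27.3,3.85,0.70
10,M,58,168,82,29.1,3.56,0.69
11,F,82,158,72,28.8,7.43,0.91
12,F,17,173,68,22.7,3.80,0.69
13,F,16,169,58,20.3,3.37,0.75
14,F,17,167,69,24.7,7.75,0.51
15,F,55,155,55,22.9,3.27,0.60
16,F,38,179,52,16.2,3.78,0.66
17,F,30,172,89,30.1,5.94,0.63
18,F,49,169,52,18.2,4.98,1.40
19,F,25,170,54,18.7,4.39,0.83
20,F,29,167,60,21.5,3.76,0.72
21,F,52,162,60,22.9,3.84,0.58
22,F,29,170,72,24.9,4.54,1.24
23,F,50,164,65,24.2,4.42,0.62
24,F,16,173,58,19.4,4.71,1.10
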