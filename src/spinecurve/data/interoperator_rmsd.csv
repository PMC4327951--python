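operator,repeat,rmsd_xy_mm,rmsd_xz_mm
1,1,4.60,0.75
1,2,4.59,0.74
1,3,4.61,0.75
2,1,4.70,0.76
2,2,4.69,0.76
2,3,4.65,0.75
3,1,4.63,0.75
3,2,4.67,0.76
3,3,4.65,0.75
4,1,4.58,0.75
4,2,4.62,0.75
4,3,4.59,0.75
5,1,4.67,0.75
5,2,4.69,0.76
5,3,4.65,0.75
6,1,4.61,0.75
6,2,4.64,0.76
6,3,4.65,0.76
7,1,4.68,0.75
7,2,4.68,0.76
7,3,4.67,0.75
8,1,4.68,0.76
8,2,4.69,0.76
8,3,4.66,0.76
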