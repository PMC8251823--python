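plot_id,R,habitat_ha,density,n
1,1.02,1242,1.17,82
2,1.22,1044,0.62,80
3,1.09,885,0.92,33
4,0.94,805,1.13,42
5,0.75,1172,0.50,41
6,0.62,1101,0.43,23
7,0.89,924,0.76,22
8,1.07,929,1.62,39
9,0.77,1139,1.06,35
10,0.60,1112,0.36,34
11,0.88,678,0.88,44
12,0.90,1202,0.52,31
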