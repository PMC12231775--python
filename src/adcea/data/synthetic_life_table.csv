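age,death_prob
40,0.0010913670260126462
41,0.0012060778547253737
42,0.0013328376027486044
43,0.0014729100756265545
44,0.0016276912446913094
45,0.0017987229813425376
46,0.0019877081991863665
47,0.002196527544033655
48,0.0024272577847086474
49,0.002682192071543077
50,0.0029638622443498575
51,0.003275063387576993
52,0.003618880847225725
53,0.003998719941926576
54,0.00441833861921026
55,0.004881883327357839
56,0.005393928393078062
57,0.00595951921534521
58,0.0065842196057003255
59,0.007274163624650831
60,0.008036112281886831
61,0.008877515484026932
62,0.009806579626473577
63,0.010832341234373044
64,0.011964747059977188
65,0.01321474103784015
66,0.014594358482692638
67,0.016116827884400053
68,0.017796680606289472
69,0.01964986872268959
70,0.021693891133141352
71,0.02394792795767009
72,0.026432983041718816
73,0.02917203417127978
74,0.0321901903072247
75,0.0355148547797004
76,0.03917589292361312
77,0.04320580206733704
78,0.04763988108932726
79,0.0525163959096121
80,0.05787673626160161
81,0.06376555786932403
82,0.0702309027106901
83,0.07732428835422822
84,0.0851007553935974
85,0.09361885975590567
86,0.10294059412175671
87,0.11313121987857488
88,0.12425898796968271
89,0.13639472376927841
90,0.14961124782379598
91,0.163982601130921
92,0.17958304083666343
93,0.19648577017724067
94,0.2147613656584091
95,0.23447586547817012
96,0.25568848685174816
97,0.27844894715695157
98,0.3027943758185082
99,0.3287458218622178
100,0.35630438742658943
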