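rank,name,D,zeta,ic50_predicted
1,Kojic acid,0.028,0.238333,-112089.011
2,Chrysin,0.004082228,0.202216066,-40655.55419
3,Shikonin,0.028074722,0.193499615,-33061.25049
4,Baicalein,0.00625,0.19833325,-26435.10902
5,Galangin,0.00725,0.18,-14014.27835
6,Dihydromyricetin,0.022355552,0.149968431,-9665.559405
7,Naphthazarin,0.020408163,0.193877551,-3748.192859
8,Xanthoxylin,0.036443149,0.147959184,-2455.072672
9,Tropolone,0.008230453,0.222222222,-1193.329897
10,Morin,0.017843727,0.170110186,35.71991087
11,Quercetin,0.018407213,0.177341598,93.33756038
12,Quercetin-3-rutinoside,0.018407213,0.177341591,93.33764064
13,Taxfolin,0.018407213,0.177341529,93.33836295
14,Rhamnetin,0.016931043,0.187775677,105.5945071
15,Dihydroquercetin-4'-methylether,0.016848853,0.187145558,113.0227843
16,Tamarixetin,0.016931043,0.193761815,147.3433049
17,"Dihydroquercetin-7,4'-dimethylether",0.015552662,0.1953125,162.703958
18,Luteolin,0.015117158,0.197656841,259.6199685
19,Luteolin-7-methyl ether,0.013899324,0.202479339,352.5847798
20,"5,7,3',5'-Tetrahydroxyflavanone",0.014685239,0.155706727,427.3532608
21,Blumeatin,0.013429752,0.164600551,617.4170072
22,Apigenin,0.0105,0.21916667,4333.366225
23,Fisetin,0.01425332,0.212018141,4757.002259
24,Rosmarinic acid,0.020197997,0.250493047,6636.142322
25,"3,7,4'-Trihydroxyflavone",0.01025,0.2352,27875.46695
26,Isoeugenol,0.020833333,0.275462986,33581.06508
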