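name,D,zeta,ic50
Dihydroquercetin-4'-methylether,0.016848853,0.187145558,115
"Dihydroquercetin-7,4'-dimethylether",0.015552662,0.1953125,162
"5,7,3',5'-Tetrahydroxyflavanone",0.014685239,0.155706727,423
Blumeatin,0.013429752,0.164600551,624
Quercetin,0.018407213,0.177341598,96
Rhamnetin,0.016931043,0.187775677,107
Tamarixetin,0.016931043,0.193761815,144
Luteolin,0.015117158,0.197656841,258
Luteolin-7-methyl ether,0.013899324,0.202479339,350
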