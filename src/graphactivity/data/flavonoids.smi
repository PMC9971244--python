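# Hydrogen-suppressed structures of the 26 screening-set compounds,
# encoded from the standard published structures of the named molecules.
# Format: SMILES<TAB>name
OCC1=CC(=O)C(O)=CO1	Kojic acid
O=c1cc(-c2ccccc2)oc2cc(O)cc(O)c12	Chrysin
CC(C)=CCC(O)C1=CC(=O)c2c(O)ccc(O)c2C1=O	Shikonin
O=c1cc(-c2ccccc2)oc2cc(O)c(O)c(O)c12	Baicalein
O=c1c(O)c(-c2ccccc2)oc2cc(O)cc(O)c12	Galangin
O=C1c2c(O)cc(O)cc2OC(c2cc(O)c(O)c(O)c2)C1O	Dihydromyricetin
O=C1C=CC(=O)c2c(O)ccc(O)c21	Naphthazarin
CC(=O)c1c(O)cc(OC)cc1OC	Xanthoxylin
O=C1C=CC=CC=C1O	Tropolone
O=c1c(O)c(-c2ccc(O)cc2O)oc2cc(O)cc(O)c12	Morin
O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	Quercetin
CC1OC(OCC2OC(Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)C(O)C(O)C2O)C(O)C(O)C1O	Quercetin-3-rutinoside
O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)C1O	Taxfolin
COc1cc(O)c2c(c1)oc(-c1ccc(O)c(O)c1)c(O)c2=O	Rhamnetin
COc1ccc(C2Oc3cc(O)cc(O)c3C(=O)C2O)cc1O	Dihydroquercetin-4'-methylether
COc1ccc(-c2oc3cc(O)cc(O)c3c(=O)c2O)cc1O	Tamarixetin
COc1ccc(C2Oc3cc(OC)cc(O)c3C(=O)C2O)cc1O	Dihydroquercetin-7,4'-dimethylether
O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	Luteolin
COc1cc(O)c2c(=O)cc(-c3ccc(O)c(O)c3)oc2c1	Luteolin-7-methyl ether
O=C1CC(c2cc(O)cc(O)c2)Oc2cc(O)cc(O)c21	5,7,3',5'-Tetrahydroxyflavanone
COc1cc(O)c2c(c1)OC(c1cc(O)cc(O)c1)CC2=O	Blumeatin
O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12	Apigenin
O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)ccc12	Fisetin
O=C(O)C(Cc1ccc(O)c(O)c1)OC(=O)C=Cc1ccc(O)c(O)c1	Rosmarinic acid
O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)ccc12	3,7,4'-Trihydroxyflavone
CC=Cc1ccc(O)c(OC)c1	Isoeugenol
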