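# Cumulative formation constants (log10 beta, molar scale, 25 C, I ~ 0.1 M unless noted)
# for the Gd(III) / Ca(II) / Zn(II) -- synthetic chelator -- endogenous ligand system at
# physiological pH. Hydroxide species are encoded with negative proton stoichiometry
# (log *beta convention); the water ionization constant is the table-level pKw below.
#
# Component declarations: "#! name charge kind"
#! H	+1	proton
#! Gd	+3	metal
#! Ca	+2	metal
#! Zn	+2	metal
#! HOPO	-4	synthetic_chelator
#! DTPA	-5	synthetic_chelator
#! DOTA	-4	synthetic_chelator
#! DTPA-BMA	-3	synthetic_chelator
#! EDTA	-4	synthetic_chelator
#! PO4	-3	endogenous_ligand
#! CO3	-2	endogenous_ligand
#! Cit	-3	endogenous_ligand
#! Ox	-2	endogenous_ligand
#! Lac	-1	endogenous_ligand
#@ pKw	13.78
label	log_beta	H	Gd	Ca	Zn	HOPO	DTPA	DOTA	DTPA-BMA	EDTA	PO4	CO3	Cit	Ox	Lac	provenance
HHOPO	6.64	1	0	0	0	1	0	0	0	0	0	0	0	0	0	Sturzbecher-Hoehne 2011; highest pKa 6.6
H2HOPO	12.58	2	0	0	0	1	0	0	0	0	0	0	0	0	0	Sturzbecher-Hoehne 2011
H3HOPO	17.42	3	0	0	0	1	0	0	0	0	0	0	0	0	0	Sturzbecher-Hoehne 2011
H4HOPO	21.05	4	0	0	0	1	0	0	0	0	0	0	0	0	0	Sturzbecher-Hoehne 2011
HDTPA	10.40	1	0	0	0	0	1	0	0	0	0	0	0	0	0	highest pKa 10.4; Martell & Smith
H2DTPA	19.00	2	0	0	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith
H3DTPA	23.28	3	0	0	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith
H4DTPA	25.88	4	0	0	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith
H5DTPA	27.88	5	0	0	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith
HDOTA	11.20	1	0	0	0	0	0	1	0	0	0	0	0	0	0	highest pKa 11.2; NIST-selected
H2DOTA	20.90	2	0	0	0	0	0	1	0	0	0	0	0	0	0	NIST-selected
H3DOTA	25.40	3	0	0	0	0	0	1	0	0	0	0	0	0	0	NIST-selected
H4DOTA	29.54	4	0	0	0	0	0	1	0	0	0	0	0	0	0	NIST-selected
HDTPA-BMA	9.42	1	0	0	0	0	0	0	1	0	0	0	0	0	0	Paul-Roth & Raymond region; representative
H2DTPA-BMA	13.80	2	0	0	0	0	0	0	1	0	0	0	0	0	0	representative literature value
H3DTPA-BMA	17.11	3	0	0	0	0	0	0	1	0	0	0	0	0	0	representative literature value
HEDTA	10.19	1	0	0	0	0	0	0	0	1	0	0	0	0	0	Martell & Smith
H2EDTA	16.32	2	0	0	0	0	0	0	0	1	0	0	0	0	0	Martell & Smith
H3EDTA	19.01	3	0	0	0	0	0	0	0	1	0	0	0	0	0	Martell & Smith
H4EDTA	21.01	4	0	0	0	0	0	0	0	1	0	0	0	0	0	Martell & Smith
HPO4	12.35	1	0	0	0	0	0	0	0	0	1	0	0	0	0	Martell & Smith
H2PO4	19.55	2	0	0	0	0	0	0	0	0	1	0	0	0	0	Martell & Smith
H3PO4	21.70	3	0	0	0	0	0	0	0	0	1	0	0	0	0	Martell & Smith
HCO3	10.33	1	0	0	0	0	0	0	0	0	0	1	0	0	0	Martell & Smith
H2CO3	16.68	2	0	0	0	0	0	0	0	0	0	1	0	0	0	Martell & Smith (CO2(aq) convention)
HCit	6.40	1	0	0	0	0	0	0	0	0	0	0	1	0	0	Martell & Smith
H2Cit	11.16	2	0	0	0	0	0	0	0	0	0	0	1	0	0	Martell & Smith
H3Cit	14.29	3	0	0	0	0	0	0	0	0	0	0	1	0	0	Martell & Smith
HOx	4.27	1	0	0	0	0	0	0	0	0	0	0	0	1	0	Martell & Smith
H2Ox	5.52	2	0	0	0	0	0	0	0	0	0	0	0	1	0	Martell & Smith
HLac	3.86	1	0	0	0	0	0	0	0	0	0	0	0	0	1	Martell & Smith
GdHOPO	20.60	0	1	0	0	1	0	0	0	0	0	0	0	0	0	back-computed from reported pH-7.4 conditional constant 20.5(1) and the HOPO protonation ladder
GdDTPA	22.46	0	1	0	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith
GdHDTPA	24.85	1	1	0	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith (protonated complex)
GdDOTA	24.40	0	1	0	0	0	0	1	0	0	0	0	0	0	0	NIST-selected range 24.0-24.7; representative
GdDTPA-BMA	16.85	0	1	0	0	0	0	0	1	0	0	0	0	0	0	Cacheris 1990
GdEDTA	17.37	0	1	0	0	0	0	0	0	1	0	0	0	0	0	Martell & Smith
Gd(OH)	-8.20	-1	1	0	0	0	0	0	0	0	0	0	0	0	0	Baes & Mesmer hydrolysis, log *beta1
Gd(OH)2	-17.00	-2	1	0	0	0	0	0	0	0	0	0	0	0	0	Baes & Mesmer hydrolysis, log *beta2
Gd(CO3)	7.10	0	1	0	0	0	0	0	0	0	0	1	0	0	0	lanthanide carbonate, representative
Gd(CO3)2	12.90	0	1	0	0	0	0	0	0	0	0	2	0	0	0	lanthanide carbonate, representative
GdHPO4	17.55	1	1	0	0	0	0	0	0	0	1	0	0	0	0	Ln + HPO4 logK ~ 5.2; representative
GdH2PO4	21.45	2	1	0	0	0	0	0	0	0	1	0	0	0	0	Ln + H2PO4 logK ~ 1.9; representative
Gd(Cit)	7.83	0	1	0	0	0	0	0	0	0	0	0	1	0	0	Martell & Smith
Gd(Cit)2	13.90	0	1	0	0	0	0	0	0	0	0	0	2	0	0	lanthanide bis-citrate, representative
Gd(Ox)	6.00	0	1	0	0	0	0	0	0	0	0	0	0	1	0	lanthanide oxalate, representative
Gd(Ox)2	10.30	0	1	0	0	0	0	0	0	0	0	0	0	2	0	lanthanide oxalate, representative
Gd(Lac)	2.77	0	1	0	0	0	0	0	0	0	0	0	0	0	1	Martell & Smith
Gd(Lac)2	4.94	0	1	0	0	0	0	0	0	0	0	0	0	0	2	Martell & Smith
CaDTPA	10.75	0	0	1	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith
CaHDTPA	16.86	1	0	1	0	0	1	0	0	0	0	0	0	0	0	Martell & Smith (protonated complex)
CaDOTA	17.23	0	0	1	0	0	0	1	0	0	0	0	0	0	0	NIST-selected
CaDTPA-BMA	7.17	0	0	1	0	0	0	0	1	0	0	0	0	0	0	Cacheris 1990
CaEDTA	10.61	0	0	1	0	0	0	0	0	1	0	0	0	0	0	Martell & Smith
Ca(OH)	-12.60	-1	0	1	0	0	0	0	0	0	0	0	0	0	0	Baes & Mesmer hydrolysis
CaHCO3	11.43	1	0	1	0	0	0	0	0	0	0	1	0	0	0	Martell & Smith
Ca(CO3)	3.22	0	0	1	0	0	0	0	0	0	0	1	0	0	0	Martell & Smith
CaHPO4	15.09	1	0	1	0	0	0	0	0	0	1	0	0	0	0	Martell & Smith
Ca(Cit)	3.50	0	0	1	0	0	0	0	0	0	0	0	1	0	0	Martell & Smith
Ca(Ox)	3.00	0	0	1	0	0	0	0	0	0	0	0	0	1	0	Martell & Smith
Ca(Lac)	1.45	0	0	1	0	0	0	0	0	0	0	0	0	0	1	Martell & Smith
ZnDTPA	18.29	0	0	0	1	0	1	0	0	0	0	0	0	0	0	Martell & Smith
ZnHDTPA	23.89	1	0	0	1	0	1	0	0	0	0	0	0	0	0	Martell & Smith (protonated complex)
ZnDOTA	18.70	0	0	0	1	0	0	1	0	0	0	0	0	0	0	NIST-selected
ZnDTPA-BMA	12.04	0	0	0	1	0	0	0	1	0	0	0	0	0	0	Cacheris 1990
ZnEDTA	16.50	0	0	0	1	0	0	0	0	1	0	0	0	0	0	Martell & Smith
Zn(OH)	-8.96	-1	0	0	1	0	0	0	0	0	0	0	0	0	0	Baes & Mesmer hydrolysis
ZnHCO3	11.83	1	0	0	1	0	0	0	0	0	0	1	0	0	0	Martell & Smith
Zn(CO3)	5.30	0	0	0	1	0	0	0	0	0	0	1	0	0	0	Martell & Smith
ZnHPO4	15.55	1	0	0	1	0	0	0	0	0	1	0	0	0	0	Martell & Smith
Zn(Cit)	4.98	0	0	0	1	0	0	0	0	0	0	0	1	0	0	Martell & Smith
Zn(Ox)	4.87	0	0	0	1	0	0	0	0	0	0	0	0	1	0	Martell & Smith
Zn(Ox)2	7.65	0	0	0	1	0	0	0	0	0	0	0	0	2	0	Martell & Smith
Zn(Lac)	2.20	0	0	0	1	0	0	0	0	0	0	0	0	0	1	Martell & Smith
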