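gene	de_direction
Dmrt1	none
Dmrt2	none
DmrtA1	none
DmrtA2	none
DmrtB1	testis
Amh	testis
Foxl2	ovary
Bmp15	ovary
Cyp19a	ovary
Ctnnb1	none
OCT4	ovary
Lhx1	none
Sf1	none
Rspo1	testis
Sox3	ovary
Sox4	testis
Sox5	testis
Sox6	none
Sox7	ovary
Sox8	testis
Sox9	testis
Sox10	none
Sox18	none
AR	none
Vasa	testis
ER	testis
Pdgfra	none
Hsd11b2	testis
Lhx9	none
Emx2	none
Fshr	testis
Gnrhr	none
IgfI	none
Dkk1	ovary
Wt1	none
Fgfr2	none
VR	none
Fem1	none
Gsdf	testis
Spo11	none
Fstb2	none
Ozf6	testis
Ozf7	testis
Ozf22	none
Hsp	ovary
Hsp70	ovary
Hsp75	none
Hsp90	ovary
Kpi1	none
Gsf1	ovary
ATRX	testis
Sap2	testis
Sap5	testis
Sap6	testis
Sap7	none
Sap13	none
Sap17	none
Sap20	none
Sap22	none
Sap24	ovary
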