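Gene	Coefficient
FAM3D|FABP3	−0.123212435
APOD|PTGDS	0.102940062
APOD|IDO1	0.114162789
APOD|CCL19	0.175640735
PLA2G2A|FABP3	−0.154866389
PLAU|DEFB1	0.411294017
MMP9|SLURP1	0.118514628
SORT1|IGHG4	0.048939964
ULBP2|IDO1	0.02698727
TYMP|DES	−0.039797787
OASL|SPP1	−0.345276271
CLDN4|IGHG2	0.074023063
TNFRSF12A|TNC	0.467337778
RSAD2|TPM2	−0.049203572
STAT1|IGHG2	0.204728651
TAP1|IGHG2	0.303345321
CXCL11|IL1A	−0.22016231
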