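FAM3D
FABP3
APOD
PTGDS
IDO1
CCL19
PLA2G2A
PLAU
DEFB1
MMP9
SLURP1
SORT1
IGHG4
ULBP2
TYMP
DES
OASL
SPP1
CLDN4
IGHG2
TNFRSF12A
TNC
RSAD2
TPM2
STAT1
TAP1
CXCL11
IL1A
CCL3
CCL5
CXCL8
CXCL9
CXCL10
CXCL12
CXCR4
CCR7
TGFB1
TNF
IFNG
IL2
IL6
IL10
IL1B
IL2RA
CD274
PDCD1
CTLA4
CD8A
CD4
FOXP3
GZMB
PRF1
B2M
C3
TLR4
HLA-A
HLA-B
LAG3
HAVCR2
ICOS
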