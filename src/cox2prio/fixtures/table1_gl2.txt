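FBXO32
PPP1R1B
THBS1
LAMC2
STAC2
ATP1B1
DEGS1
IER3
OGFRL1
GNAS
TFAP2C
CD55
SFRP1
ITGB4
MFGE8
EPHB3
ACTN4
RGS2
PTGS2
SLC2A1
COL9A2
DSP
MDFI
PTP4A1
TNFRSF21
ID4
FURIN
CTNNB1
KLK7
TPM4
TACSTD2
FBLN2
SERPINB5
KLK5
KLK6
RBP1
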