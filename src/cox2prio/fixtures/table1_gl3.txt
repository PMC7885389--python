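TPM4
TNFRSF21
RGS2
TFAP2C
ITGA6
COL9A1
SFRP1
FURIN
LAMC2
TACSTD2
MSN
S100B
FBXO32
STAC2
DSP
KRT6B
SERPINB5
ITGB4
FOXI1
EPHB3
MDFI
KLK7
OGFRL1
MFGE8
ACTN4
KLK5
SLC44A2
KLK6
ID4
RBP1
PTP4A1
TMX4
SLC2A1
GNAS
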