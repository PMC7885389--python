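TPM4
TNFRSF21
RGS2
TFAP2C
ITGA6
SFRP1
FURIN
LAMC2
CD55
MSN
S100B
FBXO32
STAC2
KRT6B
FBLN2
SERPINB5
ITGB4
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
TMX4
SLC2A1
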