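MDFI
EPHB3
FBXO32
MSN
SFRP1
ID4
ACTN4
TNFRSF21
MFGE8
TFAP2C
RGS2
ITGB4
SLC44A2
ITGA6
S100B
KLK7
DEGS1
GNAS
PTGS2
LAMC2
KLK5
TACSTD2
SLC2A1
CTNNB1
KLK6
CD55
TPM4
FURIN
RBP1
KRT6B
PPP1R1B
SERPINB5
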