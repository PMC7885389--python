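GNAS
TPM4
RGS2
TFAP2C
ITGA6
ATP1B1
LAMC2
CD55
TACSTD2
CTNNB1
KRT6B
SERPINB5
IER3
ITGB4
KLK7
MFGE8
KLK5
ID4
RBP1
PTP4A1
SLC2A1
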