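TPM4
RGS2
COL9A2
SFRP1
LAMC2
FBLN2
SERPINB5
KLK7
MFGE8
KLK5
ID4
RBP1
SLC2A1
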