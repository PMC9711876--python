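# Stand-in panel of 10 canonical androgen receptor target genes.
# This is a configurable default (a widely used 10-gene AR activity
# signature), not asserted to be any specific study's list; supply your
# own panel file to replace it.
KLK3
KLK2
FKBP5
STEAP1
STEAP2
PLPP1
RAB3B
NKX3-1
ACSL3
NDRG1
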