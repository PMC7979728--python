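# Synthetic stand-in cell-cycle marker panel (51 genes, one symbol per line).
# Canonical markers spanning G1/S, S, G2 and M phases; replaceable with a
# study-specific panel file of the same format.
CCNE1
CCNE2
E2F1
E2F8
CDC6
CDT1
CDC45
CDC25A
PCNA
MCM2
MCM3
MCM4
MCM5
MCM6
MCM7
GINS2
CLSPN
DTL
FEN1
RRM2
TYMS
EXO1
RFC4
UNG
HELLS
CCNA2
TOP2A
FOXM1
CDK1
CCNB1
CCNB2
CDC25C
PLK1
AURKA
AURKB
BUB1
CDC20
UBE2C
BIRC5
TPX2
KIF11
KIF23
KIF2C
CENPA
CENPE
CENPF
NDC80
NUSAP1
ANLN
ECT2
MKI67
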