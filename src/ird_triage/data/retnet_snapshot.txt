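# Snapshot of retinal-disease-associated gene symbols (RetNet-style list).
# Subset covering the genes exercised by this package; config-replaceable.
ABCA4
BBS10
CACNA1F
CEP290
CHM
CRB1
EYS
FAM161A
GUCY2D
MFRP
NDP
NYX
PDE6A
PDE6B
PGK1
PROM1
PRPH2
PRPS1
RHO
RP1
RP1L1
RP2
RPE65
RPGR
TIMM8A
USH2A
WHRN
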