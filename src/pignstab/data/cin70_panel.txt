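# CIN70 chromosomal-instability expression signature (70 genes).
# Symbols updated to current HGNC nomenclature where the historical
# probe annotation used an alias (CDC2->CDK1, CDC45L->CDC45, CNAP1->NCAPD2,
# BRRN1->NCAPH, TOPK->PBK, ch-TOG->CKAP5, MTB->ZNF639, FLJ10036->ZWILCH).
# This packaged list is a curated reconstruction of the published signature;
# pass a custom panel file to substitute an alternative membership.
TPX2
PRC1
FOXM1
CDK1
TGIF2
MCM2
H2AFZ
TOP2A
PCNA
UBE2C
MELK
TRIP13
NCAPD2
MCM7
RNASEH2A
RAD51AP1
KIF20A
CDC45
MAD2L1
ESPL1
CCNB2
FEN1
TTK
CCT5
RFC4
ATAD2
CKAP5
NUP205
CDC20
CKS2
RRM2
ELAVL1
CCNB1
RRM1
AURKB
MSH6
EZH2
CTPS1
DKC1
OIP5
CDCA8
PTTG1
CEP55
H2AFX
CMAS
NCAPH
MCM10
LSM4
ZNF639
ASF1B
ZWINT
PBK
ZWILCH
CDCA3
ECT2
CDC6
UNG
MTCH2
RAD21
ACTL6A
SPAG5
KIF2C
NDC80
NUSAP1
AURKA
BUB1B
CENPA
KIF11
BIRC5
PLK1
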