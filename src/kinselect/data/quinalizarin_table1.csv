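kinase,activity_percent,group_key,is_reference_target
CK2α2β2,10,CK2,true
CK2α,42,CK2,true
PIM3,62,,
MLK3,63,,
CK1δ,72,,
BRK,72,,
PLK1,75,,
MST2,77,,
MST4,78,,
CHK2,80,,
MKK1,81,,
TrkA,81,,
PKBb,81,,
CAMK1,82,,
MKK2,82,,
ABL,82,,
PDK1,83,,
MAP4K3,84,,
MLK1,84,,
PIM1,85,,
FGF-R1,85,,
MAP4K5,86,,
PAK6,87,,
TIE2,88,,
MNK2,88,,
SIK2,89,,
MARK3,89,,
YES1,89,,
GCK,90,,
ERK1,90,,
TESK1,90,,
PKBa,91,,
DYRK2,91,,
SGK1,91,,
CK1γ2,91,,
S6K1,91,,
CLK2,91,,
SmMLCK,92,,
JNK1,92,,
ULK1,92,,
Aurora B,93,,
DAPK1,93,,
ERK2,94,,
CAMKKb,94,,
EF2K,94,,
BRSK2,95,,
PKD1,95,,
Src,95,,
PKCa,95,,
IRAK4,95,,
HIPK3,96,,
JNK3,96,,
IGF-1R,96,,
VEG-FR,96,,
IRAK1,97,,
MAPKAP-K2,97,,
PAK5,97,,
IKKe,97,,
GSK3b,98,,
DYRK1A,98,,
MAPKAP-K3,98,,
MSK1,99,,
AMPK (hum),99,,
SYK,99,,
PDGFRA,99,,
LKB1,99,,
p38a MAPK,99,,
HIPK2,99,,
HER4,100,,
MARK2,100,,
TTBK2,100,,
EPH-B2,101,,
TTK,101,,
ULK2,101,,
WNK1,101,,
ERK8,102,,
PINK,102,,
PKCz,102,,
PAK4,102,,
JAK2,102,,
MARK4,103,,
BRSK1,103,,
PRAK,103,,
RIPK2,103,,
TBK1,103,,
DYRK3,104,,
NUAK1,104,,
NEK2a,105,,
SIK3,105,,
ROCK 2,105,,
MINK1,105,,
ERK5,106,,
EPH-B1,106,,
PAK2,106,,
MARK1,106,,
PHK,107,,
TAK1,107,,
CDK9-Cyclin T1,108,,
RSK1,108,,
MPSK1,108,,
RSK2,108,,
DDR2,109,,
EPH-A2,110,,
MNK1,110,,
PKCγ,110,,
CHK1,111,,
OSR1,111,,
JNK2,112,,
STK33,112,,
NEK6,112,,
IKKb,112,,
EIF2AK3,112,,
p38g MAPK,114,,
MKK6,114,,
ZAP70,114,,
p38b MAPK,114,,
CSK,114,,
TTBK1,115,,
Aurora A,115,,
TAO1,115,,
MEKK1,115,,
MELK,116,,
SRPK1,117,,
EPH-B3,117,,
PRK2,118,,
PIM2,120,,
IRR,120,,
ASK1,120,,
p38d MAPK,120,,
PKA,121,,
CDK2-Cyclin A,121,,
Lck,122,,
HIPK1,123,,
BTK,125,,
EPH-A4,126,,
TLK1,126,,
MST3,126,,
IR,128,,
TGFBR1,130,,
TSSK1,131,,
EPH-B4,132,,
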