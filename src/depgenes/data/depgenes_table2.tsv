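gene	combined_score
DBH	47.74
BDNF	46.52
SLC6A4	46.29
NGFR	46.04
TNF	43.61
GSK3B	40.25
CHRNA7	40.24
GABRA3	37.55
CYP2C9	37.33
NTRK3	37.17
ADCY7	36.13
PDLIM5	35.99
HTR1A	35.50
P2RX7	35.39
HTR2A	35.29
CCL2	35.24
PDE9A	34.90
DAOA	34.00
NPY	33.68
GRIN1	33.44
CHRM2	33.25
NR3C1	32.95
DRD4	32.77
CREB1	32.54
DRD3	32.31
CRHR2	31.97
CRHR1	31.36
AR	30.79
DRD1	30.63
PLXNA2	30.09
MAOA	29.57
OPRM1	29.30
IL6	29.06
HTR1B	28.99
TPH2	28.50
CRH	28.03
ACCN2	27.79
ESR1	27.67
ACSL4	27.58
SLC6A3	27.20
SLC6A2	26.99
ADRA2A	26.87
CNR1	26.64
NQO1	26.41
AVPR1B	26.30
TACR1	26.16
GAD2	26.12
TAAR6	26.00
TPH1	25.81
HTR3A	25.77
GABRA1	25.67
ESR2	25.61
COMT	25.55
PLA2G2A	25.53
GAD1	25.51
DTNBP1	25.00
ACE	24.14
XBP1	23.41
MAOB	23.36
P2RX4	23.35
APOE	23.11
WFS1	23.03
IL10	22.88
DRD2	22.63
DISC1	22.59
PDE4B	22.59
CRHBP	22.19
PDE5A	22.00
NOS1	21.94
PRKACA	21.93
GFAP	21.87
IL1B	21.86
HTR2C	21.72
TH	21.42
CYP1A1	21.33
HTR5A	21.00
SMPD1	20.97
APAF1	20.79
TSPO	20.57
GNAL	20.48
GMIP	20.29
TOR1A	20.23
CCKAR	20.10
CTLA4	20.00
ADCYAP1	20.00
CYP1A2	19.89
GNAS	19.88
FKBP5	19.61
GDNF	19.50
PLA2G4A	19.42
ADRA1A	19.17
SLC1A4	18.88
HSPA1A	18.83
CACNA1C	18.52
GRIK3	18.45
AGTR1	18.27
PDE1A	18.24
CHRNA5	18.20
CPLX2	18.20
HTR6	18.15
CCK	18.12
ARRB2	18.10
ANXA2	18.07
GNB3	18.04
ADRB1	18.03
POMC	18.01
NOS3	18.00
D2S2944	18.00
DXS7	18.00
GABRA5	18.00
LBP	18.00
M6PR	18.00
MAMDC1	18.00
MCP1	18.00
PDE11A	18.00
SLC5A7	18.00
VMAT2	18.00
ABCB1	17.89
PDYN	17.71
SAT1	17.35
S100B	17.34
CD63	17.14
GABRA6	17.12
ALDH1A1	17.03
RELN	17.00
ATP6V1B2	16.87
CAMK2A	16.68
BCR	16.58
HTT	16.56
CLOCK	16.56
GRIN2B	16.56
PCLO	16.53
NRG1	16.50
QKI	16.47
GRIN2A	16.42
DIO2	16.42
TSNAX	16.41
TFCP2	16.39
CYP2C19	16.39
GRIA1	16.36
FMR1	16.35
SLC5A4	16.32
CC2D1A	16.32
GLI2	16.30
CAT	16.29
L1CAM	16.28
CDH17	16.27
DNAJB1	16.27
CD3E	16.22
MTHFR	16.19
VEGFA	16.18
DNMT3B	16.15
AKT1	16.14
SERPINE1	16.13
HSPA12A	16.13
S100A10	16.11
CYP2D6	16.07
GABRA2	16.03
PTX3	16.00
C5orf20	16.00
GHRL	16.00
IVNS1ABP	16.00
PDSS1	16.00
GAL	15.86
AGT	15.78
TAC1	15.75
NTRK2	15.68
SLC6A1	15.56
CTNNB1	15.18
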