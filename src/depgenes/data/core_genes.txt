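# Core gene set: 14 well-replicated depression candidate genes.
# Six from the Lopez-Leon MDD meta-analysis, eight from MDD review articles.
APOE
DRD4
GNB3
MTHFR
SLC6A3
SLC6A4
BDNF
CREB1
GRM7
HTR1A
HTR1B
HTR2A
MAOA
TPH1
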