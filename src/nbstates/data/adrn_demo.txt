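# Demo adrenergic (ADRN) marker genes for tests and examples
PHOX2B
PHOX2A
DBH
TH
GATA2
GATA3
HAND2
ASCL1
ISL1
KLF7
EYA1
SIX3
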