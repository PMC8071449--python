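# Demo mesenchymal (MES) marker genes for tests and examples
YAP1
WWTR1
FN1
HES1
SNAI2
VIM
PRRX1
MET
AXL
CD44
SMAD3
NOTCH2
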