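ARNTL
ARNTL2
CLOCK
NPAS2
PER1
PER2
PER3
CRY1
CRY2
NR1D1
NR1D2
RORA
RORB
RORC
CSNK1D
CSNK1E
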