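state	group
TssA	Active
TssAFlnk	Active
TxFlnk	Active
Tx	Active
TxWk	Active
EnhG	Enhancers
Enh	Enhancers
TssBiv	Bivalent
BivFlnk	Bivalent
EnhBiv	Bivalent
ZNF/Rpts	Repressed
Het	Repressed
ReprPC	Repressed
ReprPCWk	Repressed
Quies	Repressed
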