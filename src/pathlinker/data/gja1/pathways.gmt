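SignaLink::EGF/MAPK	human EGF/MAPK signaling	CSK	PRKA	PRKX	SRC	ERK1	ERK5	RAF1	MAP2K1	GRB2
SignaLink::WNT	human WNT signaling	PRKA	CCND1	CSNK1D	CTNNB1	LEF1	APC	AXIN1	GSK3B
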