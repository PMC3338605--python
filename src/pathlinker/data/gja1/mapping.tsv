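gja1	GJA1	1.0
connexin-43	GJA1	0.95
cx43	GJA1	0.9
csk	CSK	1.0
prka	PRKA	1.0
akap	PRKA	0.9
prkx	PRKX	1.0
src	SRC	1.0
erk1	ERK1	1.0
erk5	ERK5	1.0
ccnd1	CCND1	1.0
csnk1d	CSNK1D	1.0
ctnnb1	CTNNB1	1.0
beta-catenin	CTNNB1	0.9
lef1	LEF1	1.0
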