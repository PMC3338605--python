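cdc-25.1	CDC-25.1	1.0
cdc-25	CDC-25.1	0.8
daf-2	DAF-2	1.0
sma-6	SMA-6	1.0
let-60	LET-60	1.0
sem-5	SEM-5	1.0
pop-1	POP-1	1.0
glp-1	GLP-1	1.0
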