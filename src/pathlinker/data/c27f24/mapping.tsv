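c27f2.4	C27F2.4	1.0
C27F2.4	C27F2.4	1.0
bar-1	BAR-1	1.0
clk-2	CLK-2	1.0
rha-2	RHA-2	1.0
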