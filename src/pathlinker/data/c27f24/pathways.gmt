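SignaLink::WNT	worm WNT signaling	BAR-1	POP-1	MOM-2	LIN-44	MIG-5
SignaLink::EGF/MAPK	worm EGF/MAPK signaling	BAR-1	LET-60	SEM-5	MPK-1	LIN-45
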