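SignaLink::EGF/MAPK	worm EGF/MAPK signaling	LET-60	SEM-5	MPK-1	LIN-45	MEK-2	BAR-1
SignaLink::IGF	worm insulin/IGF signaling	DAF-2	AGE-1	AKT-1	DAF-16	PDK-1
SignaLink::Notch	worm Notch signaling	GLP-1	LIN-12	LAG-1	SEL-12
SignaLink::TGF	worm TGF-beta signaling	SMA-6	DAF-4	SMA-2	SMA-3	SMA-4
SignaLink::WNT	worm WNT signaling	POP-1	BAR-1	MOM-2	LIN-44	MIG-5
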