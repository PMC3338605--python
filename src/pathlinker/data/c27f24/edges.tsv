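# Reconstruction (synthetic) of the C27F2.4 neighborhood from high-throughput
# physical interaction screens. Not a database snapshot.
a	b	source	evidence_type	pubmed_ids
C27F2.4	BAR-1	WI8	high_throughput_physical	
C27F2.4	CLK-2	WI8	high_throughput_physical	
C27F2.4	RHA-2	WI8	high_throughput_physical	
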