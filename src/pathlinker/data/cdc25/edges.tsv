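# Reconstruction (synthetic) of the CDC-25.1 first-neighbor star: the six
# named signaling interactors plus three placeholder non-signaling neighbors
# (X1-X3). Not a database snapshot.
a	b	source	evidence_type	pubmed_ids
CDC-25.1	DAF-2	BioGRID	small_scale_physical	
CDC-25.1	SMA-6	BioGRID	small_scale_physical	
CDC-25.1	LET-60	BioGRID	genetic	
CDC-25.1	SEM-5	STRING	high_throughput_physical	
CDC-25.1	POP-1	WI8	high_throughput_physical	
CDC-25.1	GLP-1	BioGRID	genetic	
CDC-25.1	X1	WI8	high_throughput_physical	
CDC-25.1	X2	WI8	high_throughput_physical	
CDC-25.1	X3	STRING	high_throughput_physical	
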