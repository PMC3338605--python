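# Reconstruction (synthetic) of the GJA1 (Connexin-43) neighborhood reduced to
# the ten interactors named in the case study. Not a database snapshot: the
# full database-scale neighborhood (dozens of interactors) is out of scope.
a	b	source	evidence_type	pubmed_ids
GJA1	CSK	HPRD	small_scale_physical	
GJA1	PRKA	HPRD	small_scale_physical	
GJA1	PRKX	BioGRID	small_scale_physical	
GJA1	SRC	HPRD	small_scale_physical	
GJA1	ERK1	BioGRID	small_scale_physical	
GJA1	ERK5	STRING	high_throughput_physical	
GJA1	CCND1	BioGRID	small_scale_physical	
GJA1	CSNK1D	STRING	high_throughput_physical	
GJA1	CTNNB1	HPRD	small_scale_physical	
GJA1	LEF1	STRING	high_throughput_physical	
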