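{
  "name": "gja1",
  "species": "human",
  "universe_size": 20000,
  "query_term": "gja1",
  "query_accession": "GJA1",
  "n_edges": 10,
  "n_neighbors": 10,
  "egf_mapk_direct_interactors": 6,
  "wnt_direct_interactors": 5,
  "multi_pathway_interactor": "PRKA",
  "drugs": ["cisplatin", "mercaptopurine", "methotrexate"]
}
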