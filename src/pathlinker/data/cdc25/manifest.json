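{
  "name": "cdc25",
  "species": "worm",
  "universe_size": 20000,
  "query_term": "cdc-25.1",
  "query_accession": "CDC-25.1",
  "n_edges": 9,
  "n_neighbors": 9,
  "n_neighbors_with_membership": 6,
  "pathways": ["EGF/MAPK", "IGF", "Notch", "TGF", "WNT"]
}
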