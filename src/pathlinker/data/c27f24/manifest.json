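{
  "name": "c27f24",
  "species": "worm",
  "universe_size": 20000,
  "query_term": "C27F2.4",
  "query_accession": "C27F2.4",
  "n_edges": 3,
  "n_neighbors": 3,
  "neighbors": ["BAR-1", "CLK-2", "RHA-2"],
  "n_neighbors_with_membership": 1,
  "n_neighbors_without_membership": 2,
  "bar1_memberships": [["SignaLink", "EGF/MAPK"], ["SignaLink", "WNT"]]
}
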