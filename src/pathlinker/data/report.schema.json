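{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pathlinker neighborhood report",
  "type": "object",
  "required": [
    "format", "version", "config", "query_terms", "resolved", "unresolved",
    "query", "neighbors", "displayed", "memberships", "membership_counts",
    "subnetwork", "enrichment", "warnings"
  ],
  "properties": {
    "format": {"type": "string", "enum": ["pathlinker-report"]},
    "version": {"type": "integer"},
    "config": {"type": "object"},
    "query_terms": {"type": "array", "items": {"type": "string"}},
    "resolved": {"type": "object"},
    "unresolved": {"type": "array", "items": {"type": "string"}},
    "query": {"type": "array", "items": {"type": "string"}},
    "neighbors": {"type": "array", "items": {"type": "string"}},
    "displayed": {"type": "array", "items": {"type": "string"}},
    "memberships": {"type": "object"},
    "membership_counts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source_db", "pathway_name", "count"],
        "properties": {
          "source_db": {"type": "string"},
          "pathway_name": {"type": "string"},
          "count": {"type": "integer"}
        }
      }
    },
    "subnetwork": {
      "type": "object",
      "required": ["species", "nodes", "edges"],
      "properties": {
        "species": {"type": "string"},
        "nodes": {"type": "array", "items": {"type": "string"}},
        "edges": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["a", "b", "sources", "evidence_types", "pubmed_ids"],
            "properties": {
              "a": {"type": "string"},
              "b": {"type": "string"},
              "sources": {"type": "array", "items": {"type": "string"}},
              "evidence_types": {"type": "array", "items": {"type": "string"}},
              "pubmed_ids": {"type": "array", "items": {"type": "string"}}
            }
          }
        }
      }
    },
    "enrichment": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source_db", "pathway_name", "N", "n", "K", "M", "p_raw", "p_adj", "significant"],
        "properties": {
          "source_db": {"type": "string"},
          "pathway_name": {"type": "string"},
          "N": {"type": "integer"},
          "n": {"type": "integer"},
          "K": {"type": "integer"},
          "M": {"type": "integer"},
          "p_raw": {"type": "number"},
          "p_adj": {"type": "number"},
          "significant": {"type": "boolean"}
        }
      }
    },
    "warnings": {"type": "array", "items": {"type": "string"}}
  }
}
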