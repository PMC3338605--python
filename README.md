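# pathlinker

Offline analysis engine for linking proteins to signaling pathways. Given a
query — protein or gene names, synonyms, or drug names — `pathlinker`
resolves the query to canonical accessions, extracts its first-neighbor
subnetwork from integrated multi-source protein-interaction data, annotates
which displayed proteins belong to known signaling pathways, and scores each
pathway's overrepresentation. It is aimed at experimentalists who want a
quick first estimate of the signaling side effects of perturbing a protein
(knockdown, knockout, drug treatment) and at computational biologists who
want that estimate scriptable and reproducible: everything runs from local
files, with no web services.

## The statistic

Let the species background (universe) hold M proteins and a pathway S hold K
of them. If the displayed set — the queried proteins plus their first
neighbors — has n proteins, N of them in S, then under the null that the
displayed set is an unstructured draw the overlap is hypergeometric, and the
overrepresentation p-value is the upper tail

&nbsp;&nbsp;&nbsp;&nbsp;p = P(X ≥ N) = Σᵢ₌ₙ^min(n,K) C(K,i)·C(M−K,n−i) / C(M,n),

computed in log space so proteome-scale M is safe. One test per (pathway
database, pathway) pair; the whole family is adjusted with Benjamini–Hochberg
(default threshold 0.05), and raw p-values are always reported alongside.
See `docs/methods.md` for assumptions and design choices.

## Worked example

Three small packaged fixtures reconstruct published case-study neighborhoods
from the printed protein names (they are reconstructions, not database
snapshots). The `c27f24` fixture holds the uncharacterized worm gene C27F2.4
and its three interactors:

```sh
pathlinker run --fixture c27f24 --query C27F2.4
```

prints

```
PathwayLinker-style neighborhood report
=======================================

Query terms: C27F2.4
  C27F2.4 -> C27F2.4

Query proteins (1):
  C27F2.4

First neighbors (3):
  BAR-1	SignaLink::EGF/MAPK; SignaLink::WNT
  CLK-2	(no pathway)
  RHA-2	(no pathway)

Pathway membership counts in displayed set:
  SignaLink::EGF/MAPK	1
  SignaLink::WNT	1

Enrichment (sorted by adjusted p):
  source	pathway	N	n	K	M	p_raw	p_adj	significant
  SignaLink	EGF/MAPK	1	4	5	20000	0.0009997	0.0009997	yes
  SignaLink	WNT	1	4	5	20000	0.0009997	0.0009997	yes
```

Reading it: of C27F2.4's three interactors only BAR-1 (the worm β-catenin
ortholog) is a known signaling protein, a member of both the WNT and
EGF/MAPK pathways. Each pathway has K = 5 members in a universe of
M = 20000; seeing N = 1 member inside the n = 4 displayed proteins has a
hypergeometric tail p ≈ 1.0 × 10⁻³, still significant after BH adjustment —
so C27F2.4 plausibly functions near these pathways even though it has no
annotation of its own.

The same engine runs on your own files:

```sh
pathlinker run --edges edges.tsv --gmt pathways.gmt --mapping synonyms.tsv \
    --drugs drugs.tsv --query methotrexate --universe-size 20000 \
    --evidence small_scale_physical --out report.json --sif-out subnet.sif
```

Formats: a normalized 5-column interaction TSV (`a  b  source
evidence_type  pubmed_ids`), GMT pathway sets named `SOURCE::Pathway`,
synonym TSV (`term  accession  score`), drug TSV (`drug  accession`).
Outputs: JSON (schema shipped in `src/pathlinker/data/report.schema.json`),
plain text, SIF, and GraphML. `pathlinker validate` parse-checks inputs;
`pathlinker fixtures generate --seed N ...` writes seeded synthetic
networks; `pathlinker fixtures load NAME` verifies a packaged fixture.
Exit codes: 0 success, 1 usage error, 2 data error.

The library mirrors the CLI: `pathlinker.run_analysis(network, collection,
terms, synonyms, ...)` returns a `NeighborhoodReport` with the neighbor set,
per-protein memberships, the induced subnetwork, and the enrichment table.

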