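# Methods

## The problem

Perturbing a protein — by knockdown, knockout, or a drug — can hit signaling
pathways through that protein's interaction partners, biasing experiments in
ways that are invisible when only the perturbed protein itself is considered.
`pathlinker` gives a first estimate of such effects: it resolves the query
(protein names, synonyms, or drug names) to canonical accessions, extracts the
query's first-neighbor interaction subnetwork from integrated multi-source
interaction data, annotates which of the displayed proteins are members of
known signaling pathways, and scores each pathway's overrepresentation.

## The statistical model

Let M be the number of proteins in the species background (the universe), and
consider a pathway S with K members. The analysis displays n proteins — the
queried proteins together with their first-neighbor interactors — and observes
N of them in S. Under the null hypothesis that the displayed set is an
unstructured draw of n proteins from the universe, N follows the
hypergeometric distribution, and the overrepresentation score is its upper
tail:

    p = P(X >= N) = sum_{i=N}^{min(n,K)} C(K,i) C(M-K, n-i) / C(M,n).

The tail is computed in log space from log-factorials (`gammaln`) combined
with `logsumexp`, so it is numerically stable for proteome-scale M (1e5 and
beyond) and tiny tail masses. N = 0 returns exactly 1. An independent
cross-check against `scipy.stats.hypergeom.sf` and against exhaustive
enumeration of all C(M, n) draws (exact rational arithmetic, every valid
parameter combination with M <= 12) lives in the test suite; the enumeration
oracle was written first and its values frozen into the tests.

Every (pathway source database, pathway) pair is one test; tests are never
pooled across source databases, preserving per-database reporting. The family
of all tests in one run is adjusted with the Benjamini–Hochberg step-up
procedure (via `scipy.stats.false_discovery_control`) and flagged significant
at an adjustable threshold (default 0.05). Raw p-values are always reported
alongside, so users can apply their own correction.

### Modeling assumptions

- The null treats the displayed set as an unstructured sample; it ignores the
  fact that neighbors were selected through network topology. This is the
  standard overrepresentation approximation, appropriate for a first
  estimate, not a topology-aware null.
- The universe M is a free parameter of the test. Its default comes with the
  pathway collection (an explicit accession set, or a declared integer such
  as a proteome size); if absent, M falls back to |network proteins ∪ all
  pathway members| with a logged warning. Larger M makes any fixed overlap
  look more surprising, so M should be the species proteome, not the network.
- By default the tested set is the full displayed set (query ∪ neighbors),
  because query and neighbors are reported as one set; `overlap_mode =
  "neighbors-only"` excludes the query proteins for users who consider the
  query's own membership uninformative.

## Network model and neighbor extraction

Interactions are undirected, stored once per unordered accession pair with
canonical (lexicographic) endpoint ordering. Records of the same pair from
different databases merge by set union of source labels, evidence types
(small-scale physical / high-throughput physical / genetic), and PubMed IDs.
Self-loops are dropped by default (a self-edge would otherwise make a query
protein its own first neighbor); a flag retains them.

First-neighbor extraction takes optional source and evidence filters: an edge
qualifies iff its sources intersect the source filter AND its evidence types
intersect the evidence filter. The neighbor set contains the endpoints of
qualifying edges incident to the query, minus the query; the reported
subnetwork contains all qualifying edges among the displayed set, including
neighbor–neighbor edges. Enlarging either filter can only grow the neighbor
set (tested). Correctness is checked against a naive edge-scan oracle on 100
seeded random networks of up to 200 nodes.

## Identifier resolution

A synonym table maps case-folded search terms to scored candidate accessions,
sorted by score descending with lexicographic accession tie-break — the
scores are treated as opaque non-negative numbers, since synonym-search
services do not document a scale. Quick mode takes the top candidate per
term; advanced mode returns exactly the user's selections (validated against
the candidate list). A term matching the drug→target table resolves to the
drug's full target set instead. Duplicate (term, accession) rows keep the
maximum score. Unresolved terms degrade to warnings; only a fully unresolved
query is an error. Resolutions are recorded in a cache that can be persisted
and reloaded, and warmed-cache lookups are identical to cold ones regardless
of prior query order (tested).

Two query terms resolving to the same protein deduplicate in the displayed
set; species is a free label validated only for uniformity within a network.

## File formats and numerical choices

- Interaction edge lists use one normalized TSV dialect (a, b, source,
  evidence_type, pipe-separated PubMed IDs; `#` comments; optional header).
  Converters from vendor dump formats are the user's responsibility — vendor
  formats drift by version. Unknown evidence values and malformed rows are
  rejected with line numbers; a permissive flag downgrades them to warnings.
- Pathways use standard GMT with a `SOURCE::PathwayName` convention so one
  file carries several pathway databases; duplicate rows merge by member
  union. If the collection declares an explicit universe set, members outside
  it are dropped with a warning and proteins outside it are removed from n,
  keeping n <= M provable.
- Reports are emitted as JSON (validated against the shipped schema,
  `src/pathlinker/data/report.schema.json`) and plain text; subnetworks as
  SIF (relation `pp`, isolated nodes as bare rows) and GraphML (via
  networkx, provenance as pipe-joined attributes). Export→parse round trips
  preserve node/edge sets and annotations (property-tested).
- Report ordering is fully deterministic: enrichment sorts by adjusted p,
  ties broken by (source_db, pathway_name); all sets serialize sorted. Two
  runs on identical inputs give byte-identical JSON (tested). No stage of
  the analysis uses randomness; all seeds live in the synthetic generator.

## Packaged fixtures and the synthetic generator

The three packaged datasets are transparent reconstructions of published
case-study neighborhoods, built from the protein names printed in the case
studies — not database snapshots:

- `cdc25` (worm): CDC-25.1 linked to nine interactors; the six named
  signaling proteins (DAF-2, SMA-6, LET-60, SEM-5, POP-1, GLP-1) carry their
  pathway annotations (IGF, TGF, EGF/MAPK ×2, WNT, Notch respectively), and
  the three unnamed interactors are placeholders X1–X3 with no annotation.
- `c27f24` (worm): C27F2.4 linked to BAR-1 (WNT and EGF/MAPK member), CLK-2
  and RHA-2 (no memberships).
- `gja1` (human): GJA1/Connexin-43 linked to the ten printed interactors;
  six are EGF/MAPK members (CSK, PRKA, PRKX, SRC, ERK1, ERK5), five WNT
  members (PRKA, CCND1, CSNK1D, CTNNB1, LEF1), PRKA in both; a drug table
  maps cisplatin, mercaptopurine and methotrexate to GJA1.

Each fixture ships a manifest of expected counts that is re-verified on every
load, so the packaged files cannot drift from the counts the tests assert.
The fixture universe size is set to M = 20000, a realistic protein-coding
proteome scale for both species; the absolute p-values therefore illustrate
the method rather than reproduce any particular database snapshot, whose M
was never published. Database-scale figures (e.g. a hub's full interactor
count across pinned database versions) are deliberately not reconstructed.

What passing fixture tests show: the engine reproduces the case studies'
counting logic exactly on faithful inputs. What they do not show: robustness
to the noise, redundancy, and identifier messiness of real database dumps —
the property suites on random networks cover the machinery, but curation
quality of real inputs remains the user's responsibility.

The synthetic generator draws simple undirected graphs uniformly without
duplicate pairs (edges sampled by unranking uniformly chosen pair indices),
one source and evidence type per edge, and pathway memberships uniformly
without replacement, all under a mandatory seed; identical seeds give
identical objects and files. Default test problem sizes (networks up to 200
nodes, 100 oracle seeds, exhaustive enumeration up to M = 12) were chosen so
the whole suite runs in about a second while still covering every parameter
combination the enumeration oracle can reach exactly.

## Known limitations

- The hypergeometric null ignores network topology and annotation bias;
  well-studied proteins have more recorded interactions and memberships.
- No second-order neighborhoods, centrality statistics, or GO/domain
  enrichment — the scope is first neighbors and pathway membership.
- Confidence scores (e.g. from probabilistic interaction databases) are not
  part of the edge-list dialect; users pre-filter by confidence upstream.
- Live synonym-search and drug-database lookups are out of scope; the
  mapping and drug tables are user-supplied files.
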