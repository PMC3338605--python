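"""Readers and writers for every external format the engine touches.

One normalized tab-separated edge-list dialect carries interaction data from
any source database (converters from vendor dump formats are the user's
responsibility — vendor formats drift by version). Pathway sets use standard
GMT with a ``SOURCE::PathwayName`` naming convention so one file can carry
several pathway databases. Reports are written as machine-readable JSON
(validated against the shipped schema) and plain text; subnetworks export to
SIF and GraphML for network viewers.

Every reader rejects, with a line number, any row violating its dialect; no
silent skips unless the permissive flag is set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable, Optional

import networkx as nx

from .analysis import EnrichmentRecord, NeighborhoodReport, PathwayCollection
from .model import (
    EVIDENCE_TYPES,
    DrugTargetTable,
    IntegratedNetwork,
    Interaction,
    PathLinkerError,
    ProteinRef,
    SynonymTable,
    build_network,
)

logger = logging.getLogger(__name__)


class DataFormatError(PathLinkerError):
    """A row violating a reader's dialect, reported with its line number."""


@dataclass(frozen=True)
class EdgeListDialect:
    """The normalized interaction edge-list dialect.

    Tab-separated columns ``a, b, source, evidence_type, pubmed_ids``;
    ``#`` starts a comment line; PubMed IDs are ``|``-separated and may be
    empty. Evidence values outside the known vocabulary are rejected.
    """

    columns: tuple[str, ...] = ("a", "b", "source", "evidence_type", "pubmed_ids")
    delimiter: str = "\t"
    comment_prefix: str = "#"
    pubmed_separator: str = "|"


DEFAULT_DIALECT = EdgeListDialect()


def read_edge_list(
    stream: IO[str],
    dialect: EdgeListDialect = DEFAULT_DIALECT,
    species: str = "",
    permissive: bool = False,
) -> tuple[list[Interaction], list[ProteinRef]]:
    """Parse an edge-list stream into interactions plus inferred proteins.

    One interaction per data row (merging happens in ``build_network``).
    Proteins are inferred from endpoints, display_name defaulting to the
    accession. With ``permissive``, malformed rows are logged and skipped
    instead of raising.
    """
    interactions: list[Interaction] = []
    accessions: dict[str, None] = {}
    ncol = len(dialect.columns)
    seen_data = False
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith(dialect.comment_prefix):
            continue
        fields = line.split(dialect.delimiter)
        if not seen_data and tuple(f.strip() for f in fields) == dialect.columns:
            continue  # optional header on the first non-comment line
        seen_data = True
        try:
            if len(fields) != ncol:
                raise DataFormatError(
                    f"line {lineno}: expected {ncol} tab-separated columns, "
                    f"got {len(fields)}"
                )
            a, b, source, evidence, pubmed = (f.strip() for f in fields)
            if evidence not in EVIDENCE_TYPES:
                raise DataFormatError(
                    f"line {lineno}: unknown evidence type {evidence!r} "
                    f"(expected one of {sorted(EVIDENCE_TYPES)})"
                )
            if not a or not b or not source:
                raise DataFormatError(f"line {lineno}: empty accession or source")
            pmids = frozenset(p for p in pubmed.split(dialect.pubmed_separator) if p)
            interactions.append(
                Interaction(a, b, frozenset({source}), frozenset({evidence}), pmids)
            )
            accessions.setdefault(a)
            accessions.setdefault(b)
        except DataFormatError as exc:
            if permissive:
                logger.warning("skipping malformed row: %s", exc)
            else:
                raise
    proteins = [ProteinRef(acc, acc, species) for acc in accessions]
    return interactions, proteins


def read_gmt(
    stream: IO[str],
    universe: Optional[Iterable[str]] = None,
    universe_size: Optional[int] = None,
) -> PathwayCollection:
    """Parse GMT rows (``name<TAB>description<TAB>member...``).

    The set name follows the ``SOURCE::PathwayName`` convention; a name
    without ``::`` is filed under source ``"unspecified"``. Duplicate
    (source, name) rows merge by member union; rows with fewer than three
    fields or no members are rejected with their line number.
    """
    pathways: dict[tuple[str, str], set[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataFormatError(
                f"line {lineno}: GMT row needs name, description and at "
                f"least one member (got {len(fields)} fields)"
            )
        name_field = fields[0].strip()
        members = {m.strip() for m in fields[2:] if m.strip()}
        if not members:
            raise DataFormatError(f"line {lineno}: pathway {name_field!r} has no members")
        if "::" in name_field:
            source, name = name_field.split("::", 1)
        else:
            source, name = "unspecified", name_field
        key = (source, name)
        pathways.setdefault(key, set()).update(members)
    return PathwayCollection(
        pathways={k: frozenset(v) for k, v in pathways.items()},
        universe=frozenset(universe) if universe is not None else None,
        universe_size=universe_size,
    )


def read_mapping_table(stream: IO[str]) -> SynonymTable:
    """Parse ``term<TAB>accession<TAB>score`` rows into a SynonymTable."""
    table = SynonymTable()
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise DataFormatError(
                f"line {lineno}: expected term, accession, score; got "
                f"{len(fields)} fields"
            )
        term, acc, score_s = (f.strip() for f in fields)
        try:
            score = float(score_s)
        except ValueError:
            raise DataFormatError(f"line {lineno}: non-numeric score {score_s!r}")
        if score < 0:
            raise DataFormatError(f"line {lineno}: negative score {score}")
        if not term or not acc:
            raise DataFormatError(f"line {lineno}: empty term or accession")
        table.add(term, acc, score)
    return table


def read_drug_targets(stream: IO[str]) -> DrugTargetTable:
    """Parse ``drug<TAB>accession`` rows into a DrugTargetTable."""
    staged: dict[str, set[str]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise DataFormatError(
                f"line {lineno}: expected drug, accession; got {len(fields)} fields"
            )
        drug, acc = (f.strip() for f in fields)
        if not drug or not acc:
            raise DataFormatError(f"line {lineno}: empty drug or accession")
        staged.setdefault(drug, set()).add(acc)
    return DrugTargetTable(staged)


# ---------------------------------------------------------------------------
# report serialization

REPORT_SCHEMA_RESOURCE = "report.schema.json"


def load_report_schema() -> dict:
    text = (resources.files("pathlinker") / "data" / REPORT_SCHEMA_RESOURCE).read_text()
    return json.loads(text)


def report_to_dict(report: NeighborhoodReport) -> dict:
    """Deterministic JSON-ready dict (all sets sorted)."""
    sub = report.subnetwork
    return {
        "format": "pathlinker-report",
        "version": 1,
        "config": report.config,
        "query_terms": list(report.query_terms),
        "resolved": {t: sorted(a) for t, a in sorted(report.resolved.items())},
        "unresolved": sorted(report.unresolved),
        "query": sorted(report.query),
        "neighbors": sorted(report.neighbors),
        "displayed": sorted(report.displayed),
        "memberships": {
            acc: [[s, n] for s, n in mem]
            for acc, mem in sorted(report.memberships.items())
        },
        "membership_counts": [
            {"source_db": s, "pathway_name": n, "count": c}
            for (s, n), c in sorted(report.membership_counts.items())
        ],
        "subnetwork": {
            "species": sub.species,
            "nodes": sorted(sub.proteins),
            "edges": [
                {
                    "a": e.a,
                    "b": e.b,
                    "sources": sorted(e.sources),
                    "evidence_types": sorted(e.evidence_types),
                    "pubmed_ids": sorted(e.pubmed_ids),
                }
                for e in sub.interactions()
            ],
        },
        "enrichment": [
            {
                "source_db": r.source_db,
                "pathway_name": r.pathway_name,
                "N": r.N,
                "n": r.n,
                "K": r.K,
                "M": r.M,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
            }
            for r in report.enrichment
        ],
        "warnings": list(report.warnings),
    }


def validate_report_dict(doc: dict) -> None:
    """Structural validation of a report document against the shipped schema.

    A compact recursive checker covering the subset of JSON Schema the shipped
    schema uses (type, required, properties, items, enum).
    """
    schema = load_report_schema()

    def check(node, sch, path="$"):
        if "enum" in sch and node not in sch["enum"]:
            raise DataFormatError(f"{path}: {node!r} not in {sch['enum']}")
        t = sch.get("type")
        if t:
            pytypes = {
                "object": dict,
                "array": list,
                "string": str,
                "integer": int,
                "number": (int, float),
                "boolean": bool,
                "null": type(None),
            }
            allowed = t if isinstance(t, list) else [t]
            if not any(isinstance(node, pytypes[a]) for a in allowed) or (
                isinstance(node, bool) and "boolean" not in allowed
            ):
                raise DataFormatError(f"{path}: expected {t}, got {type(node).__name__}")
        for req in sch.get("required", []):
            if req not in node:
                raise DataFormatError(f"{path}: missing required key {req!r}")
        for key, sub in sch.get("properties", {}).items():
            if isinstance(node, dict) and key in node:
                check(node[key], sub, f"{path}.{key}")
        if "items" in sch and isinstance(node, list):
            for i, item in enumerate(node):
                check(item, sch["items"], f"{path}[{i}]")

    check(doc, schema)


def write_report_json(report: NeighborhoodReport, stream: IO[str]) -> None:
    doc = report_to_dict(report)
    validate_report_dict(doc)
    json.dump(doc, stream, indent=2, sort_keys=False)
    stream.write("\n")


def read_report_json(stream: IO[str]) -> dict:
    doc = json.load(stream)
    validate_report_dict(doc)
    return doc


def write_report_text(report: NeighborhoodReport, stream: IO[str]) -> None:
    """Human-readable plain-text report."""
    w = stream.write
    w("PathwayLinker-style neighborhood report\n")
    w("=======================================\n\n")
    w(f"Query terms: {', '.join(report.query_terms)}\n")
    for term in sorted(report.resolved):
        w(f"  {term} -> {', '.join(report.resolved[term])}\n")
    for term in sorted(report.unresolved):
        w(f"  {term} -> UNRESOLVED\n")
    w(f"\nQuery proteins ({len(report.query)}):\n")
    for acc in sorted(report.query):
        w(f"  {acc}\n")
    w(f"\nFirst neighbors ({len(report.neighbors)}):\n")
    for acc in sorted(report.neighbors):
        mems = report.memberships.get(acc, [])
        label = (
            "; ".join(f"{s}::{n}" for s, n in mems) if mems else "(no pathway)"
        )
        w(f"  {acc}\t{label}\n")
    w("\nPathway membership counts in displayed set:\n")
    for (s, n), c in sorted(report.membership_counts.items()):
        w(f"  {s}::{n}\t{c}\n")
    w("\nEnrichment (sorted by adjusted p):\n")
    w("  source\tpathway\tN\tn\tK\tM\tp_raw\tp_adj\tsignificant\n")
    for r in report.enrichment:
        w(
            f"  {r.source_db}\t{r.pathway_name}\t{r.N}\t{r.n}\t{r.K}\t{r.M}"
            f"\t{r.p_raw:.6g}\t{r.p_adj:.6g}\t{'yes' if r.significant else 'no'}\n"
        )
    if report.warnings:
        w("\nWarnings:\n")
        for msg in report.warnings:
            w(f"  {msg}\n")


# ---------------------------------------------------------------------------
# network exports

def export_sif(subnetwork: IntegratedNetwork, stream: IO[str]) -> None:
    """Simple Interaction Format with relation label ``pp``.

    Isolated nodes are written as bare single-column rows, the SIF convention
    that keeps the node set round-trippable.
    """
    linked: set[str] = set()
    for e in subnetwork.interactions():
        stream.write(f"{e.a}\tpp\t{e.b}\n")
        linked.add(e.a)
        linked.add(e.b)
    for acc in sorted(set(subnetwork.proteins) - linked):
        stream.write(f"{acc}\n")


def parse_sif(stream: IO[str], species: str = "") -> IntegratedNetwork:
    """Inverse of :func:`export_sif` (provenance reduces to source ``sif``)."""
    interactions = []
    accessions: dict[str, None] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            accessions.setdefault(fields[0].strip())
        elif len(fields) == 3:
            a, rel, b = (f.strip() for f in fields)
            interactions.append(
                Interaction(
                    a, b, frozenset({"sif"}), frozenset({"small_scale_physical"})
                )
            )
            accessions.setdefault(a)
            accessions.setdefault(b)
        else:
            raise DataFormatError(f"line {lineno}: SIF rows have 1 or 3 columns")
    proteins = [ProteinRef(acc, acc, species) for acc in accessions]
    return build_network(interactions, proteins, allow_self_loops=True)


def to_networkx(subnetwork: IntegratedNetwork) -> nx.Graph:
    g = nx.Graph()
    g.graph["species"] = subnetwork.species
    for acc in sorted(subnetwork.proteins):
        p = subnetwork.proteins[acc]
        g.add_node(acc, display_name=p.display_name)
    for e in subnetwork.interactions():
        g.add_edge(
            e.a,
            e.b,
            sources="|".join(sorted(e.sources)),
            evidence_types="|".join(sorted(e.evidence_types)),
            pubmed_ids="|".join(sorted(e.pubmed_ids)),
        )
    return g


def export_graphml(subnetwork: IntegratedNetwork, stream: IO[str]) -> None:
    """GraphML via networkx, with provenance as pipe-joined edge attributes."""
    for line in nx.generate_graphml(to_networkx(subnetwork), named_key_ids=True):
        stream.write(line + "\n")


def parse_graphml(stream: IO[str]) -> IntegratedNetwork:
    """Inverse of :func:`export_graphml`, rebuilding full provenance."""
    g = nx.parse_graphml(stream.read())
    species = g.graph.get("species", "")
    proteins = [
        ProteinRef(acc, data.get("display_name", acc), species)
        for acc, data in sorted(g.nodes(data=True))
    ]
    interactions = []
    for a, b, data in g.edges(data=True):
        interactions.append(
            Interaction(
                a,
                b,
                frozenset(s for s in data.get("sources", "").split("|") if s),
                frozenset(
                    s for s in data.get("evidence_types", "").split("|") if s
                ),
                frozenset(s for s in data.get("pubmed_ids", "").split("|") if s),
            )
        )
    return build_network(interactions, proteins, allow_self_loops=True)
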