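"""Domain model: proteins, interactions, the integrated network, and query resolution.

The integrated network is an undirected multi-source interaction graph over
canonical accessions. Interactions carry their provenance (source databases,
evidence types, PubMed IDs); duplicate records of the same unordered protein
pair are merged by set union, mirroring how interaction databases that report
the same physical contact from different screens are integrated into a single
edge.

Query terms (gene names, synonyms, drug names) are resolved to accessions
through a scored synonym table — in "quick" mode the highest-scoring candidate
wins automatically, in "advanced" mode the caller supplies an explicit
selection per term. Drug names resolve to the drug's full target set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

EVIDENCE_TYPES = frozenset(
    {"small_scale_physical", "high_throughput_physical", "genetic"}
)


class PathLinkerError(Exception):
    """Base class for all errors raised by this package."""


class NetworkConstructionError(PathLinkerError):
    """Invalid input while assembling an integrated network."""


class ResolutionError(PathLinkerError):
    """Query-term resolution failed outright."""


def _fold(term: str) -> str:
    return term.strip().casefold()


@dataclass(frozen=True)
class ProteinRef:
    """A protein node: canonical accession plus display metadata.

    ``accession`` is an opaque, case-sensitive canonical identifier (in
    practice a UniProt primary accession, but any unique string works).
    """

    accession: str
    display_name: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.display_name:
            object.__setattr__(self, "display_name", self.accession)


@dataclass(frozen=True)
class Interaction:
    """One undirected interaction between two proteins, with provenance.

    Stored with canonical endpoint ordering (lexicographic on accession), so
    (a, b) and (b, a) are the same interaction.
    """

    a: str
    b: str
    sources: frozenset[str]
    evidence_types: frozenset[str]
    pubmed_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.a or not self.b:
            raise ValueError("interaction endpoints must be non-empty accessions")
        if self.b < self.a:
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)
        object.__setattr__(self, "sources", frozenset(self.sources))
        object.__setattr__(self, "evidence_types", frozenset(self.evidence_types))
        object.__setattr__(self, "pubmed_ids", frozenset(self.pubmed_ids))
        if not self.sources:
            raise ValueError("interaction needs at least one source database")
        bad = self.evidence_types - EVIDENCE_TYPES
        if bad or not self.evidence_types:
            raise ValueError(
                f"evidence_types must be a non-empty subset of {sorted(EVIDENCE_TYPES)}; "
                f"got {sorted(self.evidence_types)}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)

    def merged_with(self, other: "Interaction") -> "Interaction":
        if self.key != other.key:
            raise ValueError("cannot merge interactions of different pairs")
        return Interaction(
            self.a,
            self.b,
            self.sources | other.sources,
            self.evidence_types | other.evidence_types,
            self.pubmed_ids | other.pubmed_ids,
        )


class IntegratedNetwork:
    """Undirected multi-source interaction graph over canonical accessions.

    Invariants: every edge endpoint exists in ``proteins``; at most one stored
    interaction per unordered pair; the adjacency index equals the symmetric
    closure of the edge set (verifiable via :meth:`rebuild_adjacency`).
    """

    def __init__(
        self,
        species: str,
        proteins: Mapping[str, ProteinRef],
        edges: Mapping[tuple[str, str], Interaction],
    ) -> None:
        self.species = species
        self.proteins: dict[str, ProteinRef] = dict(proteins)
        self.edges: dict[tuple[str, str], Interaction] = dict(edges)
        self._adjacency = self.rebuild_adjacency()

    def rebuild_adjacency(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {acc: set() for acc in self.proteins}
        for (a, b) in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    @property
    def adjacency(self) -> dict[str, set[str]]:
        return self._adjacency

    def neighbors(self, accession: str) -> set[str]:
        return set(self._adjacency.get(accession, set()))

    def degree(self, accession: str) -> int:
        return len(self._adjacency.get(accession, set()))

    def interactions(self) -> list[Interaction]:
        return [self.edges[k] for k in sorted(self.edges)]

    def __contains__(self, accession: str) -> bool:
        return accession in self.proteins

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntegratedNetwork):
            return NotImplemented
        return (
            self.species == other.species
            and self.proteins == other.proteins
            and self.edges == other.edges
        )

    def __repr__(self) -> str:
        return (
            f"IntegratedNetwork(species={self.species!r}, "
            f"{len(self.proteins)} proteins, {len(self.edges)} edges)"
        )


def build_network(
    interactions: Iterable[Interaction],
    proteins: Iterable[ProteinRef],
    allow_self_loops: bool = False,
) -> IntegratedNetwork:
    """Assemble an :class:`IntegratedNetwork`, merging duplicate pairs.

    Duplicate unordered pairs are merged by union of sources, evidence types
    and PubMed IDs. Self-loops are dropped unless ``allow_self_loops`` — a
    self-edge would otherwise count a query protein as its own first neighbor.

    Raises :class:`NetworkConstructionError` if an endpoint accession is not in
    ``proteins`` or if the proteins span more than one species.
    """
    prot_map: dict[str, ProteinRef] = {}
    species_seen: set[str] = set()
    for p in proteins:
        prot_map[p.accession] = p
        species_seen.add(p.species)
    if len(species_seen) > 1:
        raise NetworkConstructionError(
            f"mixed species in one network: {sorted(species_seen)}"
        )
    species = next(iter(species_seen)) if species_seen else ""

    edges: dict[tuple[str, str], Interaction] = {}
    for inter in interactions:
        for acc in (inter.a, inter.b):
            if acc not in prot_map:
                raise NetworkConstructionError(
                    f"interaction endpoint {acc!r} missing from protein list"
                )
        if inter.a == inter.b and not allow_self_loops:
            continue
        if inter.key in edges:
            edges[inter.key] = edges[inter.key].merged_with(inter)
        else:
            edges[inter.key] = inter
    return IntegratedNetwork(species, prot_map, edges)


class SynonymTable:
    """Scored term → accession mapping with a persistent cache contract.

    Per-term candidate lists are kept sorted by score descending, ties broken
    lexicographically by accession, so the "highest-scoring" candidate is
    deterministic. Lookups are case-insensitive (terms are case-folded).

    Every lookup is recorded in an in-memory cache which can be persisted with
    :meth:`save_cache` and re-loaded with :meth:`load_cache`; cached lookups
    return results identical to the original resolution.
    """

    def __init__(
        self, entries: Mapping[str, Sequence[tuple[str, float]]] | None = None
    ) -> None:
        self._entries: dict[str, list[tuple[str, float]]] = {}
        self._cache: dict[str, list[tuple[str, float]]] = {}
        if entries:
            for term, cands in entries.items():
                for acc, score in cands:
                    self.add(term, acc, score)

    def add(self, term: str, accession: str, score: float) -> None:
        if score < 0:
            raise ValueError(f"negative synonym score {score} for term {term!r}")
        key = _fold(term)
        cands = self._entries.setdefault(key, [])
        for i, (acc, old) in enumerate(cands):
            if acc == accession:
                # duplicate (term, accession): keep the max score
                if score > old:
                    cands[i] = (acc, score)
                break
        else:
            cands.append((accession, score))
        cands.sort(key=lambda c: (-c[1], c[0]))

    def candidates(self, term: str) -> list[tuple[str, float]]:
        """Ordered candidate list for ``term`` (cache-backed, may be empty)."""
        key = _fold(term)
        if key in self._cache:
            return list(self._cache[key])
        result = list(self._entries.get(key, []))
        self._cache[key] = result
        return list(result)

    def __contains__(self, term: str) -> bool:
        return bool(self.candidates(term))

    def __len__(self) -> int:
        return len(self._entries)

    def save_cache(self, path: str | Path) -> None:
        payload = {t: [[a, s] for a, s in c] for t, c in sorted(self._cache.items())}
        Path(path).write_text(json.dumps(payload, indent=0, sort_keys=True))

    def load_cache(self, path: str | Path) -> None:
        payload = json.loads(Path(path).read_text())
        for term, cands in payload.items():
            self._cache[term] = [(a, float(s)) for a, s in cands]
            # cached resolutions double as entries for future lookups
            self._entries.setdefault(term, [(a, float(s)) for a, s in cands])


class DrugTargetTable:
    """Drug/compound name → set of target accessions (case-folded keys)."""

    def __init__(self, mapping: Mapping[str, Iterable[str]] | None = None) -> None:
        self._targets: dict[str, frozenset[str]] = {}
        if mapping:
            for drug, accs in mapping.items():
                self.add(drug, accs)

    def add(self, drug: str, accessions: Iterable[str]) -> None:
        accs = frozenset(a for a in accessions if a)
        if not accs:
            return  # empty target sets are not stored
        key = _fold(drug)
        self._targets[key] = self._targets.get(key, frozenset()) | accs

    def targets(self, drug: str) -> frozenset[str]:
        return self._targets.get(_fold(drug), frozenset())

    def __contains__(self, drug: str) -> bool:
        return _fold(drug) in self._targets

    def __len__(self) -> int:
        return len(self._targets)


def resolve_terms(
    terms: Sequence[str],
    table: SynonymTable,
    drugs: Optional[DrugTargetTable] = None,
    mode: str = "quick",
    selections: Optional[Mapping[str, Iterable[str]]] = None,
) -> tuple[dict[str, set[str]], list[str]]:
    """Resolve query terms to accession sets.

    Quick mode picks, per term, the single highest-scoring accession
    (lexicographic tie-break). A term found in the drug table resolves to the
    drug's full target set instead. Advanced mode returns exactly the caller's
    ``selections`` (each must be a subset of the term's candidates). Unresolved
    terms are returned as a warning list, not fatal — unless *every* term is
    unresolved, which raises :class:`ResolutionError`.
    """
    if not terms:
        raise ResolutionError("no query terms given")
    if mode not in ("quick", "advanced"):
        raise ValueError(f"unknown resolution mode {mode!r}")
    folded_selections = {_fold(t): set(a) for t, a in (selections or {}).items()}

    resolved: dict[str, set[str]] = {}
    unresolved: list[str] = []
    for term in terms:
        if drugs is not None and term in drugs:
            resolved[term] = set(drugs.targets(term))
            continue
        cands = table.candidates(term)
        if not cands:
            unresolved.append(term)
            continue
        if mode == "quick":
            resolved[term] = {cands[0][0]}
        else:
            chosen = folded_selections.get(_fold(term))
            if chosen is None:
                unresolved.append(term)
                continue
            cand_accs = {a for a, _ in cands}
            for acc in sorted(chosen):
                if acc not in cand_accs:
                    raise ResolutionError(
                        f"advanced selection {acc!r} for term {term!r} "
                        f"is not among its candidates"
                    )
            resolved[term] = set(chosen)
    if not resolved:
        raise ResolutionError("no query could be resolved")
    return resolved, unresolved
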