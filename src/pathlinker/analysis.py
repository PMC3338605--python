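"""First-neighbor extraction, pathway annotation, and overrepresentation.

The statistical question: given the displayed set (the queried proteins plus
their first-neighbor interactors, n proteins drawn from a species background
of M proteins), is a signaling pathway S with K members overrepresented among
them? The score is the hypergeometric upper tail

    P(X >= N) = sum_{i=N}^{min(n,K)} C(K,i) C(M-K, n-i) / C(M,n),

the probability of seeing at least the observed overlap N by chance when
drawing n proteins without replacement. Each (pathway source database,
pathway) pair is tested separately; the family of all tests in one run is
adjusted with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import false_discovery_control

from .model import (
    IntegratedNetwork,
    Interaction,
    PathLinkerError,
    ProteinRef,
    build_network,
)

logger = logging.getLogger(__name__)

PathwayKey = tuple[str, str]  # (source_db, pathway_name)


class AnalysisError(PathLinkerError):
    """Invalid parameters or inputs in the analysis stage."""


class AnalysisStageError(AnalysisError):
    """An error propagated from a pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PathwayCollection:
    """Named protein sets grouped by pathway source database, plus background.

    ``universe`` may be an explicit accession set (then M = |universe| and
    pathway members outside it are dropped with a warning) or absent, in which
    case ``universe_size`` declares M directly. With neither, M must be fixed
    by the caller before testing (see :func:`run_analysis`).
    """

    pathways: dict[PathwayKey, frozenset[str]] = field(default_factory=dict)
    universe: Optional[frozenset[str]] = None
    universe_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            self.universe = frozenset(self.universe)
            trimmed = {}
            for key, members in self.pathways.items():
                outside = members - self.universe
                if outside:
                    logger.warning(
                        "pathway %s::%s: %d member(s) outside the declared "
                        "universe dropped",
                        key[0], key[1], len(outside),
                    )
                trimmed[key] = frozenset(members & self.universe)
            self.pathways = trimmed
            self.universe_size = len(self.universe)
        if self.universe_size is not None:
            for (src, name), members in self.pathways.items():
                if len(members) > self.universe_size:
                    raise AnalysisError(
                        f"pathway {src}::{name} has {len(members)} members, "
                        f"larger than the declared universe M={self.universe_size}"
                    )

    @property
    def sources(self) -> set[str]:
        return {src for src, _ in self.pathways}

    def members(self, source_db: str, pathway_name: str) -> frozenset[str]:
        return self.pathways.get((source_db, pathway_name), frozenset())

    def all_members(self) -> frozenset[str]:
        out: set[str] = set()
        for m in self.pathways.values():
            out |= m
        return frozenset(out)


@dataclass
class EnrichmentRecord:
    """One pathway's overlap counts and raw/adjusted p-values.

    N = overlap between the analyzed set and the pathway; n = analyzed-set
    size; K = pathway size; M = universe size.
    """

    source_db: str
    pathway_name: str
    N: int
    n: int
    K: int
    M: int
    p_raw: float
    p_adj: float = float("nan")
    significant: bool = False


@dataclass
class NeighborhoodReport:
    """The full result of one analysis run."""

    query_terms: list[str]
    resolved: dict[str, list[str]]          # term -> sorted accessions
    unresolved: list[str]
    query: set[str]                         # union of resolved accessions
    neighbors: set[str]                     # first neighbors, query excluded
    memberships: dict[str, list[PathwayKey]]
    membership_counts: dict[PathwayKey, int]
    subnetwork: IntegratedNetwork
    enrichment: list[EnrichmentRecord]
    config: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def displayed(self) -> set[str]:
        return self.query | self.neighbors


def _log_choose(a: float, b: float) -> float:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(N: int, n: int, K: int, M: int) -> float:
    """P(X >= N) for X ~ Hypergeometric(M, K, n), computed in log space.

    Parameters: N observed overlap, n draws (analyzed-set size), K successes
    in the universe (pathway size), M universe size. Stable for M up to 1e5
    and beyond, since each term is assembled from log-factorials.
    """
    for ok, ineq in (
        (0 <= N, "0 <= N"),
        (N <= n, "N <= n"),
        (n <= M, "n <= M"),
        (K <= M, "K <= M"),
        (0 <= K, "0 <= K"),
        (N <= K, "N <= K"),
    ):
        if not ok:
            raise AnalysisError(
                f"hypergeometric parameter constraint violated: {ineq} "
                f"(N={N}, n={n}, K={K}, M={M})"
            )
    if N == 0:
        return 1.0
    hi = min(n, K)
    log_denom = _log_choose(M, n)
    log_terms = [
        _log_choose(K, i) + _log_choose(M - K, n - i) - log_denom
        for i in range(N, hi + 1)
    ]
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def hypergeom_pmf(i: int, n: int, K: int, M: int) -> float:
    """P(X = i), exposed for normalization checks."""
    if i < max(0, n - (M - K)) or i > min(n, K):
        return 0.0
    return math.exp(_log_choose(K, i) + _log_choose(M - K, n - i) - _log_choose(M, n))


def adjust_pvalues(
    records: Sequence[EnrichmentRecord],
    method: str = "benjamini_hochberg",
    threshold: float = 0.05,
) -> list[EnrichmentRecord]:
    """Benjamini-Hochberg step-up over the whole family of pathway tests.

    Returns new records with ``p_adj`` filled in and ``significant`` set at
    ``threshold``. Raw p-values are always preserved so users may apply their
    own procedure.
    """
    if method != "benjamini_hochberg":
        raise AnalysisError(f"unknown adjustment method {method!r}")
    if not records:
        return []
    p_raw = np.array([r.p_raw for r in records], dtype=float)
    if np.any(p_raw <= 0) or np.any(p_raw > 1):
        raise AnalysisError("raw p-values must lie in (0, 1]")
    p_adj = false_discovery_control(p_raw, method="bh")
    return [
        replace(r, p_adj=float(pa), significant=bool(pa <= threshold))
        for r, pa in zip(records, p_adj)
    ]


def first_neighbors(
    network: IntegratedNetwork,
    query: Iterable[str],
    source_filter: Optional[Iterable[str]] = None,
    evidence_filter: Optional[Iterable[str]] = None,
) -> tuple[set[str], IntegratedNetwork]:
    """First-neighbor set and induced subnetwork under evidence filters.

    An edge qualifies iff its sources intersect ``source_filter`` AND its
    evidence types intersect ``evidence_filter`` (``None`` means no filter).
    Neighbors are the endpoints of qualifying edges incident to the query,
    minus the query itself. The subnetwork holds all qualifying edges among
    the displayed set, including neighbor-neighbor edges.

    Unknown query accessions are dropped with a warning; an empty query after
    dropping raises :class:`AnalysisError`.
    """
    src_f = set(source_filter) if source_filter is not None else None
    ev_f = set(evidence_filter) if evidence_filter is not None else None

    qset = set(query)
    known = {q for q in qset if q in network}
    for missing in sorted(qset - known):
        logger.warning("query accession %r not in network; dropped", missing)
    if not known:
        raise AnalysisError("empty query: no query accession is in the network")

    def qualifies(e: Interaction) -> bool:
        if src_f is not None and not (e.sources & src_f):
            return False
        if ev_f is not None and not (e.evidence_types & ev_f):
            return False
        return True

    neighbors: set[str] = set()
    for e in network.edges.values():
        if not qualifies(e):
            continue
        if e.a in known:
            neighbors.add(e.b)
        if e.b in known:
            neighbors.add(e.a)
    neighbors -= known

    displayed = known | neighbors
    sub_edges = [
        e
        for e in network.edges.values()
        if qualifies(e) and e.a in displayed and e.b in displayed
    ]
    sub_proteins = [network.proteins[acc] for acc in sorted(displayed)]
    subnetwork = build_network(sub_edges, sub_proteins, allow_self_loops=True)
    return neighbors, subnetwork


def annotate_memberships(
    displayed: Iterable[str], collection: PathwayCollection
) -> tuple[dict[str, list[PathwayKey]], dict[PathwayKey, int]]:
    """Per-protein pathway memberships and per-pathway counts in the set.

    Proteins with no memberships map to an empty list; counts are consistent
    with the per-protein lists by construction.
    """
    dset = set(displayed)
    memberships: dict[str, list[PathwayKey]] = {acc: [] for acc in dset}
    counts: dict[PathwayKey, int] = {}
    for key in sorted(collection.pathways):
        members = collection.pathways[key]
        hit = dset & members
        if hit:
            counts[key] = len(hit)
            for acc in hit:
                memberships[acc].append(key)
    for acc in memberships:
        memberships[acc].sort()
    return memberships, counts


def enrich(
    analyzed: Iterable[str],
    collection: PathwayCollection,
    threshold: float = 0.05,
    universe_size: Optional[int] = None,
) -> list[EnrichmentRecord]:
    """Hypergeometric overrepresentation of every pathway in ``analyzed``.

    Each (source database, pathway) pair is one test; tests are never pooled
    across source databases. When the collection carries an explicit universe
    set, analyzed proteins outside it are dropped from n (with a warning) so
    that n <= M always holds. Returns records sorted by adjusted p ascending,
    ties broken by (source_db, pathway_name).
    """
    aset = set(analyzed)
    M = universe_size if universe_size is not None else collection.universe_size
    if M is None:
        raise AnalysisError("universe size M is not defined for this collection")
    if collection.universe is not None:
        outside = aset - collection.universe
        if outside:
            logger.warning(
                "%d analyzed protein(s) outside the universe dropped from n",
                len(outside),
            )
            aset -= outside
    n = len(aset)
    if n > M:
        raise AnalysisError(f"analyzed-set size n={n} exceeds universe M={M}")

    records = []
    for (src, name) in sorted(collection.pathways):
        members = collection.pathways[(src, name)]
        K = len(members)
        N = len(aset & members)
        p = hypergeom_upper_tail(N, n, K, M)
        records.append(EnrichmentRecord(src, name, N, n, K, M, p_raw=p))
    records = adjust_pvalues(records, threshold=threshold)
    records.sort(key=lambda r: (r.p_adj, r.source_db, r.pathway_name))
    return records


def run_analysis(
    network: IntegratedNetwork,
    collection: PathwayCollection,
    query_terms: Sequence[str],
    synonym_table,
    drug_table=None,
    mode: str = "quick",
    selections: Optional[Mapping[str, Iterable[str]]] = None,
    source_filter: Optional[Iterable[str]] = None,
    evidence_filter: Optional[Iterable[str]] = None,
    overlap_mode: str = "displayed",
    mtc_threshold: float = 0.05,
    config: Optional[dict] = None,
) -> NeighborhoodReport:
    """End-to-end pipeline: resolve -> neighbors -> annotate -> enrich -> adjust.

    ``overlap_mode`` selects the set that enters the overrepresentation test:
    ``"displayed"`` (query plus neighbors, the default) or ``"neighbors-only"``.
    Deterministic for fixed inputs. Stage failures are re-raised as
    :class:`AnalysisStageError` tagged with the stage name.
    """
    from .model import resolve_terms  # local import keeps module surfaces clean

    if overlap_mode not in ("displayed", "neighbors-only"):
        raise AnalysisError(f"unknown overlap mode {overlap_mode!r}")
    warnings: list[str] = []

    try:
        resolved, unresolved = resolve_terms(
            query_terms, synonym_table, drug_table, mode=mode, selections=selections
        )
    except PathLinkerError as exc:
        raise AnalysisStageError("resolve", exc) from exc
    for term in unresolved:
        warnings.append(f"unresolved query term: {term}")
    query: set[str] = set()
    for accs in resolved.values():
        query |= accs  # two terms resolving to one protein deduplicate here

    try:
        in_network = {q for q in query if q in network}
        if in_network:
            neighbors, subnetwork = first_neighbors(
                network, in_network, source_filter, evidence_filter
            )
        else:
            neighbors = set()
            subnetwork = build_network([], [], allow_self_loops=True)
            warnings.append("no query protein found in the network")
        for q in sorted(query - in_network):
            warnings.append(f"query accession not in network: {q}")
    except PathLinkerError as exc:
        raise AnalysisStageError("first_neighbors", exc) from exc

    displayed = query | neighbors
    try:
        memberships, counts = annotate_memberships(displayed, collection)
    except PathLinkerError as exc:
        raise AnalysisStageError("annotate", exc) from exc

    analyzed = displayed if overlap_mode == "displayed" else neighbors
    try:
        universe_size = collection.universe_size
        if universe_size is None:
            fallback = set(network.proteins) | set(collection.all_members())
            universe_size = len(fallback)
            msg = (
                "no universe declared; using M = |network proteins ∪ pathway "
                f"members| = {universe_size}"
            )
            logger.warning(msg)
            warnings.append(msg)
        records = (
            enrich(analyzed, collection, mtc_threshold, universe_size)
            if analyzed
            else []
        )
    except PathLinkerError as exc:
        raise AnalysisStageError("enrich", exc) from exc

    full_config = {
        "mode": mode,
        "source_filter": sorted(source_filter) if source_filter is not None else None,
        "evidence_filter": (
            sorted(evidence_filter) if evidence_filter is not None else None
        ),
        "overlap_mode": overlap_mode,
        "mtc_method": "benjamini_hochberg",
        "mtc_threshold": mtc_threshold,
        "universe_size": universe_size,
        "species": network.species,
    }
    if config:
        full_config.update(config)

    return NeighborhoodReport(
        query_terms=list(query_terms),
        resolved={t: sorted(a) for t, a in resolved.items()},
        unresolved=list(unresolved),
        query=query,
        neighbors=neighbors,
        memberships=memberships,
        membership_counts=counts,
        subnetwork=subnetwork,
        enrichment=records,
        config=full_config,
        warnings=warnings,
    )
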