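"""The scientific core: hypergeometric tail, BH adjustment, neighborhoods."""

import io
import itertools
import math
import random
from fractions import Fraction

import numpy as np
import pytest
from scipy.stats import hypergeom

from pathlinker.analysis import (
    AnalysisError,
    AnalysisStageError,
    EnrichmentRecord,
    PathwayCollection,
    adjust_pvalues,
    annotate_memberships,
    enrich,
    first_neighbors,
    hypergeom_pmf,
    hypergeom_upper_tail,
    run_analysis,
)
from pathlinker.fixtures import generate_synthetic, load_fixture
from pathlinker.io import write_report_json
from pathlinker.model import Interaction, ProteinRef, SynonymTable, build_network

from conftest import star_network


def brute_force_tail(N, n, K, M):
    """Exhaustive enumeration over all C(M, n) draws (exact rational)."""
    marked = set(range(K))
    hit = total = 0
    for draw in itertools.combinations(range(M), n):
        total += 1
        if sum(1 for x in draw if x in marked) >= N:
            hit += 1
    return Fraction(hit, total)


class TestHypergeomUpperTail:
    def test_zero_overlap_is_exactly_one(self):
        assert hypergeom_upper_tail(0, 5, 3, 50) == 1.0

    @pytest.mark.parametrize(
        "N,n,K,M,expected",
        [
            (4, 4, 5, 10, 5 / 210),          # enumeration: 1/42
            (3, 6, 7, 20, 217 / 646),        # enumeration oracle, frozen
        ],
    )
    def test_frozen_enumeration_values(self, N, n, K, M, expected):
        assert hypergeom_upper_tail(N, n, K, M) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_on_small_grid(self):
        # spot grid here; the exhaustive M<=12 sweep lives in the acceptance suite
        for M in (5, 8):
            for K in range(M + 1):
                for n in range(1, M + 1):
                    for N in range(0, min(n, K) + 1):
                        exact = float(brute_force_tail(N, n, K, M))
                        got = hypergeom_upper_tail(N, n, K, M)
                        assert got == pytest.approx(exact, rel=1e-12, abs=1e-15)

    def test_matches_scipy_survival_function_at_scale(self):
        # independent cross-check against scipy's sf at realistic M
        for N, n, K, M in [(3, 10, 50, 20000), (6, 10, 9, 20000), (1, 4, 5, 100000)]:
            assert hypergeom_upper_tail(N, n, K, M) == pytest.approx(
                hypergeom.sf(N - 1, M, K, n), rel=1e-10
            )

    def test_strictly_decreasing_in_overlap(self):
        M, K, n = 1000, 40, 25
        vals = [hypergeom_upper_tail(N, n, K, M) for N in range(0, min(n, K) + 1)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_pmf_normalizes_to_one(self):
        for n, K, M in [(4, 5, 10), (6, 7, 20), (25, 40, 1000)]:
            total = sum(hypergeom_pmf(i, n, K, M) for i in range(0, min(n, K) + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "N,n,K,M,ineq",
        [(-1, 4, 5, 10, "0 <= N"), (5, 4, 5, 10, "N <= n"),
         (2, 11, 5, 10, "n <= M"), (2, 4, 11, 10, "K <= M"),
         (4, 4, 3, 10, "N <= K")],
    )
    def test_constraint_violations_name_the_inequality(self, N, n, K, M, ineq):
        with pytest.raises(AnalysisError, match=ineq.replace("<=", "<=")):
            hypergeom_upper_tail(N, n, K, M)


class TestAdjustPvalues:
    def rec(self, p):
        return EnrichmentRecord("db", f"pw{p}", 1, 5, 3, 100, p_raw=p)

    def test_single_record_is_identity(self):
        out = adjust_pvalues([self.rec(0.04)])
        assert out[0].p_adj == pytest.approx(0.04) and out[0].significant

    def test_worked_three_pvalue_example(self):
        out = adjust_pvalues([self.rec(p) for p in (0.01, 0.02, 0.04)])
        assert [r.p_adj for r in out] == pytest.approx([0.03, 0.03, 0.04])

    def test_all_ones_never_significant(self):
        out = adjust_pvalues([self.rec(1.0) for _ in range(4)])
        assert not any(r.significant for r in out)
        assert all(r.p_adj == 1.0 for r in out)

    def test_adjusted_dominates_raw_and_is_rank_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ps = rng.uniform(1e-6, 1.0, size=rng.integers(1, 30))
            out = adjust_pvalues([self.rec(float(p)) for p in ps])
            assert all(r.p_adj >= r.p_raw - 1e-15 for r in out)
            assert all(r.p_adj <= 1.0 for r in out)
            by_raw = sorted(out, key=lambda r: r.p_raw)
            adj = [r.p_adj for r in by_raw]
            assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))

    def test_invalid_raw_pvalues_rejected(self):
        with pytest.raises(AnalysisError, match=r"\(0, 1\]"):
            adjust_pvalues([self.rec(0.0)])


def naive_first_neighbors(network, query, src_f=None, ev_f=None):
    """Double-loop edge-scan oracle, independent of the adjacency index."""
    out = set()
    for e in network.edges.values():
        if src_f is not None and not (set(e.sources) & src_f):
            continue
        if ev_f is not None and not (set(e.evidence_types) & ev_f):
            continue
        if e.a in query:
            out.add(e.b)
        if e.b in query:
            out.add(e.a)
    return out - set(query)


class TestFirstNeighbors:
    def test_star_without_filters(self, star9):
        neighbors, sub = first_neighbors(star9, {"Q"})
        assert len(neighbors) == 9
        assert set(sub.proteins) == neighbors | {"Q"}

    def test_filter_excluding_all_evidence_gives_no_neighbors(self, star9):
        neighbors, sub = first_neighbors(star9, {"Q"}, evidence_filter={"genetic"})
        assert neighbors == set()
        assert set(sub.proteins) == {"Q"} and len(sub.edges) == 0

    def test_subnetwork_includes_neighbor_neighbor_edges(self):
        prots = [ProteinRef(x) for x in ("Q", "A", "B", "C")]
        edges = [
            Interaction("Q", "A", frozenset({"s"}), frozenset({"genetic"})),
            Interaction("Q", "B", frozenset({"s"}), frozenset({"genetic"})),
            Interaction("A", "B", frozenset({"s"}), frozenset({"genetic"})),
            Interaction("B", "C", frozenset({"s"}), frozenset({"genetic"})),
        ]
        net = build_network(edges, prots)
        neighbors, sub = first_neighbors(net, {"Q"})
        assert neighbors == {"A", "B"}
        assert ("A", "B") in sub.edges          # neighbor-neighbor retained
        assert ("B", "C") not in sub.edges      # C is not displayed

    def test_unknown_query_dropped_and_all_unknown_errors(self, star9):
        neighbors, _ = first_neighbors(star9, {"Q", "GHOST"})
        assert len(neighbors) == 9
        with pytest.raises(AnalysisError, match="empty query"):
            first_neighbors(star9, {"GHOST"})

    def test_agrees_with_edge_scan_oracle_on_random_networks(self):
        rng = random.Random(0)
        all_ev = ["small_scale_physical", "high_throughput_physical", "genetic"]
        all_src = ["BioGRID", "STRING", "WI8"]
        for seed in range(30):
            n = rng.randint(5, 200)
            m = rng.randint(0, min(150, n * (n - 1) // 2))
            net, _ = generate_synthetic(n, m, 1, (2, 2), seed=seed)
            accs = sorted(net.proteins)
            query = set(rng.sample(accs, rng.randint(1, min(5, len(accs)))))
            src_f = set(rng.sample(all_src, 2)) if rng.random() < 0.5 else None
            ev_f = set(rng.sample(all_ev, 2)) if rng.random() < 0.5 else None
            expected = naive_first_neighbors(net, query, src_f, ev_f)
            try:
                got, _ = first_neighbors(net, query, src_f, ev_f)
            except AnalysisError:
                assert not expected or not (query & set(net.proteins))
                continue
            assert got == expected

    def test_enlarging_filters_never_shrinks_neighbor_set(self):
        net, _ = generate_synthetic(60, 120, 1, (2, 2), seed=11)
        small, _ = first_neighbors(net, {"SYN00"}, evidence_filter={"genetic"})
        bigger, _ = first_neighbors(
            net, {"SYN00"}, evidence_filter={"genetic", "small_scale_physical"}
        )
        full, _ = first_neighbors(net, {"SYN00"})
        assert small <= bigger <= full


class TestAnnotateMemberships:
    def test_counts_consistent_with_per_protein_lists(self, small_collection):
        displayed = {"N1", "N2", "N3", "N4"}
        memberships, counts = annotate_memberships(displayed, small_collection)
        assert memberships["N4"] == []
        assert counts[("SignaLink", "WNT")] == 2
        assert counts[("KEGG", "MAPK")] == 1
        recount = {}
        for acc, mems in memberships.items():
            for key in mems:
                recount[key] = recount.get(key, 0) + 1
        assert recount == counts

    def test_empty_displayed_set(self, small_collection):
        memberships, counts = annotate_memberships(set(), small_collection)
        assert memberships == {} and counts == {}


class TestEnrich:
    def test_pathway_disjoint_from_set_has_p_one(self, small_collection):
        records = enrich({"N4", "N5"}, small_collection)
        assert all(r.p_raw == 1.0 for r in records)

    def test_pathway_equal_to_set_has_minimal_p(self):
        coll = PathwayCollection(
            pathways={
                ("db", "exact"): frozenset({"A", "B", "C"}),
                ("db", "half"): frozenset({"A", "Z1", "Z2"}),
                ("db", "none"): frozenset({"Z3", "Z4"}),
            },
            universe_size=10000,
        )
        records = enrich({"A", "B", "C"}, coll)
        assert records[0].pathway_name == "exact"
        assert records[0].p_raw == min(r.p_raw for r in records)

    def test_explicit_universe_drops_outside_proteins_from_n(self, caplog):
        coll = PathwayCollection(
            pathways={("db", "p"): frozenset({"A", "B"})},
            universe=frozenset({"A", "B", "C", "D"}),
        )
        records = enrich({"A", "OUTSIDER"}, coll)
        assert records[0].n == 1 and records[0].M == 4

    def test_sorted_by_adjusted_p_then_name(self):
        coll = PathwayCollection(
            pathways={
                ("b", "z"): frozenset({"A"}),
                ("a", "y"): frozenset({"A"}),
                ("a", "x"): frozenset({"Z9"}),
            },
            universe_size=1000,
        )
        records = enrich({"A"}, coll)
        keys = [(r.source_db, r.pathway_name) for r in records]
        assert keys == [("a", "y"), ("b", "z"), ("a", "x")]


class TestRunAnalysis:
    def test_cdc25_fixture_end_to_end(self):
        b = load_fixture("cdc25")
        report = run_analysis(
            b.network, b.collection, ["cdc-25.1"], b.synonyms, b.drugs
        )
        assert len(report.neighbors) == 9
        with_membership = [
            acc for acc in report.neighbors if report.memberships[acc]
        ]
        assert len(with_membership) == 6

    def test_query_absent_from_network_still_reports(self):
        net = star_network(n_leaves=2)
        coll = PathwayCollection(
            pathways={("db", "p"): frozenset({"LONER"})}, universe_size=100
        )
        table = SynonymTable({"loner": [("LONER", 1.0)]})
        report = run_analysis(net, coll, ["loner"], table)
        assert report.neighbors == set()
        assert report.query == {"LONER"}
        assert report.enrichment[0].n == 1 and report.enrichment[0].N == 1

    def test_drug_query_matches_direct_protein_query(self):
        b = load_fixture("gja1")
        via_drug = run_analysis(
            b.network, b.collection, ["methotrexate"], b.synonyms, b.drugs
        )
        direct = run_analysis(
            b.network, b.collection, ["gja1"], b.synonyms, b.drugs
        )
        assert via_drug.displayed == direct.displayed

    def test_stage_errors_are_tagged(self, star9, small_collection):
        with pytest.raises(AnalysisStageError, match=r"\[resolve\]"):
            run_analysis(star9, small_collection, ["nope"], SynonymTable())

    def test_two_runs_yield_byte_identical_json(self):
        b = load_fixture("gja1")
        outs = []
        for _ in range(2):
            report = run_analysis(
                b.network, b.collection, ["gja1", "cisplatin"], b.synonyms, b.drugs
            )
            buf = io.StringIO()
            write_report_json(report, buf)
            outs.append(buf.getvalue())
        assert outs[0] == outs[1]

    def test_overlap_mode_neighbors_only_excludes_query(self, star9):
        coll = PathwayCollection(
            pathways={("db", "p"): frozenset({"Q", "N1"})}, universe_size=100
        )
        table = SynonymTable({"q": [("Q", 1.0)]})
        displayed = run_analysis(star9, coll, ["q"], table)
        neigh_only = run_analysis(
            star9, coll, ["q"], table, overlap_mode="neighbors-only"
        )
        assert displayed.enrichment[0].N == 2
        assert neigh_only.enrichment[0].N == 1

    def test_missing_universe_falls_back_with_warning(self, star9):
        coll = PathwayCollection(pathways={("db", "p"): frozenset({"N1", "ZZ"})})
        table = SynonymTable({"q": [("Q", 1.0)]})
        report = run_analysis(star9, coll, ["q"], table)
        # 10 network proteins plus pathway member ZZ
        assert report.enrichment[0].M == 11
        assert any("universe" in w for w in report.warnings)
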