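"""Packaged case-study fixtures and a seeded synthetic generator.

Three small, self-contained datasets reconstruct published first-neighbor
case studies — the worm cell-cycle regulator CDC-25.1 (nine interactors, six
of them central signaling proteins), the uncharacterized worm gene C27F2.4
(three interactors, one a WNT/EGF-MAPK member), and the human drug target
GJA1/Connexin-43 (named kinase and WNT-component interactors, reachable
through three anti-cancer drugs). They are transparent reconstructions from
the printed protein names, not database snapshots: unnamed interactors are
placeholder nodes (X1, X2, ...) carrying no pathway annotation.

Each fixture ships a manifest of expected counts that is re-verified on every
load, so the packaged files cannot silently drift from the numbers the test
suite asserts.

``generate_synthetic`` draws arbitrary random networks and pathway
collections under a mandatory seed, for property testing at any size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .analysis import PathwayCollection, annotate_memberships, first_neighbors
from .io import read_drug_targets, read_edge_list, read_gmt, read_mapping_table
from .model import (
    DrugTargetTable,
    IntegratedNetwork,
    Interaction,
    PathLinkerError,
    ProteinRef,
    SynonymTable,
    build_network,
)

FIXTURE_NAMES = ("cdc25", "c27f24", "gja1")


class FixtureError(PathLinkerError):
    """Unknown fixture or a manifest count that fails to reproduce."""


@dataclass
class FixtureBundle:
    name: str
    network: IntegratedNetwork
    collection: PathwayCollection
    synonyms: SynonymTable
    drugs: Optional[DrugTargetTable]
    manifest: dict


def _fixture_dir(name: str):
    if name not in FIXTURE_NAMES:
        raise FixtureError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    return resources.files("pathlinker") / "data" / name


def load_fixture(name: str) -> FixtureBundle:
    """Load a packaged fixture and verify its manifest counts.

    Raises :class:`FixtureError` if any expected count fails to reproduce —
    the manifest is the executable form of the case study's printed numbers.
    """
    d = _fixture_dir(name)
    manifest = json.loads((d / "manifest.json").read_text())
    species = manifest["species"]
    with (d / "edges.tsv").open() as fh:
        interactions, proteins = read_edge_list(fh, species=species)
    network = build_network(interactions, proteins)
    with (d / "pathways.gmt").open() as fh:
        collection = read_gmt(fh, universe_size=manifest["universe_size"])
    with (d / "mapping.tsv").open() as fh:
        synonyms = read_mapping_table(fh)
    drugs = None
    drugs_path = d / "drugs.tsv"
    if drugs_path.is_file():
        with drugs_path.open() as fh:
            drugs = read_drug_targets(fh)
    bundle = FixtureBundle(name, network, collection, synonyms, drugs, manifest)
    _verify_manifest(bundle)
    return bundle


def _verify_manifest(bundle: FixtureBundle) -> None:
    m = bundle.manifest
    net, coll = bundle.network, bundle.collection

    def expect(label: str, got, want) -> None:
        if got != want:
            raise FixtureError(
                f"fixture {bundle.name}: {label} = {got!r}, manifest says {want!r}"
            )

    expect("edge count", len(net.edges), m["n_edges"])
    query = m["query_accession"]
    neighbors, _ = first_neighbors(net, {query})
    expect("neighbor count", len(neighbors), m["n_neighbors"])
    if "neighbors" in m:
        expect("neighbor set", sorted(neighbors), sorted(m["neighbors"]))
    memberships, _ = annotate_memberships(neighbors, coll)
    n_with = sum(1 for mem in memberships.values() if mem)
    if "n_neighbors_with_membership" in m:
        expect("neighbors with >=1 membership", n_with, m["n_neighbors_with_membership"])
    if "n_neighbors_without_membership" in m:
        expect(
            "neighbors with no membership",
            len(neighbors) - n_with,
            m["n_neighbors_without_membership"],
        )
    if "pathways" in m:
        expect(
            "pathway names",
            sorted(name for _, name in coll.pathways),
            sorted(m["pathways"]),
        )
    if "bar1_memberships" in m:
        expect(
            "BAR-1 memberships",
            [list(k) for k in memberships.get("BAR-1", [])],
            m["bar1_memberships"],
        )
    if "egf_mapk_direct_interactors" in m:
        egf = coll.members("SignaLink", "EGF/MAPK")
        expect(
            "EGF/MAPK members among direct interactors",
            len(neighbors & egf),
            m["egf_mapk_direct_interactors"],
        )
    if "wnt_direct_interactors" in m:
        wnt = coll.members("SignaLink", "WNT")
        expect(
            "WNT members among direct interactors",
            len(neighbors & wnt),
            m["wnt_direct_interactors"],
        )
    if "multi_pathway_interactor" in m:
        acc = m["multi_pathway_interactor"]
        if len(memberships.get(acc, [])) < 2:
            raise FixtureError(
                f"fixture {bundle.name}: {acc} should belong to >=2 pathways"
            )
    if "drugs" in m:
        if bundle.drugs is None:
            raise FixtureError(f"fixture {bundle.name}: drug table missing")
        expect("drug count", len(bundle.drugs), len(m["drugs"]))
        for drug in m["drugs"]:
            if query not in bundle.drugs.targets(drug):
                raise FixtureError(
                    f"fixture {bundle.name}: drug {drug!r} does not target {query}"
                )


def generate_synthetic(
    n_proteins: int,
    n_edges: int,
    n_pathways: int,
    pathway_size_range: tuple[int, int],
    seed: int,
    species: str = "synthetic",
) -> tuple[IntegratedNetwork, PathwayCollection]:
    """Random simple network plus random pathway collection, fully seeded.

    Edges are sampled uniformly without replacement from all unordered pairs;
    pathway sizes uniformly from ``pathway_size_range`` (inclusive) and
    members uniformly without replacement from the proteins. The universe is
    the full generated protein set. Identical seeds give identical output.
    """
    lo, hi = pathway_size_range
    if not (0 < lo <= hi <= n_proteins):
        raise ValueError("pathway_size_range must satisfy 0 < lo <= hi <= n_proteins")
    max_edges = n_proteins * (n_proteins - 1) // 2
    if n_edges > max_edges:
        raise ValueError(
            f"n_edges={n_edges} infeasible for {n_proteins} proteins "
            f"(max {max_edges})"
        )
    rng = np.random.default_rng(seed)
    width = len(str(max(n_proteins - 1, 0)))
    accs = [f"SYN{str(i).zfill(width)}" for i in range(n_proteins)]
    proteins = [ProteinRef(a, a, species) for a in accs]

    pair_idx = rng.choice(max_edges, size=n_edges, replace=False) if n_edges else []
    pairs = []
    # unrank the linear index into an unordered pair (i < j)
    for idx in sorted(int(i) for i in pair_idx):
        i = 0
        remaining = idx
        row = n_proteins - 1
        while remaining >= row:
            remaining -= row
            i += 1
            row -= 1
        j = i + 1 + remaining
        pairs.append((accs[i], accs[j]))
    sources = ["BioGRID", "STRING", "WI8", "DroID", "HPRD"]
    evidences = sorted({"small_scale_physical", "high_throughput_physical", "genetic"})
    interactions = [
        Interaction(
            a,
            b,
            frozenset({sources[int(rng.integers(len(sources)))]}),
            frozenset({evidences[int(rng.integers(len(evidences)))]}),
        )
        for a, b in pairs
    ]
    network = build_network(interactions, proteins)

    pathways = {}
    for k in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(n_proteins, size=size, replace=False)
        pathways[("synthetic", f"pathway{k:03d}")] = frozenset(
            accs[int(i)] for i in members
        )
    collection = PathwayCollection(pathways=pathways, universe=frozenset(accs))
    return network, collection
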