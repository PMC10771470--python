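"""Molecular-network construction, scaffold enumeration, library annotation.

A network node is one consolidated unique metabolite (represented by its
highest-TIC member spectrum).  Candidate edges are node pairs whose modified
cosine passes both thresholds (score >= 0.7 and >= 6 matched peaks by
default, inclusive); an edge survives only if each endpoint ranks in the
other's top-10 most similar candidate neighbours (the mutual rule).  Family
size is unlimited.  Connected components of >= 2 nodes are "clusters",
isolated nodes "orphans", and clusters + orphans together are the unique
scaffolds — the working proxy for distinct core chemical structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from osmacnet.msio import Spectrum
from osmacnet.simscore import SimilarityParams, cosine_score

DEFAULT_MIN_COSINE = 0.7
DEFAULT_MIN_MATCHED = 6
DEFAULT_TOP_K = 10


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    cosine: float
    n_matched: int

    def __post_init__(self) -> None:
        if not self.node_a < self.node_b:
            raise ValueError("edge endpoints must be in canonical order (node_a < node_b)")


@dataclass
class MolecularNetwork:
    nodes: list[str]
    edges: list[NetworkEdge]

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.node_a, e.node_b, cosine=e.cosine, n_matched=e.n_matched)
        return g

    @property
    def components(self) -> list[frozenset[str]]:
        return [frozenset(c) for c in nx.connected_components(self.graph)]


@dataclass
class ScaffoldSet:
    """Partition of network nodes into multi-metabolite clusters and orphans."""

    clusters: list[frozenset[str]]
    orphans: list[str]

    @property
    def n_scaffolds(self) -> int:
        return len(self.clusters) + len(self.orphans)

    def membership(self) -> dict[str, tuple[str, str]]:
        """node_id -> (scaffold_id, scaffold_kind)."""
        out: dict[str, tuple[str, str]] = {}
        for k, cluster in enumerate(self.clusters):
            for node in sorted(cluster):
                out[node] = (f"cluster_{k:04d}", "cluster")
        for k, node in enumerate(self.orphans):
            out[node] = (f"orphan_{k:04d}", "orphan")
        return out


@dataclass(frozen=True)
class LibraryHit:
    node_id: str
    library_id: str
    score: float
    n_matched: int


def _pairwise_scores(
    nodes_with_spectra: Mapping[str, Spectrum],
    sim_params: SimilarityParams,
    min_cosine: float,
    min_matched: int,
) -> dict[tuple[str, str], tuple[float, int]]:
    ids = sorted(nodes_with_spectra)
    out: dict[tuple[str, str], tuple[float, int]] = {}
    for i, na in enumerate(ids):
        sa = nodes_with_spectra[na]
        for nb in ids[i + 1 :]:
            score, n = cosine_score(sa, nodes_with_spectra[nb], sim_params)
            if score >= min_cosine and n >= min_matched:
                out[(na, nb)] = (score, n)
    return out


def build_network(
    nodes_with_spectra: Mapping[str, Spectrum] | Sequence[str],
    sim_params: SimilarityParams = SimilarityParams(),
    min_cosine: float = DEFAULT_MIN_COSINE,
    min_matched: int = DEFAULT_MIN_MATCHED,
    top_k: int = DEFAULT_TOP_K,
    pair_scores: Mapping[tuple[str, str], tuple[float, int]] | None = None,
) -> MolecularNetwork:
    """Build the thresholded, mutually top-k filtered molecular network.

    Neighbour ranking uses (cosine desc, n_matched desc, node id asc) so edge
    retention is deterministic under ties.  ``pair_scores`` (canonical pair ->
    (cosine, n_matched)) lets callers supply precomputed similarities, in
    which case ``nodes_with_spectra`` may be a plain sequence of node ids.
    """
    ids = sorted(nodes_with_spectra)
    if pair_scores is None:
        candidates = _pairwise_scores(nodes_with_spectra, sim_params, min_cosine, min_matched)
    else:
        candidates = {
            pair: sn
            for pair, sn in pair_scores.items()
            if sn[0] >= min_cosine and sn[1] >= min_matched
        }
    neighbours: dict[str, list[tuple[float, int, str]]] = {n: [] for n in ids}
    for (na, nb), (score, n) in candidates.items():
        neighbours[na].append((score, n, nb))
        neighbours[nb].append((score, n, na))
    top: dict[str, set[str]] = {}
    for node, cand in neighbours.items():
        cand.sort(key=lambda t: (-t[0], -t[1], t[2]))
        top[node] = {c[2] for c in cand[:top_k]}
    edges = [
        NetworkEdge(na, nb, score, n)
        for (na, nb), (score, n) in sorted(candidates.items())
        if nb in top[na] and na in top[nb]
    ]
    return MolecularNetwork(nodes=ids, edges=edges)


def extract_scaffolds(network: MolecularNetwork) -> ScaffoldSet:
    """Partition the network into clusters (components of >= 2) and orphans."""
    clusters: list[frozenset[str]] = []
    orphans: list[str] = []
    for comp in network.components:
        if len(comp) >= 2:
            clusters.append(comp)
        else:
            orphans.append(next(iter(comp)))
    clusters.sort(key=lambda c: (-len(c), min(c)))
    orphans.sort()
    return ScaffoldSet(clusters=clusters, orphans=orphans)


def library_annotate(
    nodes_with_spectra: Mapping[str, Spectrum],
    library_spectra: Mapping[str, Spectrum],
    sim_params: SimilarityParams = SimilarityParams(),
    min_score: float = DEFAULT_MIN_COSINE,
    min_matched: int = DEFAULT_MIN_MATCHED,
) -> list[LibraryHit]:
    """Best library match per node meeting both thresholds, if any.

    Library spectra are expected to have passed the same peak filters as the
    query spectra (the caller preprocesses both sides identically).
    """
    hits: list[LibraryHit] = []
    for node_id in sorted(nodes_with_spectra):
        best: LibraryHit | None = None
        for lib_id in sorted(library_spectra):
            score, n = cosine_score(nodes_with_spectra[node_id], library_spectra[lib_id], sim_params)
            if score >= min_score and n >= min_matched:
                if best is None or (score, n) > (best.score, best.n_matched):
                    best = LibraryHit(node_id, lib_id, score, n)
        if best is not None:
            hits.append(best)
    return hits


def write_edge_list(network: MolecularNetwork, path: str | Path) -> None:
    pd.DataFrame(
        [(e.node_a, e.node_b, e.cosine, e.n_matched) for e in network.edges],
        columns=["node_a", "node_b", "cosine", "n_matched"],
    ).to_csv(path, index=False)


def write_graphml(network: MolecularNetwork, path: str | Path) -> None:
    nx.write_graphml(network.graph, str(path))


def write_scaffold_membership(scaffolds: ScaffoldSet, path: str | Path) -> None:
    rows = [
        (node, sid, kind) for node, (sid, kind) in sorted(scaffolds.membership().items())
    ]
    pd.DataFrame(rows, columns=["node_id", "scaffold_id", "scaffold_kind"]).to_csv(path, index=False)
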