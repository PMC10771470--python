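import itertools

import networkx as nx
import numpy as np
import pytest

from osmacnet.network import (
    MolecularNetwork,
    NetworkEdge,
    build_network,
    extract_scaffolds,
    library_annotate,
)
from osmacnet.simscore import SimilarityParams, cosine_score
from osmacnet.specproc import preprocess
from osmacnet.synthetic_data import GeneratorParams, generate_scaffold_library
from tests.conftest import make_spectrum


def net_from_scores(ids, scores, **kwargs):
    return build_network(ids, pair_scores=scores, **kwargs)


class TestBuildNetwork:
    def test_threshold_application(self):
        scores = {
            ("a", "b"): (0.9, 8),  # passes both
            ("a", "c"): (0.65, 10),  # cosine too low
            ("b", "c"): (0.8, 4),  # too few matched peaks
        }
        net = net_from_scores(["a", "b", "c"], scores)
        assert [(e.node_a, e.node_b) for e in net.edges] == [("a", "b")]

    def test_inclusive_thresholds(self):
        scores = {("a", "b"): (0.7, 6)}
        net = net_from_scores(["a", "b"], scores)
        assert len(net.edges) == 1

    def test_empty_input(self):
        net = build_network({})
        assert net.nodes == [] and net.edges == []

    def test_single_node_is_edgeless(self):
        s = make_spectrum("a", peaks=[(100.0, 10.0)])
        net = build_network({"a": s})
        assert net.nodes == ["a"] and net.edges == []

    def test_mutual_top_k_drops_one_sided_edges(self):
        """Hub saturated by 10 better neighbours drops a leaf that ranks it first."""
        rng = np.random.default_rng(0)
        ids = [f"n{i:02d}" for i in range(12)]
        scores = {}
        # hub n00 strongly tied to n01..n10; weakly to leaf n11
        for i in range(1, 11):
            scores[("n00", f"n{i:02d}")] = (0.95 - 0.001 * i, 20)
        scores[("n00", "n11")] = (0.75, 10)  # passes thresholds, ranks 11th for hub
        net = net_from_scores(ids, scores)
        edge_pairs = {(e.node_a, e.node_b) for e in net.edges}
        assert ("n00", "n11") not in edge_pairs
        assert len(edge_pairs) == 10

    def test_mutual_rule_against_exhaustive_ranking(self):
        """Edge retention equals a brute-force mutual top-k check on 15 nodes."""
        rng = np.random.default_rng(7)
        ids = [f"n{i:02d}" for i in range(15)]
        scores = {}
        for a, b in itertools.combinations(ids, 2):
            if rng.random() < 0.6:
                scores[(a, b)] = (float(rng.uniform(0.7, 1.0)), int(rng.integers(6, 30)))
        for top_k in (1, 2, 3, 5, 14):
            net = net_from_scores(ids, scores, top_k=top_k)
            # oracle: full neighbour ranking per node
            expected = set()
            rank = {}
            for node in ids:
                nb = []
                for (a, b), (s, n) in scores.items():
                    if node == a:
                        nb.append((-s, -n, b))
                    elif node == b:
                        nb.append((-s, -n, a))
                nb.sort()
                rank[node] = {x[2] for x in nb[:top_k]}
            for (a, b) in scores:
                if b in rank[a] and a in rank[b]:
                    expected.add((a, b))
            assert {(e.node_a, e.node_b) for e in net.edges} == expected

    def test_raising_top_k_never_removes_edges(self):
        rng = np.random.default_rng(3)
        ids = [f"n{i:02d}" for i in range(10)]
        scores = {
            (a, b): (float(rng.uniform(0.7, 1.0)), int(rng.integers(6, 30)))
            for a, b in itertools.combinations(ids, 2)
            if rng.random() < 0.7
        }
        prev = set()
        for top_k in range(1, len(ids) + 1):
            edges = {
                (e.node_a, e.node_b) for e in net_from_scores(ids, scores, top_k=top_k).edges
            }
            assert prev <= edges
            prev = edges
        # at top_k = n the mutual rule is vacuous: network equals thresholded graph
        assert prev == set(scores)


class TestScaffolds:
    def test_chain_plus_orphans(self):
        net = MolecularNetwork(
            nodes=["A", "B", "C", "D", "E"],
            edges=[NetworkEdge("A", "B", 0.9, 8), NetworkEdge("B", "C", 0.8, 7)],
        )
        sc = extract_scaffolds(net)
        assert sc.clusters == [frozenset("ABC")]
        assert sc.orphans == ["D", "E"]
        assert sc.n_scaffolds == 3

    def test_complete_graph_is_one_scaffold(self):
        nodes = ["a", "b", "c", "d"]
        edges = [NetworkEdge(x, y, 0.9, 8) for x, y in itertools.combinations(nodes, 2)]
        sc = extract_scaffolds(MolecularNetwork(nodes=nodes, edges=edges))
        assert len(sc.clusters) == 1 and sc.orphans == [] and sc.n_scaffolds == 1

    def test_counting_rule_on_full_scale_partition(self):
        """69 clusters plus 126 orphans count as 195 unique scaffolds."""
        nodes, edges = [], []
        for c in range(69):
            a, b = f"c{c:03d}a", f"c{c:03d}b"
            nodes += [a, b]
            edges.append(NetworkEdge(a, b, 0.9, 8))
        nodes += [f"o{i:03d}" for i in range(126)]
        sc = extract_scaffolds(MolecularNetwork(nodes=nodes, edges=edges))
        assert (len(sc.clusters), len(sc.orphans)) == (69, 126)
        assert sc.n_scaffolds == 195

    def test_components_partition_nodes_exactly(self):
        rng = np.random.default_rng(5)
        ids = [f"n{i:02d}" for i in range(20)]
        edges = [
            NetworkEdge(a, b, 0.9, 8)
            for a, b in itertools.combinations(ids, 2)
            if rng.random() < 0.1
        ]
        net = MolecularNetwork(nodes=ids, edges=edges)
        sc = extract_scaffolds(net)
        covered = sorted(itertools.chain(sc.orphans, *sc.clusters))
        assert covered == sorted(ids)

    def test_synthetic_scaffold_partition_identity(self):
        """Zero-noise scaffold library: components recover the generating scaffolds."""
        params = GeneratorParams(
            seed=9, n_scaffolds=4, analogs_per_scaffold=3,
            n_both=4, n_native_only=0, n_activated_only=0,
        )
        templates, truth = generate_scaffold_library(params)
        nodes = {t.metabolite_id: preprocess(t.to_spectrum(t.metabolite_id)) for t in templates}
        net = build_network(nodes)
        recovered = {frozenset(c) for c in net.components}
        expected = {}
        for mid, sid in truth.scaffold_of.items():
            expected.setdefault(sid, set()).add(mid)
        assert recovered == {frozenset(v) for v in expected.values()}


class TestLibraryAnnotate:
    def test_identical_entry_scores_one(self):
        s = make_spectrum("q", peaks=[(100.0 + 25 * i, 1000.0 * (i + 1)) for i in range(8)])
        hits = library_annotate({"q": s}, {"lib1": s})
        assert len(hits) == 1
        assert hits[0].library_id == "lib1"
        assert hits[0].score == pytest.approx(1.0)
        assert hits[0].n_matched == 8

    def test_empty_library_gives_no_hits(self):
        s = make_spectrum("q", peaks=[(100.0, 10.0)])
        assert library_annotate({"q": s}, {}) == []

    def test_degraded_query_decided_by_recomputed_score(self):
        """Query = library entry minus 20% of peaks: hit iff the direct score passes."""
        peaks = [(100.0 + 20 * i, 1000.0 + 100 * i) for i in range(10)]
        lib = make_spectrum("lib", peaks=peaks)
        query = make_spectrum("q", peaks=peaks[:8])  # 20% of peaks removed
        score, n = cosine_score(query, lib, SimilarityParams())
        hits = library_annotate({"q": query}, {"L": lib})
        if score >= 0.7 and n >= 6:
            assert hits and hits[0].score == pytest.approx(score)
        else:
            assert hits == []
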