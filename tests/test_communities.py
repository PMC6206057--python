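"""Signed modularity, spin-glass annealing, independence, root tracking."""

import itertools

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import morbinet as mn
from morbinet.communities import DEFAULT_SCHEDULE, _signed_arrays


def set_partitions(items):
    """All set partitions (restricted-growth strings)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for k in range(len(smaller)):
            yield smaller[:k] + [[first] + smaller[k]] + smaller[k + 1:]
        yield [[first]] + smaller


def exhaustive_min_h(net, gammas=(1.0, 1.0)):
    best = np.inf
    for parts in set_partitions(sorted(net.graph.nodes)):
        assignment = {v: k for k, block in enumerate(parts) for v in block}
        h = mn.hamiltonian(net, assignment, *gammas)
        best = min(best, h)
    return best


def two_cliques_net(make_net, k=4, bridge_rr=0.4):
    edges = []
    left = [f"L{i}" for i in range(k)]
    right = [f"R{i}" for i in range(k)]
    for grp in (left, right):
        for i, u in enumerate(grp):
            for v in grp[i + 1:]:
                edges.append((u, v, 2.0))
    edges.append((left[0], right[0], bridge_rr))
    return make_net(edges), left, right


class TestSignedModularity:
    def test_matches_newman_girvan_on_positive_graphs(self, make_net):
        """gamma = 1 signed Q equals standard modularity (networkx oracle)."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            g = nx.gnm_random_graph(int(rng.integers(6, 15)),
                                    int(rng.integers(8, 20)),
                                    seed=int(rng.integers(2**31)))
            g.remove_nodes_from(list(nx.isolates(g)))
            if g.number_of_edges() < 2:
                continue
            net = make_net([(f"N{u}", f"N{v}", 2.0) for u, v in g.edges])
            # random 2-community assignment
            nodes = sorted(net.graph.nodes)
            labels = rng.integers(0, 2, len(nodes))
            assignment = dict(zip(nodes, labels.tolist()))
            communities = [
                {v for v in nodes if assignment[v] == c} for c in (0, 1)
            ]
            communities = [c for c in communities if c]
            expected = nx.community.modularity(
                net.graph, communities, weight="weight"
            )
            got = mn.signed_modularity(net, assignment)
            assert got == pytest.approx(expected, abs=1e-10)

    def test_regular_graph_single_community_zero(self, make_net):
        net = make_net([(f"N{i}", f"N{(i + 1) % 6}", 2.0) for i in range(6)])
        assignment = {v: 0 for v in net.graph.nodes}
        assert mn.signed_modularity(net, assignment) == pytest.approx(0.0,
                                                                      abs=1e-12)

    def test_split_beats_merged_for_signed_cliques(self, make_net):
        net, left, right = two_cliques_net(make_net)
        split = {v: 0 for v in left} | {v: 1 for v in right}
        merged = {v: 0 for v in left + right}
        q_split = mn.signed_modularity(net, split)
        q_merged = mn.signed_modularity(net, merged)
        assert q_split > 0
        assert q_split > q_merged

    def test_empty_weight_rejected(self, make_net):
        net = mn.SignedNetwork(("19-24", "men"), nx.Graph())
        net.graph.add_node("A")
        with pytest.raises(ValueError):
            mn.signed_modularity(net, {"A": 0})


class TestHamiltonian:
    def test_qh_identity_fuzz(self, make_net):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = int(rng.integers(3, 20))
            net = mn.SignedNetwork(("19-24", "men"), nx.Graph())
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.3:
                        rr = float(rng.choice([0.2, 0.6, 1.7, 2.4, 5.0]))
                        net.graph.add_edge(f"N{i:02d}", f"N{j:02d}",
                                           weight=mn.signed_weight(rr), rr=rr)
            if net.graph.number_of_edges() == 0:
                continue
            gp, gm = float(rng.uniform(0.3, 3)), float(rng.uniform(0.3, 3))
            nodes = sorted(net.graph.nodes)
            assignment = dict(zip(nodes,
                                  rng.integers(0, 4, len(nodes)).tolist()))
            q = mn.signed_modularity(net, assignment, gp, gm)
            h = mn.hamiltonian(net, assignment, gp, gm)
            _, w = _signed_arrays(net)
            total = np.abs(w).sum()
            assert abs(q * total + h) < 1e-10

    def test_singleton_partition_is_null_self_terms(self, make_net):
        net = make_net([("A", "B", 2.0), ("B", "C", 2.0)])
        assignment = {"A": 0, "B": 1, "C": 2}
        nodes, w = _signed_arrays(net)
        wp = np.maximum(w, 0).sum(axis=1)
        expected = float(np.sum(wp**2) / wp.sum())  # -sum of -(gamma wi^2/2w)
        assert mn.hamiltonian(net, assignment) == pytest.approx(expected)

    def test_energy_rises_when_node_misplaced(self, make_net):
        net, left, right = two_cliques_net(make_net)
        good = {v: 0 for v in left} | {v: 1 for v in right}
        bad = dict(good)
        bad[left[1]] = 1
        assert mn.hamiltonian(net, good) < mn.hamiltonian(net, bad)


class TestSpinglassPartition:
    def test_recovers_two_cliques(self, make_net):
        net, left, right = two_cliques_net(make_net)
        hits = 0
        for seed in range(100):
            part = mn.spinglass_partition(net, seed=seed)
            truth = [0] * len(left) + [1] * len(right)
            got = [part.assignment[v] for v in left + right]
            hits += adjusted_rand_score(truth, got) == 1.0
        assert hits >= 95

    def test_reaches_enumerated_optimum_small_graph(self, make_net):
        net = make_net([("A", "B", 2.0), ("B", "C", 0.5), ("C", "D", 3.0),
                        ("A", "D", 1.8), ("A", "C", 0.4)])
        target = exhaustive_min_h(net)
        part = mn.spinglass_partition(net, seed=0)
        assert part.hamiltonian == pytest.approx(target, abs=1e-9)

    def test_empty_edges_gives_singletons(self):
        net = mn.SignedNetwork(("19-24", "men"), nx.Graph())
        net.graph.add_nodes_from("ABC")
        part = mn.spinglass_partition(net, seed=0)
        assert len(set(part.assignment.values())) == 3

    def test_reproducible(self, make_net):
        net, _, _ = two_cliques_net(make_net, k=5)
        p1 = mn.spinglass_partition(net, seed=123)
        p2 = mn.spinglass_partition(net, seed=123)
        assert p1.assignment == p2.assignment
        assert p1.hamiltonian == p2.hamiltonian

    def test_labels_contiguous(self, make_net):
        net, _, _ = two_cliques_net(make_net)
        part = mn.spinglass_partition(net, seed=5)
        labels = set(part.assignment.values())
        assert labels == set(range(len(labels)))

    def test_invalid_schedule_rejected(self, make_net):
        net, _, _ = two_cliques_net(make_net)
        with pytest.raises(ValueError):
            mn.spinglass_partition(net, schedule=(0.01, 1.0, 0.99, 50))

    def test_agrees_with_igraph_on_positive_graph(self, make_net):
        """Independent cross-check against igraph's community detection."""
        import igraph as ig

        net, left, right = two_cliques_net(make_net, k=5, bridge_rr=0.4)
        pos = net.subgraph_by_sign("positive")
        nodes = sorted(pos.nodes)
        idx = {v: k for k, v in enumerate(nodes)}
        g = ig.Graph(
            n=len(nodes),
            edges=[(idx[u], idx[v]) for u, v in pos.edges],
        )
        ref = g.community_multilevel()
        ref_labels = [ref.membership[idx[v]] for v in nodes]
        part = mn.spinglass_partition(net, seed=3)
        got = [part.assignment[v] for v in nodes]
        assert adjusted_rand_score(ref_labels, got) == 1.0


class TestEstimateGammas:
    def test_planted_blocks_converge(self, make_net):
        net, _, _ = two_cliques_net(make_net, k=5)
        converged = 0
        for seed in range(20):
            gp, gm = mn.estimate_gammas(net, seed=seed)
            converged += 0.2 <= gp <= 5.0
        assert converged == 20

    def test_unstructured_layer_returns_one(self, make_net):
        rng = np.random.default_rng(7)
        edges = []
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.5:
                    edges.append((f"N{i:02d}", f"N{j:02d}", 0.5))
        net = make_net(edges)
        with pytest.warns(UserWarning, match="no assortative structure"):
            gp, gm = mn.estimate_gammas(net, max_rounds=2, seed=0)
        assert gm == 1.0

    def test_complete_graph_has_equal_relative_densities(self, make_net):
        # on K_n any split gives omega_in == omega_out == n/(n-1) exactly,
        # the guarded analytic limit of the gamma update
        from morbinet.communities import _layer_densities

        edges = [(f"N{i}", f"N{j}", 2.0)
                 for i in range(6) for j in range(i + 1, 6)]
        net = make_net(edges)
        _, w = _signed_arrays(net)
        spins = np.array([0, 0, 0, 1, 1, 1])
        w_in, w_out = _layer_densities(w, spins, 1)
        assert w_in == pytest.approx(w_out, abs=1e-12)
        assert w_in == pytest.approx(6 / 5)


class TestCommunityIndependence:
    def test_negative_boundary_rewarded(self, make_net):
        # community {A,B,C}: external negative edges with |w| = 2+2+2 = 6
        net = make_net([("A", "B", 2.0), ("B", "C", 2.0),
                        ("A", "X", 0.5), ("B", "Y", 0.5), ("C", "Z", 0.5)])
        part = mn.spinglass_partition(net, seed=0)
        assignment = {"A": 0, "B": 0, "C": 0, "X": 1, "Y": 2, "Z": 3}
        part.assignment = assignment
        scores = mn.community_independence(net, part)
        assert scores[0] == pytest.approx(2.0)

    def test_isolated_community_scores_zero(self, make_net):
        net = make_net([("A", "B", 2.0), ("X", "Y", 2.0)])
        part = mn.spinglass_partition(net, seed=0)
        part.assignment = {"A": 0, "B": 0, "X": 1, "Y": 1}
        scores = mn.community_independence(net, part)
        assert scores[0] == 0.0 and scores[1] == 0.0

    def test_positive_boundary_penalised(self, make_net):
        net = make_net([("A", "B", 2.0), ("A", "X", 3.0)])
        part = mn.spinglass_partition(net, seed=0)
        part.assignment = {"A": 0, "B": 0, "X": 1}
        assert mn.community_independence(net, part)[0] < 0


class TestTrackRoots:
    @staticmethod
    def snap(band, *comms):
        return (band, [(frozenset(c), s) for c, s in comms])

    def test_persistent_community_tracked(self):
        core = {"A", "B", "C", "D", "E"}
        per_stratum = [
            self.snap("b0", ({"X", "Y"}, 1.0)),
            self.snap("b1", (core, 2.0)),
            self.snap("b2", (core | {"F"}, 2.0)),
            self.snap("b3", (core, 1.5)),
            self.snap("b4", (core - {"E"} | {"G"}, 1.0)),
        ]
        tracks = mn.track_roots(per_stratum, gender="men")
        spans = {t.span for t in tracks}
        assert ("b1", "b4") in spans
        main = next(t for t in tracks if t.span == ("b1", "b4"))
        assert main.root == frozenset({"A", "B", "C", "D"})

    def test_single_stratum_is_no_track(self):
        per_stratum = [
            self.snap("b0", ({"A", "B", "C"}, 1.0)),
            self.snap("b1", ({"X", "Y", "Z"}, 1.0)),
        ]
        assert mn.track_roots(per_stratum) == []

    def test_overlap_of_one_does_not_chain(self):
        per_stratum = [
            self.snap("b0", ({"A", "B", "C"}, 1.0)),
            self.snap("b1", ({"C", "X", "Y"}, 1.0)),
        ]
        assert mn.track_roots(per_stratum) == []

    def test_ambiguity_resolved_by_overlap_then_independence(self):
        core = {"A", "B", "C", "D"}
        per_stratum = [
            self.snap("b0", (core, 1.0)),
            self.snap("b1", ({"A", "B", "X"}, 5.0), ({"A", "B", "C"}, 1.0)),
            self.snap("b2", ({"A", "B", "C"}, 1.0)),
        ]
        tracks = mn.track_roots(per_stratum)
        main = max(tracks, key=lambda t: len(t.snapshots))
        # larger overlap (3 nodes) wins over higher independence (5.0)
        assert main.snapshots[1][1] == frozenset({"A", "B", "C"})


class TestPlantedCommunityRecovery:
    def test_ari_against_truth(self, default_cohort, cohort_partitions):
        """Estimated-resolution partitions recover the planted communities."""
        _, _, truth, summaries = default_cohort
        aris = []
        for s in summaries:
            part = cohort_partitions[s.stratum]
            members = truth.community_memberships[s.stratum]
            common = [c for c in part.assignment if c in members]
            aris.append(adjusted_rand_score(
                [members[c] for c in common],
                [part.assignment[c] for c in common],
            ))
        assert min(aris) >= 0.8
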