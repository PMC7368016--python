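import itertools
import json

import numpy as np
import pytest

from chemobarcode import (
    NoTrunkError,
    PhyloTree,
    PigeonholeError,
    build_tree,
    enumerate_trajectories,
)
from chemobarcode.clustering import CloneCluster


def cl(cid, ccf, size=100):
    return CloneCluster(id=cid, ccf=ccf, members=list(range(size)))


# ---------------------------------------------------------------------------
# Independent exhaustive oracle
# ---------------------------------------------------------------------------


def feasible(parent_map, clusters, tol=1e-9):
    """Check the pigeonhole constraints of a candidate parent map."""
    by_id = {c.id: c for c in clusters}
    samples = sorted(clusters[0].ccf)
    roots = [c for c, p in parent_map.items() if p == "ROOT"]
    if len(roots) != 1:
        return False
    # connectivity and acyclicity
    for cid in parent_map:
        seen, cur = set(), cid
        while parent_map[cur] != "ROOT":
            if cur in seen:
                return False
            seen.add(cur)
            cur = parent_map[cur]
    for cid, pid in parent_map.items():
        if pid == "ROOT":
            continue
        child, parent = by_id[cid], by_id[pid]
        sibs = [by_id[c] for c, p in parent_map.items() if p == pid and c != cid]
        for s in samples:
            if child.ccf[s] > parent.ccf[s] + tol:
                return False
            if child.ccf[s] + sum(b.ccf[s] for b in sibs) > parent.ccf[s] + tol:
                return False
    return True


def all_feasible_trees(clusters, trunk_id, tol=1e-9):
    """Enumerate every feasible parent assignment rooted at the trunk."""
    others = [c.id for c in clusters if c.id != trunk_id]
    ids = [c.id for c in clusters]
    out = []
    for parents in itertools.product(ids, repeat=len(others)):
        pm = {trunk_id: "ROOT"}
        ok = True
        for cid, pid in zip(others, parents):
            if pid == cid:
                ok = False
                break
            pm[cid] = pid
        if ok and feasible(pm, clusters, tol):
            out.append(pm)
    return out


def random_planted_tree(rng, max_nodes=8):
    """Random clone tree with CCFs that make the topology identifiable.

    Each leaf is the resident clone of its own sample; CCFs decrease
    strictly along every root-to-leaf path, so the planted parent is
    always the deepest feasible parent.
    """
    m = rng.integers(2, max_nodes + 1)
    parent_idx = [None] + [int(rng.integers(0, i)) for i in range(1, m)]
    children = [[] for _ in range(m)]
    for i, p in enumerate(parent_idx):
        if p is not None:
            children[p].append(i)
    leaves = [i for i in range(m) if not children[i]]
    samples = [f"s{j}" for j in range(len(leaves))]
    ccf = {i: {s: 0.0 for s in samples} for i in range(m)}
    for j, leaf in enumerate(leaves):
        path = [leaf]
        while parent_idx[path[-1]] is not None:
            path.append(parent_idx[path[-1]])
        path = path[::-1]  # root .. leaf
        value = 1.0
        ccf[path[0]][samples[j]] = value
        for node in path[1:]:
            value *= rng.uniform(0.35, 0.75)
            ccf[node][samples[j]] = round(value, 4)
    clusters = [cl(f"n{i}", ccf[i]) for i in range(m)]
    planted = {
        f"n{i}": ("ROOT" if p is None else f"n{p}") for i, p in enumerate(parent_idx)
    }
    return clusters, planted


class TestBuildTreeExamples:
    def test_single_clonal_cluster(self):
        tree = build_tree([cl("a", {"s0": 1.0, "s1": 1.0})])
        assert tree.trunk == "a"
        traj = enumerate_trajectories(tree)
        assert traj.count == 1
        assert traj.paths == [["a"]]

    def test_disjoint_branches_attach_to_trunk(self):
        clusters = [
            cl("trunk", {"s0": 1.0, "s1": 1.0}),
            cl("A", {"s0": 0.6, "s1": 0.0}),
            cl("B", {"s0": 0.0, "s1": 0.7}),
        ]
        tree = build_tree(clusters)
        assert tree.parent == {"trunk": "ROOT", "A": "trunk", "B": "trunk"}
        assert enumerate_trajectories(tree).count == 2
        # oracle: the feasible tree is unique
        assert all_feasible_trees(clusters, "trunk", tol=0.05) == [tree.parent]

    def test_sibling_sum_forces_nesting(self):
        clusters = [
            cl("trunk", {"s0": 1.0, "s1": 1.0}),
            cl("A", {"s0": 0.6, "s1": 0.6}),
            cl("B", {"s0": 0.5, "s1": 0.5}),
        ]
        tree = build_tree(clusters)
        assert tree.parent["B"] == "A"
        oracle = all_feasible_trees(clusters, "trunk", tol=0.05)
        assert {"trunk": "ROOT", "A": "trunk", "B": "A"} in oracle
        assert {"trunk": "ROOT", "A": "trunk", "B": "trunk"} not in oracle

    def test_no_trunk_raises(self):
        with pytest.raises(NoTrunkError):
            build_tree([cl("a", {"s0": 0.5, "s1": 0.9})])

    def test_infeasible_cluster_raises_with_samples(self):
        clusters = [
            cl("trunk", {"s0": 1.0, "s1": 1.0}),
            cl("A", {"s0": 0.7, "s1": 0.1}),
            cl("B", {"s0": 0.6, "s1": 0.6}),
        ]
        with pytest.raises(PigeonholeError, match="s0"):
            build_tree(clusters)


class TestTrajectories:
    def test_three_leaf_children(self):
        clusters = [cl("t", {"s0": 1.0, "s1": 1.0, "s2": 1.0})] + [
            cl(f"b{j}", {f"s{j}": 0.5, **{f"s{i}": 0.0 for i in range(3) if i != j}})
            for j in range(3)
        ]
        tree = build_tree(clusters)
        assert enumerate_trajectories(tree).count == 3

    def test_caterpillar_chain(self):
        clusters = [
            cl("a", {"s0": 1.0}),
            cl("b", {"s0": 0.7}),
            cl("c", {"s0": 0.45}),
            cl("d", {"s0": 0.2}),
        ]
        tree = build_tree(clusters)
        traj = enumerate_trajectories(tree)
        assert traj.count == 1
        assert traj.paths == [["a", "b", "c", "d"]]


class TestTopologyRecovery:
    def test_noiseless_random_trees_recovered_exactly(self):
        """100 random identifiable trees: the greedy construction
        returns the planted topology, and the planted topology is
        feasible under the independent exhaustive oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            clusters, planted = random_planted_tree(rng)
            tree = build_tree(clusters, tolerance=1e-6)
            assert dict(tree.parent) == planted
            assert feasible(planted, clusters, tol=1e-6)

    def test_recovery_under_sequencing_noise(self):
        """With CCF gaps >= 0.2 and read-count noise at ~90X coverage,
        at least 90% of planted topologies are recovered."""
        rng = np.random.default_rng(7)
        depth, cluster_size = 90, 150
        hits = 0
        trials = 100
        for _ in range(trials):
            clusters, planted = random_planted_tree_gapped(rng)
            noisy = []
            for c in clusters:
                ccf = {}
                for s, v in c.ccf.items():
                    d = rng.poisson(depth, size=cluster_size)
                    a = rng.binomial(d, v / 2.0)
                    ccf[s] = float(np.clip(2 * a.sum() / max(d.sum(), 1), 0, 1))
                noisy.append(cl(c.id, ccf, size=cluster_size))
            try:
                tree = build_tree(noisy, tolerance=0.05)
                hits += dict(tree.parent) == planted
            except (NoTrunkError, PigeonholeError):
                pass
        assert hits / trials >= 0.90


def random_planted_tree_gapped(rng, max_nodes=6):
    """Like random_planted_tree but with CCF gaps of at least 0.2."""
    while True:
        clusters, planted = random_planted_tree(rng, max_nodes)
        ok = True
        for c in clusters:
            pid = planted[c.id]
            if pid == "ROOT":
                continue
            parent = next(x for x in clusters if x.id == pid)
            for s, v in c.ccf.items():
                if v > 0 and parent.ccf[s] - v < 0.2:
                    ok = False
            if any(0 < v < 0.15 for v in c.ccf.values()):
                ok = False
        if ok:
            return clusters, planted


class TestSerialisation:
    def test_json_round_trip(self):
        clusters = [
            cl("trunk", {"s0": 1.0, "s1": 1.0}),
            cl("A", {"s0": 0.6, "s1": 0.0}, size=40),
        ]
        tree = build_tree(clusters)
        back = PhyloTree.from_json(tree.to_json())
        assert back.parent == tree.parent
        assert back.trunk == tree.trunk
        assert [c.id for c in back.nodes] == [c.id for c in tree.nodes]

    def test_newick_structure(self):
        clusters = [
            cl("trunk", {"s0": 1.0, "s1": 1.0}, size=500),
            cl("A", {"s0": 0.6, "s1": 0.0}, size=100),
            cl("B", {"s0": 0.0, "s1": 0.7}, size=200),
        ]
        nwk = build_tree(clusters).to_newick()
        assert nwk == "(A:100,B:200)trunk:500;"

    def test_trunk_fraction(self):
        clusters = [
            cl("trunk", {"s0": 1.0}, size=800),
            cl("A", {"s0": 0.5}, size=200),
        ]
        assert build_tree(clusters).trunk_fraction() == pytest.approx(0.8)
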