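"""Pigeonhole-principle phylogenetic trees from clone clusters.

With multi-sample CCF estimates per clone, nesting relations follow
from two constraints that any valid clone tree must satisfy in every
sample: a descendant clone cannot exceed its ancestor's CCF, and
sibling subclones of one parent cannot jointly exceed the parent's CCF
(the pigeonhole principle).  The clone whose mutations are clonal in
all samples forms the trunk; remaining clones are attached greedily,
largest first, each to its deepest feasible parent.  An evolutionary
trajectory is a root-to-leaf path through the resulting tree.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .clustering import CloneCluster

ROOT = "ROOT"


class NoTrunkError(ValueError):
    """No cluster is clonal in every sample."""


class PigeonholeError(ValueError):
    """A cluster cannot be attached without violating CCF constraints."""


@dataclass
class TrajectorySet:
    """Root-to-leaf paths of a clone tree (trunk first in each path)."""

    paths: list[list[str]]

    @property
    def count(self) -> int:
        return len(self.paths)


@dataclass
class PhyloTree:
    """A clone tree: trunk plus nested/sibling branch clusters."""

    nodes: list[CloneCluster]
    parent: dict[str, str]
    trunk: str
    samples: list[str]
    tolerance: float = 0.05

    def __post_init__(self) -> None:
        self._by_id = {c.id: c for c in self.nodes}
        if self.parent.get(self.trunk) != ROOT:
            raise ValueError("trunk must have parent ROOT")

    def node(self, node_id: str) -> CloneCluster:
        return self._by_id[node_id]

    def children(self, node_id: str) -> list[str]:
        return [c for c, p in self.parent.items() if p == node_id]

    @property
    def branch_nodes(self) -> list[CloneCluster]:
        return [c for c in self.nodes if c.id != self.trunk]

    def leaves(self) -> list[str]:
        have_children = set(self.parent.values())
        return [c.id for c in self.nodes if c.id not in have_children]

    def depth(self, node_id: str) -> int:
        d = 0
        while self.parent[node_id] != ROOT:
            node_id = self.parent[node_id]
            d += 1
        return d

    def trunk_fraction(self) -> float:
        total = sum(c.size for c in self.nodes)
        return self.node(self.trunk).size / total if total else float("nan")

    def topology(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.parent.items())

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "trunk": self.trunk,
            "samples": self.samples,
            "tolerance": self.tolerance,
            "nodes": [
                {
                    "id": c.id,
                    "parent": self.parent[c.id],
                    "size": c.size,
                    "ccf": {s: c.ccf[s] for s in self.samples},
                    "members": c.members,
                }
                for c in self.nodes
            ],
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "PhyloTree":
        nodes = [
            CloneCluster(id=nd["id"], ccf=dict(nd["ccf"]), members=list(nd["members"]))
            for nd in d["nodes"]
        ]
        parent = {nd["id"]: nd["parent"] for nd in d["nodes"]}
        return cls(
            nodes=nodes,
            parent=parent,
            trunk=d["trunk"],
            samples=list(d["samples"]),
            tolerance=d.get("tolerance", 0.05),
        )

    @classmethod
    def from_json(cls, text: str) -> "PhyloTree":
        return cls.from_dict(json.loads(text))

    def to_newick(self) -> str:
        def render(node_id: str) -> str:
            kids = sorted(self.children(node_id))
            size = self.node(node_id).size
            label = f"{node_id}:{size}"
            if not kids:
                return label
            return "(" + ",".join(render(k) for k in kids) + ")" + label

        return render(self.trunk) + ";"


def _violations(
    child: CloneCluster,
    parent: CloneCluster,
    siblings: list[CloneCluster],
    samples: list[str],
    tol: float,
) -> list[str]:
    bad = []
    for s in samples:
        if child.ccf[s] > parent.ccf[s] + tol:
            bad.append(s)
        elif child.ccf[s] + sum(sib.ccf[s] for sib in siblings) > parent.ccf[s] + tol:
            bad.append(s)
    return bad


def build_tree(
    clusters: list[CloneCluster],
    clonal_ccf_threshold: float = 0.85,
    tolerance: float = 0.05,
) -> PhyloTree:
    """Greedy pigeonhole tree construction.

    The trunk is the cluster clonal (CCF >= ``clonal_ccf_threshold``) in
    every sample; with several such clusters the largest-CCF one roots
    the tree and the others nest beneath it.  Remaining clusters are
    attached in order of decreasing summed CCF, each to the feasible
    parent with the smallest summed CCF (the deepest feasible parent),
    subject in every sample to the child-below-parent and sibling-sum
    constraints within ``tolerance``.  Ties break on cluster id order.
    """
    if not clusters:
        raise ValueError("no clusters")
    samples = sorted(clusters[0].ccf)
    for c in clusters:
        if sorted(c.ccf) != samples:
            raise ValueError(f"cluster {c.id} has inconsistent sample set")

    clonal = [c for c in clusters if all(c.ccf[s] >= clonal_ccf_threshold for s in samples)]
    if not clonal:
        raise NoTrunkError(
            "no cluster is clonal in every sample "
            f"(threshold {clonal_ccf_threshold})"
        )
    trunk = max(clonal, key=lambda c: (sum(c.ccf[s] for s in samples), c.id))

    rest = [c for c in clusters if c.id != trunk.id]
    rest.sort(key=lambda c: (-sum(c.ccf[s] for s in samples), c.id))

    parent: dict[str, str] = {trunk.id: ROOT}
    placed: list[CloneCluster] = [trunk]
    by_id = {trunk.id: trunk}
    for child in rest:
        feasible: list[CloneCluster] = []
        for cand in placed:
            sibs = [by_id[c] for c, p in parent.items() if p == cand.id]
            if not _violations(child, cand, sibs, samples, tolerance):
                feasible.append(cand)
        if not feasible:
            sibs = [by_id[c] for c, p in parent.items() if p == trunk.id]
            bad = _violations(child, trunk, sibs, samples, tolerance)
            raise PigeonholeError(
                f"cluster {child.id} has no feasible parent; "
                f"constraints violated vs trunk in sample(s) {bad}"
            )
        best = min(feasible, key=lambda c: (sum(c.ccf[s] for s in samples), c.id))
        parent[child.id] = best.id
        placed.append(child)
        by_id[child.id] = child

    return PhyloTree(
        nodes=[trunk] + rest,
        parent=parent,
        trunk=trunk.id,
        samples=samples,
        tolerance=tolerance,
    )


def enumerate_trajectories(tree: PhyloTree) -> TrajectorySet:
    """One trajectory per leaf: the trunk-to-leaf path of clusters."""
    paths = []
    for leaf in sorted(tree.leaves()):
        path = [leaf]
        while tree.parent[path[-1]] != ROOT:
            path.append(tree.parent[path[-1]])
        paths.append(path[::-1])
    return TrajectorySet(paths=paths)
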