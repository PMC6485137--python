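"""Distance-based subgroup classification: p-distances, neighbor joining,
threshold edge cutting, Newick output.

This is a lightweight reproducible stand-in for Bayesian/ML tree
inference: the family's subgroup structure is a partition, and canonical
Saitou–Nei NJ on domain p-distances followed by long-edge cutting yields
one deterministically.  NJ reconstructs any additive distance matrix
exactly (topology and branch lengths).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import ValidationError
from .homology import ScoringScheme, align_global

__all__ = [
    "DistanceMatrix",
    "PhyloTree",
    "domain_pdistance",
    "neighbor_joining",
    "cut_subgroups",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("diagonal must be zero")
        if (self.d < -1e-12).any():
            raise ValidationError("distances must be nonnegative")


@dataclass
class PhyloTree:
    """An unrooted tree as a networkx graph with branch lengths ≥ 0.

    Leaves are the nodes named by sequence labels; internal nodes are
    integers.  ``newick()`` serializes rooted at the last internal node.
    """

    graph: nx.Graph
    leaves: list[str] = field(default_factory=list)

    def newick(self) -> str:
        internal = [n for n in self.graph.nodes if n not in set(self.leaves)]
        root = internal[-1] if internal else self.leaves[0]

        def sub(node, parent):
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{sub(c, node)}:{self.graph.edges[node, c]['length']:.6g}"
                for c in sorted(children, key=str)
            )
            return f"({inner})"

        return sub(root, None) + ";"

    def leaf_distances(self) -> DistanceMatrix:
        """Path-length distances between all leaf pairs."""
        labels = sorted(self.leaves)
        n = len(labels)
        d = np.zeros((n, n))
        lengths = dict(nx.all_pairs_dijkstra_path_length(self.graph, weight="length"))
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = lengths[labels[i]][labels[j]]
        return DistanceMatrix(labels, d)


def domain_pdistance(
    seqs: dict[str, str], scheme: ScoringScheme | None = None
) -> DistanceMatrix:
    """Pairwise p-distances over globally aligned domain sequences.

    d = fraction of mismatched columns among columns where neither row is
    gapped.  Requires ≥ 3 sequences.
    """
    labels = sorted(seqs)
    if len(labels) < 3:
        raise ValidationError("need ≥ 3 sequences for a distance matrix")
    scheme = scheme or ScoringScheme()
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        _, ga, gb = align_global(seqs[labels[i]], seqs[labels[j]], scheme)
        both = [(x, y) for x, y in zip(ga, gb) if x != "-" and y != "-"]
        if not both:
            raise ValidationError(
                f"no aligned columns between {labels[i]} and {labels[j]}"
            )
        mism = sum(1 for x, y in both if x != y)
        d[i, j] = d[j, i] = mism / len(both)
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Canonical Saitou–Nei neighbor joining.

    Ties in the Q criterion break to the lexicographically smallest label
    pair; negative branch lengths are clamped to 0 with the deficit moved
    to the sister branch.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("NJ needs ≥ 3 taxa")
    graph = nx.Graph()
    active: list[object] = list(dm.labels)
    # smallest leaf label under each node, for deterministic tie-breaking
    key: dict[object, str] = {lab: lab for lab in active}
    d: dict[tuple, float] = {}
    for i, a in enumerate(dm.labels):
        for j, b in enumerate(dm.labels):
            if i != j:
                d[(a, b)] = dm.d[i, j]

    next_internal = 0
    while len(active) > 2:
        m = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(active, 2):
            qv = (m - 2) * d[(a, b)] - r[a] - r[b]
            cand = (qv, tuple(sorted((key[a], key[b]))), a, b)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, _, a, b = best
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (m - 2))
        lb = d[(a, b)] - la
        if la < 0:  # clamp, move deficit to sister
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        u = next_internal
        next_internal += 1
        graph.add_edge(a, u, length=la)
        graph.add_edge(b, u, length=lb)
        for c in active:
            if c == a or c == b:
                continue
            duc = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(u, c)] = d[(c, u)] = max(duc, 0.0)
        active = [c for c in active if c != a and c != b] + [u]
        key[u] = min(key[a], key[b])
    a, b = active
    graph.add_edge(a, b, length=max(d[(a, b)], 0.0))
    return PhyloTree(graph=graph, leaves=list(dm.labels))


def cut_subgroups(tree: PhyloTree, max_intra_distance: float) -> dict[str, str]:
    """Partition leaves by cutting every edge longer than the threshold.

    Connected leaf components become subgroups labelled by their smallest
    member id; deterministic and independent of input order.
    """
    g = tree.graph.copy()
    long_edges = [
        (u, v) for u, v, ln in g.edges(data="length") if ln > max_intra_distance
    ]
    g.remove_edges_from(long_edges)
    leafset = set(tree.leaves)
    out: dict[str, str] = {}
    for comp in nx.connected_components(g):
        members = sorted(str(x) for x in comp & leafset)
        if not members:
            continue
        label = members[0]
        for mbr in members:
            out[mbr] = label
    return out
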