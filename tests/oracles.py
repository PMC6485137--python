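"""Independent brute-force oracles used by the test suite.

Deliberately written without reusing the package's internals: the
genetic code comes from Biopython, alignment scoring is enumerated
recursively, NG86 pathways are walked by DFS, and tail probabilities are
direct pmf summations.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_global_score(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Best global alignment score by exhaustive enumeration (short seqs).

    Affine convention: a gap of length k costs open + (k-1)·extend.
    """

    best = [-math.inf]

    def rec(i, j, score, prev):  # prev: 'm', 'a' (gap in b), 'b' (gap in a)
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + _BLOSUM62[a[i], b[j]], "m")
        if i < len(a):
            cost = gap_extend if prev == "a" else gap_open
            rec(i + 1, j, score - cost, "a")
        if j < len(b):
            cost = gap_extend if prev == "b" else gap_open
            rec(i, j + 1, score - cost, "b")

    rec(0, 0, 0.0, "m")
    return best[0]


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _is_stop(codon: str) -> bool:
    return _aa(codon) == "*"


@lru_cache(maxsize=None)
def oracle_codon_sites(codon: str) -> float:
    """Synonymous site count of a codon via direct one-step enumeration."""
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if not _is_stop(alt) and _aa(alt) == _aa(codon):
                s += 1 / 3
    return s


def oracle_pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) by depth-first pathway enumeration."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return (0.0, 0.0)
    complete: list[tuple[int, int, bool]] = []  # (sd, nd, crossed_stop)

    def walk(cur: str, remaining: tuple[int, ...], sd: int, nd: int, crossed: bool):
        if not remaining:
            complete.append((sd, nd, crossed))
            return
        for pos in remaining:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            step_crossed = crossed or _is_stop(nxt)
            syn = (not _is_stop(cur)) and (not _is_stop(nxt)) and _aa(cur) == _aa(nxt)
            walk(
                nxt,
                tuple(p for p in remaining if p != pos),
                sd + (1 if syn else 0),
                nd + (0 if syn else 1),
                step_crossed,
            )

    walk(ca, tuple(diff), 0, 0, False)
    clean = [(s, n) for s, n, crossed in complete if not crossed]
    if not clean:
        clean = [(s, n) for s, n, _ in complete]
    sd = sum(s for s, _ in clean) / len(clean)
    nd = sum(n for _, n in clean) / len(clean)
    return sd, nd


def ac_pmf(yprime: int, x: int, rho: float) -> float:
    """Audic–Claverie predictive pmf P(y'|x) by the closed formula."""
    log_p = (
        yprime * math.log(rho)
        + math.lgamma(x + yprime + 1)
        - math.lgamma(x + 1)
        - math.lgamma(yprime + 1)
        - (x + yprime + 1) * math.log1p(rho)
    )
    return math.exp(log_p)


def ac_upper_tail(y: int, x: int, rho: float, terms: int = 4000) -> float:
    """P(Y ≥ y | x) by direct summation of the predictive pmf."""
    total = sum(ac_pmf(t, x, rho) for t in range(0, y))
    return max(0.0, 1.0 - total)


def random_additive_tree(rng, n_leaves: int):
    """A random binary tree with positive branch lengths and its leaf
    path-length distance matrix (labels, matrix, edge list)."""
    import networkx as nx
    import numpy as np

    labels = [f"t{i:02d}" for i in range(n_leaves)]
    g = nx.Graph()
    nodes = list(labels)
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        u = f"i{nxt}"
        nxt += 1
        g.add_edge(a, u, length=float(rng.uniform(0.1, 2.0)))
        g.add_edge(b, u, length=float(rng.uniform(0.1, 2.0)))
        nodes = [x for x in nodes if x not in (a, b)] + [u]
    g.add_edge(nodes[0], nodes[1], length=float(rng.uniform(0.1, 2.0)))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    d = np.zeros((n_leaves, n_leaves))
    for i in range(n_leaves):
        for j in range(i + 1, n_leaves):
            d[i, j] = d[j, i] = lengths[labels[i]][labels[j]]
    return labels, d, g
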