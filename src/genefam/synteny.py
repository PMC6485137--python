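"""Window-regression collinearity (microsynteny) detection.

For every homologous family pair, a window of genes is extracted around
each member (default 15 genes each side); homologous pairs with both
members in-window are the anchors.  A candidate block passes when it has
at least ``min_anchors`` anchors, the squared Pearson correlation of the
anchor ranks (the Q-value, orientation-agnostic) is at least ``min_q``,
and the binomial-tail block E-value given the background homolog density
is at most ``max_block_e``.  Duplicate blocks reached from different
focal pairs are merged keeping the anchor-maximal one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .errors import ValidationError
from .genome_io import GenomeAnnotation
from .homology import HomologPair

__all__ = [
    "SyntenyParams",
    "AnchorPair",
    "SyntenyBlock",
    "extract_window",
    "collinearity_q",
    "block_significance",
    "detect_synteny_blocks",
]


@dataclass
class SyntenyParams:
    """Gates of the collinearity detector (defaults: 15-gene flanks,
    ≥3 anchors, block E ≤ 0.01, Q ≥ 0.9, pair E ≤ 1e-5)."""

    window: int = 15
    min_anchors: int = 3
    max_block_e: float = 0.01
    min_q: float = 0.9
    max_pair_e: float = 1e-5

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValidationError("window must be ≥ 1")
        if self.min_anchors < 2:
            raise ValidationError("min_anchors must be ≥ 2")
        if not 0 < self.min_q <= 1:
            raise ValidationError("min_q must be in (0, 1]")


@dataclass
class AnchorPair:
    """A homologous gene pair anchoring two windows, with chromosome ranks."""

    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int


@dataclass
class SyntenyBlock:
    """An accepted collinear segment pair.

    ``segment_a``/``segment_b`` are (chromosome, (min_rank, max_rank))
    spans of the anchors; ``mean_ks``/``sd_ks`` are filled by the Ka/Ks
    stage.
    """

    focal_pair: tuple[str, str]
    segment_a: tuple[str, tuple[int, int]]
    segment_b: tuple[str, tuple[int, int]]
    anchors: list[AnchorPair]
    q: float
    block_e: float
    mean_ks: float | None = None
    sd_ks: float | None = None
    n_saturated: int = 0
    era: str | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def anchor_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset((a.gene_a, a.gene_b)) for a in self.anchors)


def extract_window(g: GenomeAnnotation, gene_id: str, w: int) -> list[str]:
    """Up to 2w+1 gene ids centered on the focal gene, in rank order."""
    chrom, r = g.rank[gene_id] if gene_id in g.rank else (None, None)
    if chrom is None:
        raise ValidationError(f"unknown gene id {gene_id!r}")
    order = g.chromosome_genes(chrom)
    return order[max(0, r - w) : r + w + 1]


def collinearity_q(anchors: list[AnchorPair]) -> float:
    """Q = r², the squared Pearson correlation of anchor ranks.

    Orientation-agnostic: inverted segments score identically.  Requires
    at least two anchors with distinct rank_a values.
    """
    if len(anchors) < 2:
        raise ValidationError("need ≥ 2 anchors for a regression")
    xs = np.array([a.rank_a for a in anchors], dtype=float)
    ys = np.array([a.rank_b for a in anchors], dtype=float)
    if np.unique(xs).size < 2:
        raise ValidationError("need ≥ 2 distinct rank_a values")
    if np.unique(ys).size < 2:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def block_significance(
    n_anchors: int, window_a: int, window_b: int, density: float
) -> float:
    """Binomial-tail block E-value: P(X ≥ n_anchors) with
    X ~ Binomial(window_a·window_b, density)."""
    if not 0.0 <= density <= 1.0:
        raise ValidationError("density must be in [0, 1]")
    if n_anchors <= 0:
        return 1.0
    return float(binom.sf(n_anchors - 1, window_a * window_b, density))


def homolog_density(pairs: list[HomologPair], n_genes: int) -> float:
    """Background homolog density: pair count over total cross-pair count."""
    if n_genes < 2:
        raise ValidationError("need ≥ 2 genes for a density")
    return len(pairs) / (n_genes * (n_genes - 1) / 2.0)


def _segments_overlap(seg1, seg2) -> bool:
    (c1, (s1, e1)), (c2, (s2, e2)) = seg1, seg2
    return c1 == c2 and s1 <= e2 and s2 <= e1


def detect_synteny_blocks(
    g: GenomeAnnotation,
    family: list[str],
    pairs: list[HomologPair],
    params: SyntenyParams | None = None,
    density: float | None = None,
) -> list[SyntenyBlock]:
    """Detect collinear blocks seeded from homologous family pairs.

    ``pairs`` is the precomputed homolog universe at ``max_pair_e`` (it
    supplies both the family focal pairs and the window anchors).
    ``density`` defaults to the homolog density implied by ``pairs`` over
    the whole annotation.  Blocks with mutually overlapping segments on
    both sides are merged keeping the anchor-maximal one (ties: larger Q,
    then leftmost segment).
    """
    params = params or SyntenyParams()
    family_set = set(family)
    for gid in family_set:
        if gid not in g.rank:
            raise ValidationError(f"family gene {gid!r} missing from annotation")
    usable = [p for p in pairs if p.evalue <= params.max_pair_e]
    if density is None:
        density = homolog_density(usable, len(g))
    by_gene: dict[str, set[str]] = {}
    for p in usable:
        by_gene.setdefault(p.gene_a, set()).add(p.gene_b)
        by_gene.setdefault(p.gene_b, set()).add(p.gene_a)
    focal_pairs = sorted(
        (p.gene_a, p.gene_b)
        for p in usable
        if p.gene_a in family_set and p.gene_b in family_set
    )
    candidates: list[SyntenyBlock] = []
    for fa, fb in focal_pairs:
        win_a = extract_window(g, fa, params.window)
        win_b = extract_window(g, fb, params.window)
        set_b = set(win_b)
        anchors = []
        used_b: set[str] = set()
        for ga in win_a:
            partners = sorted((by_gene.get(ga) or set()) & set_b - used_b - {ga})
            if not partners:
                continue
            gb = partners[0]  # deterministic: smallest id
            used_b.add(gb)
            anchors.append(
                AnchorPair(ga, gb, rank_a=g.rank[ga][1], rank_b=g.rank[gb][1])
            )
        if len(anchors) < params.min_anchors:
            continue
        try:
            q = collinearity_q(anchors)
        except ValidationError:
            continue
        e = block_significance(len(anchors), len(win_a), len(win_b), density)
        if q < params.min_q or e > params.max_block_e:
            continue
        ra = [a.rank_a for a in anchors]
        rb = [a.rank_b for a in anchors]
        seg_a = (g.rank[fa][0], (min(ra), max(ra)))
        seg_b = (g.rank[fb][0], (min(rb), max(rb)))
        if seg_a > seg_b:
            seg_a, seg_b = seg_b, seg_a
            anchors = [
                AnchorPair(a.gene_b, a.gene_a, a.rank_b, a.rank_a) for a in anchors
            ]
            fa, fb = fb, fa
        candidates.append(
            SyntenyBlock(
                focal_pair=(fa, fb),
                segment_a=seg_a,
                segment_b=seg_b,
                anchors=anchors,
                q=q,
                block_e=e,
            )
        )
    return _merge_blocks(candidates)


def _merge_blocks(blocks: list[SyntenyBlock]) -> list[SyntenyBlock]:
    """Group blocks whose segments overlap on both sides; keep the
    anchor-maximal representative (ties: larger Q, then leftmost)."""
    order = sorted(
        range(len(blocks)),
        key=lambda i: (
            -blocks[i].n_anchors,
            -blocks[i].q,
            blocks[i].segment_a,
            blocks[i].segment_b,
        ),
    )
    kept: list[SyntenyBlock] = []
    for i in order:
        b = blocks[i]
        duplicate = any(
            (
                _segments_overlap(b.segment_a, k.segment_a)
                and _segments_overlap(b.segment_b, k.segment_b)
            )
            or (
                _segments_overlap(b.segment_a, k.segment_b)
                and _segments_overlap(b.segment_b, k.segment_a)
            )
            for k in kept
        )
        if not duplicate:
            kept.append(b)
    kept.sort(key=lambda b: (b.segment_a, b.segment_b))
    return kept
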