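"""Nei–Gojobori (1986) Ka/Ks estimation and Ks-based WGD dating.

Implements codon back-translation alignment, NG86 synonymous /
nonsynonymous site and difference counting with equal-weight mutational
pathway averaging, Jukes–Cantor correction, per-block Ks summaries,
kernel-density Ks peak finding, WGD-era assignment and the Ks < 0.3
candidate filter for downstream branch-site testing.

Site counting
-------------
For a codon, the synonymous fraction of position *j* is the number of the
three possible one-step nucleotide changes at *j* that preserve the amino
acid (changes creating a stop codon count as nonsynonymous), divided by 3.
A pair's site totals average the two codons, so S + N = 3·n_codons
exactly.  For codons differing at d positions, the d! orders of applying
the changes are enumerated; pathways crossing a stop codon are excluded
(if every pathway crosses a stop, all are kept with equal weight) and each
surviving pathway's synonymous/nonsynonymous step counts are averaged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import gaussian_kde

from .errors import ValidationError

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "KsPeak",
    "WgdEra",
    "codon_align",
    "ng86_counts",
    "compute_kaks",
    "jukes_cantor",
    "block_mean_ks",
    "ks_distribution_peaks",
    "assign_wgd_era",
    "filter_candidates_for_branch_site",
]

BASES = "ACGT"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_CODON_TABLE = {}
_T = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product("TCAG", repeat=3)):
    _CODON_TABLE[_a + _b + _c] = _T[_i]

SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(BASES, repeat=3))
    if c not in STOP_CODONS
)


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def syn_fraction(codon: str, pos: int) -> float:
    """Fraction of one-step changes at ``pos`` that are synonymous (NG86)."""
    aa = _CODON_TABLE[codon]
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if alt not in STOP_CODONS and _CODON_TABLE[alt] == aa:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3); nonsynonymous = 3 − this."""
    if codon in STOP_CODONS:
        raise ValidationError(f"stop codon {codon} has no NG86 sites")
    return sum(syn_fraction(codon, j) for j in range(3))


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    Enumerates every order of applying the differing positions, drops
    orders whose intermediate codons are stops (keeping all orders if
    every one is blocked) and averages the per-step synonymous /
    nonsynonymous classifications with equal weights.  Sd + Nd equals the
    number of differing positions.
    """
    diff = [j for j in range(3) if codon_a[j] != codon_b[j]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(diff):
        cur = codon_a
        steps = []
        blocked = False
        for j in order:
            nxt = cur[:j] + codon_b[j] + cur[j + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((blocked, steps))
    usable = [s for blocked, s in pathways if not blocked]
    if not usable:  # every route crosses a stop; fall back to all routes
        usable = [s for _, s in pathways]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if (
                cur not in STOP_CODONS
                and nxt not in STOP_CODONS
                and _CODON_TABLE[cur] == _CODON_TABLE[nxt]
            ):
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


@dataclass
class CodonAlignment:
    """Gap-free aligned codon pairs from a back-translated protein alignment."""

    pairs: list[tuple[str, str]]

    @property
    def n_codons(self) -> int:
        return len(self.pairs)


@dataclass
class KaKsResult:
    """NG86 site/difference counts, JC-corrected rates and selection class.

    ``omega`` is None when Ks = 0 (undefined ratio); ``saturated`` flags
    ps or pn ≥ 3/4, where the JC correction diverges — such results carry
    ``Ka``/``Ks`` = None rather than NaN.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ka: float | None
    Ks: float | None
    omega: float | None
    selection_class: str | None
    saturated: bool = False


def jukes_cantor(p: float) -> float:
    """JC69 distance d = −(3/4)·ln(1 − 4p/3); requires p < 3/4."""
    if p >= 0.75:
        raise ValidationError(f"proportion {p} saturated (≥ 3/4)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _split_codons(cds: str):
    cds = cds.upper()
    if len(cds) % 3:
        cds = cds[: len(cds) - len(cds) % 3]
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def codon_align(
    cds_a: str, cds_b: str, aligned_a: str, aligned_b: str
) -> CodonAlignment:
    """Back-translate a gapped protein alignment onto the two CDSs.

    ``aligned_a``/``aligned_b`` are the gapped rows of a protein
    alignment of translate(cds_a) and translate(cds_b).  Columns with a
    gap in either row are dropped.  A trailing stop codon on either CDS is
    trimmed; internal stops are errors.
    """
    codons_a = _split_codons(cds_a)
    codons_b = _split_codons(cds_b)
    if codons_a and codons_a[-1] in STOP_CODONS:
        codons_a = codons_a[:-1]
    if codons_b and codons_b[-1] in STOP_CODONS:
        codons_b = codons_b[:-1]
    for codons, name in ((codons_a, "cds_a"), (codons_b, "cds_b")):
        for c in codons:
            if c in STOP_CODONS:
                raise ValidationError(f"{name}: internal stop codon {c}")
    if len(aligned_a) != len(aligned_b):
        raise ValidationError("aligned rows differ in length")
    if len(aligned_a.replace("-", "")) != len(codons_a):
        raise ValidationError("cds_a length does not match its aligned protein")
    if len(aligned_b.replace("-", "")) != len(codons_b):
        raise ValidationError("cds_b length does not match its aligned protein")
    pairs = []
    ia = ib = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca != "-" and cb != "-":
            pairs.append((codons_a[ia], codons_b[ib]))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return CodonAlignment(pairs)


def ng86_counts(al: CodonAlignment) -> tuple[float, float, float, float]:
    """NG86 (S, N, Sd, Nd) over a codon alignment."""
    if al.n_codons < 1:
        raise ValidationError("empty codon alignment")
    S = Sd = Nd = 0.0
    for ca, cb in al.pairs:
        S += 0.5 * (codon_sites(ca) + codon_sites(cb))
        sd, nd = pathway_differences(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * al.n_codons - S
    return S, N, Sd, Nd


#: tolerance inside which omega counts as exactly neutral
NEUTRAL_TOL = 1e-9


def compute_kaks(al: CodonAlignment) -> KaKsResult:
    """Full NG86 + Jukes–Cantor Ka/Ks result with selection classification."""
    S, N, Sd, Nd = ng86_counts(al)
    if S <= 0 or N <= 0:
        raise ValidationError("degenerate alignment: S or N is zero")
    ps, pn = Sd / S, Nd / N
    saturated = ps >= 0.75 or pn >= 0.75
    Ks = jukes_cantor(ps) if ps < 0.75 else None
    Ka = jukes_cantor(pn) if pn < 0.75 else None
    omega = None
    sel = None
    if Ka is not None and Ks is not None and Ks > 0:
        omega = Ka / Ks
        if abs(omega - 1.0) <= NEUTRAL_TOL:
            sel = "neutral"
        elif omega < 1.0:
            sel = "purifying"
        else:
            sel = "positive"
    return KaKsResult(S, N, Sd, Nd, ps, pn, Ka, Ks, omega, sel, saturated)


def block_mean_ks(ks_values: list[float | None]) -> tuple[float, float, int]:
    """Mean and sample SD of finite anchor Ks values in a block.

    Saturated/undefined anchors (None) are excluded and counted; the SD of
    a single value is 0 by convention.  Returns (mean, sd, n_excluded).
    """
    finite = [k for k in ks_values if k is not None and math.isfinite(k)]
    excluded = len(ks_values) - len(finite)
    if not finite:
        raise ValidationError("all anchors saturated; block Ks undefined")
    mean = float(np.mean(finite))
    sd = float(np.std(finite, ddof=1)) if len(finite) > 1 else 0.0
    return mean, sd, excluded


@dataclass
class KsPeak:
    """A mode of the Ks density with the fraction of pairs nearest to it."""

    mode: float
    mass: float


def ks_distribution_peaks(ks_values, grid_points: int = 2048) -> list[KsPeak]:
    """Modes of a Gaussian-KDE (Silverman bandwidth) Ks density.

    Local maxima of the density are reported as peaks ordered by mode;
    every value is assigned to its nearest mode to give each peak's mass.
    Requires at least 20 finite values.
    """
    vals = np.asarray([k for k in ks_values if k is not None], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < 20:
        raise ValidationError("need ≥ 20 finite Ks values for a density")
    kde = gaussian_kde(vals, bw_method="silverman")
    lo, hi = vals.min(), vals.max()
    pad = 3 * kde.factor * vals.std(ddof=1) if vals.std(ddof=1) > 0 else 1.0
    grid = np.linspace(lo - pad, hi + pad, grid_points)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    modes = grid[1:-1][interior]
    if modes.size == 0:  # flat/degenerate density
        modes = np.array([grid[np.argmax(dens)]])
    nearest = np.argmin(np.abs(vals[:, None] - modes[None, :]), axis=1)
    peaks = [
        KsPeak(mode=float(m), mass=float(np.mean(nearest == i)))
        for i, m in enumerate(modes)
    ]
    peaks.sort(key=lambda p: p.mode)
    return peaks


@dataclass
class WgdEra:
    """WGD-era label for a block-mean Ks value."""

    label: str
    ks_interval: tuple[float, float]


#: Ks intervals for the two documented pear WGD events: the recent
#: lineage-specific WGD (Ks ≲ 0.3, ~30–45 MYA) and the ancient core-eudicot
#: WGD (Ks 1.5–1.8, ~140 MYA).
RECENT_WGD_MAX_KS = 0.3
ANCIENT_WGD_KS = (1.5, 1.8)


def assign_wgd_era(ks: float) -> WgdEra:
    """Map a Ks value to a WGD era: recent, ancient, older, or undated."""
    if not math.isfinite(ks) or ks < 0:
        raise ValidationError(f"invalid Ks {ks}")
    if ks <= RECENT_WGD_MAX_KS:
        return WgdEra("recent_wgd", (0.0, RECENT_WGD_MAX_KS))
    if ANCIENT_WGD_KS[0] <= ks <= ANCIENT_WGD_KS[1]:
        return WgdEra("ancient_wgd", ANCIENT_WGD_KS)
    if ks > ANCIENT_WGD_KS[1]:
        return WgdEra("older", (ANCIENT_WGD_KS[1], math.inf))
    return WgdEra("undated", (RECENT_WGD_MAX_KS, ANCIENT_WGD_KS[0]))


def filter_candidates_for_branch_site(blocks, max_ks: float = 0.3):
    """Blocks young enough (mean Ks < ``max_ks``) for branch-site testing.

    The branch-site likelihood test itself is external; this exports the
    candidate list the way the collinearity pipeline feeds it.
    """
    return [b for b in blocks if b.mean_ks is not None and b.mean_ks < max_ks]
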