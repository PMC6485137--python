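"""Family delimitation by position-specific scoring matrix (PSSM) scan.

A log-odds profile is built from a seed alignment of the target domain
(for a NAC-type family, the conserved N-terminal DNA-binding domain) and
slid over every proteome entry; proteins with at least one window at or
above the bit threshold are family members.  This is a windowed PSSM, not
a profile HMM: there are no insert/delete states, the acceptance decision
is binary domain presence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "DomainProfile",
    "DomainHit",
    "build_pssm",
    "scan_protein",
    "identify_family_members",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

#: default acceptance threshold as a fraction of the consensus score
DEFAULT_MIN_BITS_FRACTION = 0.6


@dataclass
class DomainProfile:
    """Per-column log2-odds scores over the 20 amino acids.

    ``scores`` has shape (length, 20); ``min_bits`` is the acceptance
    threshold for a window.  Residues outside the 20-letter alphabet
    score 0 (background) during scanning.
    """

    scores: np.ndarray
    background: np.ndarray
    min_bits: float

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def consensus_score(self) -> float:
        """Score of the per-column best residue sequence (the maximum)."""
        return float(self.scores.max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.scores.argmax(axis=1))


@dataclass
class DomainHit:
    """One accepted window: gene, 0-based protein offset and bit score."""

    gene_id: str
    window_start: int
    bits: float


def build_pssm(
    seed_alignment: dict[str, str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    min_bits: float | None = None,
    max_gap_fraction: float = 0.5,
) -> DomainProfile:
    """Build a log-odds profile from an aligned set of domain sequences.

    score(col, aa) = log2(((count + pseudocount·bg_aa) / (n + pseudocount))
    / bg_aa) with n the non-gap count of the column.  Columns with more
    than ``max_gap_fraction`` gaps are dropped.  ``min_bits`` defaults to
    0.6 × consensus score.
    """
    seqs = list(seed_alignment.values())
    if len(seqs) < 2:
        raise ValidationError("seed alignment needs ≥ 2 sequences")
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValidationError("seed alignment rows differ in length")
    allowed = set(AA_ALPHABET) | {"-"}
    for name, s in seed_alignment.items():
        bad = set(s.upper()) - allowed
        if bad:
            raise ValidationError(f"{name}: symbols outside 20 AAs + gap: {sorted(bad)}")
    if background is None:
        background = np.full(20, 0.05)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not np.isclose(background.sum(), 1.0):
        raise ValidationError("background must be 20 frequencies summing to 1")
    cols = []
    for j in range(width):
        column = [s[j].upper() for s in seqs]
        gaps = column.count("-")
        if gaps / len(seqs) > max_gap_fraction:
            continue
        counts = np.zeros(20)
        for a in column:
            if a != "-":
                counts[_AA_INDEX[a]] += 1
        n = counts.sum()
        freq = (counts + pseudocount * background) / (n + pseudocount)
        cols.append(np.log2(freq / background))
    scores = np.vstack(cols)
    if scores.shape[0] < 10:
        raise ValidationError("profile length must be ≥ 10 after gap-column removal")
    profile = DomainProfile(scores=scores, background=background, min_bits=0.0)
    if min_bits is None:
        min_bits = DEFAULT_MIN_BITS_FRACTION * profile.consensus_score
    profile.min_bits = float(min_bits)
    return profile


def _encode(protein: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(a, -1) for a in protein.upper()], dtype=np.int64)


def window_scores(profile: DomainProfile, protein: str) -> np.ndarray:
    """Bit score of every length-L window of the protein (vectorized)."""
    L = profile.length
    idx = _encode(protein)
    if idx.size < L:
        return np.empty(0)
    win = np.lib.stride_tricks.sliding_window_view(idx, L)  # (n_windows, L)
    scores = np.zeros((L, 21))  # extra column: unknown residues score 0
    scores[:, :20] = profile.scores
    lookup = np.where(win >= 0, win, 20)
    return scores[np.arange(L)[None, :], lookup].sum(axis=1)


def scan_protein(profile: DomainProfile, protein: str, gene_id: str = "") -> list[DomainHit]:
    """All windows at or above ``min_bits``, overlaps collapsed to the best.

    Overlapping accepted windows are greedily reduced to the highest
    scoring one (ties resolved leftmost).
    """
    scores = window_scores(profile, protein)
    hits = [
        (float(s), i) for i, s in enumerate(scores) if s >= profile.min_bits
    ]
    if not hits:
        return []
    hits.sort(key=lambda t: (-t[0], t[1]))
    kept: list[tuple[float, int]] = []
    L = profile.length
    for s, i in hits:
        if all(abs(i - j) >= L for _, j in kept):
            kept.append((s, i))
    kept.sort(key=lambda t: t[1])
    return [DomainHit(gene_id=gene_id, window_start=i, bits=s) for s, i in kept]


def identify_family_members(
    proteome: dict[str, str], profile: DomainProfile
) -> list[str]:
    """Sorted ids of proteins with at least one accepted domain window."""
    if not proteome:
        raise ValidationError("empty proteome")
    members = []
    for gid in sorted(proteome):
        if scan_protein(profile, proteome[gid], gid):
            members.append(gid)
    return members
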