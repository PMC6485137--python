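"""Pairwise protein homology with calibrated E-values.

Global Needleman–Wunsch alignment (affine gaps, BLOSUM62 via Biopython's
PairwiseAligner) scored into bits with Karlin–Altschul statistics
(defaults λ = 0.267, K = 0.041, the standard gapped-BLOSUM62 values) and
an E-value E = m·n·2^(−bits).  E-values here are calibrated screens, not
BLAST-bit-compatible reproductions; within-family all-vs-all at
E ≤ 1e-5 defines the homologous-pair universe for synteny and
duplication classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError

__all__ = ["ScoringScheme", "HomologPair", "align_global", "evalue", "all_vs_all"]

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap penalties and E-value constants.

    ``gap_open`` is the cost of the first residue of a gap and
    ``gap_extend`` the cost of each further residue (both positive).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValidationError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValidationError("Karlin–Altschul constants must be positive")
        self._matrix = substitution_matrices.load(self.matrix_name)

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = self._matrix
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        aligner.mode = "global"
        return aligner


@dataclass(order=True)
class HomologPair:
    """An unordered homologous pair stored once with gene_a < gene_b."""

    gene_a: str
    gene_b: str
    raw_score: float = field(compare=False)
    bits: float = field(compare=False)
    evalue: float = field(compare=False)

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            raise ValidationError("HomologPair requires gene_a < gene_b")


def _check_protein(seq: str, name: str) -> None:
    if not seq:
        raise ValidationError(f"{name}: empty sequence")
    bad = set(seq.upper()) - _VALID_AA
    if bad:
        raise ValidationError(f"{name}: non-amino-acid symbols {sorted(bad)}")


def align_global(
    a: str, b: str, scheme: ScoringScheme | None = None
) -> tuple[float, str, str]:
    """Optimal global alignment of two proteins.

    Returns (raw_score, gapped_a, gapped_b).  Deterministic: Biopython's
    first optimal traceback is reported.
    """
    scheme = scheme or ScoringScheme()
    _check_protein(a, "a")
    _check_protein(b, "b")
    aligner = scheme.make_aligner()
    aln = aligner.align(a.upper(), b.upper())[0]
    return float(aln.score), str(aln[0]), str(aln[1])


def align_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Score-only fast path of :func:`align_global` (same optimum)."""
    scheme = scheme or ScoringScheme()
    _check_protein(a, "a")
    _check_protein(b, "b")
    return float(scheme.make_aligner().score(a.upper(), b.upper()))


def bit_score(raw_score: float, scheme: ScoringScheme | None = None) -> float:
    scheme = scheme or ScoringScheme()
    return (scheme.karlin_lambda * raw_score - math.log(scheme.karlin_k)) / math.log(2)


def evalue(
    raw_score: float, m: int, n: int, scheme: ScoringScheme | None = None
) -> float:
    """Karlin–Altschul expect value E = m·n·2^(−bits) for a raw score."""
    if m < 1 or n < 1:
        raise ValidationError("sequence/database lengths must be ≥ 1")
    bits = bit_score(raw_score, scheme)
    return float(m) * float(n) * 2.0 ** (-bits)


def all_vs_all(
    proteins: dict[str, str],
    scheme: ScoringScheme | None = None,
    max_e: float = 1e-5,
    candidate_pairs=None,
) -> list[HomologPair]:
    """All unordered pairs scoring at or below ``max_e``.

    The database length n used in the E-value is the total residue count
    of the searched set.  ``candidate_pairs`` optionally restricts which
    pairs are evaluated (e.g. cross-window pairs during synteny search)
    without changing how any evaluated pair is scored.
    """
    scheme = scheme or ScoringScheme()
    ids = sorted(proteins)
    if len(ids) < 2:
        raise ValidationError("need at least two proteins")
    total_residues = sum(len(s) for s in proteins.values())
    aligner = scheme.make_aligner()
    if candidate_pairs is None:
        candidate_pairs = [
            (ids[i], ids[j]) for i in range(len(ids)) for j in range(i + 1, len(ids))
        ]
    out: list[HomologPair] = []
    seen: set[tuple[str, str]] = set()
    for a, b in candidate_pairs:
        a, b = (a, b) if a < b else (b, a)
        if a == b or (a, b) in seen:
            continue
        seen.add((a, b))
        raw = float(aligner.score(proteins[a], proteins[b]))
        e = evalue(raw, len(proteins[a]), total_residues, scheme)
        if e <= max_e:
            out.append(
                HomologPair(a, b, raw_score=raw, bits=bit_score(raw, scheme), evalue=e)
            )
    out.sort()
    return out
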