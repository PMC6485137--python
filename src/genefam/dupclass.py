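"""Five-category duplication classification of family genes.

Each family gene receives exactly one of {wgd_segmental, tandem,
proximal, dispersed, singleton} under the MCScanX-style precedence
wgd_segmental > tandem > proximal > dispersed > singleton: block
anchorship wins; otherwise the closest same-chromosome homolog decides
tandem (rank gap ≤ 1) vs proximal (rank gap ≤ 10); any remaining homolog
makes the gene dispersed; a gene without homologs is a singleton.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .genome_io import GenomeAnnotation
from .homology import HomologPair
from .synteny import SyntenyBlock

__all__ = ["DuplicationCall", "DupSummary", "classify_duplicates", "summarize_categories"]

CATEGORIES = ("singleton", "dispersed", "proximal", "tandem", "wgd_segmental")


@dataclass
class DuplicationCall:
    """One gene's duplication category with its supporting partner/block."""

    gene_id: str
    category: str
    evidence: str | None


@dataclass
class DupSummary:
    """Per-category gene counts, percentages of family size, pair counts."""

    gene_counts: dict[str, int]
    percentages: dict[str, float]
    pair_counts: dict[str, int]
    family_size: int


def classify_duplicates(
    g: GenomeAnnotation,
    family: list[str],
    pairs: list[HomologPair],
    blocks: list[SyntenyBlock],
    proximal_max_gap: int = 10,
    tandem_max_gap: int = 1,
) -> list[DuplicationCall]:
    """Classify every family gene into one duplication category.

    Deterministic: evidence partners are chosen by smallest rank gap then
    lexicographic id; input order never changes a call.
    """
    family_sorted = sorted(set(family))
    for gid in family_sorted:
        if gid not in g.rank:
            raise ValidationError(f"family gene {gid!r} missing from annotation")
    partners: dict[str, set[str]] = {gid: set() for gid in family_sorted}
    for p in pairs:
        if p.gene_a in partners:
            partners[p.gene_a].add(p.gene_b)
        if p.gene_b in partners:
            partners[p.gene_b].add(p.gene_a)
    anchor_block: dict[str, str] = {}
    for bi, b in enumerate(sorted(blocks, key=lambda b: (b.segment_a, b.segment_b))):
        bid = f"block{bi}"
        for a in b.anchors:
            for gid in (a.gene_a, a.gene_b):
                anchor_block.setdefault(gid, bid)
    calls = []
    for gid in family_sorted:
        chrom, rank = g.rank[gid]
        if gid in anchor_block:
            calls.append(DuplicationCall(gid, "wgd_segmental", anchor_block[gid]))
            continue
        homs = sorted(partners[gid])
        if not homs:
            calls.append(DuplicationCall(gid, "singleton", None))
            continue
        same_chrom = [
            (abs(g.rank[h][1] - rank), h)
            for h in homs
            if h in g.rank and g.rank[h][0] == chrom
        ]
        same_chrom.sort()
        if same_chrom and same_chrom[0][0] <= tandem_max_gap:
            calls.append(DuplicationCall(gid, "tandem", same_chrom[0][1]))
        elif same_chrom and same_chrom[0][0] <= proximal_max_gap:
            calls.append(DuplicationCall(gid, "proximal", same_chrom[0][1]))
        else:
            calls.append(DuplicationCall(gid, "dispersed", homs[0]))
    return calls


def summarize_categories(calls: list[DuplicationCall]) -> DupSummary:
    """Category counts, percentages of family size, and evidence-pair counts."""
    if not calls:
        raise ValidationError("no calls to summarize")
    counts = {c: 0 for c in CATEGORIES}
    pair_evidence: dict[str, set[frozenset[str]]] = {c: set() for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
        if call.evidence and not call.evidence.startswith("block"):
            pair_evidence[call.category].add(frozenset((call.gene_id, call.evidence)))
    n = len(calls)
    percentages = {c: 100.0 * counts[c] / n for c in CATEGORIES}
    pair_counts = {c: len(pair_evidence[c]) for c in CATEGORIES}
    return DupSummary(counts, percentages, pair_counts, family_size=n)
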