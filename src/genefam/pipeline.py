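"""End-to-end orchestration: identify → homology → synteny → Ka/Ks →
classify, with TSV emission.

The genome-wide homologous-pair universe is built in two exact passes:
family×family pairs are always aligned, and the remaining gene pairs are
screened by equal-length CDS nucleotide identity (a cheap exact filter
that cleanly separates substitution-diverged duplicate pairs from
unrelated genes at the divergences the pipeline dates) before protein
alignment and E-value scoring.  Every pair that reaches the output was scored by the same
alignment + Karlin–Altschul path as :func:`genefam.homology.all_vs_all`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .dupclass import DuplicationCall, DupSummary, classify_duplicates, summarize_categories
from .errors import ValidationError
from .famscan import DomainProfile, build_pssm, identify_family_members
from .genome_io import GenomeAnnotation
from .homology import HomologPair, ScoringScheme, all_vs_all
from .kaks import (
    KaKsResult,
    assign_wgd_era,
    block_mean_ks,
    codon_align,
    compute_kaks,
)
from .homology import align_global
from .synteny import SyntenyBlock, SyntenyParams, detect_synteny_blocks

__all__ = ["PipelineResult", "build_homolog_universe", "pair_kaks", "run_family_analysis"]


def build_homolog_universe(
    proteins: dict[str, str],
    cds: dict[str, str],
    family: list[str],
    scheme: ScoringScheme | None = None,
    max_e: float = 1e-5,
    prescreen_min_cds_identity: float = 0.45,
) -> list[HomologPair]:
    """Homologous pairs at ``max_e`` across the whole gene set.

    The E-value database length is the total residue count of the full
    protein set.  Family×family pairs are aligned unconditionally; every
    other pair must first pass a cheap exact prescreen: equal CDS length
    and per-site nucleotide identity ≥ ``prescreen_min_cds_identity``
    (random same-length CDSs sit near 25% identity, substitution-diverged
    duplicates well above 55%).  The prescreen exploits the fact that
    duplicate divergence here is substitution-dominated; every surviving
    pair is scored by the exact alignment + E-value path.
    """
    scheme = scheme or ScoringScheme()
    family_set = set(family)
    candidates: list[tuple[str, str]] = [
        (a, b)
        for i, a in enumerate(sorted(family_set))
        for b in sorted(family_set)[i + 1 :]
        if a in proteins and b in proteins
    ]
    by_length: dict[int, list[str]] = {}
    for gid in sorted(cds):
        if gid in proteins:
            by_length.setdefault(len(cds[gid]), []).append(gid)
    for length, members in by_length.items():
        if len(members) < 2 or length == 0:
            continue
        mat = np.frombuffer(
            "".join(cds[g] for g in members).encode(), dtype=np.uint8
        ).reshape(len(members), length)
        for i in range(len(members)):
            ident = (mat[i + 1 :] == mat[i]).mean(axis=1)
            for off in np.nonzero(ident >= prescreen_min_cds_identity)[0]:
                a, b = members[i], members[i + 1 + off]
                if not (a in family_set and b in family_set):
                    candidates.append((a, b))
    if not candidates:
        return []
    return all_vs_all(proteins, scheme, max_e=max_e, candidate_pairs=candidates)


def pair_kaks(
    gene_a: str,
    gene_b: str,
    proteins: dict[str, str],
    cds: dict[str, str],
    scheme: ScoringScheme | None = None,
) -> KaKsResult:
    """Align two proteins, back-translate, and run NG86 + JC."""
    _, ga, gb = align_global(proteins[gene_a], proteins[gene_b], scheme)
    al = codon_align(cds[gene_a], cds[gene_b], ga, gb)
    return compute_kaks(al)


@dataclass
class PipelineResult:
    """Everything the family pipeline computes in one pass."""

    profile: DomainProfile
    family: list[str]
    pairs: list[HomologPair]
    blocks: list[SyntenyBlock]
    calls: list[DuplicationCall]
    summary: DupSummary
    anchor_kaks: dict[tuple[str, str], KaKsResult] = field(default_factory=dict)
    block_ks_values: list[float] = field(default_factory=list)


def run_family_analysis(
    annotation: GenomeAnnotation,
    proteins: dict[str, str],
    cds: dict[str, str],
    seed_alignment: dict[str, str],
    synteny_params: SyntenyParams | None = None,
    scheme: ScoringScheme | None = None,
    min_bits: float | None = None,
) -> PipelineResult:
    """Run identify → homology → synteny → Ka/Ks → classify."""
    synteny_params = synteny_params or SyntenyParams()
    scheme = scheme or ScoringScheme()
    profile = build_pssm(seed_alignment, min_bits=min_bits)
    family = identify_family_members(proteins, profile)
    if len(family) < 2:
        raise ValidationError("fewer than two family members identified")
    pairs = build_homolog_universe(
        proteins, cds, family, scheme, max_e=synteny_params.max_pair_e
    )
    blocks = detect_synteny_blocks(annotation, family, pairs, synteny_params)
    anchor_kaks: dict[tuple[str, str], KaKsResult] = {}
    block_ks_values = []
    for b in blocks:
        ks_list = []
        for a in b.anchors:
            k = (a.gene_a, a.gene_b)
            if k not in anchor_kaks:
                anchor_kaks[k] = pair_kaks(a.gene_a, a.gene_b, proteins, cds, scheme)
            ks_list.append(anchor_kaks[k].Ks)
        mean, sd, n_sat = block_mean_ks(ks_list)
        b.mean_ks, b.sd_ks, b.n_saturated = mean, sd, n_sat
        b.era = assign_wgd_era(mean).label
        block_ks_values.append(mean)
    calls = classify_duplicates(annotation, family, pairs, blocks)
    summary = summarize_categories(calls)
    return PipelineResult(
        profile=profile,
        family=family,
        pairs=pairs,
        blocks=blocks,
        calls=calls,
        summary=summary,
        anchor_kaks=anchor_kaks,
        block_ks_values=block_ks_values,
    )


# ---------------------------------------------------------------------------
# TSV emission


def _write_tsv(path, frame: pd.DataFrame, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# genefam {__version__}\n# {stamp}\n")
        frame.to_csv(fh, sep="\t", index=False)


def write_results(result: PipelineResult, outdir, stamp: str = "") -> None:
    """Emit family / pairs / blocks / anchors / calls / summary TSVs."""
    import os

    os.makedirs(outdir, exist_ok=True)
    _write_tsv(
        os.path.join(outdir, "family.tsv"),
        pd.DataFrame({"gene_id": result.family}),
        stamp,
    )
    _write_tsv(
        os.path.join(outdir, "homolog_pairs.tsv"),
        pd.DataFrame(
            [
                {
                    "gene_a": p.gene_a,
                    "gene_b": p.gene_b,
                    "raw_score": p.raw_score,
                    "bits": p.bits,
                    "evalue": p.evalue,
                }
                for p in result.pairs
            ]
        ),
        stamp,
    )
    block_rows, anchor_rows = [], []
    for i, b in enumerate(result.blocks):
        block_rows.append(
            {
                "block_id": f"block{i}",
                "focal_a": b.focal_pair[0],
                "focal_b": b.focal_pair[1],
                "chrom_a": b.segment_a[0],
                "span_a": f"{b.segment_a[1][0]}-{b.segment_a[1][1]}",
                "chrom_b": b.segment_b[0],
                "span_b": f"{b.segment_b[1][0]}-{b.segment_b[1][1]}",
                "n_anchors": b.n_anchors,
                "Q": b.q,
                "block_E": b.block_e,
                "mean_Ks": b.mean_ks,
                "sd_Ks": b.sd_ks,
                "era": b.era,
            }
        )
        for a in b.anchors:
            res = result.anchor_kaks.get((a.gene_a, a.gene_b))
            anchor_rows.append(
                {
                    "block_id": f"block{i}",
                    "gene_a": a.gene_a,
                    "gene_b": a.gene_b,
                    "rank_a": a.rank_a,
                    "rank_b": a.rank_b,
                    "Ka": res.Ka if res else None,
                    "Ks": res.Ks if res else None,
                    "omega": res.omega if res else None,
                    "class": res.selection_class if res else None,
                }
            )
    _write_tsv(os.path.join(outdir, "blocks.tsv"), pd.DataFrame(block_rows), stamp)
    _write_tsv(os.path.join(outdir, "anchors.tsv"), pd.DataFrame(anchor_rows), stamp)
    _write_tsv(
        os.path.join(outdir, "duplication_calls.tsv"),
        pd.DataFrame(
            [
                {"gene_id": c.gene_id, "category": c.category, "evidence": c.evidence}
                for c in result.calls
            ]
        ),
        stamp,
    )
    _write_tsv(
        os.path.join(outdir, "duplication_summary.tsv"),
        pd.DataFrame(
            [
                {
                    "category": cat,
                    "genes": result.summary.gene_counts[cat],
                    "percent": round(result.summary.percentages[cat], 2),
                    "pairs": result.summary.pair_counts[cat],
                }
                for cat in result.summary.gene_counts
            ]
        ),
        stamp,
    )
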