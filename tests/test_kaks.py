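import itertools
import math

import numpy as np
import pytest

from genefam.errors import ValidationError
from genefam.kaks import (
    SENSE_CODONS,
    CodonAlignment,
    assign_wgd_era,
    block_mean_ks,
    codon_align,
    codon_sites,
    compute_kaks,
    filter_candidates_for_branch_site,
    jukes_cantor,
    ks_distribution_peaks,
    ng86_counts,
    pathway_differences,
)
from oracles import oracle_codon_sites, oracle_pathway_counts


def _al(pairs):
    return CodonAlignment(list(pairs))


def test_phe_codon_has_one_third_synonymous_site():
    # TTT: only the position-3 T->C change (TTC, Phe) is synonymous
    assert codon_sites("TTT") == pytest.approx(1 / 3)


def test_single_synonymous_difference():
    s, n, sd, nd = ng86_counts(_al([("TTT", "TTC")]))
    assert (sd, nd) == (1.0, 0.0)


def test_identical_codons_have_no_differences():
    _, _, sd, nd = ng86_counts(_al([("TTT", "TTT")]))
    assert (sd, nd) == (0.0, 0.0)


def test_site_counts_match_enumeration_oracle_for_every_sense_codon():
    for codon in SENSE_CODONS:
        assert codon_sites(codon) == pytest.approx(oracle_codon_sites(codon))


def test_pathway_averaging_matches_oracle_on_all_sense_codon_pairs():
    """Exhaustive NG86 pathway check over the full 61x61 sense-codon grid."""
    for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
        sd, nd = pathway_differences(ca, cb)
        osd, ond = oracle_pathway_counts(ca, cb)
        assert sd == pytest.approx(osd), (ca, cb)
        assert nd == pytest.approx(ond), (ca, cb)
        hamming = sum(x != y for x, y in zip(ca, cb))
        assert sd + nd == pytest.approx(hamming)


def test_counts_symmetric_in_rows():
    rng = np.random.default_rng(0)
    pairs = [
        (SENSE_CODONS[i], SENSE_CODONS[j])
        for i, j in rng.integers(0, len(SENSE_CODONS), (30, 2))
    ]
    fwd = ng86_counts(_al(pairs))
    rev = ng86_counts(_al([(b, a) for a, b in pairs]))
    assert fwd == pytest.approx(rev)


def test_sites_sum_to_three_per_codon():
    rng = np.random.default_rng(1)
    pairs = [
        (SENSE_CODONS[i], SENSE_CODONS[j])
        for i, j in rng.integers(0, len(SENSE_CODONS), (50, 2))
    ]
    s, n, _, _ = ng86_counts(_al(pairs))
    assert s + n == pytest.approx(3 * len(pairs))


def test_jukes_cantor_closed_form():
    assert jukes_cantor(0.3) == pytest.approx(0.75 * -math.log(0.6))
    with pytest.raises(ValidationError):
        jukes_cantor(0.75)


def test_identical_sequences_have_zero_rates_and_undefined_omega():
    r = compute_kaks(_al([("ATG", "ATG"), ("GCT", "GCT")]))
    assert r.Ka == 0.0 and r.Ks == 0.0
    assert r.omega is None and r.selection_class is None


def test_codon_align_identity():
    al = codon_align("ATGGCTAAA", "ATGGCTAAA", "MAK", "MAK")
    assert al.n_codons == 3
    assert all(a == b for a, b in al.pairs)


def test_codon_align_drops_gap_columns():
    al = codon_align("ATGGCTAAA", "ATGAAA", "MAK", "M-K")
    assert al.n_codons == 2
    assert al.pairs == [("ATG", "ATG"), ("AAA", "AAA")]


def test_codon_align_rejects_mismatched_protein():
    with pytest.raises(ValidationError):
        codon_align("ATGGCT", "ATG", "MAK", "M")


def test_codon_align_rejects_internal_stop():
    with pytest.raises(ValidationError):
        codon_align("ATGTAAAAA", "ATGTAAAAA", "M*K", "M*K")


def test_trailing_stop_trimmed():
    al = codon_align("ATGGCTTAA", "ATGGCTTGA", "MA", "MA")
    assert al.n_codons == 2


def test_block_mean_ks_single_anchor():
    assert block_mean_ks([0.5]) == (0.5, 0.0, 0)


def test_block_mean_ks_arithmetic():
    mean, sd, excluded = block_mean_ks([0.02, 0.04, 0.06])
    assert mean == pytest.approx(0.04)
    assert sd == pytest.approx(0.02)
    assert excluded == 0


def test_saturated_anchor_exclusion_leaves_mean_unchanged():
    mean, _, excluded = block_mean_ks([0.02, 0.04, 0.06, None])
    assert mean == pytest.approx(0.04)
    assert excluded == 1
    with pytest.raises(ValidationError):
        block_mean_ks([None, None])


def test_two_planted_peaks_recovered():
    rng = np.random.default_rng(0)
    vals = np.concatenate(
        [rng.normal(0.2, 0.05, 200), rng.normal(1.65, 0.15, 200)]
    )
    peaks = ks_distribution_peaks(vals)
    top = sorted(peaks, key=lambda p: -p.mass)[:2]
    modes = sorted(p.mode for p in top)
    assert abs(modes[0] - 0.2) < 0.05
    assert abs(modes[1] - 1.65) < 0.05


def test_unimodal_sample_yields_one_peak():
    rng = np.random.default_rng(1)
    peaks = ks_distribution_peaks(rng.normal(0.5, 0.1, 300))
    assert len(peaks) == 1
    assert peaks[0].mass == pytest.approx(1.0)


def test_peak_modes_shift_equivariantly():
    rng = np.random.default_rng(2)
    vals = np.concatenate([rng.normal(0.3, 0.05, 150), rng.normal(1.2, 0.1, 150)])
    base = ks_distribution_peaks(vals)
    shifted = ks_distribution_peaks(vals + 0.7)
    assert len(base) == len(shifted)
    for p, q in zip(base, shifted):
        assert q.mode - p.mode == pytest.approx(0.7, abs=1e-6)


def test_too_few_values_for_density():
    with pytest.raises(ValidationError):
        ks_distribution_peaks([0.1] * 19)


@pytest.mark.parametrize(
    "ks,label",
    [
        (0.04, "recent_wgd"),  # young block of the recent lineage WGD
        (1.65, "ancient_wgd"),
        (2.88, "older"),
        (0.9, "undated"),
        (0.3, "recent_wgd"),
        (1.5, "ancient_wgd"),
    ],
)
def test_wgd_era_assignment(ks, label):
    assert assign_wgd_era(ks).label == label


def test_negative_ks_rejected():
    with pytest.raises(ValidationError):
        assign_wgd_era(-0.1)


class _FakeBlock:
    def __init__(self, mean_ks):
        self.mean_ks = mean_ks


def test_branch_site_candidate_boundary():
    kept = filter_candidates_for_branch_site(
        [_FakeBlock(0.29), _FakeBlock(0.31), _FakeBlock(None)]
    )
    assert [b.mean_ks for b in kept] == [0.29]
    assert filter_candidates_for_branch_site([]) == []


def test_recent_blocks_kept_ancient_blocks_dropped(pipeline_result):
    blocks = pipeline_result.blocks
    kept = filter_candidates_for_branch_site(blocks)
    for b in blocks:
        assert (b in kept) == (b.mean_ks < 0.3)
    assert any(b.mean_ks < 0.3 for b in blocks)  # a recent block exists


def test_estimated_ks_distribution_bimodal_with_saturation_bias():
    """NG86-estimated Ks over pairs planted from the two WGD peaks is
    bimodal: the recent mode is recovered within ±0.05, while the ancient
    mode sits below the planted 1.65 by the documented Jukes–Cantor
    near-saturation bias (concavity plus truncation at p = 3/4)."""
    from genefam.synthio import _random_codons, evolve_duplicate_pair

    rng = np.random.default_rng(0)
    ks_hat = []
    for mean, sd in ((0.2, 0.05), (1.65, 0.15)):
        for _ in range(120):
            ks = max(0.01, rng.normal(mean, sd))
            cds = "".join(_random_codons(rng, 500))
            a, b = evolve_duplicate_pair(cds, ks, 0.25, rng)
            r = compute_kaks(
                CodonAlignment(
                    [(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)]
                )
            )
            if r.Ks is not None:
                ks_hat.append(r.Ks)
    top = sorted(ks_distribution_peaks(ks_hat), key=lambda p: -p.mass)[:2]
    modes = sorted(p.mode for p in top)
    assert abs(modes[0] - 0.2) < 0.05
    assert 1.35 < modes[1] < 1.70
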