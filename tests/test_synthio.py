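import dataclasses

import numpy as np
import pytest

from genefam.errors import ValidationError
from genefam.genome_io import translate_cds
from genefam.kaks import CodonAlignment, compute_kaks
from genefam.synthio import (
    SimConfig,
    evolve_duplicate_pair,
    simulate_expression_counts,
    simulate_genome,
)


def test_same_seed_reproduces_genome_exactly(small_config):
    a = simulate_genome(small_config)
    b = simulate_genome(small_config)
    assert a.proteins == b.proteins
    assert a.cds == b.cds
    assert a.truth.pairs == b.truth.pairs
    assert a.seed_alignment == b.seed_alignment


def test_full_retention_block_has_all_anchor_pairs(small_config):
    cfg = dataclasses.replace(small_config, wgd_retention=1.0, seed=5)
    sim = simulate_genome(cfg)
    (block,) = sim.truth.blocks
    assert len(block.anchor_pairs) == cfg.wgd_block_length


def test_partial_retention_matches_binomial_expectation(small_config):
    # non-family block genes retained with p=0.8; family genes always kept
    cfg = dataclasses.replace(
        small_config, wgd_retention=0.8, wgd_block_length=30, genes_per_chromosome=120
    )
    retained = []
    for seed in range(30):
        sim = simulate_genome(dataclasses.replace(cfg, seed=seed))
        retained.append(len(sim.truth.blocks[0].anchor_pairs))
    n_background = cfg.wgd_block_length - cfg.family_genes_per_block
    expected = cfg.family_genes_per_block + 0.8 * n_background
    se = np.sqrt(n_background * 0.8 * 0.2 / len(retained))
    assert abs(np.mean(retained) - expected) < 4 * se + 1e-9


def test_planted_pairs_exist_in_annotation(sim_genome):
    for p in sim_genome.truth.pairs:
        assert p.gene_a in sim_genome.annotation
        assert p.gene_b in sim_genome.annotation
        assert p.category in {"wgd_segmental", "tandem", "proximal", "dispersed"}


def test_evolve_zero_ks_is_identity():
    rng = np.random.default_rng(0)
    cds = "ATGGCTGGTCCTAAAGGT"
    a, b = evolve_duplicate_pair(cds, 0.0, 0.3, rng)
    assert a == b == cds


def test_evolve_zero_omega_changes_no_amino_acids():
    rng = np.random.default_rng(1)
    from genefam.synthio import _random_codons

    cds = "".join(_random_codons(rng, 300))
    a, b = evolve_duplicate_pair(cds, 0.8, 0.0, rng)
    assert translate_cds(a) == translate_cds(b)
    assert a != b  # synonymous divergence did happen


def test_evolve_rejects_internal_stop():
    rng = np.random.default_rng(0)
    with pytest.raises(ValidationError):
        evolve_duplicate_pair("ATGTAAGGT", 0.1, 0.5, rng)


def test_evolve_never_creates_stops():
    from genefam.kaks import STOP_CODONS
    from genefam.synthio import _random_codons

    rng = np.random.default_rng(2)
    cds = "".join(_random_codons(rng, 200))
    for ks in (0.2, 1.8):
        a, b = evolve_duplicate_pair(cds, ks, 0.5, rng)
        for s in (a, b):
            assert not any(
                s[i : i + 3] in STOP_CODONS for i in range(0, len(s), 3)
            )


def test_ng86_recovers_planted_ks():
    from genefam.synthio import _random_codons

    rng = np.random.default_rng(3)
    ks_hat = []
    for _ in range(40):
        cds = "".join(_random_codons(rng, 500))
        a, b = evolve_duplicate_pair(cds, 0.2, 0.3, rng)
        al = CodonAlignment([(a[i : i + 3], b[i : i + 3]) for i in range(0, len(a), 3)])
        ks_hat.append(compute_kaks(al).Ks)
    assert abs(np.mean(ks_hat) - 0.2) / 0.2 < 0.15


def test_expression_counts_deterministic(small_config):
    a, _ = simulate_expression_counts(small_config)
    b, _ = simulate_expression_counts(small_config)
    assert (a.counts.values == b.counts.values).all()


def test_expression_planted_fold_visible_in_rpkm(small_config):
    from genefam.expression import compute_rpkm

    cm, truth = simulate_expression_counts(small_config)
    rpkm = compute_rpkm(cm)
    ratios = []
    for d in truth.de_genes:
        for t in d.timepoints:
            ratios.append(rpkm.loc[d.gene_id, t] / rpkm.loc[d.gene_id, "0h"] / d.fold)
    # Poisson noise only: observed/planted fold concentrates near 1
    assert abs(np.mean(ratios) - 1) < 0.1


def test_expression_rejects_nonpositive_library(small_config):
    import dataclasses as dc

    cfg = dc.replace(small_config)
    cfg.expression = dc.replace(cfg.expression, library_size=0.0)
    with pytest.raises(ValidationError):
        simulate_expression_counts(cfg)


def test_capacity_overflow_errors(small_config):
    cfg = dataclasses.replace(
        small_config, n_chromosomes=1, genes_per_chromosome=40, wgd_blocks=2
    )
    with pytest.raises(ValidationError, match="capacity"):
        simulate_genome(cfg)


def test_emitted_files_parse_cleanly(tmp_path, sim_genome):
    from genefam.genome_io import read_fasta, read_gff3
    from genefam.synthio import write_simulation

    write_simulation(sim_genome, tmp_path)
    ann = read_gff3(tmp_path / "genes.gff3")
    prot = read_fasta(tmp_path / "proteins.fasta")
    assert len(ann) == len(sim_genome.annotation)
    assert prot == sim_genome.proteins
    # planted block spans agree with the rank index of the parsed GFF
    for block in sim_genome.truth.blocks:
        for ga, gb in block.anchor_pairs:
            assert block.span_a[0] <= ann.rank[ga][1] <= block.span_a[1]
            assert block.span_b[0] <= ann.rank[gb][1] <= block.span_b[1]
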