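"""Synthetic genomes, sequences and count matrices with known truth.

Generates multi-chromosome gene orders carrying planted WGD/segmental
blocks, tandem, proximal and dispersed duplicate pairs whose pairwise
divergence is planted at chosen Ks with ω < 1; protein sequences carrying
a planted domain (so the family-delimitation, homology, synteny and
classification stages can be validated against truth tables); and
negative-binomial time-course count matrices with planted up-regulation.

Divergence planting is calibrated to the NG86 estimator: substitution
events are drawn per codon position from the *total* planted Ks using the
Jukes–Cantor inverse p = (3/4)(1 − e^(−4·Ks/3)) (ω·Ks for nonsynonymous
positions) and each event is assigned to one of the two copies at
random.  The pairwise difference probability is then exactly the JC
inverse of the planted distance, which makes NG86 + JC approximately
unbiased on simulator output.

Within a simulated family every member shares the planted domain, so all
family members are mutually homologous at the usual E-value screen
(as in a real transcription-factor family); the truth table therefore
labels unpaired family genes "dispersed", never "singleton".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_io import GeneModel, GenomeAnnotation, translate_cds, write_fasta, write_gff3
from .kaks import SENSE_CODONS, STOP_CODONS, syn_fraction, translate_codon
from .famscan import AA_ALPHABET

__all__ = [
    "ExpressionPlan",
    "SimConfig",
    "TruthTable",
    "SimulatedGenome",
    "evolve_duplicate_pair",
    "simulate_genome",
    "simulate_expression_counts",
    "write_simulation",
]

_CODONS_BY_AA: dict[str, list[str]] = {}
for _c in SENSE_CODONS:
    _CODONS_BY_AA.setdefault(translate_codon(_c), []).append(_c)


@dataclass
class ExpressionPlan:
    """Design of the simulated stress time course.

    One library per timepoint (no biological replicates).  ``nb_dispersion``
    is the negative-binomial dispersion φ (variance μ + φμ²); the default 0
    gives Poisson counts, the counting-noise-only regime the no-replicate
    differential test models.  DE genes have their baseline multiplied by a
    fold (cycled from ``de_folds``) at ``de_timepoints``.
    """

    timepoints: tuple[str, ...] = ("0h", "1h", "3h", "6h", "rec24h")
    library_size: float = 2e7
    nb_dispersion: float = 0.0
    n_genes: int = 520
    n_de_genes: int = 20
    de_folds: tuple[float, ...] = (4.0, 8.0)
    de_timepoints: tuple[str, ...] = ("3h", "6h")
    baseline_log_rpkm_mean: float = math.log(30.0)
    baseline_log_rpkm_sd: float = 0.5


@dataclass
class SimConfig:
    """Genome-simulation plan: sizes, duplication counts, Ks peaks, seed."""

    n_chromosomes: int = 5
    genes_per_chromosome: int = 200
    domain_profile_length: int = 50
    n_family_genes: int = 50
    wgd_blocks: int = 2
    wgd_block_length: int = 20
    wgd_retention: float = 0.8
    family_genes_per_block: int = 2
    tandem_pairs: int = 4
    proximal_pairs: int = 4
    dispersed_pairs: int = 4
    proximal_gap: tuple[int, int] = (2, 10)
    ks_peaks: tuple[tuple[float, float], ...] = ((0.2, 0.05), (1.65, 0.15))
    omega_range: tuple[float, float] = (0.1, 0.3)
    family_length_codons: int = 150
    filler_length_codons: tuple[int, int] = (100, 150)
    n_seed_seqs: int = 8
    seed_seq_divergence: float = 0.05
    domain_omega_scale: float = 0.05
    window_margin: int = 17
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.wgd_retention <= 1:
            raise ValidationError("retention must be in (0, 1]")
        if self.omega_range[0] < 0:
            raise ValidationError("omega must be ≥ 0")
        for c in (
            self.wgd_blocks,
            self.tandem_pairs,
            self.proximal_pairs,
            self.dispersed_pairs,
        ):
            if c < 0:
                raise ValidationError("duplication counts must be ≥ 0")


@dataclass
class PlantedPair:
    gene_a: str
    gene_b: str
    category: str
    planted_ks: float
    planted_omega: float
    block_id: str | None = None


@dataclass
class PlantedBlock:
    block_id: str
    chrom_a: str
    chrom_b: str
    span_a: tuple[int, int]  # rank interval on chrom_a
    span_b: tuple[int, int]
    anchor_pairs: list[tuple[str, str]]
    planted_ks: float


@dataclass
class PlantedDe:
    gene_id: str
    fold: float
    timepoints: tuple[str, ...]


@dataclass
class TruthTable:
    """Everything the simulator planted, for downstream validation."""

    pairs: list[PlantedPair] = field(default_factory=list)
    blocks: list[PlantedBlock] = field(default_factory=list)
    family: list[str] = field(default_factory=list)
    expected_category: dict[str, str] = field(default_factory=dict)
    de_genes: list[PlantedDe] = field(default_factory=list)


@dataclass
class SimulatedGenome:
    annotation: GenomeAnnotation
    proteins: dict[str, str]
    cds: dict[str, str]
    truth: TruthTable
    seed_alignment: dict[str, str]


def _random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n)]


def _reverse_translate(rng: np.random.Generator, protein: str) -> list[str]:
    return [
        _CODONS_BY_AA[a][rng.integers(0, len(_CODONS_BY_AA[a]))] for a in protein
    ]


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = []
    for a in protein:
        if rng.random() < rate:
            out.append(AA_ALPHABET[rng.integers(0, 20)])
        else:
            out.append(a)
    return "".join(out)


def evolve_duplicate_pair(
    cds: str,
    ks: float,
    omega: float,
    rng: np.random.Generator,
    omega_codon_scale: np.ndarray | None = None,
):
    """Diverge one CDS into two copies at planted (Ks, ω).

    For each codon position the NG86 synonymous fraction f splits the
    site; a synonymous event occurs with probability f·p_s,
    p_s = (3/4)(1 − e^(−4Ks/3)), a nonsynonymous event with probability
    (1−f)·p_n, p_n = (3/4)(1 − e^(−4ωKs/3)).  Events pick a target
    uniformly within their class; substitutions that would create a stop
    codon are redrawn within the class (left unchanged if the class has
    no stop-free member).  Each event lands on one of the two copies at
    random, so the planted divergence is split symmetrically.
    ``omega_codon_scale`` optionally multiplies ω per codon (used to hold
    planted domains under stronger purifying selection).
    """
    if ks < 0:
        raise ValidationError("ks must be ≥ 0")
    if omega < 0:
        raise ValidationError("omega must be ≥ 0")
    codons = [cds[i : i + 3].upper() for i in range(0, len(cds) - len(cds) % 3, 3)]
    for c in codons:
        if c in STOP_CODONS:
            raise ValidationError("internal stop codon in input CDS")
    p_s = 0.75 * -math.expm1(-4.0 * ks / 3.0)
    copy_a, copy_b = [], []
    for ci, codon in enumerate(codons):
        scale = 1.0 if omega_codon_scale is None else float(omega_codon_scale[ci])
        p_n = 0.75 * -math.expm1(-4.0 * omega * scale * ks / 3.0)
        state = [codon, codon]  # current codon of each copy
        for j in range(3):
            f = syn_fraction(codon, j)
            u = rng.random()
            if u < f * p_s:
                wanted_syn = True
            elif u < f * p_s + (1.0 - f) * p_n:
                wanted_syn = False
            else:
                continue
            which = int(rng.random() < 0.5)
            cur = state[which]
            aa = translate_codon(cur)
            choices = []
            for b in "ACGT":
                if b == cur[j]:
                    continue
                alt = cur[:j] + b + cur[j + 1 :]
                if alt in STOP_CODONS:
                    continue
                if (translate_codon(alt) == aa) == wanted_syn:
                    choices.append(alt)
            if not choices:
                continue
            state[which] = choices[rng.integers(0, len(choices))]
        copy_a.append(state[0])
        copy_b.append(state[1])
    return "".join(copy_a), "".join(copy_b)


class _Gene:
    __slots__ = ("gene_id", "codons", "family", "domain_span")

    def __init__(self, gene_id, codons, family=False, domain_span=None):
        self.gene_id = gene_id
        self.codons = codons
        self.family = family
        self.domain_span = domain_span  # (start_codon, end_codon) or None


def _draw_ks(rng, peak):
    mean, sd = peak
    return max(0.01, float(rng.normal(mean, sd)))


def simulate_genome(cfg: SimConfig) -> SimulatedGenome:
    """Build a genome realization of the simulation plan.

    Family features (blocks, tandem/proximal/dispersed pairs, unpaired
    members) are placed so that distinct features never share a synteny
    window; WGD blocks are contiguous runs copied onto another chromosome
    with per-gene loss (family members of a block are always retained, so
    every planted block stays discoverable from a family focal pair).
    """
    rng = np.random.default_rng(cfg.seed)
    n_chrom, n_per = cfg.n_chromosomes, cfg.genes_per_chromosome
    L = cfg.wgd_block_length
    margin = cfg.window_margin

    # --- the domain and its seed alignment -------------------------------
    master = "".join(AA_ALPHABET[i] for i in rng.integers(0, 20, cfg.domain_profile_length))
    seed_alignment = {
        f"seed{i}": _mutate_protein(rng, master, cfg.seed_seq_divergence)
        for i in range(cfg.n_seed_seqs)
    }

    # --- plan family feature placement ----------------------------------
    # Features are laid out with a per-chromosome cursor and a guard gap of
    # window_margin genes, so no two features ever share a synteny window.
    cursor = [int(rng.integers(0, 8)) for _ in range(n_chrom)]

    def alloc(width: int, exclude: int | None = None) -> tuple[int, int]:
        viable = [
            c
            for c in range(n_chrom)
            if c != exclude and cursor[c] + width + 4 <= n_per
        ]
        if not viable:
            raise ValidationError("duplication plan exceeds genome capacity")
        # fill the emptiest chromosome first, random tie-break
        rng.shuffle(viable)
        c = min(viable, key=lambda c: cursor[c])
        lo = cursor[c] + int(rng.integers(0, 4))
        if lo + width > n_per:
            lo = n_per - width
        cursor[c] = lo + width + margin + 1
        return c, lo

    blocks_plan = []
    for b in range(cfg.wgd_blocks):
        cs, src = alloc(L)
        ct, tgt = alloc(L, exclude=cs)
        peak = cfg.ks_peaks[b % len(cfg.ks_peaks)]
        blocks_plan.append((f"wgd{b}", cs, src, ct, tgt, peak))

    def place_pair_positions(gap: int):
        chrom, lo = alloc(gap + 1)
        return chrom, lo, lo + gap

    tandem_plan = [place_pair_positions(1) for _ in range(cfg.tandem_pairs)]
    proximal_plan = [
        place_pair_positions(int(rng.integers(cfg.proximal_gap[0], cfg.proximal_gap[1] + 1)))
        for _ in range(cfg.proximal_pairs)
    ]
    dispersed_plan = []
    for _ in range(cfg.dispersed_pairs):
        c1, p1 = alloc(1)
        c2, p2 = alloc(1, exclude=c1)
        dispersed_plan.append((c1, p1, c2, p2))

    n_planned = (
        2 * cfg.family_genes_per_block * cfg.wgd_blocks
        + 2 * (cfg.tandem_pairs + cfg.proximal_pairs + cfg.dispersed_pairs)
    )
    n_single = cfg.n_family_genes - n_planned
    if n_single < 0:
        raise ValidationError(
            f"n_family_genes={cfg.n_family_genes} below planned duplicates ({n_planned})"
        )
    singles_plan = []
    for _ in range(n_single):
        chrom, pos = alloc(1)
        singles_plan.append((chrom, pos))

    # --- build base chromosomes -----------------------------------------
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"G{counter:05d}"

    chromosomes: list[list[_Gene]] = []
    for c in range(n_chrom):
        genes = []
        for _ in range(n_per):
            n_codons = int(rng.integers(*cfg.filler_length_codons))
            genes.append(_Gene(new_id(), _random_codons(rng, n_codons)))
        chromosomes.append(genes)

    domain_codon_offset = 30

    def make_family_gene(gene: _Gene) -> None:
        protein_domain = _mutate_protein(rng, master, 0.04)
        codons = _random_codons(rng, cfg.family_length_codons)
        dom = _reverse_translate(rng, protein_domain)
        s = domain_codon_offset
        codons[s : s + len(dom)] = dom
        gene.codons = codons
        gene.family = True
        gene.domain_span = (s, s + len(dom))

    truth = TruthTable()

    def omega_scale_for(gene: _Gene) -> np.ndarray | None:
        if gene.domain_span is None:
            return None
        scale = np.ones(len(gene.codons))
        s, e = gene.domain_span
        scale[s:e] = cfg.domain_omega_scale
        return scale

    def duplicate(gene: _Gene, ks: float, omega: float) -> _Gene:
        cds = "".join(gene.codons)
        a, b = evolve_duplicate_pair(cds, ks, omega, rng, omega_scale_for(gene))
        gene.codons = [a[i : i + 3] for i in range(0, len(a), 3)]
        dup = _Gene(
            new_id(),
            [b[i : i + 3] for i in range(0, len(b), 3)],
            family=gene.family,
            domain_span=gene.domain_span,
        )
        return dup

    # --- WGD blocks ------------------------------------------------------
    for block_id, cs, src, ct, tgt, peak in blocks_plan:
        block_ks = _draw_ks(rng, peak)
        fam_offsets = {2, L - 3} if cfg.family_genes_per_block >= 2 else {L // 2}
        anchor_pairs = []
        for off in range(L):
            gene = chromosomes[cs][src + off]
            is_fam = off in fam_offsets
            if is_fam:
                make_family_gene(gene)
            retained = is_fam or rng.random() < cfg.wgd_retention
            if not retained:
                continue
            ks = max(0.01, block_ks + float(rng.normal(0, 0.02)))
            omega = float(rng.uniform(*cfg.omega_range))
            dup = duplicate(gene, ks, omega)
            chromosomes[ct][tgt + off] = dup
            anchor_pairs.append((gene.gene_id, dup.gene_id))
            truth.pairs.append(
                PlantedPair(gene.gene_id, dup.gene_id, "wgd_segmental", ks, omega, block_id)
            )
            if is_fam:
                truth.expected_category[gene.gene_id] = "wgd_segmental"
                truth.expected_category[dup.gene_id] = "wgd_segmental"
        truth.blocks.append(
            PlantedBlock(
                block_id,
                chrom_a=f"chr{cs + 1}",
                chrom_b=f"chr{ct + 1}",
                span_a=(src, src + L - 1),
                span_b=(tgt, tgt + L - 1),
                anchor_pairs=anchor_pairs,
                planted_ks=block_ks,
            )
        )

    # --- tandem / proximal / dispersed pairs ----------------------------
    def plant_pair(category, chrom1, pos1, chrom2, pos2):
        gene = chromosomes[chrom1][pos1]
        make_family_gene(gene)
        peak = cfg.ks_peaks[int(rng.integers(0, len(cfg.ks_peaks)))]
        ks = _draw_ks(rng, peak)
        omega = float(rng.uniform(*cfg.omega_range))
        dup = duplicate(gene, ks, omega)
        chromosomes[chrom2][pos2] = dup
        truth.pairs.append(PlantedPair(gene.gene_id, dup.gene_id, category, ks, omega))
        truth.expected_category[gene.gene_id] = category
        truth.expected_category[dup.gene_id] = category

    for chrom, p1, p2 in tandem_plan:
        plant_pair("tandem", chrom, p1, chrom, p2)
    for chrom, p1, p2 in proximal_plan:
        plant_pair("proximal", chrom, p1, chrom, p2)
    for c1, p1, c2, p2 in dispersed_plan:
        plant_pair("dispersed", c1, p1, c2, p2)
    for chrom, pos in singles_plan:
        gene = chromosomes[chrom][pos]
        make_family_gene(gene)
        # every family member shares the domain, hence has homologs:
        # an unpaired member is expected to classify as dispersed
        truth.expected_category[gene.gene_id] = "dispersed"

    # --- coordinates, annotation, sequences -----------------------------
    models = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    for c, genes in enumerate(chromosomes):
        pos = 1
        for gene in genes:
            cds = "".join(gene.codons)
            n_exons = int(rng.integers(1, 6))
            exonic = len(cds)
            cuts = sorted(rng.choice(np.arange(1, exonic // 3), n_exons - 1, replace=False) * 3) if n_exons > 1 else []
            bounds = [0, *cuts, exonic]
            start = pos + int(rng.integers(200, 2000))
            exons = []
            at = start
            for i in range(n_exons):
                size = bounds[i + 1] - bounds[i]
                exons.append((at, at + size - 1))
                at += size + int(rng.integers(50, 500))
            end = exons[-1][1]
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                GeneModel(
                    gene_id=gene.gene_id,
                    chromosome=f"chr{c + 1}",
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                    cds=cds,
                )
            )
            proteins[gene.gene_id] = translate_cds(cds)
            cds_map[gene.gene_id] = cds
            pos = end
    truth.family = sorted(
        g.gene_id for genes in chromosomes for g in genes if g.family
    )
    annotation = GenomeAnnotation(models)
    return SimulatedGenome(annotation, proteins, cds_map, truth, seed_alignment)


def simulate_expression_counts(
    cfg: SimConfig,
    gene_lengths: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
):
    """Simulate a no-replicate time-course count matrix with planted DE.

    Counts are NB(mean = baseline_rpkm · length_kb · libsize/10⁶,
    dispersion φ from the plan; φ = 0 → Poisson).  DE genes (first
    ``n_de_genes`` of a random draw) have their baseline multiplied by a
    fold at the designated timepoints.  Returns (CountMatrix, TruthTable
    with de_genes filled).
    """
    from .expression import CountMatrix  # local import to avoid cycle

    plan = cfg.expression
    if len(plan.timepoints) < 2:
        raise ValidationError("need ≥ 2 timepoints")
    if plan.library_size <= 0:
        raise ValidationError("library size must be positive")
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if gene_lengths is None:
        gene_lengths = {
            f"E{i:05d}": int(rng.integers(300, 1500)) for i in range(plan.n_genes)
        }
    genes = sorted(gene_lengths)
    lengths = np.array([gene_lengths[g] for g in genes], dtype=float)
    baseline = np.exp(
        rng.normal(plan.baseline_log_rpkm_mean, plan.baseline_log_rpkm_sd, len(genes))
    )
    de_idx = rng.choice(len(genes), size=min(plan.n_de_genes, len(genes)), replace=False)
    truth = TruthTable()
    folds = np.ones((len(genes), len(plan.timepoints)))
    for rank, gi in enumerate(sorted(de_idx)):
        fold = plan.de_folds[rank % len(plan.de_folds)]
        for t in plan.de_timepoints:
            folds[gi, plan.timepoints.index(t)] = fold
        truth.de_genes.append(PlantedDe(genes[gi], fold, tuple(plan.de_timepoints)))
    mu = (
        baseline[:, None]
        * folds
        * (lengths[:, None] / 1000.0)
        * (plan.library_size / 1e6)
    )
    if plan.nb_dispersion > 0:
        size = 1.0 / plan.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    frame = pd.DataFrame(counts, index=genes, columns=list(plan.timepoints))
    cm = CountMatrix(
        counts=frame,
        gene_length_bp=pd.Series(lengths, index=genes),
        library_size=pd.Series(plan.library_size, index=list(plan.timepoints)),
    )
    return cm, truth


def write_simulation(sim: SimulatedGenome, outdir) -> None:
    """Emit FASTA/GFF3/truth TSVs for a simulated genome."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_gff3(os.path.join(outdir, "genes.gff3"), sim.annotation)
    write_fasta(os.path.join(outdir, "proteins.fasta"), sim.proteins)
    write_fasta(os.path.join(outdir, "cds.fasta"), sim.cds)
    write_fasta(os.path.join(outdir, "seed_alignment.fasta"), sim.seed_alignment)
    pd.DataFrame([asdict(p) for p in sim.truth.pairs]).to_csv(
        os.path.join(outdir, "truth_pairs.tsv"), sep="\t", index=False
    )
    rows = []
    for b in sim.truth.blocks:
        rows.append(
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "span_a": f"{b.span_a[0]}-{b.span_a[1]}",
                "span_b": f"{b.span_b[0]}-{b.span_b[1]}",
                "n_anchors": len(b.anchor_pairs),
                "planted_ks": b.planted_ks,
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(outdir, "truth_blocks.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        {
            "gene_id": sim.truth.family,
            "expected_category": [
                sim.truth.expected_category.get(g, "") for g in sim.truth.family
            ],
        }
    ).to_csv(os.path.join(outdir, "truth_family.tsv"), sep="\t", index=False)
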