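# Methods

This note records the models behind each stage, the parameters that
matter, what the simulator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Family delimitation (PSSM scan)

A windowed position-specific scoring matrix replaces a profile HMM: the
delimitation decision is binary domain presence, and a PSSM is fully
auditable. From an aligned set of domain sequences, columns with > 50%
gaps are dropped and each remaining column scores
`log2(((n_aa + τ·q_aa) / (n + τ)) / q_aa)` with pseudocount τ (default 1)
and background q (default uniform 0.05). The acceptance threshold
defaults to 0.6 × the consensus score: a profile-specific gathering
cutoff is not available for a homemade PSSM, and 0.6 sits far above the
score distribution of unrelated windows (which is near 0 by
construction) while tolerating ~20–25% domain divergence. Overlapping
hits collapse to the best-scoring window, ties leftmost. No
insert/delete states are modelled, so family members whose domain
carries indels relative to the seed would be penalized — a known
limitation, irrelevant for the substitution-only simulator.

## Homology and E-values

Within-family scoring uses *global* Needleman–Wunsch (affine gaps,
BLOSUM62, open 11 / extend 1, a gap of length k costing 11 + (k−1))
rather than local alignment: family members are domain-anchored and
near-full-length. Raw scores convert to bits with the standard gapped
BLOSUM62 Karlin–Altschul constants (λ = 0.267, K = 0.041) and
E = m·n·2^(−bits) with n the total residue count of the searched set.
These E-values are a calibrated screen, not a reproduction of any
particular local-alignment tool's statistics; the 1e-5 threshold
separates diverged duplicates (hundreds of bits) from unrelated global
alignments (near or below zero raw score) by a wide margin.

The genome-wide homolog universe used by the synteny stage
(`pipeline.build_homolog_universe`) prescreens non-family candidate
pairs by equal CDS length + per-site nucleotide identity ≥ 0.45 before
exact alignment. Random same-length coding sequences sit near 25%
identity and substitution-diverged duplicates above ~55%, so the screen
is conservative at the divergences the pipeline dates (Ks ≤ ~2). It
assumes substitution-dominated duplicate divergence (no indels), which
holds exactly for the simulator; on real genomes a BLAST-style search
would take this role. Family×family pairs are always aligned exactly.

## Collinearity detection

For each homologous family pair, a window of 15 genes each side of both
members is extracted (truncated at chromosome ends); anchors are
homologous pairs with one member in each window, matched greedily one
partner per gene (smallest id on ties, deterministic). Three gates must
hold simultaneously:

* **≥ 3 anchors** (the minimum-evidence gate);
* **Q ≥ 0.9**, where Q is r², the squared Pearson correlation of anchor
  ranks. r² rather than |r| or a slope statistic: it is bounded in
  [0, 1], orientation-agnostic (an inverted segment is still collinear),
  and affine-invariant, so window-local and chromosome-global ranks give
  identical values (asserted in tests);
* **block E ≤ 0.01**, formalized as the upper binomial tail
  P(X ≥ n_anchors), X ~ Binomial(w_a·w_b, ρ) with ρ the genome-wide
  homolog density (homolog pairs / total gene pairs). This is the
  simplest calibrated null — anchors falling independently at the
  background rate — and is isolated in one function so it can be
  swapped. At the simulated density (~2.5 × 10⁻³) three anchors are not
  significant (E ≈ 0.4) but ten are (E < 10⁻⁴), which is what keeps
  tandem clusters from masquerading as blocks.

Blocks reachable from several focal pairs are merged keeping the
anchor-maximal one (ties: larger Q, then leftmost span).

## Ka/Ks (NG86) and WGD dating

Synonymous site fractions per codon position count the one-step changes
preserving the amino acid (changes to stops count as nonsynonymous);
pair sites average the two codons, so S + N = 3·n_codons exactly.
Multi-position codon differences are averaged over all orders of
applying the changes with equal weights; pathways crossing a stop codon
are excluded, and in the rare case that every pathway crosses a stop all
are kept. Proportions are corrected with Jukes–Cantor
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is an explicit "saturated" state (the
pair is flagged and excluded from block means, never a silent NaN).
ω = 1 is declared neutral within |ω − 1| ≤ 1e-9; exact equality is
measure-zero.

Block mean Ks dates the duplication: ≤ 0.3 → the recent lineage WGD
(~30–45 MYA), 1.5–1.8 → the ancient WGD (~140 MYA), > 1.8 → older,
otherwise undated. Ks peaks are modes of a Gaussian KDE with Silverman
bandwidth, each value assigned to its nearest mode. Known bias: near
saturation the JC correction is concave and the saturation cut truncates
the upper tail, so block mean Ks for ancient blocks estimated from
~100–150-codon genes runs ~10–15% low (an ancient block planted at
Ks 1.65 is typically estimated near 1.45 and may land in "undated");
at 500 codons the estimator recovers Ks 1.5 within ~10% (measured by
`scripts/acceptance.py`).

Blocks with mean Ks < 0.3 are exported as candidates for an external
branch-site likelihood analysis; running that analysis is out of scope.

## Duplication classification

Precedence per family gene: WGD/segmental (anchor in an accepted block)
> tandem (homolog at rank gap ≤ 1, same chromosome) > proximal
(gap ≤ 10) > dispersed (any other homolog) > singleton. The precedence
and the gap defaults follow the established duplicate-gene-classifier
convention the five-category vocabulary comes from. Evidence partners
are chosen by smallest rank gap, then lexicographic id, making calls
independent of input order.

## Neighbor joining and subgroups

Canonical Saitou–Nei NJ with the Q criterion; ties break to the
lexicographically smallest leaf-label pair; negative branch lengths are
clamped to zero with the deficit moved to the sister branch. NJ is exact
on additive matrices — tested by path-length identity on random trees up
to 32 leaves and cross-checked against an independent NJ implementation.
Subgroups are connected leaf components after cutting every edge longer
than a threshold; the threshold is a user choice (no principled value
exists for mapping clades to named subgroups), and the examples show how
the partition coarsens with it. Bootstrap/posterior support is out of
scope.

## Expression analysis

With one library per timepoint, only a two-library count test is
defensible; the Audic–Claverie predictive distribution is used:
P(y′|x) = ρ^y′ (x+y′)! / (x! y′! (1+ρ)^(x+y′+1)), ρ = n₂/n₁. The
two-sided p symmetrizes the two conditionings,
p = min(1, 2·min(P(Y ≥ y|x), P(X ≥ x|y))), which makes swapping the two
libraries a strict no-op (the literal one-sided conditioning is not
swap-symmetric). Measured type-I error at nominal 0.05 is ~0.04–0.05
(slightly conservative, as expected for a doubled discrete test).

DEG thresholds are FDR ≤ 0.001 (Benjamini–Hochberg) and |log2FC| ≥ 1,
both inclusive; fold changes use RPKM with an ε = 0.01 pseudocount
against zeros. The ≥ 1.5-fold up-regulation filter takes the maximum
over all non-baseline timepoints. Heatmap clustering is average-linkage
hierarchical clustering of z-scored rows cut into k = 6 clusters
(deterministic; constant rows go to a sentinel cluster 0). qPCR
quantification is 2^−ΔΔCt over three replicates with a delta-method
standard error. Enrichment is the upper hypergeometric tail with BH
across terms.

## The simulator and what passing tests mean

`synthio` generates the regime the analysis assumes: 5 chromosomes × 200
genes; a 50-member family carrying a 50-residue domain; two WGD blocks
of 20 genes copied to another chromosome with per-gene retention 0.8
(family members of a block always retained, so every planted block
remains discoverable from a family focal pair); 4 tandem, 4 proximal
(gap 2–10) and 4 dispersed pairs; pair divergence drawn from two Ks
peaks, N(0.2, 0.05) and N(1.65, 0.15) — the two documented WGD eras —
with ω ~ U(0.1, 0.3), typical purifying selection for a conserved
regulator family. Inside the planted domain ω is scaled by 0.05 (domains
sit under stronger constraint); without this, ancient duplicates would
shed the domain and no scanner could delimit the family. Features are
placed so that no two occupy one synteny window, which makes planted
truth unambiguous. Substitution events are drawn per codon position from
the *total* planted Ks via the JC inverse p = (3/4)(1 − e^(−4Ks/3))
(ω·Ks for nonsynonymous positions) and assigned to a random copy, so the
pairwise difference probability is exactly the JC inverse and NG86 + JC
is approximately unbiased by construction; substitutions that would
create a stop are redrawn within their class.

Counts are NB(mean = baseline·length_kb·libsize/10⁶, dispersion φ) over
timepoints 0/1/3/6 h + 24 h recovery with 2 × 10⁷-read libraries;
planted DE genes carry 4×/8× folds at 3 h and 6 h. φ defaults to 0
(Poisson): one library per timepoint gives the differential test no way
to see biological dispersion, and with φ ≳ 0.01 chance 2-fold
fluctuations among null genes become "significant" by construction —
planting dispersion the test cannot model would only document that
no-replicate designs cannot control it. That is the central caveat for
real data: passing these tests shows correct behaviour under counting
noise, not robustness to biological replication variance.

Other features of real data deliberately not emulated: indel evolution,
codon-usage bias, intergenic sequence, isoform variation, and
mapping/quantification error (counts are generated, not aligned).

## Problem sizes and determinism

Validation sizes (all chosen as comfortable desk-scale defaults): the
NG86 oracle check covers all 3721 sense-codon pairs; estimator recovery
uses 200 pairs × 6 (Ks, ω) settings at 500 codons; synteny/classification
recovery uses 20 simulated genomes of 1000 genes; peak finding 20 seeds
of 200 + 200 draws; the differential test 10⁴ null genes and 20
simulated time courses; NJ 20 random trees up to 32 leaves. Every
stochastic step takes an explicit seed or generator; a fixed seed
reproduces simulator output, pipeline results and CLI output directories
byte for byte.
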