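# genefam

Desk-scale tooling for genome-wide surveys of plant transcription-factor
gene families — the analysis chain behind questions like *"how did this
NAC-type family expand, which duplication events produced it, what
selection acted on the duplicates, and which members respond to
drought/cold stress?"*

It is written for computational biologists who want each stage of such a
survey as a tested, importable operation rather than a pile of one-off
scripts: family delimitation by domain scan, microsynteny detection,
duplication classification, Ka/Ks dating, subgroup phylogenetics, and
no-replicate RNA-seq stress-expression analysis. A truth-emitting
simulator generates genomes and count matrices with known planted
structure, so every stage is validated end to end without downloads.

## What it computes

- **Family delimitation** (`genefam.famscan`) — a position-specific
  scoring matrix built from a seed alignment of the family domain,
  score(col, aa) = log2(((n_aa + τ·q_aa)/(n + τ))/q_aa), slid over the
  proteome; proteins with a window above the bit threshold are members.
- **Homology** (`genefam.homology`) — global Needleman–Wunsch with
  affine gaps over BLOSUM62, converted to bits by Karlin–Altschul
  statistics (λ = 0.267, K = 0.041) and screened at E = m·n·2^(−bits) ≤ 1e-5.
- **Collinearity** (`genefam.synteny`) — for each homologous family
  pair, 15 genes are taken from each side of both members; homologous
  pairs inside the two windows are anchors. A block is reported when it
  has ≥ 3 anchors, the squared Pearson correlation of anchor ranks
  (the Q-value) is ≥ 0.9, and a binomial-tail block E-value given the
  background homolog density is ≤ 0.01.
- **Ka/Ks and WGD dating** (`genefam.kaks`) — Nei–Gojobori (1986) site
  counting with equal-weight mutational-pathway averaging and
  Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); block mean Ks values
  date duplications (Ks ≤ 0.3 → recent WGD, 1.5–1.8 → ancient WGD);
  ω = Ka/Ks < 1 purifying, = 1 neutral, > 1 positive; blocks with
  mean Ks < 0.3 are exported as branch-site test candidates.
- **Duplication classes** (`genefam.dupclass`) — every family gene gets
  one of singleton / dispersed / proximal / tandem / WGD-segmental under
  the precedence block-anchor > tandem (rank gap ≤ 1) > proximal
  (gap ≤ 10) > dispersed.
- **Phylogeny** (`genefam.phylo`) — p-distances, canonical Saitou–Nei
  neighbor joining (exact on additive matrices), Newick output, and
  subgroup partitioning by cutting long edges.
- **Expression** (`genefam.expression`) — RPKM; the Audic–Claverie
  two-library count test (the defensible choice with one replicate per
  timepoint) with Benjamini–Hochberg FDR; DEG filter FDR ≤ 0.001 and
  |log2FC| ≥ 1; ≥ 1.5-fold up-regulation filter; 6-cluster average-linkage
  heatmap clustering of z-scored rows; 2^−ΔΔCt qPCR quantification;
  hypergeometric term enrichment.
- **Simulator** (`genefam.synthio`) — multi-chromosome gene orders with
  planted WGD blocks, tandem/proximal/dispersed pairs diverged at chosen
  Ks and ω < 1, domain-carrying family proteins, and negative-binomial
  time-course counts with planted fold changes; all with truth tables.

## Worked example

`examples/01_simulate_and_detect_synteny.py` simulates a 5-chromosome,
1000-gene genome with two planted WGD blocks and a 50-member family,
then runs the full chain:

```
family members identified: 50 (planted: 50)
homologous pairs (E <= 1e-5): 1255
collinear blocks detected: 2 (planted: 2)
  chr1 ranks (4, 21)  <->  chr5 ranks (3, 20): 15 anchors, Q=1.000, E=4.11e-08, mean Ks=0.142 (recent_wgd)
  chr2 ranks (6, 23)  <->  chr3 ranks (7, 24): 16 anchors, Q=1.000, E=7.00e-12, mean Ks=2.036 (older)

duplication categories (genes, % of family):
       singleton:   0  (0.00%)
       dispersed:  26  (52.00%)
        proximal:   8  (16.00%)
          tandem:   8  (16.00%)
   wgd_segmental:   8  (16.00%)

agreement with planted categories: 50/50
```

Reading this: all 50 planted family members were recovered by the domain
scan; both planted blocks were detected with Q ≈ 1 (anchor ranks on a
straight line — the collinearity signature of segmental/WGD duplication).
The first block's mean anchor Ks of 0.14 places it in the recent WGD
era; the second diverged far earlier. Every gene's duplication category
matches the planted truth. The other examples cover Ka/Ks estimation,
PSSM scanning, the expression stage, and NJ subgroups — each prints the
numbers it computes and what they mean.

There is also a thin CLI (`genefam simulate|identify|homology|synteny|
kaks|classify|express|qpcr|phylo|demo|run`); `genefam demo --outdir out
--seed 0` runs the whole chain on simulated data and writes a
truth-vs-called report.

## Layout

```
src/genefam/     library modules (genome_io, synthio, famscan, homology,
                 synteny, kaks, dupclass, phylo, expression, pipeline, cli)
examples/        one short narrative script per capability
tests/           pytest suite with independent brute-force oracles
docs/methods.md  models, assumptions, parameter choices, limitations
```
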