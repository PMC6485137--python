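"""Count-to-result expression analysis for a no-replicate time course.

RPKM normalization, the Audic–Claverie two-library count test with
Benjamini–Hochberg FDR, the differential-expression filters
(FDR ≤ 0.001 and |log2FC| ≥ 1; ≥ 1.5-fold up-regulation), z-scored
average-linkage clustering into k clusters, the 2^−ΔΔCt relative
expression estimator, and hypergeometric term enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom, nbinom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "CountMatrix",
    "DegRecord",
    "QpcrMeasurement",
    "compute_rpkm",
    "ac_test",
    "bh_fdr",
    "call_degs",
    "upregulated_filter",
    "cluster_expression",
    "ddct",
    "hypergeom_enrich",
]

#: RPKM pseudocount used in every fold-change ratio
FOLD_EPSILON = 0.01


@dataclass
class CountMatrix:
    """Genes × samples integer counts with gene lengths and library sizes.

    ``library_size`` is the total mapped reads of each library; it need
    not equal the in-matrix column sum.
    """

    counts: pd.DataFrame  # genes x samples, ints
    gene_length_bp: pd.Series  # per gene
    library_size: pd.Series  # per sample

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise ValidationError("counts must be nonnegative")
        self.gene_length_bp = self.gene_length_bp.reindex(self.counts.index)
        self.library_size = self.library_size.reindex(self.counts.columns)
        if self.gene_length_bp.isna().any() or (self.gene_length_bp <= 0).any():
            raise ValidationError("every gene needs a positive length")
        if self.library_size.isna().any() or (self.library_size <= 0).any():
            raise ValidationError("every sample needs a positive library size")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


def compute_rpkm(c: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads, elementwise."""
    length_kb = c.gene_length_bp / 1000.0
    lib_m = c.library_size / 1e6
    return c.counts.div(length_kb, axis=0).div(lib_m, axis=1)


def ac_test(x, y, n1: float, n2: float):
    """Two-sided Audic–Claverie p-value for one gene in two libraries.

    Under the AC model the predictive distribution of the second count
    given the first is negative binomial:
    P(y'|x) = ρ^y' (x+y')! / (x! y'! (1+ρ)^(x+y'+1)) with ρ = n2/n1.
    The two-sided p symmetrizes the upper tails of both conditionings,
    p = min(1, 2·min(P(Y ≥ y | x), P(X ≥ x | y))), so that swapping
    (x, n1) and (y, n2) leaves the value unchanged.  Accepts scalars or
    numpy arrays for ``x``/``y``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValidationError("library sizes must be positive")
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("counts must be nonnegative")
    rho = n2 / n1
    # P(Y >= y | x): Y ~ NB(x+1 successes, success prob 1/(1+rho))
    upper_y = nbinom.sf(y - 1, x + 1, 1.0 / (1.0 + rho))
    # P(X >= x | y): X ~ NB(y+1, success prob rho/(1+rho))
    upper_x = nbinom.sf(x - 1, y + 1, rho / (1.0 + rho))
    p = np.minimum(1.0, 2.0 * np.minimum(upper_y, upper_x))
    return float(p) if p.ndim == 0 else p


def bh_fdr(pvalues):
    """Benjamini–Hochberg step-up adjusted values (monotone, tie-stable)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must be in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


#: DEG thresholds: FDR ≤ 0.001 and |log2 fold change| ≥ 1, both inclusive
DEG_MAX_FDR = 0.001
DEG_MIN_ABS_LOG2FC = 1.0


@dataclass
class DegRecord:
    """Per-gene differential-expression result for one sample pair."""

    gene_id: str
    reference_sample: str
    test_sample: str
    log2fc: float
    pvalue: float
    fdr: float
    is_deg: bool


def call_degs(
    rpkm: pd.DataFrame,
    c: CountMatrix,
    reference_sample: str,
    test_sample: str,
    max_fdr: float = DEG_MAX_FDR,
    min_abs_log2fc: float = DEG_MIN_ABS_LOG2FC,
) -> list[DegRecord]:
    """Differential calls between two libraries.

    log2FC uses RPKM with an ε = 0.01 pseudocount; p-values come from the
    Audic–Claverie test on the raw counts, adjusted across genes by BH.
    A gene is a DEG iff fdr ≤ max_fdr and |log2FC| ≥ min_abs_log2fc
    (boundaries inclusive).
    """
    for s in (reference_sample, test_sample):
        if s not in c.counts.columns:
            raise ValidationError(f"unknown sample {s!r}")
    x = c.counts[reference_sample].to_numpy()
    y = c.counts[test_sample].to_numpy()
    p = ac_test(
        x, y, float(c.library_size[reference_sample]), float(c.library_size[test_sample])
    )
    fdr = bh_fdr(p)
    log2fc = np.log2(
        (rpkm[test_sample].to_numpy() + FOLD_EPSILON)
        / (rpkm[reference_sample].to_numpy() + FOLD_EPSILON)
    )
    out = []
    for i, gid in enumerate(c.counts.index):
        out.append(
            DegRecord(
                gene_id=gid,
                reference_sample=reference_sample,
                test_sample=test_sample,
                log2fc=float(log2fc[i]),
                pvalue=float(p[i]),
                fdr=float(fdr[i]),
                is_deg=bool(fdr[i] <= max_fdr and abs(log2fc[i]) >= min_abs_log2fc),
            )
        )
    return out


def upregulated_filter(
    rpkm: pd.DataFrame, baseline_sample: str, min_fold: float = 1.5
) -> list[str]:
    """Genes up-regulated ≥ ``min_fold`` (inclusive) in any non-baseline sample."""
    if baseline_sample not in rpkm.columns:
        raise ValidationError(f"unknown sample {baseline_sample!r}")
    others = [s for s in rpkm.columns if s != baseline_sample]
    base = rpkm[baseline_sample] + FOLD_EPSILON
    fold = (rpkm[others].add(FOLD_EPSILON)).div(base, axis=0).max(axis=1)
    return sorted(fold.index[fold >= min_fold])


def cluster_expression(rpkm: pd.DataFrame, k: int = 6) -> dict[str, int]:
    """Cut an average-linkage tree over z-scored rows into ``k`` clusters.

    Rows are z-scored; constant rows have no z-score and are assigned the
    sentinel cluster 0.  Cluster labels 1..k are renumbered by first gene
    appearance, so the output is deterministic.
    """
    values = rpkm.to_numpy(dtype=float)
    sd = values.std(axis=1)
    variable = sd > 0
    n_var = int(variable.sum())
    if n_var < k:
        raise ValidationError(f"need ≥ {k} nonconstant rows, have {n_var}")
    z = (values[variable] - values[variable].mean(axis=1, keepdims=True)) / sd[
        variable, None
    ]
    labels = fcluster(linkage(z, method="average", metric="euclidean"), k, "maxclust")
    remap: dict[int, int] = {}
    out: dict[str, int] = {}
    var_genes = rpkm.index[variable]
    for gid, lab in zip(var_genes, labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[gid] = remap[lab]
    for gid in rpkm.index[~variable]:
        out[gid] = 0
    return out


@dataclass
class QpcrMeasurement:
    """2^−ΔΔCt relative expression with a delta-method standard error."""

    delta_delta_ct: float
    relative_expression: float
    se: float
    n_replicates: int = 3


def ddct(
    target_treated,
    reference_treated,
    target_control,
    reference_control,
) -> QpcrMeasurement:
    """2^−ΔΔCt from per-replicate Ct values of target and reference genes.

    ΔCt = mean(Ct_target − Ct_reference) per condition, ΔΔCt =
    ΔCt_treated − ΔCt_control, expression = 2^−ΔΔCt.  The SE combines the
    replicate SEs of both ΔCt means and is propagated to the expression
    scale (delta method).  Three replicates per condition are required.
    """
    arrays = [
        np.asarray(a, dtype=float)
        for a in (target_treated, reference_treated, target_control, reference_control)
    ]
    if any(a.size != 3 for a in arrays):
        raise ValidationError("need exactly 3 replicates per condition")
    if any(not np.isfinite(a).all() for a in arrays):
        raise ValidationError("Ct values must be finite")
    tt, rt, tc, rc = arrays
    dct_t = tt - rt
    dct_c = tc - rc
    ddct_val = float(dct_t.mean() - dct_c.mean())
    se_ddct = math.sqrt(dct_t.var(ddof=1) / 3 + dct_c.var(ddof=1) / 3)
    expr = 2.0 ** (-ddct_val)
    return QpcrMeasurement(
        delta_delta_ct=ddct_val,
        relative_expression=expr,
        se=math.log(2) * expr * se_ddct,
    )


@dataclass
class EnrichmentResult:
    term: str
    k_study: int
    n_study: int
    k_population: int
    n_population: int
    fold: float
    pvalue: float
    fdr: float = field(default=float("nan"))


def hypergeom_enrich(
    study_set, population, annotations: dict[str, list[str]]
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of annotation terms.

    For each term with K annotated genes in a population of N, a study
    set of n genes containing k of them scores p = P(X ≥ k),
    X ~ Hypergeom(N, K, n); BH across terms; fold = (k/n)/(K/N).
    """
    study = set(study_set)
    pop = set(population)
    if not study:
        raise ValidationError("empty study set")
    if not study <= pop:
        raise ValidationError("study set must be a subset of the population")
    terms: dict[str, set[str]] = {}
    for gene, term_list in annotations.items():
        if gene not in pop:
            continue
        for t in term_list:
            terms.setdefault(t, set()).add(gene)
    N, n = len(pop), len(study)
    results = []
    for t in sorted(terms):
        K = len(terms[t])
        k = len(terms[t] & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        results.append(EnrichmentResult(t, k, n, K, N, fold, min(p, 1.0)))
    if results:
        adj = bh_fdr([r.pvalue for r in results])
        for r, a in zip(results, adj):
            r.fdr = float(a)
    return results


# ---------------------------------------------------------------------------
# TSV I/O for count matrices and Ct tables


def write_counts_tsv(path, c: CountMatrix) -> None:
    """Write a counts TSV: gene_id, length_bp, one column per sample.

    Library sizes travel in a '# library_size:' comment line so the file
    is self-contained.
    """
    with open(path, "w") as fh:
        sizes = ",".join(
            f"{s}={c.library_size[s]:.0f}" for s in c.counts.columns
        )
        fh.write(f"# library_size: {sizes}\n")
        frame = c.counts.copy()
        frame.insert(0, "length_bp", c.gene_length_bp.astype(int))
        frame.insert(0, "gene_id", c.counts.index)
        frame.to_csv(fh, sep="\t", index=False)


def read_counts_tsv(path) -> CountMatrix:
    """Read a counts TSV written by :func:`write_counts_tsv`."""
    sizes: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# library_size:"):
                for part in line.split(":", 1)[1].strip().split(","):
                    k, v = part.split("=")
                    sizes[k.strip()] = float(v)
            if not line.startswith("#"):
                break
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame = frame.set_index("gene_id")
    lengths = frame.pop("length_bp")
    if not sizes:
        raise ValidationError(f"{path}: missing '# library_size:' header")
    return CountMatrix(
        counts=frame,
        gene_length_bp=lengths.astype(float),
        library_size=pd.Series(sizes).reindex(frame.columns),
    )


def read_ct_table(path) -> pd.DataFrame:
    """Read a qPCR Ct table: gene, condition, replicate, target_ct, reference_ct."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "condition", "replicate", "target_ct", "reference_ct"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return frame


def ddct_from_table(table: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Run 2^−ΔΔCt per gene × condition against a control condition."""
    if control_condition not in set(table["condition"]):
        raise ValidationError(f"control condition {control_condition!r} not in table")
    rows = []
    for gene, sub in table.groupby("gene"):
        ctl = sub[sub["condition"] == control_condition]
        if len(ctl) == 0:
            raise ValidationError(f"gene {gene!r}: no control replicates")
        for cond, grp in sub.groupby("condition"):
            if cond == control_condition:
                continue
            m = ddct(
                grp["target_ct"].to_numpy(),
                grp["reference_ct"].to_numpy(),
                ctl["target_ct"].to_numpy(),
                ctl["reference_ct"].to_numpy(),
            )
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "ddct": m.delta_delta_ct,
                    "relative_expression": m.relative_expression,
                    "se": m.se,
                }
            )
    return pd.DataFrame(rows)
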