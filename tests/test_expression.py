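import numpy as np
import pandas as pd
import pytest

from genefam.errors import ValidationError
from genefam.expression import (
    CountMatrix,
    ac_test,
    bh_fdr,
    call_degs,
    cluster_expression,
    compute_rpkm,
    ddct,
    hypergeom_enrich,
    upregulated_filter,
)
from oracles import ac_upper_tail


def _cm(counts, lengths, libsizes):
    frame = pd.DataFrame(counts)
    return CountMatrix(
        counts=frame,
        gene_length_bp=pd.Series(lengths, index=frame.index),
        library_size=pd.Series(libsizes, index=frame.columns),
    )


def test_rpkm_plugin_value():
    cm = _cm({"s": [200]}, [500], {"s": 2e6})
    assert compute_rpkm(cm).iloc[0, 0] == pytest.approx(200.0)


def test_rpkm_zero_count_and_column_scaling():
    cm = _cm({"a": [0, 100], "b": [0, 100]}, [500, 1000], {"a": 1e6, "b": 2e6})
    rpkm = compute_rpkm(cm)
    assert rpkm.loc[0, "a"] == 0.0
    assert rpkm.loc[1, "a"] == pytest.approx(2 * rpkm.loc[1, "b"])


def test_rpkm_rejects_zero_length():
    with pytest.raises(ValidationError):
        _cm({"s": [1]}, [0], {"s": 1e6})


def test_ac_equal_counts_equal_libraries_not_significant():
    assert ac_test(100, 100, 1e6, 1e6) == pytest.approx(1.0)


def test_ac_extreme_difference_is_tiny():
    assert ac_test(0, 50, 1e6, 1e6) < 1e-10


def test_ac_symmetric_under_swap():
    for x, y, n1, n2 in [(5, 9, 1e6, 2e6), (100, 130, 1e6, 1e6), (7, 2, 2e6, 1e6)]:
        assert ac_test(x, y, n1, n2) == pytest.approx(ac_test(y, x, n2, n1))


def test_ac_tails_match_direct_summation():
    for x, y, rho in [(10, 25, 1.0), (40, 20, 0.5), (3, 3, 2.0)]:
        expected = min(
            1.0,
            2
            * min(
                ac_upper_tail(y, x, rho),
                ac_upper_tail(x, y, 1 / rho),
            ),
        )
        assert ac_test(x, y, 1e6, rho * 1e6) == pytest.approx(expected, rel=1e-6)


def test_ac_rejects_bad_inputs():
    with pytest.raises(ValidationError):
        ac_test(-1, 3, 1e6, 1e6)
    with pytest.raises(ValidationError):
        ac_test(1, 3, 0, 1e6)


def test_bh_hand_example():
    assert bh_fdr([0.001, 0.01, 0.04]) == pytest.approx([0.003, 0.015, 0.04])


def test_bh_edge_cases():
    assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])
    p = np.array([0.2, 0.01, 0.8, 0.05])
    assert (bh_fdr(p) >= p).all()
    with pytest.raises(ValidationError):
        bh_fdr([0.5, 1.5])


def test_identical_columns_give_no_degs():
    counts = {"t0": [100, 50, 7], "t1": [100, 50, 7]}
    cm = _cm(counts, [500, 500, 500], {"t0": 1e6, "t1": 1e6})
    recs = call_degs(compute_rpkm(cm), cm, "t0", "t1")
    assert not any(r.is_deg for r in recs)


def test_deg_flag_matches_its_definition(small_config):
    from genefam.synthio import simulate_expression_counts

    cm, _ = simulate_expression_counts(small_config)
    rpkm = compute_rpkm(cm)
    for rec in call_degs(rpkm, cm, "0h", "3h"):
        assert rec.is_deg == (rec.fdr <= 0.001 and abs(rec.log2fc) >= 1.0)


def test_planted_degs_recovered_exactly(small_config):
    from genefam.synthio import simulate_expression_counts

    cm, truth = simulate_expression_counts(small_config)
    rpkm = compute_rpkm(cm)
    planted = {d.gene_id for d in truth.de_genes}
    called = set()
    for t in ("3h", "6h"):
        called |= {r.gene_id for r in call_degs(rpkm, cm, "0h", t) if r.is_deg}
    assert called == planted


def test_upregulated_filter_boundary_inclusive():
    rpkm = pd.DataFrame(
        {"t0": [2.0, 5.0, 1.0], "t1": [3.005, 5.0, 0.5]},
        index=["boundary", "flat", "down"],
    )
    # (3.005 + 0.01) / (2.0 + 0.01) == 1.5 exactly
    assert upregulated_filter(rpkm, "t0", min_fold=1.5) == ["boundary"]


def test_cluster_two_archetypes_perfectly_separated():
    rng = np.random.default_rng(0)
    up = np.array([1, 2, 8, 9, 1.5])
    down = up[::-1]
    rows = [up + rng.normal(0, 0.05, 5) for _ in range(10)]
    rows += [down + rng.normal(0, 0.05, 5) for _ in range(10)]
    rpkm = pd.DataFrame(rows, index=[f"g{i}" for i in range(20)])
    clusters = cluster_expression(rpkm, k=2)
    first = {clusters[f"g{i}"] for i in range(10)}
    second = {clusters[f"g{i}"] for i in range(10, 20)}
    assert len(first) == len(second) == 1
    assert first != second


def test_cluster_count_equal_to_genes_gives_singletons():
    rng = np.random.default_rng(1)
    rpkm = pd.DataFrame(rng.uniform(1, 10, (5, 4)), index=list("abcde"))
    clusters = cluster_expression(rpkm, k=5)
    assert sorted(clusters.values()) == [1, 2, 3, 4, 5]


def test_cluster_labels_invariant_to_column_affine_transform():
    rng = np.random.default_rng(2)
    rpkm = pd.DataFrame(rng.uniform(1, 10, (12, 5)))
    transformed = rpkm * 3.7 + 11.0
    assert cluster_expression(rpkm, k=3) == cluster_expression(transformed, k=3)


def test_constant_rows_go_to_sentinel_cluster():
    rng = np.random.default_rng(3)
    frame = pd.DataFrame(rng.uniform(1, 10, (8, 4)), index=[f"g{i}" for i in range(8)])
    frame.loc["flat"] = 2.0
    clusters = cluster_expression(frame, k=3)
    assert clusters["flat"] == 0


def test_ddct_null_gives_unit_expression():
    m = ddct([24, 24, 24], [20, 20, 20], [24, 24, 24], [20, 20, 20])
    assert m.relative_expression == pytest.approx(1.0)


def test_ddct_plugin_example():
    # treated 24 vs 20, control 26 vs 20: ddCt = -2 -> expression 4
    m = ddct([24, 24, 24], [20, 20, 20], [26, 26, 26], [20, 20, 20])
    assert m.delta_delta_ct == pytest.approx(-2.0)
    assert m.relative_expression == pytest.approx(4.0)


def test_ddct_invariant_to_global_ct_shift():
    rng = np.random.default_rng(4)
    tt, rt, tc, rc = (rng.uniform(18, 30, 3) for _ in range(4))
    base = ddct(tt, rt, tc, rc)
    shifted = ddct(tt + 3, rt + 3, tc + 3, rc + 3)
    assert shifted.relative_expression == pytest.approx(base.relative_expression)
    assert shifted.se == pytest.approx(base.se)


def test_ddct_requires_three_replicates():
    with pytest.raises(ValidationError):
        ddct([24, 24], [20, 20], [26, 26], [20, 20])


def test_enrich_private_term_minimum_p():
    import math

    population = [f"g{i}" for i in range(20)]
    study = population[:5]
    annotations = {g: ["T"] for g in study}
    (res,) = hypergeom_enrich(study, population, annotations)
    assert res.pvalue == pytest.approx(1 / math.comb(20, 5))


def test_enrich_absent_term_not_enriched():
    population = [f"g{i}" for i in range(20)]
    study = population[:5]
    annotations = {g: ["T"] for g in population[10:14]}
    (res,) = hypergeom_enrich(study, population, annotations)
    assert res.fold <= 1.0
    assert res.pvalue >= 0.5


def test_enrich_study_equals_population_fold_one():
    population = [f"g{i}" for i in range(10)]
    annotations = {g: ["A"] if int(g[1:]) % 2 else ["B"] for g in population}
    for res in hypergeom_enrich(population, population, annotations):
        assert res.fold == pytest.approx(1.0)


def test_enrich_requires_nonempty_study_subset():
    with pytest.raises(ValidationError):
        hypergeom_enrich([], ["g1"], {})
    with pytest.raises(ValidationError):
        hypergeom_enrich(["x"], ["g1"], {})
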