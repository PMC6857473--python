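"""BH adjustment, built-in DE test, thresholding, consensus, separation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fracseq.diffexpr import (
    DEResult,
    bh_adjust,
    builtin_de_test,
    consensus,
    threshold_method,
    validate_separation,
)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def test_bh_worked_example():
    # p*m/rank with the step-up minimum: all become 0.04
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_identity_and_zeros():
    np.testing.assert_allclose(bh_adjust([0.5]), [0.5])
    np.testing.assert_allclose(bh_adjust([0.0, 0.0, 0.0]), [0.0] * 3)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
def test_bh_dominates_input_and_is_permutation_equivariant(pvals):
    adj = bh_adjust(pvals)
    assert np.all(adj >= np.asarray(pvals) - 1e-12)
    assert np.all(adj <= 1.0 + 1e-12)
    perm = np.random.default_rng(0).permutation(len(pvals))
    adj_perm = bh_adjust(np.asarray(pvals)[perm])
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    np.testing.assert_allclose(adj_perm[inv], adj)


# ---------------------------------------------------------------------------
# built-in DE test


def test_builtin_de_identical_matrices_gives_zero_lfc():
    rng = np.random.default_rng(1)
    m = pd.DataFrame(rng.poisson(50, size=(20, 4)).astype(float))
    res = builtin_de_test(m, m.copy())
    assert all(r.log2_fold_change == 0 for r in res)


def test_builtin_de_exact_mwu_for_separated_groups():
    """Fully separated 4v4 groups: exact two-sided MWU p = 2/70 = 0.0286."""
    tumor = pd.DataFrame([[100, 110, 90, 105]], index=["t"], dtype=float)
    adjacent = pd.DataFrame([[10, 9, 11, 10]], index=["t"], dtype=float)
    # equal library sizes so scaling is a no-op
    tumor.loc["filler"] = [100, 100, 120, 105]
    adjacent.loc["filler"] = [190, 201, 199, 200]
    res = {r.transcript_id: r for r in builtin_de_test(tumor, adjacent)}
    assert res["t"].log2_fold_change > 3
    assert res["t"].p_value == pytest.approx(2 / 70, rel=1e-9)


def test_builtin_de_requires_two_samples():
    m = pd.DataFrame([[1.0]], index=["t"])
    with pytest.raises(ValueError):
        builtin_de_test(m, m)


def test_builtin_de_null_calibration():
    """i.i.d. null counts: fraction of raw p < 0.05 within 0.05 +/- 0.02."""
    rng = np.random.default_rng(7)
    shape = (2000, 8)
    r, mu = 20.0, 100.0
    make = lambda: pd.DataFrame(
        rng.negative_binomial(r, r / (r + mu), size=shape).astype(float)
    )
    res = builtin_de_test(make(), make())
    frac = np.mean([x.p_value < 0.05 for x in res])
    assert 0.03 <= frac <= 0.07


# ---------------------------------------------------------------------------
# thresholding and consensus


def _r(tid, lfc, padj=None, ppde=None):
    return DEResult(tid, "m", lfc, adjusted_p=padj, ppde=ppde)


def test_threshold_rules_and_boundaries():
    res = [
        _r("a", 1.5, padj=0.005),
        _r("b", 1.0, padj=0.001),  # |lfc| not strictly > 1
        _r("c", -2.0, padj=0.5),
        _r("d", 2.0, padj=0.01),  # padj not strictly < 0.01
    ]
    assert threshold_method(res, "fdr") == {("a", "up_in_tumor")}
    ppde_res = [_r("e", -2.0, ppde=0.995), _r("f", -2.0, ppde=0.99)]
    assert threshold_method(ppde_res, "ppde") == {("e", "down_in_tumor")}


def test_threshold_missing_field_errors():
    with pytest.raises(ValueError, match="m"):
        threshold_method([_r("a", 2.0, ppde=0.999)], "fdr")


def test_threshold_sanity_bound():
    res = [_r("a", 0.5, padj=0.2), _r("b", -0.1, padj=0.9), _r("z", 0.0, padj=0.0)]
    out = threshold_method(res, "fdr", lfc_cutoff=0.0, alpha=1.0)
    assert {t for t, _ in out} == {"a", "b"}  # all nonzero fold changes


def test_consensus_intersection_rules():
    up = ("t1", "up_in_tumor")
    dn = ("t1", "down_in_tumor")
    other = ("t2", "up_in_tumor")
    same = [{up, other}, {up, other}]
    assert {c.transcript_id for c in consensus(same)} == {"t1", "t2"}
    # absent from the third method -> excluded
    assert {c.transcript_id for c in consensus([{up, other}, {up, other}, {other}])} == {"t2"}
    # conflicting directions -> excluded
    assert consensus([{up}, {dn}]) == []
    # order independence
    sets = [{up, other}, {other}, {up, other}]
    for rotated in (sets, sets[::-1], [sets[1], sets[2], sets[0]]):
        assert {c.transcript_id for c in consensus(rotated)} == {"t2"}
    with pytest.raises(ValueError):
        consensus([{up}])


def test_consensus_is_subset_of_each_method(small_study):
    """Pipeline property: consensus calls appear in every method's set."""
    from fracseq.diffexpr import read_de_table

    study = small_study
    builtin = builtin_de_test(study.cohort.counts_tumor, study.cohort.counts_adjacent)
    sets = [threshold_method(builtin, "fdr")]
    for name, table in study.cohort.method_tables.items():
        rule = "ppde" if table["ppde"].notna().any() else "fdr"
        results = [
            DEResult(
                row.transcript_id,
                name,
                row.log2fc,
                adjusted_p=None if pd.isna(row.padj) else row.padj,
                ppde=None if pd.isna(row.ppde) else row.ppde,
            )
            for row in table.itertuples()
        ]
        sets.append(threshold_method(results, rule))
    calls = consensus(sets)
    call_pairs = {(c.transcript_id, c.direction) for c in calls}
    for s in sets:
        assert call_pairs <= s
    # recall of planted DE transcripts
    genes = study.truth.genes
    planted = {
        study.truth.transcript_of_gene[g] for g in genes.index[genes["true_de"] != "none"]
    }
    recovered = {c.transcript_id for c in calls}
    assert len(recovered & planted) / len(planted) >= 0.9


# ---------------------------------------------------------------------------
# separation validation


def _block_expression(rng, n_up, n_down, n_per_group):
    """Dysregulated-style matrix: some features high in tumor, some low."""
    up_t = rng.lognormal(5, 0.2, size=(n_up, n_per_group))
    up_n = rng.lognormal(1, 0.2, size=(n_up, n_per_group))
    dn_t = rng.lognormal(1, 0.2, size=(n_down, n_per_group))
    dn_n = rng.lognormal(5, 0.2, size=(n_down, n_per_group))
    mat = np.vstack([np.hstack([up_t, up_n]), np.hstack([dn_t, dn_n])])
    cols = [f"t{i}" for i in range(n_per_group)] + [f"n{i}" for i in range(n_per_group)]
    return pd.DataFrame(mat, columns=cols)


def test_validate_separation_block_matrix():
    rng = np.random.default_rng(5)
    expr = _block_expression(rng, n_up=6, n_down=6, n_per_group=20)
    status = {c: ("tumor" if c.startswith("t") else "nontumor") for c in expr.columns}
    assignment, chi2, p = validate_separation(expr, status)
    assert p < 1e-6
    # clusters coincide with status; chi-square for [[20,0],[0,20]] is 40
    assert chi2 == pytest.approx(40.0)
    assert assignment.groupby(pd.Series(status)).nunique().max() == 1


def test_validate_separation_chi_square_closed_form():
    """Perfect 10+10 split gives the closed-form chi-square of [[10,0],[0,10]]."""
    rng = np.random.default_rng(8)
    expr = _block_expression(rng, n_up=3, n_down=3, n_per_group=10)
    status = {c: ("tumor" if c.startswith("t") else "nontumor") for c in expr.columns}
    _, chi2, _ = validate_separation(expr, status)
    assert chi2 == pytest.approx(20.0)


def test_validate_separation_zero_variance_dropped():
    rng = np.random.default_rng(9)
    expr = pd.DataFrame(rng.lognormal(2, 1, size=(3, 8)))
    expr.loc[3] = 7.0  # constant feature: dropped, not fatal
    status = {c: ("tumor" if c < 4 else "nontumor") for c in expr.columns}
    validate_separation(expr, status)
    with pytest.raises(ValueError):
        validate_separation(pd.DataFrame(5.0, index=[0, 1], columns=expr.columns), status)
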