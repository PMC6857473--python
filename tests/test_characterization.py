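"""Promoter marks, embryo expression calls, Kaplan-Meier/log-rank screening,
and the combined candidate report."""

import numpy as np
import pandas as pd
import pytest

from fracseq.characterization import (
    EXPRESSED,
    LINEAGE_SPECIFIC,
    NOT_EXPRESSED,
    PeakSet,
    build_report,
    embryo_expression_call,
    km_logrank,
    promoter_mark_hits,
    survival_screen,
)

from conftest import make_tx


# ---------------------------------------------------------------------------
# promoter marks


def _peakset(eid, category, *peaks):
    return PeakSet(eid, category, tuple(("chr1", s, e) for s, e in peaks))


def test_promoter_hit_within_window():
    t = make_tx("t", [(10000, 10200), (10400, 10600)], "+")  # tss 10000
    sets = [_peakset("E1", "ESC", (10500, 10600))]
    assert promoter_mark_hits(t, sets)["ESC"] == 1


def test_promoter_boundaries_inclusive_window():
    t = make_tx("t", [(10000, 10200), (10400, 10600)], "+")  # tss 10000
    # last covered base 10000-1001: outside the inclusive +/-1000 window
    outside = [_peakset("E1", "ESC", (8000, 10000 - 1000))]
    assert promoter_mark_hits(t, outside)["ESC"] == 0
    # last covered base exactly tss-1000: inside
    edge = [_peakset("E1", "ESC", (8000, 10000 - 999))]
    assert promoter_mark_hits(t, edge)["ESC"] == 1


def test_promoter_minus_strand_tss_is_rightmost():
    t = make_tx("t", [(5100, 5200), (5300, 5400)], "-")  # tss 5400
    far = [_peakset("E1", "iPSC", (6500, 6700))]  # beyond tss+1000
    near = [_peakset("E1", "iPSC", (5900, 6000))]
    assert promoter_mark_hits(t, far)["iPSC"] == 0
    assert promoter_mark_hits(t, near)["iPSC"] == 1


def test_promoter_unknown_strand_errors():
    t = make_tx("t", [(100, 200), (300, 400)], ".")
    with pytest.raises(ValueError):
        promoter_mark_hits(t, [])


def test_promoter_monotone_in_window():
    rng = np.random.default_rng(3)
    t = make_tx("t", [(50000, 50200), (50400, 50600)], "+")
    sets = [
        _peakset(f"E{i}", "ESC", (int(p), int(p) + 150))
        for i, p in enumerate(rng.integers(45000, 56000, size=20))
    ]
    counts = [promoter_mark_hits(t, sets, window=w)["ESC"] for w in (100, 500, 1000, 3000)]
    assert counts == sorted(counts)


def test_promoter_counts_per_category(small_study):
    """Planted candidates carry peaks in every stem-cell epigenome."""
    study = small_study
    for g in study.truth.candidates:
        t = study.assembled[study.truth.transcript_of_gene[g]]
        counts = promoter_mark_hits(t, study.peak_sets)
        assert counts["ESC"] == 8
        assert counts["ESC_derived"] == 9
        assert counts["iPSC"] == 5


# ---------------------------------------------------------------------------
# embryo expression


def _embryo_frame(rows):
    return pd.DataFrame(rows, columns=["stage", "embryo_id", "cell_id", "g"])


def test_embryo_expressed_needs_two_embryos():
    rows = []
    for e, expr in (("E1", 5.0), ("E2", 3.0), ("E3", 0.0)):
        for c in range(4):
            rows.append(("8cell", e, f"{e}c{c}", expr if c == 0 else 0.0))
    calls = embryo_expression_call("g", _embryo_frame(rows))
    assert calls["8cell"].expressed
    # only one expressing embryo -> not expressed
    rows2 = [r if r[1] == "E1" else (r[0], r[1], r[2], 0.0) for r in rows]
    calls2 = embryo_expression_call("g", _embryo_frame(rows2))
    assert not calls2["8cell"].expressed
    assert calls2["8cell"].label == NOT_EXPRESSED


def test_embryo_lineage_specific_minority():
    # 3 of 10 cells expressing: >=2 cells and 0.3 < 0.67 -> lineage specific
    rows = [
        ("4cell", "E1", f"c{c}", 5.0 if c < 3 else 0.0) for c in range(10)
    ] + [("4cell", "E2", f"d{c}", 5.0 if c < 3 else 0.0) for c in range(10)]
    calls = embryo_expression_call("g", _embryo_frame(rows))
    assert calls["4cell"].lineage_specific
    assert calls["4cell"].label == LINEAGE_SPECIFIC


def test_embryo_all_cells_expressing_not_lineage_specific():
    rows = [("morula", e, f"{e}c{c}", 5.0) for e in ("E1", "E2") for c in range(3)]
    calls = embryo_expression_call("g", _embryo_frame(rows))
    assert calls["morula"].expressed
    assert not calls["morula"].lineage_specific
    assert calls["morula"].label == EXPRESSED


def test_embryo_single_embryo_stage_non_evaluable():
    rows = [("zygote", "E1", f"c{c}", 5.0) for c in range(4)]
    calls = embryo_expression_call("g", _embryo_frame(rows))
    assert not calls["zygote"].evaluable
    assert calls["zygote"].label == "non_evaluable"


def test_embryo_lineage_implies_two_expressing_cells(small_study):
    """Every lineage-specific call is backed by >=2 expressing cells in some
    embryo of that stage."""
    study = small_study
    embryo = study.embryo
    for g in study.truth.candidates:
        calls = embryo_expression_call(g, embryo)
        for stage, call in calls.items():
            if call.lineage_specific:
                stage_df = embryo[embryo["stage"] == stage]
                per_embryo = (stage_df[g] > 1).groupby(stage_df["embryo_id"]).sum()
                assert (per_embryo >= 2).any()


def test_embryo_onset_stage_respected(small_study):
    study = small_study
    onset = study.cfg.lineage_onset_stage
    stages = ("oocyte", "zygote", "2cell", "4cell", "8cell", "morula", "late_blastocyst")
    onset_i = stages.index(onset)
    g = study.truth.candidates[0]
    calls = embryo_expression_call(g, study.embryo)
    for i, stage in enumerate(stages):
        if i < onset_i:
            assert calls[stage].label == NOT_EXPRESSED
        else:
            assert calls[stage].lineage_specific


# ---------------------------------------------------------------------------
# survival


def test_logrank_identical_groups_is_null():
    times = [30.0, 60, 90, 120, 150] * 2
    surv = pd.DataFrame(
        {
            "time": times,
            "event": [1] * 10,
            "g": [0.0] * 5 + [10.0] * 5,  # median split separates the two copies
        }
    )
    res = km_logrank(surv, "g")
    assert res.statistic == pytest.approx(0.0, abs=1e-9)
    assert res.p_value == pytest.approx(1.0)
    assert (res.n_low, res.n_high) == (5, 5)


def _hand_logrank(times_a, times_b):
    """Independent O/E/V tabulation over distinct event times (no censoring)."""
    stat_o_minus_e = 0.0
    var = 0.0
    all_times = sorted(set(times_a) | set(times_b))
    for t in all_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = times_a.count(t)
        d_b = times_b.count(t)
        n, d = n_a + n_b, d_a + d_b
        e_a = d * n_a / n
        stat_o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    chi2 = stat_o_minus_e**2 / var
    return chi2


def test_logrank_matches_hand_tabulation():
    times_a = [1.0, 2.0, 3.0]
    times_b = [10.0, 20.0, 30.0]
    surv = pd.DataFrame(
        {
            "time": times_a + times_b,
            "event": [1] * 6,
            "g": [0.0] * 3 + [10.0] * 3,
        }
    )
    res = km_logrank(surv, "g")
    expected_chi2 = _hand_logrank(times_a, times_b)
    assert res.statistic == pytest.approx(expected_chi2, rel=1e-9)
    from scipy.stats import chi2 as chi2_dist

    assert res.p_value == pytest.approx(chi2_dist.sf(expected_chi2, 1), rel=1e-9)


def test_km_curve_equals_empirical_survival_without_censoring():
    rng = np.random.default_rng(17)
    times = rng.exponential(100, size=30).round(2)
    surv = pd.DataFrame(
        {
            "time": np.concatenate([times, times + 1]),
            "event": [1] * 60,
            "g": [0.0] * 30 + [10.0] * 30,
        }
    )
    res = km_logrank(surv, "g")
    km = res.km_low
    assert km.iloc[0] == pytest.approx(1.0)
    assert (np.diff(km.to_numpy()) <= 1e-12).all()  # non-increasing
    for t in times:
        empirical = (times > t).mean()
        assert km.loc[t] == pytest.approx(empirical, abs=1e-12)


def test_logrank_validation_errors():
    surv = pd.DataFrame({"time": [1.0, 2, 3, 4], "event": [1, 1, 1, 1], "g": [1.0] * 4})
    with pytest.raises(ValueError, match="zero-variance"):
        km_logrank(surv, "g")
    surv2 = pd.DataFrame(
        {"time": [1.0, 2, 3, 4], "event": [0, 0, 0, 0], "g": [1.0, 2, 3, 4]}
    )
    with pytest.raises(ValueError, match="events"):
        km_logrank(surv2, "g")


def test_planted_hazard_gene_detected_nulls_calibrated(small_study):
    """The planted prognostic genes screen significant; null genes do not."""
    surv = small_study.cohort.survival
    genes = small_study.truth.genes
    prognostic = sorted(genes.index[genes["prognostic"]])
    nulls = [c for c in surv.columns if c.startswith("NULLSURV")]
    screen = survival_screen(surv, prognostic + nulls)
    assert (screen.loc[prognostic, "logrank_p"] < 0.05).all()
    assert 0.1 <= screen.loc[nulls, "logrank_p"].median() <= 0.9


# ---------------------------------------------------------------------------
# report


def test_build_report_not_expressed_boundary():
    fpkm = pd.DataFrame(
        {
            "g_hi": [1.0] * 8,
            "g_4low": [0.1] * 4 + [1.0] * 4,  # < 0.5 in 4 lines: not flagged
            "g_5low": [0.1] * 5 + [1.0] * 3,  # < 0.5 in 5 lines: flagged
        }
    ).T
    status = {g: "nuclear_enriched" for g in fpkm.index}
    reports = {r.gene_id: r for r in build_report(fpkm.index, status, fpkm)}
    assert not reports["g_4low"].not_expressed_flag
    assert reports["g_5low"].not_expressed_flag
    assert not reports["g_hi"].not_expressed_flag


def test_build_report_missing_enrichment_errors():
    fpkm = pd.DataFrame({"g": [1.0] * 8}).T
    with pytest.raises(ValueError):
        build_report(["g"], {}, fpkm)


def test_build_report_empty_candidates():
    fpkm = pd.DataFrame({"g": [1.0] * 8}).T
    assert build_report([], {}, fpkm) == []


def test_build_report_rows_sorted_and_survival_flagged():
    from fracseq.characterization import report_to_frame

    fpkm = pd.DataFrame({"b": [1.0] * 8, "a": [1.0] * 8}).T
    status = {"a": "nuclear_enriched", "b": "non_fraction_specific"}
    reports = build_report(["b", "a"], status, fpkm, survival_p={"a": 0.01, "b": 0.2})
    assert [r.gene_id for r in reports] == ["a", "b"]
    frame = report_to_frame(reports, alpha=0.05)
    assert bool(frame.loc["a", "survival_significant"])
    assert not frame.loc["b", "survival_significant"]
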