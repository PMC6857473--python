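"""Differential expression: per-method thresholding, a built-in nonparametric
test, consensus intersection, and clustering validation of the dysregulated set.

The model-based DE methods the field uses (negative-binomial GLMs,
empirical-Bayes posteriors) are consumed here as result tables; the built-in
method is a Mann-Whitney U test on library-size-scaled counts so the pipeline
can run standalone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

UP = "up_in_tumor"
DOWN = "down_in_tumor"


@dataclass(frozen=True)
class DEResult:
    transcript_id: str
    method: str
    log2_fold_change: float
    p_value: Optional[float] = None
    adjusted_p: Optional[float] = None
    ppde: Optional[float] = None

    def __post_init__(self):
        if not np.isfinite(self.log2_fold_change):
            raise ValueError(f"{self.transcript_id}: non-finite log2 fold change")


@dataclass(frozen=True)
class ConsensusDECall:
    transcript_id: str
    direction: str
    per_method_log2fc: Mapping[str, float]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def builtin_de_test(
    counts_tumor: pd.DataFrame,
    counts_adjacent: pd.DataFrame,
    *,
    pseudocount: float = 0.5,
    method_name: str = "builtin_mwu",
) -> list[DEResult]:
    """Nonparametric per-transcript DE test (tumor vs adjacent).

    Counts are scaled to a common library size (total-count ratio), the
    log2 fold change uses a pseudocount on condition means, and the p-value
    is a two-sided Mann-Whitney U (exact for small tie-free samples,
    tie-corrected normal approximation otherwise), BH-adjusted across
    transcripts.
    """
    if counts_tumor.shape[1] < 2 or counts_adjacent.shape[1] < 2:
        raise ValueError("builtin_de_test requires >=2 samples per condition")
    if not counts_tumor.index.equals(counts_adjacent.index):
        raise ValueError("tumor and adjacent matrices must share a transcript index")

    def scale(df: pd.DataFrame, target: float) -> pd.DataFrame:
        totals = df.sum(axis=0)
        return df * (target / totals)

    target = float(pd.concat([counts_tumor.sum(0), counts_adjacent.sum(0)]).mean())
    st = scale(counts_tumor, target)
    sa = scale(counts_adjacent, target)

    lfc = np.log2((st.mean(axis=1) + pseudocount) / (sa.mean(axis=1) + pseudocount))
    xt, xa = st.to_numpy(), sa.to_numpy()
    pvals = np.ones(xt.shape[0])
    for i in range(xt.shape[0]):
        row = np.concatenate([xt[i], xa[i]])
        if np.all(row == row[0]):
            continue  # constant transcript: no evidence either way
        pvals[i] = stats.mannwhitneyu(
            xt[i], xa[i], alternative="two-sided", method="auto"
        ).pvalue
    padj = bh_adjust(pvals)
    return [
        DEResult(tid, method_name, float(lfc.iloc[i]), float(pvals[i]), float(padj[i]))
        for i, tid in enumerate(counts_tumor.index)
    ]


def threshold_method(
    results: Iterable[DEResult],
    rule: str,
    *,
    lfc_cutoff: float = 1.0,
    alpha: float = 0.01,
    ppde_cutoff: float = 0.99,
) -> set[tuple[str, str]]:
    """Significant (transcript_id, direction) pairs under a thresholding rule.

    rule "fdr": |log2FC| > lfc_cutoff and adjusted_p < alpha.
    rule "ppde": |log2FC| > lfc_cutoff and ppde > ppde_cutoff.
    All inequalities strict.
    """
    if rule not in ("fdr", "ppde"):
        raise ValueError(f"unknown thresholding rule {rule!r}")
    out = set()
    for r in results:
        if rule == "fdr":
            if r.adjusted_p is None:
                raise ValueError(f"method {r.method!r}: adjusted_p required for fdr rule")
            significant = abs(r.log2_fold_change) > lfc_cutoff and r.adjusted_p < alpha
        else:
            if r.ppde is None:
                raise ValueError(f"method {r.method!r}: ppde required for ppde rule")
            significant = abs(r.log2_fold_change) > lfc_cutoff and r.ppde > ppde_cutoff
        if significant and r.log2_fold_change != 0:
            out.add((r.transcript_id, UP if r.log2_fold_change > 0 else DOWN))
    return out


def consensus(
    calls: Sequence[set[tuple[str, str]]],
    per_method_lfc: Optional[Sequence[Mapping[str, float]]] = None,
) -> list[ConsensusDECall]:
    """Direction-consistent intersection of >=2 per-method call sets.

    A transcript is a consensus call when every method calls it significant
    with the same direction; transcripts significant everywhere but with
    conflicting directions are excluded and logged.
    """
    if len(calls) < 2:
        raise ValueError("consensus requires at least two method call sets")
    as_maps = []
    for callset in calls:
        m: dict[str, set[str]] = {}
        for tid, direction in callset:
            m.setdefault(tid, set()).add(direction)
        as_maps.append(m)
    common = set(as_maps[0])
    for m in as_maps[1:]:
        common &= set(m)
    out = []
    for tid in sorted(common):
        directions = set().union(*(m[tid] for m in as_maps))
        if len(directions) != 1:
            logger.info("transcript %s excluded from consensus: conflicting directions", tid)
            continue
        lfcs = {}
        if per_method_lfc is not None:
            for i, table in enumerate(per_method_lfc):
                if tid in table:
                    lfcs[f"method_{i}"] = table[tid]
        out.append(ConsensusDECall(tid, directions.pop(), lfcs))
    return out


def validate_separation(
    expr: pd.DataFrame,
    sample_status: Mapping[str, str],
) -> tuple[pd.Series, float, float]:
    """Cluster samples on dysregulated-feature expression and test the split.

    Rows of ``expr`` (features x samples, TPM) are log2(TPM+1)-transformed
    and standardized; samples are clustered by average linkage on
    1 - Pearson correlation and cut into two clusters; a chi-square test of
    independence (1 df, no continuity correction) is applied to the
    2x2 cluster-by-status table.

    Returns (cluster assignment per sample, chi-square statistic, p-value).
    """
    statuses = pd.Series({s: sample_status[s] for s in expr.columns})
    if statuses.nunique() != 2:
        raise ValueError("sample_status must contain exactly two groups")
    if statuses.value_counts().min() < 2:
        raise ValueError("need >=2 samples per status group")
    if expr.shape[0] < 2:
        raise ValueError("need >=2 features")

    x = np.log2(expr.to_numpy(dtype=float) + 1.0)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("validate_separation: dropped %d zero-variance features", dropped)
    if not keep.any():
        raise ValueError("all features have zero variance")
    x = x[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=0, keepdims=True)

    corr = np.corrcoef(z.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = linkage(squareform(dist, checks=False), method="average")
    clusters = fcluster(link, t=2, criterion="maxclust")
    assignment = pd.Series(clusters, index=expr.columns, name="cluster")

    table = pd.crosstab(assignment, statuses)
    if table.shape != (2, 2):
        # degenerate cut: all samples in one cluster
        return assignment, 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return assignment, float(chi2), float(p)


def read_de_table(path, method: Optional[str] = None) -> list[DEResult]:
    """Read a per-method DE result TSV.

    Columns: transcript_id, method, log2fc, pvalue, padj, ppde (empty fields
    allowed for the statistics a method does not produce).
    """
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        def opt(col):
            v = row.get(col)
            return None if v is None or pd.isna(v) else float(v)

        out.append(
            DEResult(
                transcript_id=str(row["transcript_id"]),
                method=method or str(row["method"]),
                log2_fold_change=float(row["log2fc"]),
                p_value=opt("pvalue"),
                adjusted_p=opt("padj"),
                ppde=opt("ppde"),
            )
        )
    return out


def write_de_table(results: Iterable[DEResult], path) -> None:
    rows = [
        {
            "transcript_id": r.transcript_id,
            "method": r.method,
            "log2fc": r.log2_fold_change,
            "pvalue": r.p_value,
            "padj": r.adjusted_p,
            "ppde": r.ppde,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
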