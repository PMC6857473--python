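"""Candidate lncRNA characterization: active-promoter marks, preimplantation
embryo expression, survival screening, and the combined per-candidate report.

Promoter association asks whether an H3K4me3 peak lies within +/-1000 bp of a
transcript's 5' end, counted per epigenome category (ESC, ESC-derived, iPSC,
cancer). Embryo expression is called per preimplantation stage from
single-cell TPM: expressed when >=2 embryos at the stage have an expressing
cell, lineage-specific when some embryo has >=2 expressing cells covering
<67% of its cells. Survival screening is a median-split Kaplan-Meier /
log-rank test per candidate gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .catalog import TranscriptModel
from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

EPIGENOME_CATEGORIES = ("ESC", "ESC_derived", "iPSC", "cancer")

STAGES = ("oocyte", "zygote", "2cell", "4cell", "8cell", "morula", "late_blastocyst")

EXPRESSED = "expressed"
LINEAGE_SPECIFIC = "lineage_specific"
NOT_EXPRESSED = "not_expressed"
NON_EVALUABLE = "non_evaluable"


@dataclass(frozen=True)
class PeakSet:
    """H3K4me3 peak intervals of one epigenome."""

    epigenome_id: str
    category: str
    peaks: tuple[tuple[str, int, int], ...]  # (chrom, start, end), 0-based half-open

    def __post_init__(self):
        if self.category not in EPIGENOME_CATEGORIES:
            raise ValueError(f"unknown epigenome category {self.category!r}")
        for chrom, start, end in self.peaks:
            if start >= end:
                raise ValueError(f"invalid peak [{start},{end}) on {chrom}")


def read_peak_bed(path, epigenome_id: str, category: str) -> PeakSet:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            peaks.append((fields[0], int(fields[1]), int(fields[2])))
    return PeakSet(epigenome_id, category, tuple(peaks))


def promoter_mark_hits(
    t: TranscriptModel,
    peak_sets: Iterable[PeakSet],
    window: int = 1000,
) -> dict[str, int]:
    """Per-category count of epigenomes with a peak near the transcript's TSS.

    The promoter window is [tss - window, tss + window], inclusive of both
    endpoints and clipped at 0; an epigenome counts when >=1 of its peaks
    shares >=1 base with the window.
    """
    tss = t.tss  # raises for unknown strand
    win_lo = max(0, tss - window)
    win_hi = tss + window  # inclusive position
    counts = {cat: 0 for cat in EPIGENOME_CATEGORIES}
    for ps in peak_sets:
        hit = any(
            chrom == t.chrom and start <= win_hi and end - 1 >= win_lo
            for chrom, start, end in ps.peaks
        )
        if hit:
            counts[ps.category] += 1
    return counts


@dataclass(frozen=True)
class StageCall:
    stage: str
    expressed: bool
    lineage_specific: bool
    evaluable: bool

    @property
    def label(self) -> str:
        if not self.evaluable:
            return NON_EVALUABLE
        if self.lineage_specific:
            return LINEAGE_SPECIFIC
        if self.expressed:
            return EXPRESSED
        return NOT_EXPRESSED


def embryo_expression_call(
    gene_id: str,
    embryo_tpm: pd.DataFrame,
    *,
    tpm_threshold: float = 1.0,
    min_embryos: int = 2,
    min_cells: int = 2,
    max_fraction: float = 0.67,
) -> dict[str, StageCall]:
    """Per-stage expression call for one gene from single-cell embryo TPM.

    ``embryo_tpm`` is tidy: one row per cell with columns stage, embryo_id,
    cell_id and one column per gene. Per stage (evaluable when it has >=
    ``min_embryos`` embryos): expressed iff >= ``min_embryos`` embryos contain
    >=1 cell with TPM > ``tpm_threshold``; lineage_specific iff some embryo
    has >= ``min_cells`` expressing cells and its expressing fraction is
    < ``max_fraction``.
    """
    if gene_id not in embryo_tpm.columns:
        raise KeyError(f"gene {gene_id!r} absent from embryo expression table")
    out = {}
    for stage, stage_df in embryo_tpm.groupby("stage", sort=False):
        expressing = stage_df[gene_id] > tpm_threshold
        per_embryo = stage_df.assign(_x=expressing).groupby("embryo_id")["_x"]
        n_embryos = per_embryo.ngroups
        if n_embryos < min_embryos:
            out[str(stage)] = StageCall(str(stage), False, False, evaluable=False)
            continue
        n_expressing_embryos = int((per_embryo.sum() >= 1).sum())
        expressed = n_expressing_embryos >= min_embryos
        lineage = bool(
            ((per_embryo.sum() >= min_cells) & (per_embryo.mean() < max_fraction)).any()
        )
        out[str(stage)] = StageCall(str(stage), expressed, lineage, evaluable=True)
    return out


@dataclass(frozen=True)
class SurvivalResult:
    gene_id: str
    p_value: float
    statistic: float
    n_low: int
    n_high: int
    km_low: pd.Series
    km_high: pd.Series


def km_logrank(
    survival: pd.DataFrame,
    gene_id: str,
    split: str = "median",
) -> SurvivalResult:
    """Median-split Kaplan-Meier curves and two-group log-rank test.

    ``survival`` has columns time (>0), event (1=death observed, 0=censored)
    and one column per gene; patients at or below the median expression form
    the low group. The log-rank statistic is (sum(O-E))^2 / sum(V) with p
    from chi-square, 1 df.
    """
    if split != "median":
        raise ValueError(f"unsupported split {split!r}")
    for col in ("time", "event"):
        if col not in survival.columns:
            raise ValueError(f"survival table missing {col!r} column")
    if gene_id not in survival.columns:
        raise KeyError(f"gene {gene_id!r} absent from survival table")
    expr = survival[gene_id].astype(float)
    if expr.nunique() < 2:
        raise ValueError(f"gene {gene_id!r}: zero-variance expression, split impossible")
    if int(survival["event"].sum()) < 1:
        raise ValueError("no observed events in survival table")
    median = float(expr.median())
    low = expr <= median  # ties to the low group
    if low.sum() < 2 or (~low).sum() < 2:
        raise ValueError(f"gene {gene_id!r}: fewer than 2 patients in a split group")

    t, e = survival["time"].astype(float), survival["event"].astype(int)
    res = logrank_test(t[low], t[~low], event_observed_A=e[low], event_observed_B=e[~low])

    def km(mask) -> pd.Series:
        fitter = KaplanMeierFitter()
        fitter.fit(t[mask], event_observed=e[mask])
        return fitter.survival_function_.iloc[:, 0]

    return SurvivalResult(
        gene_id=gene_id,
        p_value=float(res.p_value),
        statistic=float(res.test_statistic),
        n_low=int(low.sum()),
        n_high=int((~low).sum()),
        km_low=km(low),
        km_high=km(~low),
    )


def survival_screen(
    survival: pd.DataFrame, genes: Sequence[str]
) -> pd.DataFrame:
    """km_logrank over many genes; raw and BH-adjusted p-values."""
    rows = []
    for g in genes:
        r = km_logrank(survival, g)
        rows.append({"gene_id": g, "logrank_p": r.p_value, "statistic": r.statistic})
    df = pd.DataFrame(rows).set_index("gene_id")
    df["logrank_p_adj"] = bh_adjust(df["logrank_p"].to_numpy())
    return df


@dataclass(frozen=True)
class CandidateReport:
    gene_id: str
    enrichment_status: Optional[str]
    promoter_mark_counts: Mapping[str, int]
    stage_expression: Mapping[str, str]
    survival_p: Optional[float]
    not_expressed_flag: bool


def build_report(
    candidates: Iterable[str],
    enrichment_status: Mapping[str, str],
    cellline_fpkm: pd.DataFrame,
    *,
    promoter_counts: Optional[Mapping[str, Mapping[str, int]]] = None,
    stage_calls: Optional[Mapping[str, Mapping[str, StageCall]]] = None,
    survival_p: Optional[Mapping[str, float]] = None,
    fpkm_floor: float = 0.5,
    min_low_lines: int = 5,
) -> list[CandidateReport]:
    """Merge all characterization evidence into one row per candidate gene.

    The not-expressed flag is set when the gene's FPKM is below ``fpkm_floor``
    in at least ``min_low_lines`` cell lines. Rows are ordered by gene_id;
    missing characterization fields are allowed, a missing enrichment call is
    an error.
    """
    out = []
    for gene in sorted(set(candidates)):
        if gene not in enrichment_status:
            raise ValueError(f"candidate {gene!r} has no enrichment call")
        if gene in cellline_fpkm.index:
            n_low = int((cellline_fpkm.loc[gene] < fpkm_floor).sum())
        else:
            n_low = cellline_fpkm.shape[1]  # never quantified: below floor everywhere
        marks = dict(promoter_counts.get(gene, {})) if promoter_counts else {}
        stages = (
            {s: c.label for s, c in stage_calls.get(gene, {}).items()}
            if stage_calls
            else {}
        )
        p = survival_p.get(gene) if survival_p else None
        out.append(
            CandidateReport(
                gene_id=gene,
                enrichment_status=enrichment_status[gene],
                promoter_mark_counts=marks,
                stage_expression=stages,
                survival_p=None if p is None else float(p),
                not_expressed_flag=n_low >= min_low_lines,
            )
        )
    return out


def report_to_frame(reports: Sequence[CandidateReport], alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "gene_id": r.gene_id,
            "enrichment_status": r.enrichment_status,
            "survival_p": r.survival_p,
            "survival_significant": (
                bool(r.survival_p < alpha) if r.survival_p is not None else None
            ),
            "not_expressed": r.not_expressed_flag,
        }
        for cat in EPIGENOME_CATEGORIES:
            row[f"h3k4me3_{cat}"] = r.promoter_mark_counts.get(cat)
        for stage in STAGES:
            row[f"stage_{stage}"] = r.stage_expression.get(stage)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
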