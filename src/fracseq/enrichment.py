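"""Subcellular fraction enrichment: the log2(FPKM_cyto/FPKM_nuc) statistic,
housekeeping-calibrated reference range, and three-way classification.

The metric is computed per gene and cell line after median-of-ratios
normalization of the fraction libraries; a line contributes a ratio only when
both fractions reach an expression floor (default 0.1 FPKM). The null band of
fraction bias is calibrated as the 5th-95th percentile range of mean ratios
over housekeeping genes; a gene is nuclear-enriched when its ratio falls
below the lower limit in at least ``required_lines`` cell lines (default 4 of
8), cytoplasmic-enriched symmetrically above the upper limit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NUCLEAR = "nuclear_enriched"
CYTOPLASMIC = "cytoplasmic_enriched"
NON_SPECIFIC = "non_fraction_specific"
INSUFFICIENT = "insufficient_data"

STATUSES = (NUCLEAR, CYTOPLASMIC, NON_SPECIFIC, INSUFFICIENT)


@dataclass(frozen=True)
class ReferenceRange:
    lower_limit: float
    upper_limit: float
    n_housekeeping_used: int
    percentiles: tuple[float, float] = (5.0, 95.0)

    def __post_init__(self):
        if not self.lower_limit < self.upper_limit:
            raise ValueError(
                f"degenerate reference range: lower {self.lower_limit} >= upper {self.upper_limit}"
            )


@dataclass(frozen=True)
class EnrichmentCall:
    gene_id: str
    status: str
    n_lines_below_lower: int
    n_lines_above_upper: int
    n_lines_evaluable: int
    mean_log2_ratio: Optional[float] = None


def normalize_fpkm(raw: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Median-of-ratios normalization of a genes x libraries FPKM matrix.

    Size factors are the per-library median of gene/geometric-mean ratios,
    computed over genes positive in every library; each column is divided by
    its size factor. Returns (normalized matrix, size factors).
    """
    if raw.shape[1] < 2:
        raise ValueError("normalization requires >=2 libraries")
    x = raw.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("FPKM values must be non-negative")
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene is positive in all libraries")
    logx = np.log(x[positive])
    log_geomean = logx.mean(axis=1, keepdims=True)
    size_factors = np.exp(np.median(logx - log_geomean, axis=0))
    logger.info("normalize_fpkm size factors: %s", np.round(size_factors, 4))
    normalized = raw / size_factors
    return normalized, pd.Series(size_factors, index=raw.columns, name="size_factor")


def normalize_fraction_pair(
    cyto: pd.DataFrame, nuc: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Jointly normalize paired cytoplasmic/nuclear FPKM matrices.

    Size factors are estimated once over all fraction libraries (both
    fractions of every cell line together); returns the two normalized
    matrices and the size factors.
    """
    if list(cyto.columns) != list(nuc.columns):
        raise ValueError("cyto and nuc matrices must share cell-line columns")
    joint = pd.concat([cyto.add_suffix("_cyto"), nuc.add_suffix("_nuc")], axis=1)
    normalized, size_factors = normalize_fpkm(joint)
    cyto_n = normalized[[c for c in normalized if c.endswith("_cyto")]].copy()
    nuc_n = normalized[[c for c in normalized if c.endswith("_nuc")]].copy()
    cyto_n.columns = [c[: -len("_cyto")] for c in cyto_n.columns]
    nuc_n.columns = [c[: -len("_nuc")] for c in nuc_n.columns]
    return cyto_n, nuc_n, size_factors


def compute_log_ratios(
    cyto: pd.DataFrame,
    nuc: pd.DataFrame,
    floor: float = 0.1,
) -> pd.DataFrame:
    """Per-gene, per-cell-line log2(FPKM_cyto/FPKM_nuc).

    ``cyto`` and ``nuc`` are genes x cell lines matrices with matching
    indexes and columns (columns are cell lines, pairing the two fraction
    libraries of each line). A line's ratio is undefined (NaN) unless both
    fractions are >= ``floor``.
    """
    if not cyto.index.equals(nuc.index):
        raise ValueError("cyto and nuc matrices must share a gene index")
    if list(cyto.columns) != list(nuc.columns):
        raise ValueError("cyto and nuc matrices must share cell-line columns")
    c = cyto.to_numpy(dtype=float)
    n = nuc.to_numpy(dtype=float)
    evaluable = (c >= floor) & (n >= floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(evaluable, np.log2(c / n), np.nan)
    return pd.DataFrame(ratios, index=cyto.index, columns=cyto.columns)


def mean_log_ratios(ratios: pd.DataFrame, require_all_lines: bool = False) -> pd.Series:
    """Mean log2 ratio per gene over evaluable lines (NaN if none)."""
    if require_all_lines:
        means = ratios.mean(axis=1, skipna=False)
    else:
        means = ratios.mean(axis=1, skipna=True)
    return means.rename("mean_log2_ratio")


def reference_range(
    mean_ratios: pd.Series,
    housekeeping_ids: Iterable[str],
    *,
    min_genes: int = 30,
    percentiles: tuple[float, float] = (5.0, 95.0),
    method: str = "linear",
) -> ReferenceRange:
    """Housekeeping-calibrated reference range of fraction bias.

    ``mean_ratios`` is the per-gene mean log2(cyto/nuc); the limits are the
    given percentiles (default 5th/95th, linear interpolation between order
    statistics) over the housekeeping genes with a defined mean.
    """
    hk = pd.Index(sorted(set(housekeeping_ids)))
    values = mean_ratios.reindex(hk).dropna().to_numpy()
    if values.size < min_genes:
        raise ValueError(
            f"only {values.size} evaluable housekeeping genes; need >= {min_genes}"
        )
    lo, hi = np.percentile(values, percentiles, method=method)
    return ReferenceRange(float(lo), float(hi), int(values.size), tuple(percentiles))


def classify_enrichment(
    ratios: pd.DataFrame,
    ref_range: ReferenceRange,
    required_lines: int = 4,
) -> list[EnrichmentCall]:
    """Three-way enrichment classification per gene.

    Counts the evaluable cell lines strictly below the lower limit and
    strictly above the upper limit; nuclear-enriched when the below-count
    reaches ``required_lines``, cytoplasmic-enriched symmetrically; genes
    with no evaluable line are insufficient_data.
    """
    n_lines = ratios.shape[1]
    if required_lines < 1 or required_lines > n_lines:
        raise ValueError(
            f"required_lines must be in [1, {n_lines}], got {required_lines}"
        )
    r = ratios.to_numpy(dtype=float)
    evaluable = np.isfinite(r)
    below = (r < ref_range.lower_limit) & evaluable
    above = (r > ref_range.upper_limit) & evaluable
    n_evaluable = evaluable.sum(axis=1)
    sums = np.where(evaluable, r, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(n_evaluable > 0, sums / np.maximum(n_evaluable, 1), np.nan)

    out = []
    for i, gene in enumerate(ratios.index):
        n_eval = int(evaluable[i].sum())
        n_below = int(below[i].sum())
        n_above = int(above[i].sum())
        if n_eval == 0:
            status, mean = INSUFFICIENT, None
        else:
            mean = float(means[i])
            if n_below >= required_lines:
                status = NUCLEAR
            elif n_above >= required_lines:
                status = CYTOPLASMIC
            else:
                status = NON_SPECIFIC
        out.append(EnrichmentCall(str(gene), status, n_below, n_above, n_eval, mean))
    return out


@dataclass(frozen=True)
class MarkerCheck:
    gene_id: str
    expected: str
    observed: Optional[str]
    passed: bool


@dataclass(frozen=True)
class MarkerReport:
    checks: tuple[MarkerCheck, ...]
    overall_pass: bool
    missing: tuple[str, ...]


def validate_markers(
    calls: Iterable[EnrichmentCall],
    markers: Mapping[str, str],
) -> MarkerReport:
    """Check marker genes of known localization against enrichment calls.

    Markers absent from the calls are reported missing, not fatal; the
    overall verdict passes iff every present marker matches its expectation
    (vacuously true for an empty marker map, with a warning).
    """
    if not markers:
        logger.warning("validate_markers: empty marker map; vacuous pass")
        return MarkerReport((), True, ())
    by_gene = {c.gene_id: c for c in calls}
    checks, missing = [], []
    for gene, expected in sorted(markers.items()):
        call = by_gene.get(gene)
        if call is None:
            missing.append(gene)
            continue
        checks.append(MarkerCheck(gene, expected, call.status, call.status == expected))
    overall = all(c.passed for c in checks)
    return MarkerReport(tuple(checks), overall, tuple(missing))


def calls_to_frame(calls: Iterable[EnrichmentCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "status": c.status,
                "mean_log2_ratio": c.mean_log2_ratio,
                "n_lines_below_lower": c.n_lines_below_lower,
                "n_lines_above_upper": c.n_lines_above_upper,
                "n_lines_evaluable": c.n_lines_evaluable,
            }
            for c in calls
        ]
    ).set_index("gene_id")
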