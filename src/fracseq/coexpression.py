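"""Co-expression partner analysis: pairwise Pearson correlation of candidate
lncRNA genes against all genes across tumor samples, partner selection at
(PCC >= 0.6, p < 0.05), and hierarchical clustering of candidates by their
partner-correlation profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoexpressionEdge:
    lncrna_gene: str
    partner_gene: str
    pcc: float
    p_value: float

    def __post_init__(self):
        if self.lncrna_gene == self.partner_gene:
            raise ValueError("self-correlation edge is not allowed")
        if not np.isfinite(self.pcc):
            raise ValueError("pcc must be finite")


@dataclass(frozen=True)
class LncRNACluster:
    cluster_id: int
    member_lncrna_genes: tuple[str, ...]


def prevalence_filter(expr: pd.DataFrame, min_fraction: float = 0.2) -> pd.DataFrame:
    """Drop genes expressed (value > 0) in fewer than ``min_fraction`` of samples.

    The fraction comparison is inclusive: a gene positive in exactly 20% of
    samples passes the default threshold.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if expr.empty:
        raise ValueError("expression matrix is empty")
    frac = (expr > 0).mean(axis=1)
    return expr.loc[frac >= min_fraction]


def pcc_with_p(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t distribution (n-2 df).

    Zero-variance input is undefined: reported as (nan, 1.0) with a warning
    so callers treat it as non-significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need n >= 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("pcc_with_p: zero-variance vector; correlation undefined")
        return float("nan"), 1.0
    r, p = stats.pearsonr(x, y)
    return float(np.clip(r, -1.0, 1.0)), float(p)


def _t_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def compute_edges(
    expr: pd.DataFrame,
    candidates: Sequence[str],
    *,
    log_transform: bool = True,
) -> list[CoexpressionEdge]:
    """All candidate-vs-gene correlation edges across samples.

    ``expr`` is genes x samples; rows are log2(x+1)-transformed by default
    before correlation. Zero-variance genes yield undefined correlations and
    are skipped (logged).
    """
    missing = [c for c in candidates if c not in expr.index]
    if missing:
        raise KeyError(f"candidate genes absent from expression matrix: {missing}")
    x = expr.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    n = x.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples for correlation")
    sd = x.std(axis=1)
    z = np.where(
        (sd > 0)[:, None], (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)[:, None], 0.0
    )
    genes = list(expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    edges = []
    for cand in candidates:
        ci = gene_pos[cand]
        if sd[ci] == 0:
            logger.warning("candidate %s has zero variance; skipped", cand)
            continue
        r = z @ z[ci] / n
        p = _t_pvalues(r, n)
        for gi, gene in enumerate(genes):
            if gene == cand or sd[gi] == 0:
                continue
            edges.append(CoexpressionEdge(cand, gene, float(np.clip(r[gi], -1, 1)), float(p[gi])))
    return edges


def select_partners(
    edges: Iterable[CoexpressionEdge],
    pcc_min: float = 0.6,
    alpha: float = 0.05,
    *,
    use_absolute: bool = False,
) -> list[CoexpressionEdge]:
    """Keep significantly co-expressed edges: PCC >= pcc_min (inclusive) and
    p < alpha. Signed by default (only positive correlations qualify);
    ``use_absolute`` switches to |PCC| >= pcc_min."""
    out = []
    for e in edges:
        value = abs(e.pcc) if use_absolute else e.pcc
        if value >= pcc_min and e.p_value < alpha:
            out.append(e)
    return out


def partner_matrix(
    edges: Iterable[CoexpressionEdge],
    candidates: Sequence[str],
    selected: Iterable[CoexpressionEdge],
) -> pd.DataFrame:
    """Candidates x partners PCC matrix over the union of selected partners.

    Entries for (candidate, partner) pairs without a computed edge are 0.
    """
    partners = sorted({e.partner_gene for e in selected})
    mat = pd.DataFrame(0.0, index=list(candidates), columns=partners)
    for e in edges:
        if e.partner_gene in mat.columns and e.lncrna_gene in mat.index:
            mat.loc[e.lncrna_gene, e.partner_gene] = e.pcc
    return mat


def cluster_candidates(
    candidates: Sequence[str],
    partner_pcc: pd.DataFrame,
    k: int = 3,
) -> list[LncRNACluster]:
    """Group candidates by average-linkage hierarchical clustering (Euclidean
    distance) of their partner-PCC rows, cut into k clusters."""
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the number of candidates ({len(candidates)})")
    if partner_pcc.shape[1] < 1:
        raise ValueError("partner matrix has no partner columns")
    rows = partner_pcc.reindex(index=list(candidates)).fillna(0.0)
    link = linkage(rows.to_numpy(dtype=float), method="average", metric="euclidean")
    labels = fcluster(link, t=k, criterion="maxclust")
    clusters: dict[int, list[str]] = {}
    for gene, label in zip(candidates, labels):
        clusters.setdefault(int(label), []).append(gene)
    return [
        LncRNACluster(cid, tuple(sorted(members)))
        for cid, members in sorted(clusters.items())
    ]


def edges_to_frame(edges: Iterable[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_gene": e.lncrna_gene,
                "partner_gene": e.partner_gene,
                "pcc": e.pcc,
                "p_value": e.p_value,
            }
            for e in edges
        ],
        columns=["lncrna_gene", "partner_gene", "pcc", "p_value"],
    )
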