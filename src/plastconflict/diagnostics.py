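"""Per-locus diagnostics: long-branch scores, saturation regressions, and
mean gene-tree bootstrap support.

The long-branch (LB) score of a taxon is the percent deviation of its mean
patristic distance to all other taxa from the tree-wide mean pairwise
distance; the per-locus summary is the sample standard deviation of taxon LB
scores, the statistic used to flag long-branch-prone loci. Saturation is
measured by regressing uncorrected p-distance on patristic distance through
the origin: a flat or noisy regression (low slope, low R²) indicates that
multiple substitutions have erased signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from plastconflict.core import LocusAlignment, ambiguous_for
from plastconflict.tree import PhyloTree


@dataclass
class DiagnosticsRecord:
    locus_id: str
    taxon_lb: dict[str, float]
    lb_heterogeneity: float
    slope: float
    r2: float
    mean_support: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")
        if self.lb_heterogeneity < 0:
            raise ValueError("lb heterogeneity must be non-negative")


def lb_scores(tree: PhyloTree) -> tuple[dict[str, float], float]:
    """Taxon long-branch scores and their sample standard deviation.

    LB_i = 100 · (mean_{j≠i} d(i,j) / mean_{all i≠j} d(i,j) − 1).
    """
    labels, dist = tree.patristic_distances()
    n = len(labels)
    if n < 3:
        raise ValueError("LB scores need at least 3 taxa")
    row_means = dist.sum(axis=1) / (n - 1)
    grand_mean = dist.sum() / (n * (n - 1))
    if grand_mean <= 0:
        scores = {t: 0.0 for t in labels}
        return scores, 0.0
    lb = 100.0 * (row_means / grand_mean - 1.0)
    heterogeneity = float(np.std(lb, ddof=1))
    return dict(zip(labels, lb)), heterogeneity


def p_distances(locus: LocusAlignment) -> tuple[list[str], np.ndarray]:
    """Uncorrected pairwise distances over mutually unambiguous columns.

    Pairs with no comparable site get NaN.
    """
    taxa = sorted(locus.taxa)
    amb = ambiguous_for(locus.alphabet)
    arrs = {}
    for t in taxa:
        seq = np.frombuffer(locus.seqs[t].encode("ascii"), dtype=np.uint8)
        ok = np.ones(len(seq), dtype=bool)
        for a in amb:
            ok &= seq != ord(a)
        arrs[t] = (seq, ok)
    n = len(taxa)
    dist = np.zeros((n, n))
    for i in range(n):
        si, oki = arrs[taxa[i]]
        for j in range(i + 1, n):
            sj, okj = arrs[taxa[j]]
            both = oki & okj
            m = int(both.sum())
            if m == 0:
                dist[i, j] = dist[j, i] = np.nan
            else:
                d = float((si[both] != sj[both]).sum()) / m
                dist[i, j] = dist[j, i] = d
    return taxa, dist


def saturation_regression(
    pdist: np.ndarray, patristic: np.ndarray
) -> tuple[float, float]:
    """Zero-intercept OLS of p-distance on patristic distance.

    slope = Σxy/Σx²; R² is the uncentered coefficient of determination of
    the through-origin fit, 1 − Σ(y−ŷ)²/Σy², clipped to [0, 1]. Both
    matrices must be over the same taxa in the same order.
    """
    if pdist.shape != patristic.shape:
        raise ValueError("distance matrices must have the same shape")
    iu = np.triu_indices(pdist.shape[0], 1)
    x = patristic[iu]
    y = pdist[iu]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 valid taxon pairs")
    sxx = float(np.dot(x, x))
    if sxx == 0:
        raise ValueError("all patristic distances are zero")
    slope = float(np.dot(x, y)) / sxx
    syy = float(np.dot(y, y))
    if syy == 0:
        return slope, 1.0
    ss_res = float(np.sum((y - slope * x) ** 2))
    r2 = 1.0 - ss_res / syy
    return slope, float(np.clip(r2, 0.0, 1.0))


def mean_support(tree: PhyloTree) -> float:
    """Arithmetic mean of internal-edge support values (percent)."""
    supports = [
        n.support
        for n in tree.postorder()
        if not n.is_leaf and n is not tree.root and n.support is not None
    ]
    if not supports:
        raise ValueError("no internal supports on tree")
    return float(np.mean(supports))


_METRIC_COLUMNS = {
    "lb": "lb_heterogeneity",
    "slope": "slope",
    "r2": "r2",
    "support": "mean_support",
}


def select_loci_by_threshold(
    records: pd.DataFrame,
    metric: str,
    threshold: float,
    direction: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a diagnostics table into (kept, removed) by one metric.

    Long-branch filtering removes values strictly above the threshold;
    slope/R²/support filtering removes values strictly below. Ties (value
    == threshold) are always kept.
    """
    if metric not in _METRIC_COLUMNS:
        raise ValueError(f"unknown metric {metric!r}")
    column = _METRIC_COLUMNS[metric]
    if column not in records.columns:
        raise ValueError(f"records lack column {column!r}")
    if direction is None:
        direction = "remove_above" if metric == "lb" else "remove_below"
    values = records[column]
    if direction == "remove_above":
        removed_mask = values > threshold
    elif direction == "remove_below":
        removed_mask = values < threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return records[~removed_mask].copy(), records[removed_mask].copy()


def diagnose_locus(
    locus: LocusAlignment, gene_tree: PhyloTree
) -> DiagnosticsRecord:
    """Assemble the full diagnostics record for one locus from its gene tree.

    The gene tree must be leaf-labelled by the locus's taxa, carry branch
    lengths, and have bootstrap supports on internal edges.
    """
    taxa_p, pdist = p_distances(locus)
    labels_t, pat = gene_tree.patristic_distances()
    if labels_t != taxa_p:
        order = [taxa_p.index(t) for t in labels_t]
        pdist = pdist[np.ix_(order, order)]
    slope, r2 = saturation_regression(pdist, pat)
    taxon_lb, het = lb_scores(gene_tree)
    return DiagnosticsRecord(
        locus_id=locus.locus_id,
        taxon_lb=taxon_lb,
        lb_heterogeneity=het,
        slope=slope,
        r2=r2,
        mean_support=mean_support(gene_tree),
    )


def diagnostics_table(records: list[DiagnosticsRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "locus_id": r.locus_id,
                "lb_heterogeneity": r.lb_heterogeneity,
                "slope": r.slope,
                "r2": r.r2,
                "mean_support": r.mean_support,
            }
            for r in records
        ]
    )
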