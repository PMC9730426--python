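"""Gene-wise phylogenetic-signal quantification among candidate topologies.

For each locus, the gene-wise log-likelihood score GLS under a topology is
the sum of that topology's site-wise log-likelihoods (SLS) over the locus's
columns; ΔGLS between two topologies is the difference of their GLS. Each
locus supports the topology with the highest GLS (exact ties are
"ambiguous"). Outlier loci are flagged when their mean ΔGLS — the mean of
the three oriented pairwise differences — falls more than three standard
deviations from the dataset mean; the reported bounds are additionally
capped at the observed min/max, which does not affect the flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from plastconflict.core import LocusAlignment, SiteLikelihoodTable

_TIE_TOL = 1e-9


@dataclass
class SignalRecord:
    locus_id: str
    gls: dict[str, float]
    delta: dict[tuple[str, str], float] = field(init=False)
    supported: str = field(init=False)
    mean_delta: float = field(init=False)

    def __post_init__(self) -> None:
        labels = sorted(self.gls)
        if not all(np.isfinite(v) for v in self.gls.values()):
            raise ValueError("non-finite GLS value")
        self.delta = {}
        for a, b in combinations(labels, 2):
            d = self.gls[a] - self.gls[b]
            self.delta[(a, b)] = d
            self.delta[(b, a)] = -d
        best = max(self.gls.values())
        winners = [t for t, v in self.gls.items() if best - v <= _TIE_TOL]
        self.supported = winners[0] if len(winners) == 1 else "ambiguous"
        oriented = [self.delta[(a, b)] for a, b in combinations(labels, 2)]
        self.mean_delta = float(np.mean(oriented))


def gene_wise_gls(
    tables: dict[str, SiteLikelihoodTable],
    partitions: dict[str, tuple[int, int]],
) -> list[SignalRecord]:
    """Per-locus GLS under each topology from site-likelihood tables.

    All tables must come from the same matrix, so the partition sums of each
    topology's SLS reproduce its total ln L exactly.
    """
    lengths = {label: len(t) for label, t in tables.items()}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"site-likelihood tables differ in length: {lengths}")
    L = next(iter(lengths.values()))
    end_max = max(end for _, end in partitions.values())
    if end_max != L:
        raise ValueError(f"partitions cover [0,{end_max}) but tables have {L} sites")
    records = []
    for locus, (start, end) in partitions.items():
        gls = {
            label: float(table.sls[start:end].sum()) for label, table in tables.items()
        }
        records.append(SignalRecord(locus_id=locus, gls=gls))
    return records


def signal_table(records: list[SignalRecord]) -> pd.DataFrame:
    labels = sorted(records[0].gls) if records else []
    rows = []
    for r in records:
        row = {"locus_id": r.locus_id}
        for t in labels:
            row[f"gls_{t}"] = r.gls[t]
        for a, b in combinations(labels, 2):
            row[f"delta_{a}_{b}"] = r.delta[(a, b)]
        row["supported"] = r.supported
        row["mean_delta"] = r.mean_delta
        rows.append(row)
    return pd.DataFrame(rows)


def support_proportions(records: list[SignalRecord]) -> dict[str, float]:
    """Percentage of loci supporting each topology, plus 'ambiguous'.

    Percentages are over all loci and sum to 100 up to rounding.
    """
    if not records:
        raise ValueError("no signal records")
    labels = sorted(records[0].gls)
    n = len(records)
    out = {t: 0.0 for t in labels}
    out["ambiguous"] = 0.0
    for r in records:
        out[r.supported] += 1
    return {k: 100.0 * v / n for k, v in out.items()}


@dataclass
class OutlierBounds:
    """μ±3σ outlier envelope with min/max capping on the reported bounds."""

    mean: float
    std: float
    lower: float
    upper: float
    flags: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean) and np.isfinite(self.std)):
            raise ValueError("non-finite bounds")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def outlier_bounds(values) -> OutlierBounds:
    """Flag values outside μ±3σ (sample standard deviation, n−1).

    The reported bounds are capped at the observed min/max; the capping
    affects only the reported envelope, never the flags. With σ = 0 nothing
    is flagged and a warning is issued.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values for outlier bounds")
    mu = float(np.mean(x))
    sigma = float(np.std(x, ddof=1))
    if sigma == 0:
        warnings.warn("zero standard deviation: no outliers can be flagged")
        flags = np.zeros(len(x), dtype=bool)
        return OutlierBounds(mu, 0.0, float(x.min()), float(x.max()), flags)
    lower = max(float(x.min()), mu - 3 * sigma)
    upper = min(float(x.max()), mu + 3 * sigma)
    flags = (x > mu + 3 * sigma) | (x < mu - 3 * sigma)
    return OutlierBounds(mu, sigma, lower, upper, flags)


def remove_outliers(
    loci: list[LocusAlignment], records: list[SignalRecord]
) -> tuple[list[LocusAlignment], list[str]]:
    """Drop loci whose mean ΔGLS is flagged by the μ±3σ rule.

    Returns the retained loci and the ids of the removed ones.
    """
    by_id = {r.locus_id: r for r in records}
    missing = [l.locus_id for l in loci if l.locus_id not in by_id]
    if missing:
        raise ValueError(f"signal records missing for loci: {missing}")
    ordered = [by_id[l.locus_id] for l in loci]
    bounds = outlier_bounds([r.mean_delta for r in ordered])
    removed = [l.locus_id for l, f in zip(loci, bounds.flags) if f]
    kept = [l for l, f in zip(loci, bounds.flags) if not f]
    return kept, removed
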