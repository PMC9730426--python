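"""RELL-based topology hypothesis tests: KH, SH, weighted variants, and the
multiscale-bootstrap AU test.

All tests resample per-site log-likelihoods (RELL: no re-optimisation).
Site resampling is realised as a multinomial draw over unique site-pattern
log-likelihood columns, which is distributionally identical to index
resampling and much faster on long matrices. KH follows the one-sided
replicate-mean-centering convention, so the maximum-likelihood topology
receives p = 1 by construction. The AU test fits the multiscale bootstrap
proportions BP(r) ≈ 1 − Φ(d√r + c/√r) by weighted least squares on the
probit scale and reports p = 1 − Φ(d − c).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 2))


@dataclass
class TopologyTestResult:
    topology: str
    p_au: float
    p_kh: float
    p_sh: float
    p_wkh: float
    p_wsh: float
    b: int
    scales: tuple
    seed: int | None

    def __post_init__(self) -> None:
        for name in ("p_au", "p_kh", "p_sh", "p_wkh", "p_wsh"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {p}")


def _as_matrix(sls: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    labels = list(sls)
    if len(labels) < 2:
        raise ValueError("need at least 2 topologies")
    mat = np.asarray([np.asarray(sls[t], dtype=float) for t in labels])
    if mat.size == 0:
        raise ValueError("empty site-likelihood table")
    if mat.ndim != 2 or len({len(v) for v in sls.values()}) != 1:
        raise ValueError("site-likelihood vectors differ in length")
    return labels, mat


def rell_resample(
    sls: dict[str, np.ndarray],
    b: int,
    scale: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """RELL replicate totals; shape (n_topologies, b).

    Each replicate draws ⌈scale·L⌉ sites with replacement and sums each
    topology's per-site log-likelihoods over the draw.
    """
    labels, mat = _as_matrix(sls)
    if b < 1:
        raise ValueError("need at least one replicate")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    L = mat.shape[1]
    n_draw = math.ceil(scale * L)
    # collapse duplicate site columns; multinomial over patterns is
    # equivalent to index resampling
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    pvals = counts / L
    totals = np.empty((len(labels), b))
    chunk = max(1, int(4e6 // max(1, patterns.shape[1])))
    done = 0
    while done < b:
        m = min(chunk, b - done)
        draws = rng.multinomial(n_draw, pvals, size=m)  # (m, P)
        totals[:, done : done + m] = patterns @ draws.T
        done += m
    return totals


def kh_sh_tests(
    sls: dict[str, np.ndarray],
    b: int = 10000,
    seed: int | None = None,
    weighted: bool = True,
) -> pd.DataFrame:
    """KH and SH tests (plus weighted variants) from RELL replicates.

    Replicate totals are centred by their own replicate mean per topology.
    KH compares each topology against the ML topology one-sidedly; SH
    compares against the replicate-wise maximum, so p_SH ≥ p_KH on the same
    replicates. Weighted variants standardise each pairwise difference by
    its replicate standard deviation.
    """
    labels, mat = _as_matrix(sls)
    if b < 100:
        warnings.warn("fewer than 100 RELL replicates; p-values will be coarse")
    totals = mat.sum(axis=1)
    reps = rell_resample(sls, b=b, scale=1.0, seed=seed)
    centered = reps - reps.mean(axis=1, keepdims=True)
    n = len(labels)
    ml = int(np.argmax(totals))
    # pairwise replicate std of differences
    sd = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                s = float(np.std(centered[j] - centered[i], ddof=1))
                sd[i, j] = max(s, 1e-12)
    rows = []
    for i in range(n):
        obs_kh = totals[ml] - totals[i]
        p_kh = float(np.mean(centered[ml] - centered[i] >= obs_kh))
        obs_sh = float(np.max(totals) - totals[i])
        p_sh = float(np.mean(centered.max(axis=0) - centered[i] >= obs_sh))
        if weighted:
            others = [j for j in range(n) if j != i]
            obs_w = np.array([(totals[j] - totals[i]) / sd[i, j] for j in others])
            rep_w = np.array(
                [(centered[j] - centered[i]) / sd[i, j] for j in others]
            )
            jstar = int(np.argmax(obs_w))
            p_wkh = float(np.mean(rep_w[jstar] >= obs_w[jstar]))
            p_wsh = float(np.mean(rep_w.max(axis=0) >= obs_w.max()))
        else:
            p_wkh, p_wsh = p_kh, p_sh
        rows.append(
            {
                "topology": labels[i],
                "p_kh": p_kh,
                "p_sh": p_sh,
                "p_wkh": p_wkh,
                "p_wsh": p_wsh,
            }
        )
    return pd.DataFrame(rows)


def au_test(
    sls: dict[str, np.ndarray],
    scales: tuple = DEFAULT_SCALES,
    b: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Approximately unbiased test via the multiscale bootstrap.

    For each scale r the bootstrap proportion BP(r) of a topology is the
    fraction of RELL replicates (drawing ⌈rL⌉ sites) in which it attains the
    maximum total. The signed distance d and curvature c of the model
    BP(r) = 1 − Φ(d√r + c/√r) are fitted by weighted least squares on the
    probit scale with binomial weights; p_AU = 1 − Φ(d − c). Degenerate
    proportions are continuity-corrected by 1/(2B).
    """
    if len(scales) < 2:
        raise ValueError("need at least 2 bootstrap scales")
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    labels, mat = _as_matrix(sls)
    rng = np.random.default_rng(seed)
    n = len(labels)
    bp = np.zeros((n, len(scales)))
    for si, scale in enumerate(scales):
        reps = rell_resample(sls, b=b, scale=scale, rng=rng)
        best = reps.max(axis=0)
        hits = reps >= best - 1e-12  # ties count for every tied topology
        bp[:, si] = hits.mean(axis=1)
    rows = []
    for i in range(n):
        p_au, diag = _fit_au(bp[i], np.asarray(scales, dtype=float), b)
        rows.append({"topology": labels[i], "p_au": p_au, **diag})
    return pd.DataFrame(rows)


def _fit_au(bp: np.ndarray, scales: np.ndarray, b: int) -> tuple[float, dict]:
    eps = 1.0 / (2.0 * b)
    nondegenerate = (bp > 0) & (bp < 1)
    if nondegenerate.sum() < 2:
        side = 1.0 if bp.mean() > 0.5 else 0.0
        warnings.warn("fewer than 2 non-degenerate scales in AU fit")
        return side, {"au_d": np.nan, "au_c": np.nan, "au_rss": np.nan}
    bpc = np.clip(bp, eps, 1.0 - eps)
    z = norm.ppf(1.0 - bpc)  # z = d√r + c/√r
    x1 = np.sqrt(scales)
    x2 = 1.0 / np.sqrt(scales)
    phi = norm.pdf(z)
    w = b * phi**2 / (bpc * (1.0 - bpc))
    design = np.column_stack([x1, x2])
    wd = design * w[:, None]
    ata = design.T @ wd
    atz = wd.T @ z
    try:
        d, c = np.linalg.solve(ata, atz)
    except np.linalg.LinAlgError:
        return float(np.clip(1.0 - bp.mean(), 0, 1)), {
            "au_d": np.nan,
            "au_c": np.nan,
            "au_rss": np.nan,
        }
    rss = float(np.sum(w * (z - design @ np.array([d, c])) ** 2))
    p = float(1.0 - norm.cdf(d - c))
    return p, {"au_d": float(d), "au_c": float(c), "au_rss": rss}


def run_topology_tests(
    sls: dict[str, np.ndarray],
    b: int = 10000,
    scales: tuple = DEFAULT_SCALES,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[list[TopologyTestResult], pd.DataFrame]:
    """All five tests on one site-likelihood table.

    Returns the per-topology results and a tidy table with an
    interpretation column ("rejected" when p_AU < alpha).
    """
    au = au_test(sls, scales=scales, b=b, seed=seed)
    khsh = kh_sh_tests(sls, b=b, seed=None if seed is None else seed + 1)
    df = au.merge(khsh, on="topology")
    df["interpretation"] = np.where(
        df["p_au"] < alpha, f"rejected_at_{alpha}", "not_rejected"
    )
    results = [
        TopologyTestResult(
            topology=r.topology,
            p_au=float(np.clip(r.p_au, 0, 1)),
            p_kh=r.p_kh,
            p_sh=r.p_sh,
            p_wkh=r.p_wkh,
            p_wsh=r.p_wsh,
            b=b,
            scales=tuple(scales),
            seed=seed,
        )
        for r in df.itertuples()
    ]
    df["p_au"] = df["p_au"].clip(0, 1)
    return results, df
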