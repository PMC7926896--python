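"""Two-group inference for gene expression: gene-pair log ratios, exact
and asymptotic Mann-Whitney U tests, and BCa bootstrap intervals.

At the study's group sizes (n = 4 vs 4) the exact Mann-Whitney null
distribution is enumerated over all C(8, 4) = 70 group assignments of the
pooled midranks; the two-sided exact p is twice the smaller one-sided
tail, capped at 1 (the "2 x one-tailed" convention).  The asymptotic test
uses the normal approximation with the midrank tie correction in the
variance and no continuity correction.  BCa intervals follow Efron's
bias-corrected-and-accelerated construction: bias correction z0 from the
proportion of bootstrap statistics below the observed value, acceleration
a from jackknife skewness, endpoints read from the bootstrap distribution
at the adjusted quantile levels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)

_MAX_EXACT_ASSIGNMENTS = 2_000_000


@dataclass
class MannWhitneyResult:
    U: float
    n1: int
    n2: int
    p_exact: float | None = None
    z: float | None = None
    p_asymptotic: float | None = None


@dataclass
class BootstrapCI:
    lo: float
    hi: float
    level: float
    B: int
    z0: float
    a: float
    seed: int | None
    degenerate: bool = False


def _u_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """U for x (via midrank sum) and the pooled midranks."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    u = r1 - len(x) * (len(x) + 1) / 2.0
    return float(u), ranks


def mann_whitney_exact(x, y) -> MannWhitneyResult:
    """Exact two-sided Mann-Whitney U test by full enumeration.

    The null distribution of U is built by assigning every size-n1 subset
    of the pooled midranks to the first group.  Ties are permitted
    (midranks).  p = min(1, 2 * min(P(U' <= U), P(U' >= U))).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    if math.comb(n1 + n2, n1) > _MAX_EXACT_ASSIGNMENTS:
        raise ValueError(
            "exact enumeration infeasible at these group sizes; use mann_whitney_asymptotic"
        )
    u_obs, ranks = _u_statistic(x, y)
    offset = n1 * (n1 + 1) / 2.0
    n_le = 0
    n_ge = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - offset
        n_le += u <= u_obs + eps
        n_ge += u >= u_obs - eps
        total += 1
    p_one = min(n_le, n_ge) / total
    p = min(1.0, 2.0 * p_one)
    return MannWhitneyResult(U=u_obs, n1=n1, n2=n2, p_exact=p)


def mann_whitney_asymptotic(x, y) -> MannWhitneyResult:
    """Normal-approximation Mann-Whitney U test (tie-corrected, no continuity
    correction).  All observations tied gives p = 1 with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u, ranks = _u_statistic(x, y)
    n = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        logger.warning("mann_whitney_asymptotic: zero variance (all values tied); p = 1")
        return MannWhitneyResult(U=u, n1=n1, n2=n2, z=0.0, p_asymptotic=1.0)
    z = (u - n1 * n2 / 2.0) / math.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return MannWhitneyResult(U=u, n1=n1, n2=n2, z=z, p_asymptotic=p)


def pair_log_ratio(norm_df: pd.DataFrame, pair: tuple[str, str]) -> pd.DataFrame:
    """Per-sample log ratio of a gene pair: log_norm(num) - log_norm(den).

    Defined only for samples where both genes have normalized expression.
    """
    num, den = pair
    for g in (num, den):
        if g not in set(norm_df["gene"]):
            raise ValueError(f"gene {g!r} absent from normalized expression")
    cols = ["animal_id", "region", "group"]
    a = norm_df[norm_df["gene"] == num][cols + ["log_norm"]]
    b = norm_df[norm_df["gene"] == den][cols + ["log_norm"]]
    merged = a.merge(b, on=cols, suffixes=("_num", "_den"))
    merged["ratio_log"] = merged["log_norm_num"] - merged["log_norm_den"]
    merged["pair"] = f"{num}:{den}"
    return merged[cols + ["pair", "ratio_log"]]


def _bca_levels(z0: float, a: float, level: float) -> tuple[float, float]:
    """BCa-adjusted quantile levels for a central interval."""
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        zq = norm.ppf(q)
        adj = z0 + (z0 + zq) / (1.0 - a * (z0 + zq))
        out.append(float(norm.cdf(adj)))
    return out[0], out[1]


def bca_ci(
    values,
    statistic: Callable[[np.ndarray], float] = np.mean,
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Bias-corrected and accelerated bootstrap interval for a statistic.

    Resamples ``values`` with replacement B times.  A constant sample
    returns the degenerate interval (c, c).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError("BCa interval requires at least 2 observations")
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = float(statistic(values))
    if np.ptp(values) == 0.0:
        return BootstrapCI(obs, obs, level, B, 0.0, 0.0, seed, degenerate=True)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    if statistic is np.mean:  # fast path for the common case
        boot = values[idx].mean(axis=1)
    else:
        boot = np.apply_along_axis(statistic, 1, values[idx]).astype(float)

    # bias correction: proportion of bootstrap statistics below the observed
    # value, counting ties as half
    prop = (np.sum(boot < obs) + 0.5 * np.sum(boot == obs)) / B
    prop = min(max(prop, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = float(norm.ppf(prop))

    # acceleration from jackknife skewness
    jack = np.array(
        [statistic(np.delete(values, i)) for i in range(n)], dtype=float
    )
    d = jack.mean() - jack
    denom = (d**2).sum() ** 1.5
    a = float((d**3).sum() / (6.0 * denom)) if denom > 0 else 0.0

    lo_q, hi_q = _bca_levels(z0, a, level)
    lo, hi = np.quantile(boot, [lo_q, hi_q])
    return BootstrapCI(float(lo), float(hi), level, B, z0, a, seed)


def ratio_group_tests(
    ratio_df: pd.DataFrame,
    B: int = 2000,
    level: float = 0.95,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per (region, pair): exact + asymptotic Mann-Whitney on the log ratios
    and per-group BCa intervals for the group means.

    Bootstrap resampling is done within each group independently; the
    per-pair seed is derived deterministically from ``seed`` and recorded.
    """
    rows = []
    for i, ((region, pair), sub) in enumerate(
        sorted(ratio_df.groupby(["region", "pair"]), key=lambda kv: kv[0])
    ):
        x = sub.loc[sub["group"] == "stressed", "ratio_log"].to_numpy()
        y = sub.loc[sub["group"] == "control", "ratio_log"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            logger.warning("ratio_group_tests: %s %s missing a group; skipped", region, pair)
            continue
        exact = mann_whitney_exact(x, y)
        asym = mann_whitney_asymptotic(x, y)
        pair_seed = None if seed is None else seed + 1000 * i
        ci_ctrl = bca_ci(y, B=B, level=level, seed=pair_seed)
        ci_str = bca_ci(x, B=B, level=level, seed=None if pair_seed is None else pair_seed + 1)
        rows.append(
            {
                "region": region,
                "pair": pair,
                "n_control": len(y),
                "n_stressed": len(x),
                "U": exact.U,
                "p_exact": exact.p_exact,
                "z": asym.z,
                "p_asymptotic": asym.p_asymptotic,
                "control_mean": float(np.mean(y)),
                "control_ci_lo": ci_ctrl.lo,
                "control_ci_hi": ci_ctrl.hi,
                "stressed_mean": float(np.mean(x)),
                "stressed_ci_lo": ci_str.lo,
                "stressed_ci_hi": ci_str.hi,
                "B": B,
                "seed": pair_seed,
            }
        )
    return pd.DataFrame(rows)
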