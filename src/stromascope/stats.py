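"""Relative expression (2^-ddCt) and group-comparison statistics.

The statistics mirror the comparisons used for aligned-vs-random scaffold
studies: Welch's t (unequal variances), Student's t (pooled), the
two-sample Kolmogorov-Smirnov test, and summary statistics with the
standard error of the mean.  Test statistics are computed from the standard
formulas directly; p-value tails come from the scipy reference
distributions (Student t, asymptotic Kolmogorov), with exact lattice-path
enumeration for the KS test at very small sample sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "ddct_fold_change",
    "compare_groups",
    "summarize_condition",
    "type_i_error",
]


# ---------------------------------------------------------------------------
# 2^-ddCt relative expression
# ---------------------------------------------------------------------------

def ddct_fold_change(
    table: pd.DataFrame,
    baseline_condition: str,
    housekeeping_gene: str = "ACTB",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative expression by the 2^-ddCt method.

    Per sample, dCt = Ct_target - Ct_housekeeping; per condition,
    ddCt = mean dCt(condition) - mean dCt(baseline) and the fold change is
    2^-ddCt (condition-mean convention).  Samples lacking the housekeeping
    gene are dropped with a warning.

    Returns ``(per_condition, per_sample)``: the first has one row per
    (gene, condition) with ddct and fold_change; the second carries
    per-sample fold changes 2^-(dCt - mean dCt baseline) for dispersion
    estimates.
    """
    if baseline_condition not in set(table["condition"]):
        raise ValueError(f"baseline condition {baseline_condition!r} missing")
    hk = table[table["gene"] == housekeeping_gene].set_index("sample")["ct"]
    if hk.empty:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} missing")
    targets = table[table["gene"] != housekeeping_gene].copy()
    missing = ~targets["sample"].isin(hk.index)
    if missing.any():
        warnings.warn(
            "dropped samples lacking the housekeeping gene: "
            f"{sorted(targets.loc[missing, 'sample'].unique())}", stacklevel=2,
        )
        targets = targets[~missing]
    targets["dct"] = targets["ct"] - targets["sample"].map(hk)

    base_mean = (
        targets[targets["condition"] == baseline_condition]
        .groupby("gene")["dct"].mean()
    )
    per_sample = targets.copy()
    per_sample["fold_change"] = 2.0 ** -(
        per_sample["dct"] - per_sample["gene"].map(base_mean)
    )
    per_condition = (
        targets.groupby(["gene", "condition"])["dct"].mean().reset_index()
    )
    per_condition["ddct"] = per_condition["dct"] - per_condition["gene"].map(base_mean)
    per_condition["fold_change"] = 2.0 ** -per_condition["ddct"]
    return per_condition.drop(columns="dct"), per_sample


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    percent_change: float
    test: str
    statistic: float
    p_value: float


def _ks_exact_sf(d: float, n: int, m: int) -> float:
    """P(D >= d) for the two-sample KS statistic by lattice-path counting."""
    dp = np.zeros((n + 1, m + 1))
    dp[0, 0] = 1.0
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if abs(i / n - j / m) >= d - 1e-12:
                continue
            dp[i, j] = (dp[i - 1, j] if i > 0 else 0.0) + (
                dp[i, j - 1] if j > 0 else 0.0
            )
    return 1.0 - dp[n, m] / comb(n + m, n)


def _ks_2sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic from the empirical CDFs and its p-value.

    Asymptotic Kolmogorov tail for min(n, m) >= 10; exact enumeration below.
    """
    n, m = a.size, b.size
    grid = np.sort(np.concatenate([a, b]))
    cdf_a = np.searchsorted(np.sort(a), grid, side="right") / n
    cdf_b = np.searchsorted(np.sort(b), grid, side="right") / m
    d = float(np.abs(cdf_a - cdf_b).max())
    if min(n, m) >= 10:
        # asymptotic Kolmogorov tail with the Stephens finite-sample
        # correction to the effective sqrt(n)
        en = np.sqrt(n * m / (n + m))
        p = float(sps.kstwobign.sf((en + 0.12 + 0.11 / en) * d))
    else:
        p = _ks_exact_sf(d, n, m)
    return d, min(max(p, 0.0), 1.0)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    test: str = "welch_t",
    group_a: str = "a",
    group_b: str = "b",
) -> ComparisonResult:
    """Two-group comparison by Welch's t, Student's t or two-sample KS.

    Percent change is 100 * (mean_a - mean_b) / mean_b, i.e. group b is the
    baseline.  Two constant, equal groups give p = 1 by convention.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if test in ("welch_t", "student_t") and (a.size < 2 or b.size < 2):
        raise ValueError("t-tests require n >= 2 per group")
    if a.size < 1 or b.size < 1:
        raise ValueError("empty group")
    va, vb = a.var(ddof=1) if a.size > 1 else 0.0, b.var(ddof=1) if b.size > 1 else 0.0
    ma, mb = a.mean(), b.mean()

    if test == "welch_t":
        se2 = va / a.size + vb / b.size
        if se2 == 0:
            stat, p = 0.0, 1.0
        else:
            stat = (ma - mb) / np.sqrt(se2)
            df = se2**2 / (
                (va / a.size) ** 2 / (a.size - 1) + (vb / b.size) ** 2 / (b.size - 1)
            )
            p = 2.0 * sps.t.sf(abs(stat), df)
    elif test == "student_t":
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * va + (b.size - 1) * vb) / df
        se2 = sp2 * (1.0 / a.size + 1.0 / b.size)
        if se2 == 0:
            stat, p = 0.0, 1.0
        else:
            stat = (ma - mb) / np.sqrt(se2)
            p = 2.0 * sps.t.sf(abs(stat), df)
    elif test == "ks":
        stat, p = _ks_2sample(a, b)
    else:
        raise ValueError(f"unknown test {test!r}")

    return ComparisonResult(
        group_a=group_a, group_b=group_b, n_a=int(a.size), n_b=int(b.size),
        mean_a=float(ma), mean_b=float(mb),
        sem_a=float(np.sqrt(va / a.size)) if a.size > 1 else float("nan"),
        sem_b=float(np.sqrt(vb / b.size)) if b.size > 1 else float("nan"),
        percent_change=float(100.0 * (ma - mb) / mb) if mb != 0 else float("nan"),
        test=test, statistic=float(stat), p_value=float(min(max(p, 0.0), 1.0)),
    )


def summarize_condition(
    values: Sequence[float], condition: Optional[str] = None
) -> dict:
    """Mean, sample sd (n-1), standard error of the mean, and n."""
    v = np.asarray(values, float)
    if v.size < 1:
        raise ValueError("need at least one value")
    sd = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    return {
        "condition": condition,
        "mean": float(v.mean()),
        "sd": sd,
        "sem": sd / np.sqrt(v.size) if v.size > 1 else float("nan"),
        "n": int(v.size),
    }


# ---------------------------------------------------------------------------
# null calibration
# ---------------------------------------------------------------------------

def type_i_error(
    test: str,
    n_per_group: int = 10,
    n_simulations: int = 10_000,
    alpha: float = 0.05,
    seed: Optional[int] = None,
) -> float:
    """Empirical rejection rate under the standard-normal null.

    Vectorized for the t-tests; the KS path evaluates each replicate.
    """
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_simulations, n_per_group))
    b = rng.standard_normal((n_simulations, n_per_group))
    n = n_per_group
    if test in ("welch_t", "student_t"):
        va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        diff = a.mean(axis=1) - b.mean(axis=1)
        if test == "welch_t":
            se2 = va / n + vb / n
            stat = diff / np.sqrt(se2)
            df = se2**2 / ((va / n) ** 2 / (n - 1) + (vb / n) ** 2 / (n - 1))
        else:
            df = np.full(n_simulations, 2 * n - 2)
            sp2 = ((n - 1) * va + (n - 1) * vb) / (2 * n - 2)
            stat = diff / np.sqrt(sp2 * (2.0 / n))
        p = 2.0 * sps.t.sf(np.abs(stat), df)
    elif test == "ks":
        # D for equal sample sizes via ranks of pooled sample
        order = np.argsort(np.concatenate([a, b], axis=1), axis=1)
        is_a = (order < n).astype(float)
        steps = np.where(is_a > 0, 1.0 / n, -1.0 / n)
        d = np.abs(np.cumsum(steps, axis=1)).max(axis=1)
        en = np.sqrt(n / 2.0)
        p = sps.kstwobign.sf((en + 0.12 + 0.11 / en) * d)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(np.mean(p <= alpha))
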