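"""Exposure-risk ratios, cumulative-high classification and quintiles.

The exposure-risk ratio (ERR) for group j is

    [sum_i w_i p_ij / sum_i p_ij] / [sum_i w_i t_i / sum_i t_i]

with w_i the tract exposure prevalence, p_ij the group population and t_i
the tract population; ERR > 1 means the group is over-represented among the
exposed.  Cumulative ERR substitutes the product of the workplace and
transportation prevalences for w_i.  CIs come from resampling whole tracts
with replacement (default 100 replicates), reported as the 50th / 2.5th /
97.5th percentiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ERRResult",
    "compute_err",
    "compute_cumulative_err",
    "bootstrap_err",
    "classify_cumulative_high",
    "assign_quintiles",
]


@dataclass(frozen=True)
class ERRResult:
    group: str
    source: str  # 'workplace' | 'transportation' | 'cumulative'
    err: float | None
    ci_low: float | None
    ci_high: float | None
    n_bootstrap: int


def compute_err(omega: np.ndarray, group_pops: np.ndarray,
                total_pops: np.ndarray) -> float:
    """Point ERR; tracts with missing prevalence are dropped pairwise.

    Returns NaN when the denominator prevalence is zero (undefined).
    """
    omega = np.asarray(omega, dtype=float)
    p = np.asarray(group_pops, dtype=float)
    t = np.asarray(total_pops, dtype=float)
    keep = ~np.isnan(omega)
    omega, p, t = omega[keep], p[keep], t[keep]
    if p.sum() <= 0 or t.sum() <= 0:
        raise ValueError("group and total populations must sum to > 0")
    num = (omega * p).sum() / p.sum()
    den = (omega * t).sum() / t.sum()
    if den == 0:
        return float("nan")
    return float(num / den)


def compute_cumulative_err(omega_work: np.ndarray, omega_transport: np.ndarray,
                           group_pops: np.ndarray, total_pops: np.ndarray) -> float:
    """ERR with w_i replaced by the product of the two source prevalences.

    Tracts missing either prevalence are dropped pairwise.
    """
    w = np.asarray(omega_work, dtype=float) * np.asarray(omega_transport, dtype=float)
    return compute_err(w, group_pops, total_pops)


def bootstrap_err(
    omega: np.ndarray | tuple[np.ndarray, np.ndarray],
    group_pops: np.ndarray,
    total_pops: np.ndarray,
    group: str = "",
    source: str = "workplace",
    n_boot: int = 100,
    seed: int = 0,
) -> ERRResult:
    """Tract-resampling bootstrap of the ERR.

    ``omega`` is either one prevalence vector or, for ``source='cumulative'``,
    the (workplace, transportation) pair.  The central estimate is the 50th
    percentile of replicates; the CI the 2.5th/97.5th.
    """
    if source == "cumulative":
        ow, ot = omega
        w = np.asarray(ow, dtype=float) * np.asarray(ot, dtype=float)
    else:
        w = np.asarray(omega, dtype=float)
    p = np.asarray(group_pops, dtype=float)
    t = np.asarray(total_pops, dtype=float)
    n = len(w)
    if n < 2:
        raise ValueError("bootstrap requires >= 2 tracts")
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            reps[b] = compute_err(w[idx], p[idx], t[idx])
        except ValueError:
            reps[b] = np.nan
    valid = reps[~np.isnan(reps)]
    if valid.size == 0:
        warnings.warn(f"all {n_boot} bootstrap replicates undefined for "
                      f"group={group!r} source={source!r}")
        return ERRResult(group, source, None, None, None, n_boot)
    lo, mid, hi = np.percentile(valid, [2.5, 50.0, 97.5])
    return ERRResult(group, source, float(mid), float(lo), float(hi), n_boot)


def classify_cumulative_high(workplace: pd.DataFrame,
                             transport: pd.DataFrame) -> pd.DataFrame:
    """Flag tracts above the 75th percentile of both prevalence distributions.

    Percentile standing is the weak empirical CDF (percent of non-excluded
    tracts with a value <= this tract's), so ``high_both`` is exactly
    "both percentiles > 75"; for all-distinct values this coincides with
    being strictly above the linearly interpolated 75th percentile.
    """
    w = workplace.loc[~workplace["excluded"].astype(bool),
                      ["tract_id", "omega"]].rename(columns={"omega": "omega_work"})
    t = transport.loc[~transport["excluded"].astype(bool),
                      ["tract_id", "omega"]].rename(columns={"omega": "omega_trans"})
    merged = w.merge(t, on="tract_id", how="inner")

    def weak_pctile(x: pd.Series) -> np.ndarray:
        v = x.to_numpy(dtype=float)
        order = np.argsort(v, kind="mergesort")
        # weak CDF: share of values <= v_i, ties handled via searchsorted
        sorted_v = v[order]
        return 100.0 * np.searchsorted(sorted_v, v, side="right") / len(v)

    merged["workplace_pctile"] = weak_pctile(merged["omega_work"])
    merged["transport_pctile"] = weak_pctile(merged["omega_trans"])
    merged["high_both"] = (merged["workplace_pctile"] > 75.0) & \
                          (merged["transport_pctile"] > 75.0)
    return merged[["tract_id", "high_both", "workplace_pctile",
                   "transport_pctile", "omega_work", "omega_trans"]]


def assign_quintiles(values: pd.Series, strata: pd.Series,
                     tract_ids: pd.Series | None = None,
                     group: str = "") -> pd.DataFrame:
    """Stratum-specific quintiles of a tract-level composition variable.

    Boundaries are the 20/40/60/80th percentiles (linear interpolation)
    within each stratum; bins are right-closed (value <= 20th percentile is
    quintile 1) so an all-equal stratum collapses to quintile 1.  Strata
    with fewer than 5 tracts get a warning but the same rank-band rule.
    """
    values = values.reset_index(drop=True)
    strata = strata.reset_index(drop=True).astype(str)
    if tract_ids is None:
        tract_ids = pd.Series(np.arange(len(values)).astype(str))
    tract_ids = tract_ids.reset_index(drop=True)
    out = np.empty(len(values), dtype=int)
    for label, idx in values.groupby(strata).groups.items():
        sub = values.loc[idx].to_numpy(dtype=float)
        if len(sub) < 5:
            warnings.warn(f"stratum {label!r} has only {len(sub)} tracts; "
                          "quintiles follow empirical rank bands")
        bounds = np.percentile(sub, [20, 40, 60, 80])
        out[np.asarray(idx)] = 1 + (sub[:, None] > bounds[None, :]).sum(axis=1)
    return pd.DataFrame({
        "tract_id": tract_ids,
        "group": group,
        "quintile": out,
        "stratum": strata,
    })
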