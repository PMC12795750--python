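"""Monte Carlo estimation of tract-level workplace noise-exposure prevalence.

Each occupational group's 8-h TWA noise is modelled as normal on the dBA
scale with JEM-supplied mean/SD.  Per Monte Carlo iteration the number of
exposed workers in a group is an exact Binomial(employment, tail probability)
draw — distributionally equivalent to sampling one TWA per worker and
thresholding, but orders of magnitude faster.  Tract prevalence is the
employment-weighted exposed fraction; the reported estimate and CI are the
50th and 2.5th/97.5th percentiles across iterations.  Tracts with <=20
workers are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic_data import employment_columns, occupation_of

__all__ = [
    "JEMEntry",
    "PrevalenceEstimate",
    "MissingJEMGroupError",
    "NIOSH_REL_DBA",
    "WORKER_EXCLUSION_THRESHOLD",
    "group_exceedance_probability",
    "estimate_workplace_prevalence",
    "workplace_prevalence_table",
    "analytic_workplace_prevalence",
]

#: Hazardous-workplace-noise threshold (8-h TWA).
NIOSH_REL_DBA = 85.0
#: Tracts with worker counts at or below this are excluded.
WORKER_EXCLUSION_THRESHOLD = 20


class MissingJEMGroupError(KeyError):
    """An employment group present in the tract has no JEM entry."""

    def __init__(self, group: str):
        super().__init__(group)
        self.group = group

    def __str__(self) -> str:
        return f"occupational group {self.group!r} is missing from the JEM"


@dataclass(frozen=True)
class JEMEntry:
    group_id: str
    mean_twa: float
    sd_twa: float

    def __post_init__(self) -> None:
        if self.sd_twa <= 0:
            raise ValueError(f"sd_twa must be > 0, got {self.sd_twa}")

    def exceedance(self, threshold: float = NIOSH_REL_DBA) -> float:
        """Analytic P(TWA > threshold)."""
        return float(norm.sf((threshold - self.mean_twa) / self.sd_twa))


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Per-tract exposed proportion with Monte Carlo percentile CI."""

    tract_id: str
    source: str  # 'workplace' | 'transportation'
    omega: float | None
    ci_low: float | None
    ci_high: float | None
    n_iterations: int
    excluded: bool = False
    reason: str | None = None


def group_exceedance_probability(entry: JEMEntry, threshold: float = NIOSH_REL_DBA,
                                 n_draws: int = 10_000, seed: int = 0) -> float:
    """Monte Carlo P(TWA > threshold) for one occupational group.

    Converges to ``1 - Phi((threshold - mean) / sd)`` as draws grow.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.normal(entry.mean_twa, entry.sd_twa, size=n_draws)
    return float(np.mean(draws > threshold))


def _jem_lookup(jem: pd.DataFrame) -> dict[str, JEMEntry]:
    return {
        row.group_id: JEMEntry(row.group_id, float(row.mean_twa), float(row.sd_twa))
        for row in jem.itertuples()
    }


def estimate_workplace_prevalence(
    employment: Mapping[str, int],
    jem: pd.DataFrame,
    tract_id: str = "",
    threshold: float = NIOSH_REL_DBA,
    n_iterations: int = 1000,
    seed: int = 0,
) -> PrevalenceEstimate:
    """Estimate the proportion of one tract's workers above ``threshold``.

    ``employment`` maps occupational-group id to worker count.  Raises
    :class:`MissingJEMGroupError` if a group with workers lacks a JEM row.
    """
    entries = _jem_lookup(jem)
    groups = [g for g, c in employment.items() if c > 0]
    for g in groups:
        if g not in entries:
            raise MissingJEMGroupError(g)
    workers = int(sum(employment.values()))
    if workers <= WORKER_EXCLUSION_THRESHOLD:
        return PrevalenceEstimate(tract_id, "workplace", None, None, None,
                                  n_iterations, excluded=True,
                                  reason=f"<=({WORKER_EXCLUSION_THRESHOLD}) workers")
    emp = np.array([employment[g] for g in groups], dtype=np.int64)
    p = np.array([entries[g].exceedance(threshold) for g in groups])
    rng = np.random.default_rng(seed)
    exposed = rng.binomial(emp[None, :], p[None, :], size=(n_iterations, len(groups)))
    omega_iter = exposed.sum(axis=1) / workers
    lo, mid, hi = np.percentile(omega_iter, [2.5, 50.0, 97.5])
    return PrevalenceEstimate(tract_id, "workplace", float(mid), float(lo),
                              float(hi), n_iterations)


def workplace_prevalence_table(
    tracts: pd.DataFrame,
    jem: pd.DataFrame,
    threshold: float = NIOSH_REL_DBA,
    n_iterations: int = 1000,
    seed: int = 0,
    chunk_size: int = 256,
) -> pd.DataFrame:
    """Vectorised workplace prevalence for every tract in the table.

    Output columns: tract_id, source, omega, ci_low, ci_high, n_iterations,
    excluded, reason.  Deterministic given (table order, seed).
    """
    emp_cols = employment_columns(tracts)
    entries = _jem_lookup(jem)
    for col in emp_cols:
        g = occupation_of(col)
        if g not in entries and tracts[col].sum() > 0:
            raise MissingJEMGroupError(g)
    p = np.array([entries[occupation_of(c)].exceedance(threshold)
                  if occupation_of(c) in entries else 0.0
                  for c in emp_cols])
    emp = tracts[emp_cols].to_numpy(dtype=np.int64)
    workers = emp.sum(axis=1)
    rng = np.random.default_rng(seed)

    n = len(tracts)
    omega = np.full(n, np.nan)
    lo = np.full(n, np.nan)
    hi = np.full(n, np.nan)
    included = workers > WORKER_EXCLUSION_THRESHOLD
    for start in range(0, n, chunk_size):
        idx = np.arange(start, min(start + chunk_size, n))
        idx = idx[included[idx]]
        if idx.size == 0:
            continue
        draws = rng.binomial(emp[idx][None, :, :], p[None, None, :],
                             size=(n_iterations, idx.size, len(emp_cols)))
        omega_iter = draws.sum(axis=2) / workers[idx][None, :]
        q = np.percentile(omega_iter, [2.5, 50.0, 97.5], axis=0)
        lo[idx], omega[idx], hi[idx] = q[0], q[1], q[2]

    return pd.DataFrame({
        "tract_id": tracts["tract_id"],
        "source": "workplace",
        "omega": omega,
        "ci_low": lo,
        "ci_high": hi,
        "n_iterations": n_iterations,
        "excluded": ~included,
        "reason": np.where(included, "",
                           f"<=({WORKER_EXCLUSION_THRESHOLD}) workers"),
    })


def analytic_workplace_prevalence(employment: Mapping[str, int], jem: pd.DataFrame,
                                  threshold: float = NIOSH_REL_DBA) -> float:
    """Closed-form employment-weighted expected exposed fraction (the large-
    iteration limit of the Monte Carlo estimate)."""
    entries = _jem_lookup(jem)
    total = sum(employment.values())
    if total == 0:
        return float("nan")
    acc = 0.0
    for g, c in employment.items():
        if c > 0:
            acc += c * entries[g].exceedance(threshold)
    return acc / total
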