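"""Population-weighted Monte Carlo aggregation of block noise levels.

Block 24-h L_Aeq values are perturbed with configurable normal noise per
iteration, blocks are classified exposed when the perturbed level is
strictly above the threshold (default 55 dBA), and the tract estimate is
the population-weighted exposed fraction summarised by 50th / 2.5th / 97.5th
percentiles.  With ``level_uncertainty_sd = 0`` the procedure reduces to the
deterministic population fraction in blocks above the threshold.  Tracts
with <=20 residents are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .workplace_noise import PrevalenceEstimate

__all__ = [
    "TransportConfig",
    "AggregateResult",
    "RESIDENT_EXCLUSION_THRESHOLD",
    "estimate_transport_prevalence",
    "transport_prevalence_table",
    "aggregate_exposed",
    "exposed_percentage",
]

RESIDENT_EXCLUSION_THRESHOLD = 20


@dataclass(frozen=True)
class TransportConfig:
    threshold: float = 55.0
    level_uncertainty_sd: float = 2.0
    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.level_uncertainty_sd < 0:
            raise ValueError("level_uncertainty_sd must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass(frozen=True)
class AggregateResult:
    """Exposed count/percentage over a set of tracts."""

    exposed: float
    percentage: float
    ci_low: float | None
    ci_high: float | None
    population: float
    n_tracts: int


def estimate_transport_prevalence(
    blocks: pd.DataFrame, config: TransportConfig, tract_id: str | None = None,
) -> PrevalenceEstimate:
    """Tract-level exposed proportion from that tract's block table.

    ``blocks`` must have ``population`` and ``laeq_24h`` columns (one tract).
    """
    if len(blocks) == 0:
        raise ValueError("blocks table is empty")
    if (blocks["population"] < 0).any():
        raise ValueError("block populations must be >= 0")
    tid = tract_id if tract_id is not None else str(blocks["tract_id"].iloc[0]) \
        if "tract_id" in blocks.columns else ""
    pops = blocks["population"].to_numpy(dtype=float)
    total = pops.sum()
    if total == 0:
        return PrevalenceEstimate(tid, "transportation", None, None, None,
                                  config.n_iterations, excluded=True,
                                  reason="zero population")
    if total <= RESIDENT_EXCLUSION_THRESHOLD:
        return PrevalenceEstimate(tid, "transportation", None, None, None,
                                  config.n_iterations, excluded=True,
                                  reason=f"<=({RESIDENT_EXCLUSION_THRESHOLD}) residents")
    levels = blocks["laeq_24h"].to_numpy(dtype=float)
    rng = np.random.default_rng(config.seed)
    if config.level_uncertainty_sd == 0:
        frac = float(pops[levels > config.threshold].sum() / total)
        return PrevalenceEstimate(tid, "transportation", frac, frac, frac,
                                  config.n_iterations)
    noise = rng.normal(0.0, config.level_uncertainty_sd,
                       size=(config.n_iterations, len(levels)))
    exposed = (levels[None, :] + noise) > config.threshold
    omega_iter = exposed @ pops / total
    lo, mid, hi = np.percentile(omega_iter, [2.5, 50.0, 97.5])
    return PrevalenceEstimate(tid, "transportation", float(mid), float(lo),
                              float(hi), config.n_iterations)


def transport_prevalence_table(blocks: pd.DataFrame,
                               config: TransportConfig) -> pd.DataFrame:
    """Per-tract transportation prevalence for a multi-tract block table.

    Tracts are processed in first-appearance order with per-tract seed
    substreams, so results are deterministic given (table order, seed).
    """
    rows = []
    children = np.random.SeedSequence(config.seed)
    tract_ids = blocks["tract_id"].drop_duplicates().tolist()
    seeds = children.spawn(len(tract_ids))
    grouped = blocks.groupby("tract_id", sort=False)
    for tid, sub_seed in zip(tract_ids, seeds):
        sub = grouped.get_group(tid)
        cfg = TransportConfig(config.threshold, config.level_uncertainty_sd,
                              config.n_iterations,
                              seed=int(sub_seed.generate_state(1)[0] % (2**31)))
        est = estimate_transport_prevalence(sub, cfg, tract_id=str(tid))
        rows.append({
            "tract_id": tid, "source": "transportation",
            "omega": np.nan if est.omega is None else est.omega,
            "ci_low": np.nan if est.ci_low is None else est.ci_low,
            "ci_high": np.nan if est.ci_high is None else est.ci_high,
            "n_iterations": est.n_iterations,
            "excluded": est.excluded,
            "reason": est.reason or "",
        })
    return pd.DataFrame(rows)


def exposed_percentage(exposed_count: float, total_population: float) -> float:
    """Percentage of a population exposed, 100 * count / total."""
    if total_population <= 0:
        raise ValueError("total population must be > 0")
    return 100.0 * exposed_count / total_population


def aggregate_exposed(
    prevalences: pd.DataFrame,
    populations: pd.Series | pd.DataFrame,
    by: pd.Series | None = None,
) -> AggregateResult | dict[str, AggregateResult]:
    """Aggregate per-tract prevalence estimates to exposed counts/percentages.

    ``populations`` is indexed or keyed by tract_id (Series, or DataFrame with
    tract_id/population columns).  ``by`` optionally maps tract_id to a
    grouping label (county/metro); omitted means one nationwide aggregate.
    CIs are propagated from per-tract percentile CIs under a normal
    approximation with independent tracts.
    """
    if isinstance(populations, pd.DataFrame):
        populations = populations.set_index("tract_id")["population"]
    frame = prevalences.loc[~prevalences["excluded"].astype(bool)].copy()
    if len(frame) == 0:
        raise ValueError("no non-excluded prevalence estimates to aggregate")
    frame["population"] = frame["tract_id"].map(populations)
    if frame["population"].isna().any():
        missing = frame.loc[frame["population"].isna(), "tract_id"].iloc[0]
        raise KeyError(f"no population for tract {missing!r}")

    def _agg(sub: pd.DataFrame) -> AggregateResult:
        pop = sub["population"].to_numpy(dtype=float)
        omega = sub["omega"].to_numpy(dtype=float)
        count = float((pop * omega).sum())
        total = float(pop.sum())
        pct = exposed_percentage(count, total)
        ci_lo = ci_hi = None
        if sub[["ci_low", "ci_high"]].notna().all().all():
            sd_i = (sub["ci_high"] - sub["ci_low"]).to_numpy(dtype=float) / 3.92
            var = float(((pop * sd_i) ** 2).sum())
            half = 1.96 * np.sqrt(var)
            ci_lo, ci_hi = count - half, count + half
        return AggregateResult(count, pct, ci_lo, ci_hi, total, len(sub))

    if by is None:
        return _agg(frame)
    frame["_group"] = frame["tract_id"].map(by)
    return {str(k): _agg(sub) for k, sub in frame.groupby("_group")}
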