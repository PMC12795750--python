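"""Seeded synthetic census-geography generator.

Produces tract, block, job-exposure-matrix (JEM), HOLC-overlap and mortgage
tables whose statistical structure mimics the national inputs the analysis
pipeline expects: spatially clustered racial/ethnic composition within
metropolitan areas, composition-linked occupational sorting and block noise
levels, redlining overlap correlated with minority share, and discriminatory
lending in designated tracts.  Ground-truth effect sizes are recorded
alongside the tables for parameter-recovery testing and are never consumed
by the analysis stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "GroundTruth",
    "RACE_GROUPS",
    "MINORITY_GROUPS",
    "OCC_GROUPS",
    "NOISY_OCC_GROUPS",
    "generate_geography",
    "generate_jem",
    "generate_structural",
    "permutation_rank_test",
    "write_tables",
    "read_tables",
]

#: Racial/ethnic groups; exhaustive and mutually exclusive, counts sum to the
#: tract population.  ``nh_white`` is the non-minority reference.
RACE_GROUPS = ("nh_white", "nh_black", "hispanic", "nh_asian", "nh_aian", "nh_nhpi")
MINORITY_GROUPS = RACE_GROUPS[1:]

#: 22 major occupational groups (SOC-style granularity).
OCC_GROUPS = tuple(f"occ_{i:02d}" for i in range(1, 23))
#: Groups treated as "noisy" by the generator (construction/production-like).
NOISY_OCC_GROUPS = ("occ_17", "occ_18", "occ_19", "occ_20", "occ_21", "occ_22")

_EMP_PREFIX = "emp_"


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration values."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic geography generator.

    ``beta_transport`` shifts the mean block noise level (dBA) per unit tract
    minority proportion; ``beta_occupation`` shifts the log-odds of employment
    in noisy occupational groups per unit minority proportion.
    """

    n_metro_areas: int = 4
    tracts_per_metro: int = 40
    nonmetro_tracts: int = 40
    blocks_per_tract: tuple[int, int] = (2, 6)
    mean_tract_population: int = 4000
    minority_cluster_strength: float = 1.0
    beta_transport: float = 0.0
    beta_occupation: float = 0.0
    redline_fraction: float = 0.3
    discrimination_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_metro_areas": self.n_metro_areas,
            "tracts_per_metro": self.tracts_per_metro,
            "nonmetro_tracts": self.nonmetro_tracts,
            "mean_tract_population": self.mean_tract_population,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        lo, hi = self.blocks_per_tract
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                f"blocks_per_tract must be a (min, max) range with 1 <= min <= max, "
                f"got {self.blocks_per_tract}"
            )
        for name in ("redline_fraction", "discrimination_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.minority_cluster_strength < 0:
            raise ConfigurationError("minority_cluster_strength must be >= 0")

    @property
    def n_tracts(self) -> int:
        return self.n_metro_areas * self.tracts_per_metro + self.nonmetro_tracts


@dataclass
class GroundTruth:
    """Generator-side truth recorded next to the tables, never read by the
    analysis stages."""

    beta_transport: float
    beta_occupation: float
    tract_ids: list[str]
    expected_workplace_prevalence: list[float]
    expected_transport_prevalence: list[float]
    implied_q5_q1_log_or: float

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GroundTruth":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        return cls(**data)


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    # One master seed; named substreams so each table is independently
    # reproducible regardless of which generate_* functions run.
    children = np.random.SeedSequence(seed).spawn(6)
    names = ("geography", "population", "employment", "blocks", "jem", "structural")
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


# ---------------------------------------------------------------------------
# JEM
# ---------------------------------------------------------------------------

def generate_jem(groups: Sequence[str], config: GeneratorConfig) -> pd.DataFrame:
    """Per-group mean and SD of 8-h TWA noise (dBA).

    Groups listed in :data:`NOISY_OCC_GROUPS` get means near/above the 85 dBA
    hazard threshold; all others sit well below it.
    """
    if len(groups) < 2:
        raise ConfigurationError("JEM requires at least 2 occupational groups")
    rng = _substreams(config.seed)["jem"]
    rows = []
    for g in groups:
        if g in NOISY_OCC_GROUPS:
            mean = rng.uniform(84.0, 92.0)
            sd = rng.uniform(3.0, 6.0)
        else:
            mean = rng.uniform(62.0, 76.0)
            sd = rng.uniform(2.0, 5.0)
        rows.append({"group_id": g, "mean_twa": mean, "sd_twa": sd})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def _smoothed_field(rng: np.random.Generator, gx: np.ndarray, gy: np.ndarray,
                    length_scale: float = 2.0) -> np.ndarray:
    """Gaussian-kernel-smoothed white noise over grid coordinates, scaled to
    unit variance; the spatial autocorrelation backbone of minority share."""
    z = rng.normal(size=gx.size)
    d2 = (gx[:, None] - gx[None, :]) ** 2 + (gy[:, None] - gy[None, :]) ** 2
    k = np.exp(-d2 / (2.0 * length_scale**2))
    smoothed = k @ z / k.sum(axis=1)
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def _base_occupation_logits() -> np.ndarray:
    # Fixed, deterministic baseline employment mix: white-collar-heavy with a
    # moderate industrial tail, loosely shaped like national major-group shares.
    base = np.linspace(1.0, 0.35, len(OCC_GROUPS))
    return np.log(base / base.sum())


def generate_geography(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate the tract and block tables plus recorded ground truth.

    Tracts are partitioned into metro areas (RUCA 1-3) and one nonmetro
    stratum (RUCA 4-10).  Minority proportion is spatially autocorrelated
    within each metro; block noise means and noisy-occupation log-odds shift
    with the configured effect sizes.
    """
    rngs = _substreams(config.seed)
    rng_geo, rng_pop = rngs["geography"], rngs["population"]
    rng_emp, rng_block = rngs["employment"], rngs["blocks"]

    records: list[dict] = []
    minority_props: list[float] = []

    for m in range(config.n_metro_areas):
        metro_id = f"M{m + 1:03d}"
        center_lat = rng_geo.uniform(27.0, 47.0)
        center_lon = rng_geo.uniform(-122.0, -72.0)
        n = config.tracts_per_metro
        side = int(np.ceil(np.sqrt(n)))
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        gx, gy = gx.ravel()[:n].astype(float), gy.ravel()[:n].astype(float)
        field = _smoothed_field(rng_geo, gx, gy)
        metro_minority = rng_geo.uniform(0.15, 0.55)
        lo = logit(metro_minority) + config.minority_cluster_strength * field \
            + 0.3 * rng_geo.normal(size=n)
        minority = expit(lo)
        # metro-level split of the minority share across the five groups
        split = rng_geo.dirichlet([4.0, 4.0, 2.0, 0.5, 0.3])
        for i in range(n):
            records.append({
                "tract_id": f"{metro_id}-T{i + 1:04d}",
                "metro_id": metro_id,
                "ruca_code": int(rng_geo.integers(1, 4)),
                "centroid_lat": center_lat + 0.05 * gy[i] + rng_geo.normal(0, 0.01),
                "centroid_lon": center_lon + 0.05 * gx[i] + rng_geo.normal(0, 0.01),
                "_minority": float(minority[i]),
                "_split": split,
                "_urban": True,
            })
            minority_props.append(float(minority[i]))

    for i in range(config.nonmetro_tracts):
        minority = float(rng_geo.beta(1.5, 6.0))
        split = rng_geo.dirichlet([4.0, 4.0, 2.0, 0.5, 0.3])
        records.append({
            "tract_id": f"NM-T{i + 1:04d}",
            "metro_id": "",
            "ruca_code": int(rng_geo.integers(4, 11)),
            "centroid_lat": rng_geo.uniform(26.0, 48.0),
            "centroid_lon": rng_geo.uniform(-123.0, -70.0),
            "_minority": minority,
            "_split": split,
            "_urban": False,
        })
        minority_props.append(minority)

    base_logits = _base_occupation_logits()
    noisy_mask = np.array([g in NOISY_OCC_GROUPS for g in OCC_GROUPS], dtype=float)

    tract_rows = []
    block_rows = []
    tract_mu = []  # realized tract-mean block noise level

    for rec in records:
        minority = rec["_minority"]
        population = max(int(rng_pop.poisson(config.mean_tract_population)), 25)
        probs = np.concatenate(([1.0 - minority], minority * rec["_split"]))
        group_counts = rng_pop.multinomial(population, probs)
        workers = int(rng_pop.binomial(population, 0.47))
        occ_logits = base_logits + config.beta_occupation * minority * noisy_mask
        occ_probs = np.exp(occ_logits) / np.exp(occ_logits).sum()
        employment = rng_emp.multinomial(workers, occ_probs)

        row = {
            "tract_id": rec["tract_id"],
            "metro_id": rec["metro_id"],
            "ruca_code": rec["ruca_code"],
            "population": population,
            "workers": workers,
            "pct_unemployed": float(np.clip(
                expit(-2.7 + 0.8 * minority + 0.3 * rng_pop.normal()), 0, 1)),
            "pct_low_income": float(np.clip(
                expit(-1.2 + 1.2 * minority + 0.3 * rng_pop.normal()), 0, 1)),
            "pct_no_diploma": float(np.clip(
                expit(-2.0 + 1.0 * minority + 0.3 * rng_pop.normal()), 0, 1)),
            "pop_density": float(np.exp(
                rng_pop.normal(7.5 if rec["_urban"] else 4.0, 1.0))),
            "centroid_lat": rec["centroid_lat"],
            "centroid_lon": rec["centroid_lon"],
        }
        for g, c in zip(RACE_GROUPS, group_counts):
            row[g] = int(c)
        for g, c in zip(OCC_GROUPS, employment):
            row[_EMP_PREFIX + g] = int(c)
        tract_rows.append(row)

        # blocks: exact partition of the tract population
        n_blocks = int(rng_block.integers(config.blocks_per_tract[0],
                                          config.blocks_per_tract[1] + 1))
        block_pops = rng_block.multinomial(population, np.full(n_blocks, 1.0 / n_blocks))
        # nonmetro tracts are mostly quiet, with a highway-corridor minority
        if rec["_urban"] or rng_block.random() < 0.15:
            base_level = rng_block.normal(52.0, 3.0)
        else:
            base_level = rng_block.normal(44.0, 3.0)
        mu = base_level + config.beta_transport * minority
        tract_mu.append(mu)
        levels = rng_block.normal(mu, 4.0, size=n_blocks)
        for b in range(n_blocks):
            block_rows.append({
                "block_id": f"{rec['tract_id']}-B{b + 1:03d}",
                "tract_id": rec["tract_id"],
                "population": int(block_pops[b]),
                "laeq_24h": float(levels[b]),
            })

    tracts = pd.DataFrame(tract_rows)
    blocks = pd.DataFrame(block_rows)

    truth = _ground_truth(config, tracts, np.asarray(minority_props),
                          np.asarray(tract_mu), occ_noisy_mask=noisy_mask,
                          base_logits=base_logits)
    return tracts, blocks, truth


def _ground_truth(config: GeneratorConfig, tracts: pd.DataFrame,
                  minority: np.ndarray, tract_mu: np.ndarray,
                  occ_noisy_mask: np.ndarray, base_logits: np.ndarray) -> GroundTruth:
    jem = generate_jem(OCC_GROUPS, config)
    tail = norm.sf((85.0 - jem["mean_twa"].to_numpy()) / jem["sd_twa"].to_numpy())
    logits = base_logits[None, :] + config.beta_occupation * minority[:, None] * occ_noisy_mask[None, :]
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    exp_work = probs @ tail
    exp_trans = norm.sf((55.0 - tract_mu) / 4.0)

    implied = _implied_log_or(tracts, minority, exp_work, exp_trans)
    return GroundTruth(
        beta_transport=float(config.beta_transport),
        beta_occupation=float(config.beta_occupation),
        tract_ids=tracts["tract_id"].tolist(),
        expected_workplace_prevalence=[float(v) for v in exp_work],
        expected_transport_prevalence=[float(v) for v in exp_trans],
        implied_q5_q1_log_or=float(implied),
    )


def _implied_log_or(tracts: pd.DataFrame, minority: np.ndarray,
                    exp_work: np.ndarray, exp_trans: np.ndarray) -> float:
    """Descriptive Q5-vs-Q1 log odds ratio of the expected cumulative-high
    flag against pooled minority-share quintiles (Haldane-corrected)."""
    hw = exp_work > np.percentile(exp_work, 75)
    ht = exp_trans > np.percentile(exp_trans, 75)
    flag = hw & ht
    ranks = rankdata(minority, method="average")
    quint = np.ceil(5.0 * ranks / len(ranks)).astype(int)
    n5, n1 = (quint == 5).sum(), (quint == 1).sum()
    a5, a1 = flag[quint == 5].sum(), flag[quint == 1].sum()
    odds5 = (a5 + 0.5) / (n5 - a5 + 0.5)
    odds1 = (a1 + 0.5) / (n1 - a1 + 0.5)
    return np.log(odds5 / odds1)


# ---------------------------------------------------------------------------
# Structural tables (HOLC overlap, mortgage lending)
# ---------------------------------------------------------------------------

def generate_structural(
    tracts: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """HOLC grade-overlap proportions and mortgage loan/household counts.

    ``redline_fraction`` of urban tracts receive HOLC coverage with grade-D
    share increasing in minority proportion.  Among redlined tracts a
    ``discrimination_fraction`` Bernoulli draw designates tracts whose loan
    counts are constructed to give a discrimination index D < 1; all other
    tracts get proportional lending (D >= 1, ~1).
    """
    rng = _substreams(config.seed)["structural"]
    urban = tracts[tracts["ruca_code"] <= 3]
    n_red = int(round(config.redline_fraction * len(urban)))
    redlined_ids = (
        rng.choice(urban["tract_id"].to_numpy(), size=n_red, replace=False)
        if n_red > 0 else np.array([], dtype=object)
    )
    redlined = set(redlined_ids.tolist())

    minority_share = 1.0 - tracts["nh_white"] / tracts["population"]
    share_by_id = dict(zip(tracts["tract_id"], minority_share))
    pop_by_id = dict(zip(tracts["tract_id"], tracts["population"]))

    holc_rows = []
    for tid in redlined_ids:
        m = share_by_id[tid]
        total_graded = float(rng.uniform(0.15, 1.0))
        shares = rng.dirichlet([0.5 + 3.0 * (1.0 - m), 1.0, 1.0, 0.5 + 3.0 * m])
        holc_rows.append({
            "tract_id": tid,
            "overlap_a": shares[0] * total_graded,
            "overlap_b": shares[1] * total_graded,
            "overlap_c": shares[2] * total_graded,
            "overlap_d": shares[3] * total_graded,
            "total_graded": total_graded,
        })
    holc = pd.DataFrame(
        holc_rows,
        columns=["tract_id", "overlap_a", "overlap_b", "overlap_c",
                 "overlap_d", "total_graded"],
    )

    mortgage_rows = []
    for tid in urban["tract_id"]:
        m = share_by_id[tid]
        h_total = max(int(round(pop_by_id[tid] / 2.5)), 2)
        h_minority = min(max(int(round(m * h_total)), 1), h_total)
        hshare = h_minority / h_total
        l_total = max(int(rng.poisson(0.4 * h_total)), 1)
        designated = tid in redlined and rng.random() < config.discrimination_fraction
        if designated:
            # floor(0.5 * proportional) guarantees loan share < household share
            l_minority = int(np.floor(0.5 * l_total * hshare))
        else:
            l_minority = int(round(l_total * hshare))
            if l_minority / l_total < hshare:  # keep D >= 1 after rounding
                l_minority += 1
            l_minority = min(l_minority, l_total)
        mortgage_rows.append({
            "tract_id": tid,
            "loans_minority": l_minority,
            "loans_total": l_total,
            "households_minority": h_minority,
            "households_total": h_total,
        })
    mortgage = pd.DataFrame(
        mortgage_rows,
        columns=["tract_id", "loans_minority", "loans_total",
                 "households_minority", "households_total"],
    )
    return holc, mortgage


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def permutation_rank_test(
    x: np.ndarray, y: np.ndarray, n_permutations: int = 1000,
    seed: int = 0, alternative: str = "greater",
) -> tuple[float, float]:
    """Spearman rank correlation with a permutation p-value.

    Serves as the generator's own independent check that configured effects
    leave a detectable footprint (or that null configs do not).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x)
    rng = np.random.default_rng(seed)

    def rho(ry: np.ndarray) -> float:
        return float(np.corrcoef(rx, ry)[0, 1])

    observed = rho(rankdata(y))
    perms = np.empty(n_permutations)
    ry = rankdata(y)
    for i in range(n_permutations):
        perms[i] = rho(rng.permutation(ry))
    if alternative == "greater":
        extreme = perms >= observed
    elif alternative == "less":
        extreme = perms <= observed
    else:
        extreme = np.abs(perms) >= abs(observed)
    p = (1.0 + extreme.sum()) / (n_permutations + 1.0)
    return observed, float(p)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "tracts": "tracts.csv",
    "blocks": "blocks.csv",
    "jem": "jem.csv",
    "holc": "holc.csv",
    "mortgage": "mortgage.csv",
}


def write_tables(outdir: str | Path, tracts: pd.DataFrame, blocks: pd.DataFrame,
                 jem: pd.DataFrame, holc: pd.DataFrame, mortgage: pd.DataFrame,
                 truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write all generated tables (CSV, header row, UTF-8) plus the
    ground-truth YAML; returns the mapping of logical name to path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = {"tracts": tracts, "blocks": blocks, "jem": jem,
              "holc": holc, "mortgage": mortgage}
    paths = {}
    for name, frame in frames.items():
        path = outdir / _TABLE_FILES[name]
        frame.to_csv(path, index=False)
        paths[name] = path
    if truth is not None:
        path = outdir / "ground_truth.yaml"
        truth.to_yaml(path)
        paths["ground_truth"] = path
    return paths


def read_tables(indir: str | Path) -> dict[str, pd.DataFrame]:
    indir = Path(indir)
    out = {}
    for name, fname in _TABLE_FILES.items():
        path = indir / fname
        if path.exists():
            out[name] = pd.read_csv(path, keep_default_na=False,
                                    na_values=[""] if name != "tracts" else [])
            if name == "tracts":
                out[name]["metro_id"] = out[name]["metro_id"].astype(str)
    return out


def employment_columns(tracts: pd.DataFrame) -> list[str]:
    """Names of the per-occupational-group employment columns."""
    return [c for c in tracts.columns if c.startswith(_EMP_PREFIX)]


def occupation_of(column: str) -> str:
    return column[len(_EMP_PREFIX):]
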