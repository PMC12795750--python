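"""Pipeline orchestration: generate -> prevalence -> metrics -> indices ->
models -> report, as a configured, logged, resumable run directory.

Every stage writes CSV outputs into the run directory; ``run_pipeline``
finishes by writing a manifest recording the config hash, seed and the row
count and content hash of every output, so identical config+seed runs are
byte-verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inequity_metrics as im
from . import regression_models as rm
from . import structural_racism as sr
from . import synthetic_data as sd
from . import transportation_noise as tn
from . import workplace_noise as wn

__all__ = [
    "RunConfig",
    "PipelineStageError",
    "ValidationReport",
    "run_pipeline",
    "validate_inputs",
    "stage_generate",
    "stage_prevalence",
    "stage_metrics",
    "stage_indices",
    "stage_models",
    "write_manifest",
]

logger = logging.getLogger("noisequity")

ERR_GROUPS = ("minority",) + sd.MINORITY_GROUPS
ERR_SOURCES = ("workplace", "transportation", "cumulative")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    generator: sd.GeneratorConfig = field(default_factory=sd.GeneratorConfig)
    transport_threshold: float = 55.0
    transport_uncertainty_sd: float = 2.0
    transport_iterations: int = 500
    workplace_threshold: float = 85.0
    workplace_iterations: int = 500
    n_boot: int = 100
    quintile_mode: str = "per_metro"  # or 'pooled'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quintile_mode not in ("per_metro", "pooled"):
            raise ValueError("quintile_mode must be 'per_metro' or 'pooled'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"]["blocks_per_tract"] = list(d["generator"]["blocks_per_tract"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        gen = data.pop("generator", {})
        if "blocks_per_tract" in gen:
            gen["blocks_per_tract"] = tuple(gen["blocks_per_tract"])
        return cls(generator=sd.GeneratorConfig(**gen), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()

    def with_seed(self, seed: int) -> "RunConfig":
        gen = dataclasses.replace(self.generator, seed=seed)
        return dataclasses.replace(self, generator=gen, seed=seed)


def _seeds(config: RunConfig) -> dict[str, int]:
    children = np.random.SeedSequence(config.seed).spawn(4)
    names = ("workplace", "transport", "bootstrap", "models")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_generate(config: RunConfig, outdir: Path) -> None:
    tracts, blocks, truth = sd.generate_geography(config.generator)
    jem = sd.generate_jem(sd.OCC_GROUPS, config.generator)
    holc, mortgage = sd.generate_structural(tracts, config.generator)
    sd.write_tables(outdir, tracts, blocks, jem, holc, mortgage, truth)


def stage_prevalence(config: RunConfig, outdir: Path) -> None:
    tables = sd.read_tables(outdir)
    seeds = _seeds(config)
    work = wn.workplace_prevalence_table(
        tables["tracts"], tables["jem"], threshold=config.workplace_threshold,
        n_iterations=config.workplace_iterations, seed=seeds["workplace"])
    work.to_csv(outdir / "workplace_prevalence.csv", index=False)
    tcfg = tn.TransportConfig(
        threshold=config.transport_threshold,
        level_uncertainty_sd=config.transport_uncertainty_sd,
        n_iterations=config.transport_iterations, seed=seeds["transport"])
    trans = tn.transport_prevalence_table(tables["blocks"], tcfg)
    trans.to_csv(outdir / "transport_prevalence.csv", index=False)


def _group_populations(tracts: pd.DataFrame, group: str) -> pd.Series:
    if group == "minority":
        return tracts["population"] - tracts["nh_white"]
    return tracts[group]


def _strata(tracts: pd.DataFrame, mode: str) -> pd.Series:
    metro = tracts["metro_id"].astype(str)
    is_metro = (tracts["ruca_code"] <= 3) & (metro != "")
    if mode == "pooled":
        return pd.Series(np.where(is_metro, "metro", "nonmetro"))
    return pd.Series(np.where(is_metro, metro, "nonmetro"))


def stage_metrics(config: RunConfig, outdir: Path) -> None:
    tables = sd.read_tables(outdir)
    tracts = tables["tracts"]
    work = pd.read_csv(outdir / "workplace_prevalence.csv")
    trans = pd.read_csv(outdir / "transport_prevalence.csv")
    seeds = _seeds(config)

    flags = im.classify_cumulative_high(work, trans)
    flags.to_csv(outdir / "cumulative_flags.csv", index=False)

    # ERR table over a merged frame (pairwise-complete handled inside)
    merged = tracts.merge(
        work[["tract_id", "omega"]].rename(columns={"omega": "omega_work"}),
        on="tract_id", how="left").merge(
        trans[["tract_id", "omega"]].rename(columns={"omega": "omega_trans"}),
        on="tract_id", how="left")
    err_rows = []
    boot_seed = np.random.SeedSequence(seeds["bootstrap"])
    sub_seeds = boot_seed.spawn(len(ERR_GROUPS) * len(ERR_SOURCES))
    k = 0
    for group in ERR_GROUPS:
        p = _group_populations(merged, group).to_numpy(dtype=float)
        t = merged["population"].to_numpy(dtype=float)
        for source in ERR_SOURCES:
            seed_k = int(sub_seeds[k].generate_state(1)[0] % (2**31))
            k += 1
            if source == "cumulative":
                omega = (merged["omega_work"].to_numpy(dtype=float),
                         merged["omega_trans"].to_numpy(dtype=float))
            elif source == "workplace":
                omega = merged["omega_work"].to_numpy(dtype=float)
            else:
                omega = merged["omega_trans"].to_numpy(dtype=float)
            res = im.bootstrap_err(omega, p, t, group=group, source=source,
                                   n_boot=config.n_boot, seed=seed_k)
            err_rows.append(dataclasses.asdict(res))
    pd.DataFrame(err_rows).to_csv(outdir / "err_results.csv", index=False)

    # stratum-specific quintiles for each exposure group
    strata = _strata(tracts, config.quintile_mode)
    quintile_frames = []
    for group in ERR_GROUPS:
        prop = _group_populations(tracts, group) / tracts["population"]
        quintile_frames.append(im.assign_quintiles(
            prop, strata, tract_ids=tracts["tract_id"], group=group))
    pd.concat(quintile_frames, ignore_index=True).to_csv(
        outdir / "quintiles.csv", index=False)


def stage_indices(config: RunConfig, outdir: Path) -> None:
    tables = sd.read_tables(outdir)
    holc = tables.get("holc", pd.DataFrame(
        columns=["tract_id", "overlap_a", "overlap_b", "overlap_c",
                 "overlap_d", "total_graded"]))
    mortgage = tables.get("mortgage", pd.DataFrame(
        columns=["tract_id", "loans_minority", "loans_total",
                 "households_minority", "households_total"]))
    indices = sr.structural_indices_table(holc, mortgage)
    indices.to_csv(outdir / "structural_indices.csv", index=False)


def stage_models(config: RunConfig, outdir: Path) -> None:
    tables = sd.read_tables(outdir)
    tracts = tables["tracts"]
    work = pd.read_csv(outdir / "workplace_prevalence.csv")
    trans = pd.read_csv(outdir / "transport_prevalence.csv")
    flags = pd.read_csv(outdir / "cumulative_flags.csv")
    quintiles = pd.read_csv(outdir / "quintiles.csv")
    indices = pd.read_csv(outdir / "structural_indices.csv")

    rows = []

    def _collect(name: str, result: rm.ModelResult) -> None:
        for rec in result.effects.to_dict("records"):
            rows.append({"model": name, **rec, "n": result.n,
                         "converged": result.converged,
                         "separation": result.separation})

    spec_log = rm.ModelSpec(family="logistic")
    design = rm.build_design(tracts, quintiles, spec_log, flags=flags)
    _collect("cumulative_logistic", rm.fit_cumulative_logistic(design))

    spec_wp = rm.ModelSpec(family="poisson", offset="workers")
    design = rm.build_design(tracts, quintiles, spec_wp, prevalence=work)
    _collect("workplace_poisson", rm.fit_prevalence_poisson(design))

    spec_tp = rm.ModelSpec(family="poisson", offset="population")
    design = rm.build_design(tracts, quintiles, spec_tp, prevalence=trans)
    _collect("transport_poisson", rm.fit_prevalence_poisson(design))

    frame = tracts.merge(indices, on="tract_id", how="inner").merge(
        flags[["tract_id", "omega_work", "omega_trans"]], on="tract_id",
        how="left")
    frame["sustained"] = frame["sustained"].astype("boolean")
    for stratum in ("sustained", "not_sustained"):
        try:
            result = rm.fit_redlining_linear(frame, stratum)
        except Exception as exc:  # small synthetic strata may be degenerate
            logger.warning("redlining model for stratum %s skipped: %s",
                           stratum, exc)
            continue
        _collect(f"redlining_{stratum}", result)

    pd.DataFrame(rows).to_csv(outdir / "model_results.csv", index=False)
    _write_report(config, outdir)


def _write_report(config: RunConfig, outdir: Path) -> None:
    tables = sd.read_tables(outdir)
    tracts = tables["tracts"]
    work = pd.read_csv(outdir / "workplace_prevalence.csv")
    trans = pd.read_csv(outdir / "transport_prevalence.csv")
    err = pd.read_csv(outdir / "err_results.csv")
    models = pd.read_csv(outdir / "model_results.csv")

    pops = tracts.set_index("tract_id")["population"]
    workers = tracts.set_index("tract_id")["workers"]
    agg_t = tn.aggregate_exposed(trans, pops)
    agg_w = tn.aggregate_exposed(work, workers)
    pct_w_total = tn.exposed_percentage(agg_w.exposed, float(pops.sum()))

    lines = [
        "# Noise-inequity pipeline report",
        "",
        f"- config hash: `{config.config_hash()}`",
        f"- seed: {config.seed}",
        f"- tracts: {len(tracts)}",
        "",
        "## Nationwide exposure",
        "",
        f"- transportation noise: {agg_t.exposed:,.0f} of {agg_t.population:,.0f} "
        f"residents exposed ({agg_t.percentage:.1f}%)",
        f"- workplace noise: {agg_w.exposed:,.0f} of {agg_w.population:,.0f} "
        f"workers exposed ({agg_w.percentage:.1f}% of workers, "
        f"{pct_w_total:.1f}% of all residents)",
        "",
        "## Exposure-risk ratios",
        "",
        "```",
        err.to_string(index=False),
        "```",
        "",
        "## Model effects (vs quintile 1)",
        "",
        "```",
        models.to_string(index=False),
        "```",
        "",
    ]
    (outdir / "report.md").write_text("\n".join(lines), encoding="utf-8")


def write_manifest(config: RunConfig, outdir: Path) -> dict:
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": {},
    }
    for path in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.yaml")):
        data = path.read_bytes()
        rows = data.count(b"\n") - 1 if path.suffix == ".csv" else None
        manifest["files"][path.name] = {
            "rows": rows,
            "sha256": hashlib.sha256(data).hexdigest(),
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                          encoding="utf-8")
    return manifest


_STAGES = (
    ("generate", stage_generate),
    ("prevalence", stage_prevalence),
    ("metrics", stage_metrics),
    ("indices", stage_indices),
    ("models", stage_models),
)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages into ``outdir`` and return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        for name, stage in _STAGES:
            start = time.perf_counter()
            logger.info("stage %s started", name)
            try:
                stage(config, outdir)
            except Exception as exc:
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineStageError(name, exc) from exc
            logger.info("stage %s finished in %.2fs", name,
                        time.perf_counter() - start)
        manifest = write_manifest(config, outdir)
        logger.info("run complete; %d output files", len(manifest["files"]))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


_PROPORTION_COLS = ("pct_unemployed", "pct_low_income", "pct_no_diploma")


def validate_inputs(tables: dict[str, pd.DataFrame]) -> ValidationReport:
    """Schema, range and partition checks over the input tables."""
    report = ValidationReport()
    v = report.violations

    tracts = tables.get("tracts")
    if tracts is not None:
        for i, row in tracts.iterrows():
            if row["population"] < 0:
                v.append(f"tracts row {i} (tract {row['tract_id']}): "
                         f"negative population {row['population']}")
            if row["workers"] > row["population"]:
                v.append(f"tracts row {i} (tract {row['tract_id']}): "
                         f"workers {row['workers']} exceed population")
            for col in _PROPORTION_COLS:
                if not 0.0 <= row[col] <= 1.0:
                    v.append(f"tracts row {i} (tract {row['tract_id']}): "
                             f"{col}={row[col]} outside [0, 1]")
            race_sum = sum(row[g] for g in sd.RACE_GROUPS)
            if race_sum != row["population"]:
                v.append(f"tracts row {i} (tract {row['tract_id']}): race "
                         f"group counts sum to {race_sum}, "
                         f"population is {row['population']}")

    blocks = tables.get("blocks")
    if blocks is not None:
        for i, row in blocks.iterrows():
            if row["population"] < 0:
                v.append(f"blocks row {i} (block {row['block_id']}): "
                         f"negative population {row['population']}")
        if tracts is not None:
            sums = blocks.groupby("tract_id")["population"].sum()
            for row in tracts.itertuples():
                got = sums.get(row.tract_id, 0)
                if got != row.population:
                    v.append(f"tract {row.tract_id}: block populations sum "
                             f"to {got}, tract population is {row.population}")

    jem = tables.get("jem")
    if jem is not None:
        for i, row in jem.iterrows():
            if row["sd_twa"] <= 0:
                v.append(f"jem row {i} (group {row['group_id']}): "
                         f"sd_twa={row['sd_twa']} must be > 0")

    holc = tables.get("holc")
    if holc is not None:
        for i, row in holc.iterrows():
            total = sum(row[c] for c in ("overlap_a", "overlap_b",
                                         "overlap_c", "overlap_d"))
            if total > 1.0 + 1e-9:
                v.append(f"holc row {i} (tract {row['tract_id']}): grade "
                         f"overlaps sum to {total:.4f} > 1")

    mortgage = tables.get("mortgage")
    if mortgage is not None:
        for i, row in mortgage.iterrows():
            if row["loans_minority"] > row["loans_total"]:
                v.append(f"mortgage row {i} (tract {row['tract_id']}): "
                         "minority loans exceed total loans")
            if row["households_minority"] > row["households_total"]:
                v.append(f"mortgage row {i} (tract {row['tract_id']}): "
                         "minority households exceed total households")

    return report
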