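import dataclasses

import numpy as np
import pandas as pd
import pytest

from noisequity.inequity_metrics import assign_quintiles
from noisequity.pipeline import _strata
from noisequity.regression_models import (
    ModelSpec,
    build_design,
    fit_cumulative_logistic,
    fit_prevalence_poisson,
    fit_redlining_linear,
    fit_sensitivity,
    simulate_outcome,
)
from noisequity.structural_racism import structural_indices_table
from noisequity.synthetic_data import GeneratorConfig, generate_geography, generate_structural


def minority_quintiles(tracts):
    minority = 1.0 - tracts["nh_white"] / tracts["population"]
    return assign_quintiles(minority, _strata(tracts, "per_metro"),
                            tract_ids=tracts["tract_id"], group="minority")


def dummy_flags(tracts, seed=0, p=0.25):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "tract_id": tracts["tract_id"],
        "high_both": rng.random(len(tracts)) < p,
    })


def prevalence_frame(tracts, omegas):
    return pd.DataFrame({
        "tract_id": tracts["tract_id"],
        "omega": omegas,
        "ci_low": omegas, "ci_high": omegas,
        "n_iterations": 1, "excluded": False, "reason": "",
    })


@pytest.fixture(scope="module")
def tract_table():
    # ~1,600 tracts: below ~1,000 rows the 35-column design leaves the
    # logistic MLE quasi-separated and exact-invariance checks meaningless
    cfg = GeneratorConfig(n_metro_areas=5, tracts_per_metro=300,
                          nonmetro_tracts=100, blocks_per_tract=(1, 1),
                          beta_occupation=1.0, seed=42)
    tracts, _, _ = generate_geography(cfg)
    return tracts


@pytest.fixture(scope="module")
def quintile_table(tract_table):
    return minority_quintiles(tract_table)


class TestBuildDesign:
    def test_spline_and_tensor_dimensions(self, tract_table, quintile_table):
        design = build_design(tract_table, quintile_table,
                              ModelSpec(family="logistic"),
                              flags=dummy_flags(tract_table))
        dens = [c for c in design.X.columns if c.startswith("dens_s")]
        tens = [c for c in design.X.columns if c.startswith("te_")]
        assert len(dens) == 8
        assert len(tens) == 20

    def test_quintile_dummy_columns(self, tract_table, quintile_table):
        design = build_design(tract_table, quintile_table,
                              ModelSpec(family="logistic"),
                              flags=dummy_flags(tract_table))
        for k in range(2, 6):
            assert f"minority_q{k}" in design.X.columns
        assert "minority_q1" not in design.X.columns

    def test_poisson_rounding_and_offset(self, tract_table, quintile_table):
        prev = prevalence_frame(tract_table,
                                np.full(len(tract_table), 0.147))
        spec = ModelSpec(family="poisson", offset="workers")
        design = build_design(tract_table, quintile_table, spec,
                              prevalence=prev)
        i = int(np.argmax(design.frame["workers"].to_numpy() == 1000)) \
            if (design.frame["workers"] == 1000).any() else 0
        w = float(design.frame["workers"].iloc[i])
        assert design.y[i] == round(0.147 * w)
        assert design.offset[i] == pytest.approx(np.log(w))

    def test_rank_deficient_design_raises_with_names(self, tract_table,
                                                     quintile_table):
        # a second exposure with identical quintiles is perfectly aliased
        twin = quintile_table.assign(group="twin")
        both = pd.concat([quintile_table, twin], ignore_index=True)
        spec = ModelSpec(family="logistic", exposure=("minority", "twin"))
        with pytest.raises(ValueError, match="aliased"):
            build_design(tract_table, both, spec,
                         flags=dummy_flags(tract_table))

    def test_deterministic_seed_free(self, tract_table, quintile_table):
        spec = ModelSpec(family="logistic")
        d1 = build_design(tract_table, quintile_table, spec,
                          flags=dummy_flags(tract_table))
        d2 = build_design(tract_table, quintile_table, spec,
                          flags=dummy_flags(tract_table))
        pd.testing.assert_frame_equal(d1.X, d2.X)

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec(family="poisson")  # no offset
        with pytest.raises(ValueError):
            ModelSpec(family="linear")  # no stratum


class TestLogistic:
    def test_row_duplication_leaves_or_unchanged(self, tract_table,
                                                 quintile_table):
        flags = dummy_flags(tract_table, seed=3)
        spec = ModelSpec(family="logistic")
        design = build_design(tract_table, quintile_table, spec, flags=flags)
        res1 = fit_cumulative_logistic(design)
        doubled = dataclasses.replace(
            design,
            X=pd.concat([design.X, design.X], ignore_index=True),
            y=np.concatenate([design.y, design.y]))
        res2 = fit_cumulative_logistic(doubled)
        q5_1 = res1.effects.query("quintile == 5")["estimate"].iloc[0]
        q5_2 = res2.effects.query("quintile == 5")["estimate"].iloc[0]
        assert q5_2 == pytest.approx(q5_1, rel=1e-5)

    def test_reference_relabel_inverts_or(self, tract_table, quintile_table):
        spec = ModelSpec(family="logistic")
        design = build_design(tract_table, quintile_table, spec,
                              flags=dummy_flags(tract_table, seed=4))
        y = simulate_outcome(design.X, {"intercept": -2.0, "minority_q5": 1.0},
                             family="logistic", seed=4)
        design = dataclasses.replace(design, y=y)
        res = fit_cumulative_logistic(design)
        flipped = quintile_table.assign(quintile=6 - quintile_table["quintile"])
        design_f = build_design(tract_table, flipped, spec,
                                flags=dummy_flags(tract_table, seed=4))
        design_f = dataclasses.replace(design_f, y=y)
        res_f = fit_cumulative_logistic(design_f)
        or5 = res.effects.query("quintile == 5")["estimate"].iloc[0]
        or5_f = res_f.effects.query("quintile == 5")["estimate"].iloc[0]
        assert or5_f == pytest.approx(1.0 / or5, rel=1e-4)

    def test_single_replicate_recovery(self, tract_table, quintile_table):
        spec = ModelSpec(family="logistic")
        design = build_design(tract_table, quintile_table, spec,
                              flags=dummy_flags(tract_table))
        truth = {"intercept": -2.0, "minority_q2": 0.2, "minority_q3": 0.4,
                 "minority_q4": 0.7, "minority_q5": 1.0}
        y = simulate_outcome(design.X, truth, family="logistic", seed=7)
        res = fit_cumulative_logistic(dataclasses.replace(design, y=y))
        row = res.coefficients.set_index("term").loc["minority_q5"]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]


class TestPoisson:
    def test_offset_contract_scaling(self, tract_table, quintile_table):
        # doubling denominators (and hence counts) leaves PRs unchanged
        omegas = np.full(len(tract_table), 0.25)
        spec = ModelSpec(family="poisson", offset="workers")
        tracts2 = tract_table.copy()
        tracts2["workers"] = 4 * (tract_table["workers"] // 4)  # ω·d integral
        d1 = build_design(tracts2, quintile_table, spec,
                          prevalence=prevalence_frame(tracts2, omegas))
        doubled = tracts2.copy()
        doubled["workers"] = 2 * doubled["workers"]
        d2 = build_design(doubled, quintile_table, spec,
                          prevalence=prevalence_frame(doubled, omegas))
        r1 = fit_prevalence_poisson(d1)
        r2 = fit_prevalence_poisson(d2)
        for k in range(2, 6):
            e1 = r1.effects.query(f"quintile == {k}")["estimate"].iloc[0]
            e2 = r2.effects.query(f"quintile == {k}")["estimate"].iloc[0]
            assert e2 == pytest.approx(e1, rel=1e-6)

    def test_all_zero_counts_rejected(self, tract_table, quintile_table):
        spec = ModelSpec(family="poisson", offset="workers")
        prev = prevalence_frame(tract_table, np.zeros(len(tract_table)))
        design = build_design(tract_table, quintile_table, spec,
                              prevalence=prev)
        with pytest.raises(ValueError):
            fit_prevalence_poisson(design)

    def test_single_replicate_recovery(self, tract_table, quintile_table):
        spec = ModelSpec(family="poisson", offset="workers")
        prev = prevalence_frame(tract_table,
                                np.full(len(tract_table), 0.1))
        design = build_design(tract_table, quintile_table, spec,
                              prevalence=prev)
        truth = {"intercept": -2.3, "minority_q5": 0.2}
        y = simulate_outcome(design.X, truth, family="poisson",
                             offset=design.offset, seed=11)
        res = fit_prevalence_poisson(dataclasses.replace(design, y=y))
        row = res.coefficients.set_index("term").loc["minority_q5"]
        assert row["ci_low"] <= 0.2 <= row["ci_high"]

    def test_excluded_prevalence_dropped(self, tract_table, quintile_table):
        prev = prevalence_frame(tract_table, np.full(len(tract_table), 0.2))
        prev.loc[:9, "excluded"] = True
        spec = ModelSpec(family="poisson", offset="workers")
        design = build_design(tract_table, quintile_table, spec,
                              prevalence=prev)
        assert len(design.y) == len(tract_table) - 10


@pytest.fixture(scope="module")
def redlining_frame():
    # ~1,300 redlined tracts so each discrimination stratum is large enough
    # for the ~30-column covariate set to leave informative CIs
    cfg = GeneratorConfig(n_metro_areas=6, tracts_per_metro=250,
                          nonmetro_tracts=5, blocks_per_tract=(1, 1),
                          redline_fraction=0.9, discrimination_fraction=0.5,
                          seed=13)
    tracts, _, _ = generate_geography(cfg)
    holc, mortgage = generate_structural(tracts, cfg)
    indices = structural_indices_table(holc, mortgage)
    frame = tracts.merge(indices, on="tract_id", how="inner")
    frame["sustained"] = frame["sustained"].astype("boolean")
    return frame


class TestRedliningLinear:
    def _with_outcome(self, frame, slope, noise_sd, seed):
        rng = np.random.default_rng(seed)
        base = 0.05 + slope * frame["hrs"].fillna(0.0)
        omega = np.clip(base + rng.normal(0, noise_sd, len(frame)), 0, 1)
        out = frame.copy()
        out["omega_work"] = omega
        out["omega_trans"] = omega
        return out

    def test_null_slope_ci_covers_zero(self, redlining_frame):
        frame = self._with_outcome(redlining_frame, 0.0, 0.01, seed=1)
        res = fit_redlining_linear(frame, "sustained")
        lo, hi = res.effect_1to4[1], res.effect_1to4[2]
        assert lo <= 0.0 <= hi

    def test_injected_slope_recovered(self, redlining_frame):
        # 0.005 proportion per HRS unit -> 1.5 percentage points from 1 to 4
        frame = self._with_outcome(redlining_frame, 0.005, 0.002, seed=2)
        res = fit_redlining_linear(frame, "sustained")
        est, lo, hi = res.effect_1to4
        assert lo <= 1.5 <= hi
        assert est == pytest.approx(1.5, abs=0.5)

    def test_outcome_shift_leaves_slope_unchanged(self, redlining_frame):
        frame = self._with_outcome(redlining_frame, 0.004, 0.003, seed=3)
        res1 = fit_redlining_linear(frame, "not_sustained")
        shifted = frame.copy()
        shifted["omega_work"] = shifted["omega_work"] + 0.05
        shifted["omega_trans"] = shifted["omega_trans"] + 0.05
        res2 = fit_redlining_linear(shifted, "not_sustained")
        assert res2.effect_1to4[0] == pytest.approx(res1.effect_1to4[0],
                                                    rel=1e-6)

    def test_small_stratum_warns(self, redlining_frame):
        frame = self._with_outcome(redlining_frame.head(80), 0.0, 0.01, seed=4)
        with pytest.warns(UserWarning, match="tracts"):
            fit_redlining_linear(frame, "sustained")

    def test_bad_stratum_rejected(self, redlining_frame):
        with pytest.raises(ValueError):
            fit_redlining_linear(redlining_frame, "everything")


class TestSensitivity:
    def test_constant_ses_identical_estimates(self, tract_table,
                                              quintile_table):
        tracts = tract_table.copy()
        tracts["pct_low_income"] = 0.3
        tracts["pct_no_diploma"] = 0.1
        flags = dummy_flags(tracts, seed=5)
        spec = ModelSpec(family="logistic")
        with pytest.warns(UserWarning, match="constant"):
            res = fit_sensitivity(tracts, quintile_table, spec, flags=flags)
        for k in range(2, 6):
            main = res.main.effects.query(f"quintile == {k}")["estimate"].iloc[0]
            adj = res.adjusted.effects.query(f"quintile == {k}")["estimate"].iloc[0]
            assert adj == pytest.approx(main, rel=1e-6)

    def test_llf_never_decreases_with_ses(self, tract_table, quintile_table):
        flags = dummy_flags(tract_table, seed=6)
        spec = ModelSpec(family="logistic")
        res = fit_sensitivity(tract_table, quintile_table, spec, flags=flags)
        assert res.adjusted.llf >= res.main.llf - 1e-6

    def test_ses_mediated_effect_attenuates(self, tract_table, quintile_table):
        # outcome driven by the SES column (which tracks minority share):
        # adjusting for SES must shrink the Q5 estimate
        spec = ModelSpec(family="logistic")
        design = build_design(tract_table, quintile_table, spec,
                              flags=dummy_flags(tract_table),)
        lin = -2.5 + 6.0 * tract_table.reset_index(drop=True)["pct_low_income"]
        rng = np.random.default_rng(9)
        y = rng.binomial(1, 1 / (1 + np.exp(-lin))).astype(float)
        flags = pd.DataFrame({"tract_id": tract_table["tract_id"],
                              "high_both": y.astype(bool)})
        res = fit_sensitivity(tract_table, quintile_table, spec, flags=flags)
        main_q5 = res.main.effects.query("quintile == 5")["estimate"].iloc[0]
        adj_q5 = res.adjusted.effects.query("quintile == 5")["estimate"].iloc[0]
        assert main_q5 > 1.0
        assert abs(np.log(adj_q5)) < abs(np.log(main_q5))

    def test_null_covered(self, tract_table, quintile_table):
        spec = ModelSpec(family="logistic")
        design = build_design(tract_table, quintile_table, spec,
                              flags=dummy_flags(tract_table))
        y = simulate_outcome(design.X, {"intercept": -1.5}, family="logistic",
                             seed=10)
        flags = pd.DataFrame({"tract_id": design.frame["tract_id"],
                              "high_both": y.astype(bool)})
        res = fit_sensitivity(tract_table, quintile_table, spec, flags=flags)
        q5 = res.adjusted.effects.query("quintile == 5").iloc[0]
        assert q5["ci_low"] <= 1.0 <= q5["ci_high"]
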