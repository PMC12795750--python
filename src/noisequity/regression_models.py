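"""GLM stages linking tract composition and structural indices to noise.

Three families: logistic (odds of cumulatively high workplace+transportation
noise), Poisson with a log-denominator offset (prevalence ratios for each
source), and linear (average prevalence against the historical redlining
score, stratified by sustained mortgage discrimination).  Exposures enter as
stratum-specific quintile indicators relative to quintile 1.  All models
adjust for unemployment, urbanicity (where applicable), a natural spline of
log population density (8 df) and a tensor-product smooth of the tract
centroid (4 x 5 B-spline margins, 20 columns).  Smooths are unpenalized
regression-spline bases inside ordinary GLMs with Wald 95% CIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix

__all__ = [
    "ModelSpec",
    "ModelResult",
    "Design",
    "build_design",
    "fit_cumulative_logistic",
    "fit_prevalence_poisson",
    "fit_redlining_linear",
    "fit_sensitivity",
    "SensitivityResult",
    "simulate_outcome",
]

_DENSITY_DF = 8
_TENSOR_MARGINS = (4, 5)  # lat x lon B-spline margins; 20 columns total


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one regression stage."""

    family: str  # 'logistic' | 'poisson' | 'linear'
    exposure: tuple[str, ...] = ("minority",)
    offset: str | None = None  # None | 'workers' | 'population'
    include_urbanicity: bool = True
    ses_adjusted: bool = False
    stratum: str | None = None  # linear family: 'sustained' | 'not_sustained'

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "poisson", "linear"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "poisson" and self.offset is None:
            raise ValueError("poisson family requires an offset")
        if self.family == "linear" and self.stratum is None:
            raise ValueError("linear family requires a stratum")


@dataclass
class Design:
    X: pd.DataFrame
    y: np.ndarray
    offset: np.ndarray | None
    frame: pd.DataFrame  # aligned tract rows, for diagnostics/stratification


@dataclass
class ModelResult:
    family: str
    effects: pd.DataFrame  # exposure, quintile, estimate, ci_low, ci_high
    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high
    deviance: float
    llf: float
    n: int
    converged: bool
    separation: bool = False
    effect_1to4: tuple[float, float, float] | None = None  # linear family


def _spline_basis(values: np.ndarray, df: int, prefix: str) -> pd.DataFrame:
    basis = dmatrix(f"cr(x, df={df}, constraints='center') - 1",
                    {"x": values}, return_type="dataframe")
    basis.columns = [f"{prefix}{i + 1}" for i in range(basis.shape[1])]
    return basis.reset_index(drop=True)


def _bspline_margin(x: np.ndarray, df: int) -> np.ndarray:
    # equally spaced interior knots: quantile knots on spatially clustered
    # coordinates produce near-empty basis columns that quasi-separate GLMs
    lo, hi = float(x.min()), float(x.max())
    knots = list(np.linspace(lo, hi, df - 3 + 2)[1:-1])
    return np.asarray(dmatrix(
        "bs(x, knots=knots, lower_bound=lo, upper_bound=hi, degree=3) - 1",
        {"x": x, "knots": knots, "lo": lo, "hi": hi}))


def _tensor_basis(lat: np.ndarray, lon: np.ndarray) -> pd.DataFrame:
    """Columnwise products of two marginal B-spline bases (4 x 5 = 20 df)."""
    d1, d2 = _TENSOR_MARGINS
    b_lat = _bspline_margin(lat, d1)
    b_lon = _bspline_margin(lon, d2)
    cols = {}
    k = 0
    for i in range(b_lat.shape[1]):
        for j in range(b_lon.shape[1]):
            k += 1
            cols[f"te_{k:02d}"] = b_lat[:, i] * b_lon[:, j]
    return pd.DataFrame(cols)


def _quintile_dummies(quintiles: pd.DataFrame, exposure: Sequence[str],
                      tract_ids: pd.Series) -> pd.DataFrame:
    wide = quintiles.pivot(index="tract_id", columns="group", values="quintile")
    missing = [g for g in exposure if g not in wide.columns]
    if missing:
        raise KeyError(f"no quintile assignment for exposure group(s) {missing}")
    out = {}
    aligned = wide.reindex(tract_ids)
    for g in exposure:
        q = aligned[g].to_numpy()
        if np.isnan(q.astype(float)).any():
            raise ValueError(f"missing quintiles for group {g!r}")
        for k in range(2, 6):
            out[f"{g}_q{k}"] = (q == k).astype(float)
    return pd.DataFrame(out)


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    # Constant non-intercept columns are aliased to the intercept (e.g. an
    # SES covariate with no variation); drop them with a warning.
    keep = ["intercept"]
    dropped = []
    for c in X.columns:
        if c == "intercept":
            continue
        if np.ptp(X[c].to_numpy(dtype=float)) == 0.0:
            dropped.append(c)
        else:
            keep.append(c)
    if dropped:
        warnings.warn(f"dropping constant (intercept-aliased) columns: {dropped}")
    return X[keep]


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        from scipy.linalg import qr
        _, r, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        raise ValueError(f"design matrix is rank deficient (rank {rank} of "
                         f"{arr.shape[1]}); aliased columns: {aliased}")


def _covariates(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    parts = [pd.DataFrame({
        "pct_unemployed": frame["pct_unemployed"].to_numpy(dtype=float)})]
    if spec.include_urbanicity:
        parts.append(pd.DataFrame({
            "urban": (frame["ruca_code"] <= 3).astype(float).to_numpy()}))
    # density is entered on the log scale (heavy right skew)
    parts.append(_spline_basis(np.log(frame["pop_density"].to_numpy(dtype=float)),
                               _DENSITY_DF, "dens_s"))
    parts.append(_tensor_basis(frame["centroid_lat"].to_numpy(dtype=float),
                               frame["centroid_lon"].to_numpy(dtype=float)))
    if spec.ses_adjusted:
        parts.append(frame[["pct_low_income", "pct_no_diploma"]]
                     .astype(float).reset_index(drop=True))
    return pd.concat(parts, axis=1)


def build_design(
    tracts: pd.DataFrame,
    quintiles: pd.DataFrame,
    spec: ModelSpec,
    prevalence: pd.DataFrame | None = None,
    flags: pd.DataFrame | None = None,
) -> Design:
    """Assemble outcome, offset and full-rank design matrix for one model.

    Logistic models take the cumulative-high ``flags`` table as outcome;
    Poisson models take a ``prevalence`` table, with the outcome count
    round(omega * denominator) and offset log(denominator), the denominator
    being the column named by ``spec.offset``.
    """
    frame = tracts.reset_index(drop=True).copy()
    y: np.ndarray
    offset: np.ndarray | None = None

    if spec.family == "logistic":
        if flags is None:
            raise ValueError("logistic family requires the cumulative-high flags")
        merged = frame.merge(flags[["tract_id", "high_both"]], on="tract_id",
                             how="inner").reset_index(drop=True)
        frame = merged
        y = merged["high_both"].astype(float).to_numpy()
    elif spec.family == "poisson":
        if prevalence is None:
            raise ValueError("poisson family requires a prevalence table")
        prev = prevalence.loc[~prevalence["excluded"].astype(bool),
                              ["tract_id", "omega"]]
        merged = frame.merge(prev, on="tract_id", how="inner").reset_index(drop=True)
        denom = merged[spec.offset].to_numpy(dtype=float)
        keep = denom > 0
        merged = merged.loc[keep].reset_index(drop=True)
        denom = denom[keep]
        frame = merged
        y = np.round(merged["omega"].to_numpy(dtype=float) * denom)
        offset = np.log(denom)
    else:
        raise ValueError("use fit_redlining_linear for the linear family")

    parts = [pd.DataFrame({"intercept": np.ones(len(frame))}),
             _quintile_dummies(quintiles, spec.exposure, frame["tract_id"]),
             _covariates(frame, spec)]
    X = pd.concat(parts, axis=1)
    X = _drop_constant(X)
    _check_rank(X)
    return Design(X=X, y=y, offset=offset, frame=frame)


def _effects_table(result, spec_exposure: Sequence[str], ratio: bool) -> pd.DataFrame:
    params = result.params
    conf = result.conf_int()
    rows = []
    for g in spec_exposure:
        rows.append({"exposure": g, "quintile": 1,
                     "estimate": 1.0 if ratio else 0.0,
                     "ci_low": np.nan, "ci_high": np.nan})
        for k in range(2, 6):
            term = f"{g}_q{k}"
            if term not in params.index:
                continue
            b, lo, hi = params[term], conf.loc[term, 0], conf.loc[term, 1]
            if ratio:
                with np.errstate(over="ignore"):
                    b, lo, hi = np.exp(b), np.exp(lo), np.exp(hi)
            rows.append({"exposure": g, "quintile": k, "estimate": b,
                         "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _coef_table(result) -> pd.DataFrame:
    conf = result.conf_int()
    return pd.DataFrame({
        "term": result.params.index,
        "estimate": result.params.to_numpy(),
        "se": result.bse.to_numpy(),
        "ci_low": conf[0].to_numpy(),
        "ci_high": conf[1].to_numpy(),
    })


def fit_cumulative_logistic(design: Design,
                            exposure: Sequence[str] = ("minority",)) -> ModelResult:
    """Odds ratios (vs quintile 1) of being cumulatively high in both noise
    sources; complete separation is detected and flagged, not hidden."""
    model = sm.GLM(design.y, design.X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=200)
        # IRLS can diverge under quasi-separation (NaN llf, exploding
        # coefficients); a gradient optimizer stays finite there
        if not np.isfinite(res.llf) or np.abs(res.params).max() > 1e4:
            res = model.fit(method="lbfgs", maxiter=500, disp=0)
    exp_terms = [c for c in design.X.columns if any(
        c.startswith(f"{g}_q") for g in exposure)]
    separation = bool(
        not getattr(res, "converged", True)
        or any(abs(res.params[t]) > 15 or res.bse[t] > 100 for t in exp_terms)
    )
    if separation:
        warnings.warn("possible complete separation in logistic fit; "
                      "quintile estimates flagged")
    return ModelResult(
        family="logistic",
        effects=_effects_table(res, exposure, ratio=True),
        coefficients=_coef_table(res),
        deviance=float(res.deviance),
        llf=float(res.llf),
        n=len(design.y),
        converged=bool(getattr(res, "converged", True)),
        separation=separation,
    )


def fit_prevalence_poisson(design: Design,
                           exposure: Sequence[str] = ("minority",)) -> ModelResult:
    """Prevalence ratios (vs quintile 1) from a Poisson GLM with log-
    denominator offset."""
    if np.all(design.y == 0):
        raise ValueError("all outcome counts are zero; Poisson fit undefined")
    model = sm.GLM(design.y, design.X, family=sm.families.Poisson(),
                   offset=design.offset)
    res = model.fit(maxiter=200)
    return ModelResult(
        family="poisson",
        effects=_effects_table(res, exposure, ratio=True),
        coefficients=_coef_table(res),
        deviance=float(res.deviance),
        llf=float(res.llf),
        n=len(design.y),
        converged=bool(res.converged),
    )


def fit_redlining_linear(frame: pd.DataFrame, stratum: str,
                         min_stratum_size: int = 50) -> ModelResult:
    """Linear model of average noise prevalence (percentage points) on HRS.

    ``frame`` must carry hrs, sustained, omega_work, omega_trans and the
    covariate columns; ``stratum`` selects sustained (True) or not-sustained
    (False) tracts.  The reported headline effect is 3 x the HRS slope — the
    change from HRS 1 to 4 — in percentage points.  No urbanicity term: all
    HOLC-graded tracts are urban.
    """
    if stratum not in ("sustained", "not_sustained"):
        raise ValueError("stratum must be 'sustained' or 'not_sustained'")
    want = stratum == "sustained"
    sub = frame.loc[frame["hrs"].notna()
                    & frame["sustained"].notna()
                    & (frame["sustained"].astype(bool) == want)
                    & frame["omega_work"].notna()
                    & frame["omega_trans"].notna()].reset_index(drop=True)
    if len(sub) < min_stratum_size:
        warnings.warn(f"stratum {stratum!r} has only {len(sub)} tracts; "
                      "fit proceeds but estimates may be unstable")
    outcome = 100.0 * (sub["omega_work"].to_numpy(dtype=float)
                       + sub["omega_trans"].to_numpy(dtype=float)) / 2.0
    spec = ModelSpec(family="linear", stratum=stratum, include_urbanicity=False)
    X = pd.concat([
        pd.DataFrame({"intercept": np.ones(len(sub)),
                      "hrs": sub["hrs"].to_numpy(dtype=float)}),
        _covariates(sub, spec),
    ], axis=1)
    X = _drop_constant(X)
    _check_rank(X)
    res = sm.OLS(outcome, X).fit()
    conf = res.conf_int()
    slope, lo, hi = res.params["hrs"], conf.loc["hrs", 0], conf.loc["hrs", 1]
    effects = pd.DataFrame([{
        "exposure": "hrs", "quintile": 0, "estimate": 0.0,
        "ci_low": np.nan, "ci_high": np.nan,
    }, {
        "exposure": "hrs", "quintile": -1, "estimate": 3.0 * slope,
        "ci_low": 3.0 * lo, "ci_high": 3.0 * hi,
    }])
    return ModelResult(
        family="linear",
        effects=effects,
        coefficients=_coef_table(res),
        deviance=float(res.ssr),
        llf=float(res.llf),
        n=len(sub),
        converged=True,
        effect_1to4=(float(3.0 * slope), float(3.0 * lo), float(3.0 * hi)),
    )


@dataclass
class SensitivityResult:
    main: ModelResult
    adjusted: ModelResult
    comparison: pd.DataFrame  # per quintile: main vs SES-adjusted estimates


def fit_sensitivity(
    tracts: pd.DataFrame,
    quintiles: pd.DataFrame,
    spec: ModelSpec,
    prevalence: pd.DataFrame | None = None,
    flags: pd.DataFrame | None = None,
) -> SensitivityResult:
    """Refit with low-income and no-diploma covariates added; returns the
    paired main/adjusted results and a quintile-level comparison table."""
    import dataclasses as _dc
    main_spec = _dc.replace(spec, ses_adjusted=False)
    ses_spec = _dc.replace(spec, ses_adjusted=True)

    def _fit(s: ModelSpec) -> ModelResult:
        design = build_design(tracts, quintiles, s, prevalence=prevalence,
                              flags=flags)
        if s.family == "logistic":
            return fit_cumulative_logistic(design, exposure=s.exposure)
        return fit_prevalence_poisson(design, exposure=s.exposure)

    main = _fit(main_spec)
    adjusted = _fit(ses_spec)
    comparison = main.effects.merge(
        adjusted.effects, on=["exposure", "quintile"],
        suffixes=("_main", "_ses"))
    return SensitivityResult(main=main, adjusted=adjusted, comparison=comparison)


def simulate_outcome(X: pd.DataFrame, beta: Mapping[str, float], family: str,
                     offset: np.ndarray | None = None, sigma: float = 1.0,
                     seed: int = 0) -> np.ndarray:
    """Draw outcomes from a GLM with known coefficients over a design matrix.

    Terms absent from ``beta`` get coefficient 0.  Intended for parameter-
    recovery simulations.
    """
    rng = np.random.default_rng(seed)
    b = np.array([beta.get(c, 0.0) for c in X.columns])
    lin = X.to_numpy(dtype=float) @ b
    if family == "logistic":
        p = 1.0 / (1.0 + np.exp(-lin))
        return rng.binomial(1, p).astype(float)
    if family == "poisson":
        if offset is not None:
            lin = lin + offset
        return rng.poisson(np.exp(lin)).astype(float)
    if family == "linear":
        return lin + rng.normal(0.0, sigma, size=len(lin))
    raise ValueError(f"unknown family {family!r}")
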