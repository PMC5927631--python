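"""Mutations-per-year estimation from branch burdens via a random-slope model.

Burdens of the terminal subclones of one patient share ancestry, so they are
not independent observations.  The model

    burden_ib = (beta + u_i) * age_i + eps_ib,   u_i ~ N(0, sigma_u^2)

has no fixed or random intercept (a zero-age kidney carries no somatic
burden) and treats within-patient branches as exchangeable under a shared
random slope.  Variance components are estimated by REML; per-patient slopes
are the shrunken (BLUP) estimates beta + u_i.  A quadratic-in-age fixed term
provides the sensitivity check, compared by a 1-df likelihood-ratio test on
full-ML refits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLMParams


@dataclass
class RateModel:
    """Cohort slope, between-patient spread, and shrunken patient slopes."""

    slope: float  # mutations / year
    slope_sd: float  # between-patient SD of the slope
    residual_sd: float
    patient_slopes: Mapping[str, float]
    loglik: float
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    def patient_rate(self, patient: str) -> float:
        """Shrunken mutations-per-year estimate for one patient."""
        if patient not in self.patient_slopes:
            raise KeyError(f"patient {patient!r} not in fit")
        return self.patient_slopes[patient]


@dataclass(frozen=True)
class QuadraticComparison:
    """Linear vs linear+quadratic fixed-age fit, by likelihood ratio."""

    linear_slope: float
    quadratic_coef: float
    lr_statistic: float
    p_value: float
    loglik_linear: float
    loglik_quadratic: float


def _validate(burdens: pd.DataFrame) -> pd.DataFrame:
    required = {"patient", "burden", "age"}
    missing = required - set(burdens.columns)
    if missing:
        raise ValueError(f"burden table missing columns: {sorted(missing)}")
    if (burdens["age"] <= 0).any():
        raise ValueError("ages must be positive")
    if (burdens["burden"] < 0).any():
        raise ValueError("burdens must be >= 0")
    return burdens


def _per_patient_ols_slopes(burdens: pd.DataFrame) -> dict:
    out = {}
    for patient, grp in burdens.groupby("patient"):
        x = grp["age"].to_numpy(float)
        y = grp["burden"].to_numpy(float)
        out[patient] = float(np.dot(x, y) / np.dot(x, x))
    return out


def _fit_mixedlm(y, exog, age, groups, raw_slopes, reml=True):
    """MixedLM fit with informed starting values.

    The default start point collapses on burden-scale data (the optimizer
    drives the slope variance to zero and the fixed slope off target), so
    seed the fixed effects with through-origin least squares and the slope
    variance with the spread of the raw per-patient slopes.
    """
    model = sm.MixedLM(endog=y, exog=exog, groups=groups, exog_re=age[:, None])
    fe0, *_ = np.linalg.lstsq(exog, y, rcond=None)
    var0 = max(float(np.var(list(raw_slopes.values()))), 1.0)
    start = MixedLMParams.from_components(fe_params=fe0, cov_re=np.array([[var0]]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(reml=reml, start_params=start, method=["cg", "bfgs", "powell"])


def fit_rate_lme(burdens: pd.DataFrame) -> RateModel:
    """Fit the no-intercept random-slope model by REML.

    Degenerate inputs fall back deterministically: a single patient gets its
    exact through-origin least-squares slope (no shrinkage possible), and
    all-zero burdens give a zero fit.  A singular variance-component fit is
    reported through ``diagnostics`` rather than silently.
    """
    burdens = _validate(burdens)
    patients = burdens["patient"].unique()
    raw = _per_patient_ols_slopes(burdens)

    if np.allclose(burdens["burden"], 0.0):
        return RateModel(
            slope=0.0,
            slope_sd=0.0,
            residual_sd=0.0,
            patient_slopes={p: 0.0 for p in patients},
            loglik=np.nan,
            diagnostics={"degenerate": "all burdens zero"},
        )
    if len(patients) < 2:
        p = patients[0]
        return RateModel(
            slope=raw[p],
            slope_sd=0.0,
            residual_sd=0.0,
            patient_slopes=dict(raw),
            loglik=np.nan,
            diagnostics={"degenerate": "single patient; exact through-origin slope"},
        )

    age = burdens["age"].to_numpy(float)
    y = burdens["burden"].to_numpy(float)
    groups = burdens["patient"].to_numpy()
    result = _fit_mixedlm(y, age[:, None], age, groups, raw, reml=True)

    slope = float(result.fe_params[0])
    var_u = float(np.asarray(result.cov_re)[0, 0])
    slope_sd = float(np.sqrt(max(var_u, 0.0)))
    residual_sd = float(np.sqrt(result.scale))
    if var_u > 0:
        try:
            patient_slopes = {
                p: slope + float(np.asarray(re)[0]) for p, re in result.random_effects.items()
            }
        except ValueError:  # singular covariance: no shrinkage possible
            patient_slopes = {p: slope for p in patients}
    else:
        patient_slopes = {p: slope for p in patients}
    diagnostics = {}
    if getattr(result, "converged", True) is False:
        diagnostics["warning"] = "optimizer did not converge"
    # a boundary (zero) variance estimate is legitimate but worth surfacing
    if var_u <= 1e-10 * max(slope, 1.0) ** 2:
        diagnostics["singular"] = "between-patient slope variance estimated at the zero boundary"
    return RateModel(
        slope=slope,
        slope_sd=slope_sd,
        residual_sd=residual_sd,
        patient_slopes=patient_slopes,
        loglik=float(result.llf),
        converged=bool(getattr(result, "converged", True)),
        diagnostics=diagnostics,
    )


def fit_rate_quadratic(burdens: pd.DataFrame) -> QuadraticComparison:
    """Compare linear vs quadratic fixed-age terms by likelihood ratio.

    Both fits use full maximum likelihood (REML log-likelihoods are not
    comparable across fixed-effect structures); the statistic is referred to
    a chi-square with one degree of freedom.
    """
    burdens = _validate(burdens)
    if burdens["patient"].nunique() < 2:
        raise ValueError("need >= 2 patients for the quadratic comparison")
    age = burdens["age"].to_numpy(float)
    y = burdens["burden"].to_numpy(float)
    groups = burdens["patient"].to_numpy()
    raw = _per_patient_ols_slopes(burdens)

    lin = _fit_mixedlm(y, age[:, None], age, groups, raw, reml=False)
    quad = _fit_mixedlm(y, np.column_stack([age, age**2]), age, groups, raw, reml=False)
    lr = max(2.0 * (quad.llf - lin.llf), 0.0)
    p_value = float(stats.chi2.sf(lr, df=1))
    return QuadraticComparison(
        linear_slope=float(lin.fe_params[0]),
        quadratic_coef=float(quad.fe_params[1]),
        lr_statistic=float(lr),
        p_value=p_value,
        loglik_linear=float(lin.llf),
        loglik_quadratic=float(quad.llf),
    )


def patient_rate(model: RateModel, patient: str) -> float:
    """Shrunken per-patient mutations-per-year estimate (beta + u_i)."""
    return model.patient_rate(patient)


def bootstrap_slope_ci(
    model: RateModel,
    burdens: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Parametric-bootstrap CI for the cohort slope.

    Resimulates burdens from the fitted model (patient slopes Normal around
    the cohort slope, Gaussian residuals) and refits; returns percentile
    bounds.
    """
    burdens = _validate(burdens)
    rng = np.random.default_rng(seed)
    patients = burdens["patient"].unique()
    slopes = np.empty(n_boot)
    for b in range(n_boot):
        u = dict(zip(patients, rng.normal(0.0, model.slope_sd, size=len(patients))))
        sim = burdens.copy()
        sim["burden"] = (
            (model.slope + sim["patient"].map(u)) * sim["age"]
            + rng.normal(0.0, model.residual_sd, size=len(sim))
        ).clip(lower=0.0)
        slopes[b] = fit_rate_lme(sim).slope
    lo = (1 - level) / 2 * 100
    return tuple(np.percentile(slopes, [lo, 100 - lo]))
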