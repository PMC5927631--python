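"""Three-waiting-time model of sporadic and inherited cancer age incidence.

Onset age decomposes into independent waiting times

    inherited:  Y = Z1 + Z3
    sporadic:   Y = Z1 + Z2 + Z3

with Z1 ~ Gamma(a1, b1) (time to the initiating arm loss), Z3 ~ Gamma(a3, b3)
(time from biallelic inactivation to diagnosis), and Z2 ~ Exponential(lambda)
where lambda = nu * mu is the product of the precursor clone size and the
per-cell per-year driver mutation rate.  Individuals observed event-free are
right-censored; censoring is handled by data augmentation.

Posterior sampling cycles four kernels per iteration:

1/3. uncensored individuals: Metropolis-Hastings re-splits of the latent
     waiting times under a Dirichlet proposal scaled to the onset age, so
     the sum constraint holds exactly;
2/4. censored individuals: rejection draws of the latent times from their
     current priors until the sum exceeds the censoring age;
5.   (a1, b1) and (a3, b3): Metropolis-Hastings with independent gamma
     proposals against the gamma likelihood x conjugate prior, all in log
     space;
6.   lambda: an exact conjugate gamma draw.

A seventh step draws posterior-predictive onset ages with the clone size
scaled by a fraction rho, giving intervention counterfactual incidence
curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .synthetic import IncidenceCohort

logger = logging.getLogger(__name__)

_EPS = 1e-12


# ---------------------------------------------------------------------------
# priors, config, results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GammaPairPrior:
    """Conjugate prior for a gamma (shape, rate) pair.

    Density proportional to ``p^(a-1) exp(-b q) Gamma(a)^(-r) b^(a s)`` with
    hyperparameters (p, q, r, s); ``log_p`` stores log(p) so products of many
    observed ages never overflow.  Observing waiting times z updates
    ``log_p += sum(log z)``, ``q += sum(z)``, ``r += n``, ``s += n``.
    """

    log_p: float = 0.0
    q: float = 1.0
    r: float = 1.0
    s: float = 1.0

    @classmethod
    def uninformative(cls) -> "GammaPairPrior":
        return cls(log_p=0.0, q=1.0, r=1.0, s=1.0)

    @classmethod
    def from_observed_ages(cls, ages) -> "GammaPairPrior":
        """Informative prior distilled from directly estimated waiting times."""
        ages = np.asarray(ages, dtype=float)
        if ages.size == 0:
            raise ValueError("need at least one age")
        if np.any(ages <= 0):
            raise ValueError("ages must be positive")
        return cls(
            log_p=float(np.sum(np.log(ages))),
            q=float(np.sum(ages)),
            r=float(ages.size),
            s=float(ages.size),
        )


@dataclass(frozen=True)
class WaitingTimePriors:
    """Priors for (a1, b1), (a3, b3) and lambda."""

    z1: GammaPairPrior = field(default_factory=GammaPairPrior.uninformative)
    z3: GammaPairPrior = field(default_factory=GammaPairPrior.uninformative)
    lambda_shape: float = 0.01
    lambda_rate: float = 0.01


@dataclass(frozen=True)
class SamplerConfig:
    iterations: int = 50_000
    burn_in: int = 10_000
    # proposal concentrations, tuned so acceptance rates fall around 0.2-0.6
    # on the default synthetic cohort
    kappa: float = 10.0  # Dirichlet split proposal
    gamma: float = 400.0  # gamma proposal for (shape, rate) updates
    thin: int = 10
    seed: int = 0
    max_rejection_attempts: int = 10_000
    update_shape_rate: bool = True  # disable to hold (a, b) pairs fixed

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.kappa <= 0 or self.gamma <= 0:
            raise ValueError("kappa and gamma must be > 0")


@dataclass
class PosteriorDraws:
    """Retained posterior draws plus per-kernel acceptance rates."""

    draws: pd.DataFrame  # columns: a1, b1, a3, b3, lam, nu
    acceptance: dict
    mu: float
    config: SamplerConfig

    def summary(self) -> dict:
        qs = self.draws.quantile([0.025, 0.5, 0.975])
        return {
            col: {
                "median": float(qs.loc[0.5, col]),
                "lo95": float(qs.loc[0.025, col]),
                "hi95": float(qs.loc[0.975, col]),
            }
            for col in self.draws.columns
        }


# ---------------------------------------------------------------------------
# cohort draws from published-style curves
# ---------------------------------------------------------------------------


def sample_cohort_from_curves(
    n: int,
    seed: int = 0,
    incidence_table: pd.DataFrame | None = None,
    survival_curve: pd.DataFrame | None = None,
) -> IncidenceCohort:
    """Draw a cohort of individuals (or censored non-patients) from curves.

    ``incidence_table`` (columns age_lo, age_hi, rate_per_100k: annual rates
    in 5-year bands) yields sporadic individuals: each either acquires an
    event age — uniform within its band — or is censored at the table's
    upper age.  ``survival_curve`` (columns age, survival) yields inherited
    carriers by inverse-CDF draws, censored at the curve's last age.
    Exactly one input must be given.
    """
    if (incidence_table is None) == (survival_curve is None):
        raise ValueError("provide exactly one of incidence_table, survival_curve")
    rng = np.random.default_rng(seed)
    records = []
    if incidence_table is not None:
        tbl = incidence_table.sort_values("age_lo").reset_index(drop=True)
        if (tbl["rate_per_100k"] < 0).any():
            raise ValueError("negative incidence rates")
        widths = (tbl["age_hi"] - tbl["age_lo"]).to_numpy(float)
        hazards = tbl["rate_per_100k"].to_numpy(float) / 1e5
        band_surv = np.exp(-hazards * widths)
        cum_surv = np.concatenate([[1.0], np.cumprod(band_surv)])
        censor_age = float(tbl["age_hi"].iloc[-1])
        u = rng.uniform(size=n)
        for ui in u:
            if ui <= cum_surv[-1]:
                records.append({"group": "sporadic", "age": censor_age, "censored": True})
            else:
                # first band whose end-of-band survival drops below u
                idx = int(np.argmax(cum_surv[1:] < ui))
                lo = float(tbl["age_lo"].iloc[idx])
                hi = float(tbl["age_hi"].iloc[idx])
                age = rng.uniform(lo, hi)
                records.append({"group": "sporadic", "age": max(age, 1e-6), "censored": False})
    else:
        crv = survival_curve.sort_values("age").reset_index(drop=True)
        surv = crv["survival"].to_numpy(float)
        ages = crv["age"].to_numpy(float)
        if np.any(np.diff(surv) > 1e-9):
            raise ValueError("survival curve must be non-increasing")
        cdf = 1.0 - surv
        censor_age = float(ages[-1])
        u = rng.uniform(size=n)
        for ui in u:
            if ui >= cdf[-1]:
                records.append({"group": "inherited", "age": censor_age, "censored": True})
            else:
                age = float(np.interp(ui, cdf, ages))
                records.append({"group": "inherited", "age": max(age, 1e-6), "censored": False})
    return IncidenceCohort(pd.DataFrame.from_records(records)).validate()


# ---------------------------------------------------------------------------
# kernels (vectorized across individuals)
# ---------------------------------------------------------------------------


def _dirichlet_logpdf(x, a):
    """Row-wise Dirichlet log density; x, a are (n, m) arrays."""
    return gammaln(a.sum(axis=1)) - gammaln(a).sum(axis=1) + ((a - 1.0) * np.log(x)).sum(axis=1)


def dirichlet_split_update(rng, y, z, shapes, rates, kappa):
    """MH re-split of latent waiting times for uncensored individuals.

    ``z`` is an (n, m) matrix of current latent times summing to ``y`` per
    row; component j has a Gamma(shapes[j], rates[j]) marginal (the
    exponential component uses shape 1).  Proposals are
    ``y * Dirichlet(kappa * z / y)``; the acceptance ratio multiplies the
    gamma density ratios by the reverse/forward proposal-density correction.
    The row sum is preserved exactly.  Returns (z_new, n_accepted).
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    n, m = z.shape
    if n == 0:
        return z, 0
    shapes = np.asarray(shapes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    x_old = z / y[:, None]
    a_fwd = kappa * x_old
    g = rng.gamma(np.maximum(a_fwd, _EPS))
    g = np.maximum(g, _EPS)
    x_new = g / g.sum(axis=1, keepdims=True)
    z_new = y[:, None] * x_new
    a_rev = kappa * x_new

    log_target_old = ((shapes - 1.0) * np.log(z) - rates * z).sum(axis=1)
    log_target_new = ((shapes - 1.0) * np.log(z_new) - rates * z_new).sum(axis=1)
    log_q_fwd = _dirichlet_logpdf(x_new, a_fwd)
    log_q_rev = _dirichlet_logpdf(x_old, a_rev)
    log_ratio = log_target_new - log_target_old + log_q_rev - log_q_fwd
    if np.any(np.isnan(log_ratio)):
        raise FloatingPointError("NaN in split-update acceptance ratio")
    accept = np.log(rng.uniform(size=n)) < log_ratio
    out = np.where(accept[:, None], z_new, z)
    return out, int(accept.sum())


def censored_rejection_update(rng, censor_ages, shapes, rates, max_attempts=10_000):
    """Rejection draws of latent times for censored individuals.

    Each row's components are drawn from their current marginals until the
    sum exceeds the censoring age.  Raises after ``max_attempts`` rounds —
    a signal of pathological parameters, never silently truncated.
    """
    censor_ages = np.asarray(censor_ages, dtype=float)
    n = censor_ages.size
    m = len(shapes)
    shapes = np.asarray(shapes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    out = np.empty((n, m))
    pending = np.ones(n, dtype=bool)
    for _ in range(max_attempts):
        if not pending.any():
            return out
        k = int(pending.sum())
        draws = rng.gamma(shapes[None, :], 1.0 / rates[None, :], size=(k, m))
        ok = draws.sum(axis=1) > censor_ages[pending]
        idx = np.flatnonzero(pending)
        out[idx[ok]] = draws[ok]
        pending[idx[ok]] = False
    raise RuntimeError(
        f"rejection sampling failed for {int(pending.sum())} censored individuals "
        f"after {max_attempts} attempts; parameters are pathological"
    )


def _gamma_pair_log_target(a, b, prior: GammaPairPrior, sum_log_z, sum_z, n):
    """Log density of (shape, rate) under gamma likelihood x conjugate prior."""
    if a <= 0 or b <= 0:
        return -np.inf
    return (
        (a - 1.0) * (prior.log_p + sum_log_z)
        - b * (prior.q + sum_z)
        - (prior.r + n) * gammaln(a)
        + a * (prior.s + n) * np.log(b)
    )


def _gamma_proposal_logpdf(x, center, concentration):
    """log density of Gamma(shape=concentration*center, rate=concentration) at x."""
    k = concentration * center
    return k * np.log(concentration) - gammaln(k) + (k - 1.0) * np.log(x) - concentration * x


def shape_rate_update(rng, z, prior: GammaPairPrior, gamma_scale, a, b):
    """MH update of a gamma (shape, rate) pair given its latent times.

    Proposals are independent gammas centred on the current values with
    variance current/gamma_scale; the Hastings correction for the asymmetric
    proposal is included.  Returns (a_new, b_new, accepted).
    """
    if gamma_scale <= 0:
        raise ValueError("gamma proposal scale must be > 0")
    z = np.asarray(z, dtype=float)
    n = z.size
    sum_log_z = float(np.sum(np.log(z))) if n else 0.0
    sum_z = float(np.sum(z)) if n else 0.0

    a_new = rng.gamma(gamma_scale * a, 1.0 / gamma_scale)
    b_new = rng.gamma(gamma_scale * b, 1.0 / gamma_scale)
    if a_new <= 0 or b_new <= 0:
        return a, b, False

    log_ratio = (
        _gamma_pair_log_target(a_new, b_new, prior, sum_log_z, sum_z, n)
        - _gamma_pair_log_target(a, b, prior, sum_log_z, sum_z, n)
        + _gamma_proposal_logpdf(a, a_new, gamma_scale)
        + _gamma_proposal_logpdf(b, b_new, gamma_scale)
        - _gamma_proposal_logpdf(a_new, a, gamma_scale)
        - _gamma_proposal_logpdf(b_new, b, gamma_scale)
    )
    if np.isnan(log_ratio):
        raise FloatingPointError("NaN in shape/rate acceptance ratio")
    if np.log(rng.uniform()) < log_ratio:
        return float(a_new), float(b_new), True
    return a, b, False


def lambda_update(rng, n_sporadic, sum_z2, prior_shape=0.01, prior_rate=0.01):
    """Exact conjugate draw: Gamma(prior_shape + n, prior_rate + sum z2)."""
    return float(rng.gamma(prior_shape + n_sporadic, 1.0 / (prior_rate + sum_z2)))


# ---------------------------------------------------------------------------
# the full sampler
# ---------------------------------------------------------------------------


def _initial_state(rng, cohort: IncidenceCohort, priors: WaitingTimePriors):
    inh = cohort.subset("inherited")
    spo = cohort.subset("sporadic")
    state = {
        "y_inh": inh.loc[~inh["censored"], "age"].to_numpy(float),
        "cens_inh": inh.loc[inh["censored"], "age"].to_numpy(float),
        "y_spo": spo.loc[~spo["censored"], "age"].to_numpy(float),
        "cens_spo": spo.loc[spo["censored"], "age"].to_numpy(float),
    }
    # moment-matched starting values from the informative prior if present
    if priors.z1.r > 1:
        mean1 = priors.z1.q / priors.z1.r
        state["a1"], state["b1"] = 2.0, 2.0 / mean1
    else:
        state["a1"], state["b1"] = 2.0, 0.1
    state["a3"], state["b3"] = 2.0, 0.1

    # deterministic proportional splits for uncensored individuals
    state["z_inh"] = np.column_stack([0.5 * state["y_inh"], 0.5 * state["y_inh"]])
    state["z_spo"] = np.column_stack(
        [0.4 * state["y_spo"], 0.2 * state["y_spo"], 0.4 * state["y_spo"]]
    )
    lam0 = 1.0 / max(np.mean(state["z_spo"][:, 1]) if len(state["y_spo"]) else 50.0, 1.0)
    state["lam"] = lam0
    return state


def run_gibbs(
    cohort: IncidenceCohort,
    priors: WaitingTimePriors,
    mu: float,
    config: SamplerConfig,
) -> PosteriorDraws:
    """Run the full Gibbs/Metropolis-Hastings scheme.

    Per iteration: re-split or re-impute the latent waiting times of every
    individual, then update (a1, b1), (a3, b3) and lambda.  Burn-in draws
    are discarded and the rest thinned.  The derived clone size is
    ``nu = lambda / mu``.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    cohort.validate()
    if len(cohort.df) == 0:
        raise ValueError("empty cohort")
    rng = np.random.default_rng(config.seed)
    st = _initial_state(rng, cohort, priors)
    n_spor_total = len(st["y_spo"]) + len(st["cens_spo"])

    # censored latents start from a rejection draw under the initial parameters
    if len(st["cens_inh"]):
        st["zc_inh"] = censored_rejection_update(
            rng, st["cens_inh"], [st["a1"], st["a3"]], [st["b1"], st["b3"]],
            config.max_rejection_attempts,
        )
    else:
        st["zc_inh"] = np.empty((0, 2))
    if len(st["cens_spo"]):
        st["zc_spo"] = censored_rejection_update(
            rng, st["cens_spo"], [st["a1"], 1.0, st["a3"]], [st["b1"], st["lam"], st["b3"]],
            config.max_rejection_attempts,
        )
    else:
        st["zc_spo"] = np.empty((0, 3))

    keep = []
    acc = {"split_inh": [0, 0], "split_spo": [0, 0], "shape_rate_1": [0, 0], "shape_rate_3": [0, 0]}
    for it in range(config.iterations):
        a1, b1, a3, b3, lam = st["a1"], st["b1"], st["a3"], st["b3"], st["lam"]
        # 1. uncensored inherited
        st["z_inh"], n_acc = dirichlet_split_update(
            rng, st["y_inh"], st["z_inh"], [a1, a3], [b1, b3], config.kappa
        )
        acc["split_inh"][0] += n_acc
        acc["split_inh"][1] += len(st["y_inh"])
        # 2. censored inherited
        if len(st["cens_inh"]):
            st["zc_inh"] = censored_rejection_update(
                rng, st["cens_inh"], [a1, a3], [b1, b3], config.max_rejection_attempts
            )
        # 3. uncensored sporadic
        st["z_spo"], n_acc = dirichlet_split_update(
            rng, st["y_spo"], st["z_spo"], [a1, 1.0, a3], [b1, lam, b3], config.kappa
        )
        acc["split_spo"][0] += n_acc
        acc["split_spo"][1] += len(st["y_spo"])
        # 4. censored sporadic
        if len(st["cens_spo"]):
            st["zc_spo"] = censored_rejection_update(
                rng, st["cens_spo"], [a1, 1.0, a3], [b1, lam, b3], config.max_rejection_attempts
            )
        # 5. shape/rate pairs
        z1_all = np.concatenate([st["z_inh"][:, 0], st["zc_inh"][:, 0], st["z_spo"][:, 0], st["zc_spo"][:, 0]])
        z3_all = np.concatenate([st["z_inh"][:, 1], st["zc_inh"][:, 1], st["z_spo"][:, 2], st["zc_spo"][:, 2]])
        if config.update_shape_rate:
            st["a1"], st["b1"], ok = shape_rate_update(rng, z1_all, priors.z1, config.gamma, a1, b1)
            acc["shape_rate_1"][0] += ok
            acc["shape_rate_1"][1] += 1
            st["a3"], st["b3"], ok = shape_rate_update(rng, z3_all, priors.z3, config.gamma, a3, b3)
            acc["shape_rate_3"][0] += ok
            acc["shape_rate_3"][1] += 1
        # 6. lambda
        z2_all = np.concatenate([st["z_spo"][:, 1], st["zc_spo"][:, 1]])
        st["lam"] = lambda_update(
            rng, n_spor_total, float(z2_all.sum()), priors.lambda_shape, priors.lambda_rate
        )
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            keep.append((st["a1"], st["b1"], st["a3"], st["b3"], st["lam"]))

    draws = pd.DataFrame(keep, columns=["a1", "b1", "a3", "b3", "lam"])
    draws["nu"] = draws["lam"] / mu
    acceptance = {k: (v[0] / v[1] if v[1] else np.nan) for k, v in acc.items()}
    logger.info("acceptance rates: %s", acceptance)
    return PosteriorDraws(draws=draws, acceptance=acceptance, mu=mu, config=config)


# ---------------------------------------------------------------------------
# intervention counterfactuals
# ---------------------------------------------------------------------------


def simulate_intervention(
    draws: PosteriorDraws,
    rho: float,
    n_per_draw: int = 200,
    max_draws: int = 500,
    seed: int = 0,
):
    """Posterior-predictive onset ages with the clone size scaled by rho.

    For each retained posterior draw, fresh (z1, z3) are drawn from their
    gamma laws and z2 from Exponential(rho * lambda); returns the onset-age
    matrix (draws x individuals) and the z2 draws.
    """
    if not 0 < rho <= 1:
        raise ValueError("rho must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    d = draws.draws
    if len(d) > max_draws:
        idx = rng.choice(len(d), size=max_draws, replace=False)
        d = d.iloc[np.sort(idx)]
    a1 = d["a1"].to_numpy()[:, None]
    b1 = d["b1"].to_numpy()[:, None]
    a3 = d["a3"].to_numpy()[:, None]
    b3 = d["b3"].to_numpy()[:, None]
    lam = d["lam"].to_numpy()[:, None]
    shape = (len(d), n_per_draw)
    z1 = rng.gamma(a1, 1.0 / b1, size=shape)
    z3 = rng.gamma(a3, 1.0 / b3, size=shape)
    z2 = rng.exponential(1.0 / (rho * lam), size=shape)
    return z1 + z2 + z3, z2


def intervention_curves(
    draws: PosteriorDraws,
    rho: float,
    ages=None,
    n_per_draw: int = 200,
    max_draws: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Predicted cumulative incidence by age with pointwise 95% bands."""
    if ages is None:
        ages = np.arange(0.0, 91.0, 1.0)
    ages = np.asarray(ages, dtype=float)
    onset, _ = simulate_intervention(draws, rho, n_per_draw=n_per_draw, max_draws=max_draws, seed=seed)
    cum = (onset[:, :, None] <= ages[None, None, :]).mean(axis=1)  # draws x ages
    lo, hi = np.percentile(cum, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "age": ages,
            "cumulative_incidence": cum.mean(axis=0),
            "lo95": lo,
            "hi95": hi,
            "rho": rho,
        }
    )
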