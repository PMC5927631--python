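"""Chronological timing of clonal single-copy arm gains and the MRCA.

Counting model: a gained region of length ``L`` sits in a callable diploid
genome of size ``G``, so each haplotype copy of the region accrues mutations
at ``rate * L / G`` per year.  Before the gain (age 0 to ``t``) the
later-duplicated haplotype collects the mutations that end up on two copies
(``n_pre``); the untouched haplotype collects single-copy mutations over the
whole clonal period and, after the gain, three copies accrue single-copy
mutations.  Hence

    E[n_pre]    = r t                    with r = rate * L / G
    E[n_single] = r t + 3 r (T - t)      (T = age of the MRCA)

and the fraction of clonal time at the gain, pi = t / T, has the plug-in
estimator ``3 n_pre / (2 n_pre + n_single)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: callable diploid genome size (bp) used throughout as the default
DEFAULT_GENOME_SIZE = 5.32e9

#: total tumor copy number for which the closed forms hold (single-copy gain)
SUPPORTED_GAIN_CN = 3


@dataclass(frozen=True)
class GainTimingEstimate:
    """Point estimate and CI for the age of a clonal gain."""

    n_pre: int
    n_single: int
    pi: float
    gain_age: float
    mrca_age: float
    ci_low: float
    ci_high: float
    method: str  # "fraction" | "direct"
    region_length: float | None = None
    genome_size: float | None = None


def check_single_copy_gain(tumor_total_cn) -> None:
    """Reject gain configurations the closed forms do not cover.

    The pre/post counting model assumes exactly one extra copy (total CN 3);
    higher-order gains would need a different multiplicity calculus, so they
    are refused rather than guessed at.
    """
    cns = np.unique(np.asarray(tumor_total_cn))
    if not np.all(cns == SUPPORTED_GAIN_CN):
        raise ValueError(
            f"timing closed forms assume a single-copy gain (total CN "
            f"{SUPPORTED_GAIN_CN}); region has total CN {sorted(cns.tolist())}"
        )


def fraction_clonal_time(n_pre, n_single) -> float:
    """Fraction of clonal molecular time at which the gain occurred.

    ``pi = 3 n_pre / (2 n_pre + n_single)``, clamped to [0, 1]; clamping is
    logged, never silent.
    """
    n_pre = float(n_pre)
    n_single = float(n_single)
    if n_pre < 0 or n_single < 0:
        raise ValueError("counts must be non-negative")
    if n_pre + n_single == 0:
        raise ValueError("at least one of n_pre, n_single must be positive")
    raw = 3.0 * n_pre / (2.0 * n_pre + n_single)
    if raw > 1.0:
        logger.warning("raw clonal-time fraction %.4f > 1; clamped to 1", raw)
        return 1.0
    return raw


def age_of_gain_fraction(pi: float, mrca_age: float) -> float:
    """Gain age as a fraction of the time to the MRCA: ``pi * mrca_age``."""
    if not 0 <= pi <= 1:
        raise ValueError("pi must lie in [0, 1]")
    if mrca_age <= 0:
        raise ValueError("mrca_age must be positive")
    return pi * mrca_age


def age_of_gain_direct(n_pre, rate, region_length, genome_size=DEFAULT_GENOME_SIZE) -> float:
    """Gain age directly from the pre-gain count and the per-year rate.

    Pre-gain mutations accrue on one haplotype of the region at
    ``rate * L / G`` per year, so age = ``n_pre * G / (rate * L)``.
    """
    if rate <= 0 or region_length <= 0 or genome_size <= 0:
        raise ValueError("rate, region_length and genome_size must be positive")
    return float(n_pre) * genome_size / (rate * region_length)


def mrca_age(clonal_burden, rate) -> float:
    """Age of the MRCA: clonal mutation burden / mutations per year."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return float(clonal_burden) / rate


def bootstrap_timing(
    n_pre: int,
    n_single: int,
    clonal_burden: int,
    rate_mean: float,
    rate_sd: float,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "fraction",
    region_length: float | None = None,
    genome_size: float = DEFAULT_GENOME_SIZE,
) -> GainTimingEstimate:
    """Parametric-bootstrap CI for the gain age.

    Counts are resampled as Poisson at their observed values and the rate as
    Normal(rate_mean, rate_sd) truncated at zero, propagating both sources of
    uncertainty into the recomputed age.  CI bounds are the 2.5/97.5
    percentiles of the bootstrap ages.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if rate_sd < 0:
        raise ValueError("rate_sd must be >= 0")
    if method not in ("fraction", "direct"):
        raise ValueError(f"unknown method {method!r}")
    if method == "direct" and region_length is None:
        raise ValueError("direct method requires region_length")

    rng = np.random.default_rng(seed)
    pre_b = rng.poisson(n_pre, size=n_boot)
    burden_b = rng.poisson(clonal_burden, size=n_boot)
    rates_b = rng.normal(rate_mean, rate_sd, size=n_boot)
    # truncate at 0: redraw non-positive rates
    while np.any(rates_b <= 0):
        bad = rates_b <= 0
        rates_b[bad] = rng.normal(rate_mean, rate_sd, size=bad.sum())

    mrca_b = burden_b / rates_b
    if method == "fraction":
        single_b = rng.poisson(n_single, size=n_boot)
        denom = 2.0 * pre_b + single_b
        pi_b = np.where(denom > 0, 3.0 * pre_b / np.maximum(denom, 1), 0.0)
        pi_b = np.clip(pi_b, 0.0, 1.0)
        ages_b = pi_b * mrca_b
        pi_hat = fraction_clonal_time(n_pre, n_single)
        point = age_of_gain_fraction(pi_hat, mrca_age(clonal_burden, rate_mean))
    else:
        ages_b = pre_b * genome_size / (rates_b * region_length)
        pi_hat = fraction_clonal_time(n_pre, n_single) if (n_pre + n_single) else float("nan")
        point = age_of_gain_direct(n_pre, rate_mean, region_length, genome_size)

    lo, hi = np.percentile(ages_b, [2.5, 97.5])
    return GainTimingEstimate(
        n_pre=int(n_pre),
        n_single=int(n_single),
        pi=float(pi_hat),
        gain_age=float(point),
        mrca_age=float(mrca_age(clonal_burden, rate_mean)),
        ci_low=float(lo),
        ci_high=float(hi),
        method=method,
        region_length=region_length,
        genome_size=genome_size,
    )
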