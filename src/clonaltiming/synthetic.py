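"""Ground-truth generators for every input the pipeline consumes.

Mutations accrue as Poisson processes along the branches of a known clone
tree; a timed single-copy gain of a region of length ``L`` splits its clonal
mutations into a duplicated (two-copy) and a single-copy set; reads are
Binomial draws at fixed depth given purity, local copy number and
multiplicity.  Incidence cohorts are drawn from the generative
three-waiting-time model (gamma + exponential + gamma, with administrative
censoring).  Breakpoint clusters are drawn either with uniformly random join
orientations and a two-state oscillating copy-number track, or with biased
orientations and a stepwise track.

All randomness flows from a single integer seed through a named
``numpy.random.Generator``; no global state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .ccf import CopyNumberProfile, MutationTable
from .hallmarks import ORIENTATIONS, RearrangementCluster

#: callable diploid genome size in bp
DEFAULT_GENOME_SIZE = 5.32e9

#: length of the synthetic diploid background contig (chrom "1")
_BACKGROUND_LENGTH = 240_000_000

_REGION_CHROM = "5"
_BACKGROUND_CHROM = "1"

_PYRIMIDINES = ("C", "T")
_BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# clone trees and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CloneNode:
    """One clone: parent pointer, per-sample CCF, and branch duration."""

    clone_id: str
    parent: Optional[str]
    ccf: Mapping[str, float]
    branch_years: float


@dataclass(frozen=True)
class SyntheticTruth:
    """Full generator-side truth for one synthetic patient.

    depth=None means noise-free sequencing: alt/total read columns carry the
    exact expected VAF as floats (total_reads == 1.0).
    """

    rate: float  # mutations / year over the callable diploid genome
    age: float  # age at surgery, years
    clones: Sequence[CloneNode]
    mrca_age: float
    purity: Mapping[str, float]
    depth: Optional[int]
    region_length: float
    genome_size: float = DEFAULT_GENOME_SIZE
    t_dup: Optional[float] = None  # age of the region gain; None = no gain
    patient: str = "P1"

    @property
    def samples(self) -> list:
        return sorted(self.purity)

    @property
    def root(self) -> CloneNode:
        roots = [c for c in self.clones if c.parent is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        return roots[0]

    def children_of(self, clone_id: str) -> list:
        return [c for c in self.clones if c.parent == clone_id]

    def validate(self) -> "SyntheticTruth":
        if self.rate <= 0:
            raise ValueError("mutation rate must be > 0")
        if self.t_dup is not None and not (0 < self.t_dup <= self.mrca_age):
            raise ValueError("need 0 < t_dup <= mrca_age")
        if not (0 < self.mrca_age <= self.age):
            raise ValueError("need 0 < mrca_age <= age")
        if self.region_length > self.genome_size:
            raise ValueError("region_length must be <= genome_size")
        for sample, p in self.purity.items():
            if not (0 < p <= 1):
                raise ValueError(f"purity of {sample} must lie in (0, 1]")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive (or None for noise-free)")
        root = self.root  # also checks single root
        for s in self.samples:
            if abs(root.ccf.get(s, 0.0) - 1.0) > 1e-6:
                raise ValueError("root clone must be fully clonal (CCF 1) in every sample")
        ids = {c.clone_id for c in self.clones}
        for clone in self.clones:
            if clone.parent is not None and clone.parent not in ids:
                raise ValueError(f"unknown parent {clone.parent}")
            if clone.branch_years < 0:
                raise ValueError("branch durations must be >= 0")
            kids = self.children_of(clone.clone_id)
            for s in self.samples:
                total = sum(k.ccf.get(s, 0.0) for k in kids)
                if total > clone.ccf.get(s, 0.0) + 1e-6:
                    raise ValueError(
                        f"pigeonhole violated at clone {clone.clone_id} in sample {s}: "
                        f"children CCFs sum to {total:.3f}"
                    )
        return self


def single_clone_truth(
    rate: float,
    age: float,
    purity: float = 1.0,
    depth: Optional[int] = 100,
    t_dup: Optional[float] = None,
    region_length: float = 1.33e8,
    genome_size: float = DEFAULT_GENOME_SIZE,
    samples: Sequence[str] = ("R1",),
) -> SyntheticTruth:
    """Convenience truth with one fully clonal clone (MRCA at surgery)."""
    clones = [
        CloneNode("clonal", None, {s: 1.0 for s in samples}, branch_years=age),
    ]
    return SyntheticTruth(
        rate=rate,
        age=age,
        clones=clones,
        mrca_age=age,
        purity={s: purity for s in samples},
        depth=depth,
        region_length=region_length,
        genome_size=genome_size,
        t_dup=t_dup,
    ).validate()


def two_clone_truth(
    rate: float = 87.0,
    age: float = 60.0,
    mrca_age: float = 40.0,
    subclone_ccf: float = 0.4,
    purity: float = 0.8,
    depth: Optional[int] = 100,
    t_dup: Optional[float] = 10.0,
    region_length: float = 1.33e8,
    samples: Sequence[str] = ("R1", "R2"),
) -> SyntheticTruth:
    """Convenience truth: clonal trunk plus one subclone at a shared CCF."""
    clones = [
        CloneNode("clonal", None, {s: 1.0 for s in samples}, branch_years=mrca_age),
        CloneNode("sub1", "clonal", {s: subclone_ccf for s in samples}, branch_years=age - mrca_age),
    ]
    return SyntheticTruth(
        rate=rate,
        age=age,
        clones=clones,
        mrca_age=mrca_age,
        purity={s: purity for s in samples},
        depth=depth,
        region_length=region_length,
        t_dup=t_dup,
    ).validate()


# ---------------------------------------------------------------------------
# mutation tables
# ---------------------------------------------------------------------------


def _random_context(rng: np.random.Generator, n: int):
    """Pyrimidine-centred trinucleotide contexts with matching ref/alt bases."""
    mids = rng.choice(_PYRIMIDINES, size=n)
    fives = rng.choice(_BASES, size=n)
    threes = rng.choice(_BASES, size=n)
    refs = mids
    alts = np.empty(n, dtype="<U1")
    for i, ref in enumerate(refs):
        choices = [b for b in _BASES if b != ref]
        alts[i] = choices[rng.integers(len(choices))]
    contexts = np.char.add(np.char.add(fives, mids), threes)
    return contexts, refs, alts


def _expected_vaf(purity: float, ccf: float, multiplicity: int, tumor_cn: int) -> float:
    return purity * multiplicity * ccf / (purity * tumor_cn + (1.0 - purity) * 2.0)


def simulate_mutation_table(truth: SyntheticTruth, seed: int) -> tuple[MutationTable, CopyNumberProfile]:
    """Draw a multi-region mutation table and copy-number profile from truth.

    Counts per branch are Poisson at rate x branch duration, with the gained
    region's clonal counts following the duplication model (see module
    docstring); reads are Binomial(depth, expected VAF).  Deterministic for a
    fixed seed.
    """
    truth.validate()
    rng = np.random.default_rng(seed)
    L, G = truth.region_length, truth.genome_size
    has_gain = truth.t_dup is not None
    region_cn = 3 if has_gain else 2
    bg_fraction = (G - 2 * L) / G

    # per-clone mutation counts by category
    plan = []  # (clone, category, count, multiplicity, chrom, tumor_cn)
    for clone in truth.clones:
        is_root = clone.parent is None
        b = clone.branch_years
        n_bg = rng.poisson(truth.rate * b * bg_fraction)
        plan.append((clone, "background", n_bg, 1, _BACKGROUND_CHROM, 2))
        if is_root and has_gain:
            t = truth.t_dup
            T = truth.mrca_age
            n_pre = rng.poisson(truth.rate * t * L / G)
            n_single = rng.poisson(truth.rate * t * L / G + 3 * truth.rate * (T - t) * L / G)
            plan.append((clone, "pre_gain", n_pre, 2, _REGION_CHROM, 3))
            plan.append((clone, "post_gain_clonal", n_single, 1, _REGION_CHROM, 3))
        else:
            copies_in_region = 3 if has_gain and not is_root else 2
            scale = copies_in_region * L / G
            n_reg = rng.poisson(truth.rate * b * scale)
            category = "region_subclonal" if not is_root else "region_clonal"
            plan.append((clone, category, n_reg, 1, _REGION_CHROM, region_cn))

    samples = truth.samples
    rows = []
    truth_rows = []
    counter = 0
    for clone, category, count, multiplicity, chrom, tumor_cn in plan:
        if count == 0:
            continue
        if chrom == _REGION_CHROM:
            positions = rng.integers(0, int(L), size=count)
        else:
            positions = rng.integers(0, _BACKGROUND_LENGTH, size=count)
        contexts, refs, alts = _random_context(rng, count)
        for j in range(count):
            mut_id = f"{truth.patient}:{chrom}:{positions[j]}:{counter}"
            counter += 1
            truth_rows.append(
                {
                    "mutation_id": mut_id,
                    "clone": clone.clone_id,
                    "category": category,
                    "multiplicity": multiplicity,
                    "tumor_cn": tumor_cn,
                }
            )
            for s in samples:
                vaf = _expected_vaf(truth.purity[s], clone.ccf.get(s, 0.0), multiplicity, tumor_cn)
                if truth.depth is None:
                    alt_reads, total_reads = vaf, 1.0
                else:
                    total_reads = truth.depth
                    alt_reads = int(rng.binomial(total_reads, vaf))
                rows.append(
                    {
                        "patient": truth.patient,
                        "mutation_id": mut_id,
                        "sample": s,
                        "chrom": chrom,
                        "pos": int(positions[j]),
                        "ref": refs[j],
                        "alt": alts[j],
                        "alt_reads": alt_reads,
                        "total_reads": total_reads,
                        "context": contexts[j],
                    }
                )

    mut_df = pd.DataFrame.from_records(rows)
    truth_df = pd.DataFrame.from_records(truth_rows)

    cn_rows = []
    for s in samples:
        cn_rows.append(
            {
                "patient": truth.patient,
                "sample": s,
                "chrom": _BACKGROUND_CHROM,
                "start": 0,
                "end": _BACKGROUND_LENGTH,
                "major_cn": 1,
                "minor_cn": 1,
                "purity": truth.purity[s],
            }
        )
        cn_rows.append(
            {
                "patient": truth.patient,
                "sample": s,
                "chrom": _REGION_CHROM,
                "start": 0,
                "end": int(L),
                "major_cn": 2 if has_gain else 1,
                "minor_cn": 1,
                "purity": truth.purity[s],
            }
        )
    cn = CopyNumberProfile(pd.DataFrame.from_records(cn_rows)).validate()
    table = MutationTable(mut_df, truth=truth_df)
    if truth.depth is not None:
        table.validate()
    return table, cn


def simulate_gain_counts(
    t_dup: float,
    mrca_age: float,
    rate: float,
    region_length: float,
    genome_size: float = DEFAULT_GENOME_SIZE,
    seed: int = 0,
) -> tuple[int, int]:
    """Draw (n_pre, n_single_clonal) for a timed single-copy gain.

    n_pre ~ Poisson(rate * t_dup * L / G) — one haplotype, later duplicated;
    n_single ~ Poisson(rate * t_dup * L / G + 3 * rate * (mrca_age - t_dup) * L / G)
    — the other pre-gain haplotype plus three post-gain copies.
    """
    if not 0 < t_dup <= mrca_age:
        raise ValueError("need 0 < t_dup <= mrca_age")
    if region_length > genome_size:
        raise ValueError("region_length must be <= genome_size")
    rng = np.random.default_rng(seed)
    per_copy = rate * region_length / genome_size
    n_pre = rng.poisson(per_copy * t_dup)
    n_single = rng.poisson(per_copy * t_dup + 3 * per_copy * (mrca_age - t_dup))
    return int(n_pre), int(n_single)


# ---------------------------------------------------------------------------
# incidence cohorts
# ---------------------------------------------------------------------------


@dataclass
class IncidenceCohort:
    """Event / censoring ages for sporadic and inherited individuals.

    ``df`` columns: group ('sporadic' | 'inherited'), age (event age, or the
    censoring age when censored), censored (bool).
    """

    df: pd.DataFrame

    def validate(self) -> "IncidenceCohort":
        required = {"group", "age", "censored"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"incidence cohort missing columns: {sorted(missing)}")
        if (self.df["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad = set(self.df["group"]) - {"sporadic", "inherited"}
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        return self

    def subset(self, group: str) -> pd.DataFrame:
        return self.df[self.df["group"] == group]


def simulate_incidence_cohort(
    nu: float,
    mu: float,
    z1_shape: float,
    z1_rate: float,
    z3_shape: float,
    z3_rate: float,
    n_sporadic: int,
    n_inherited: int,
    censor_age: float = 85.0,
    seed: int = 0,
) -> IncidenceCohort:
    """Draw a cohort from the generative three-waiting-time model.

    Inherited ages are Z1 + Z3 (gamma + gamma); sporadic ages add
    Z2 ~ Exponential(nu * mu).  Individuals whose sum exceeds ``censor_age``
    are administratively censored at that age.
    """
    for name, val in [
        ("nu", nu), ("mu", mu), ("z1_shape", z1_shape), ("z1_rate", z1_rate),
        ("z3_shape", z3_shape), ("z3_rate", z3_rate), ("censor_age", censor_age),
    ]:
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    lam = nu * mu
    records = []
    for group, n in (("sporadic", n_sporadic), ("inherited", n_inherited)):
        z1 = rng.gamma(z1_shape, 1.0 / z1_rate, size=n)
        z3 = rng.gamma(z3_shape, 1.0 / z3_rate, size=n)
        total = z1 + z3
        if group == "sporadic":
            total = total + rng.exponential(1.0 / lam, size=n)
        censored = total > censor_age
        ages = np.where(censored, censor_age, total)
        for a, c in zip(ages, censored):
            records.append({"group": group, "age": float(a), "censored": bool(c)})
    return IncidenceCohort(pd.DataFrame.from_records(records)).validate()


# ---------------------------------------------------------------------------
# branch burdens for the rate model
# ---------------------------------------------------------------------------


def simulate_branch_burdens(
    n_patients: int,
    rate_mean: float,
    rate_sd: float,
    n_branches: int = 3,
    age_range: tuple[float, float] = (40.0, 75.0),
    seed: int = 0,
    noise: str = "poisson",
) -> pd.DataFrame:
    """Per-branch cumulative burdens under patient-specific linear rates.

    Patient slopes are Normal(rate_mean, rate_sd) truncated at zero; each
    branch burden is Poisson(slope * age) (``noise="poisson"``) or exact
    (``noise="none"``).  Returns columns patient, branch, burden, age plus a
    ``true_slope`` truth column.
    """
    if noise not in ("poisson", "none"):
        raise ValueError("noise must be 'poisson' or 'none'")
    rng = np.random.default_rng(seed)
    slopes = rng.normal(rate_mean, rate_sd, size=n_patients)
    while np.any(slopes <= 0):
        bad = slopes <= 0
        slopes[bad] = rng.normal(rate_mean, rate_sd, size=bad.sum())
    ages = rng.uniform(*age_range, size=n_patients)
    rows = []
    for i in range(n_patients):
        for b in range(n_branches):
            mean = slopes[i] * ages[i]
            burden = rng.poisson(mean) if noise == "poisson" else mean
            rows.append(
                {
                    "patient": f"P{i:03d}",
                    "branch": f"b{b}",
                    "burden": float(burden),
                    "age": float(ages[i]),
                    "true_slope": float(slopes[i]),
                }
            )
    return pd.DataFrame.from_records(rows)


# ---------------------------------------------------------------------------
# breakpoint clusters
# ---------------------------------------------------------------------------


def simulate_breakpoint_cluster(kind: str, n_breakpoints: int, seed: int = 0) -> RearrangementCluster:
    """A synthetic rearrangement cluster of the given kind.

    ``"chromothripsis"`` draws the four join orientations uniformly and
    produces a two-state oscillating copy-number track; ``"sequential"``
    produces orientation-biased joins and a stepwise (non-oscillating) track
    with more than two states for n >= 6 segments.
    """
    if n_breakpoints < 4:
        raise ValueError("n_breakpoints must be >= 4")
    rng = np.random.default_rng(seed)
    window_start = int(rng.integers(1_000_000, 50_000_000))
    positions = np.sort(rng.integers(window_start, window_start + 2_000_000, size=n_breakpoints))
    partner_chroms = rng.choice(["3", "5"], size=n_breakpoints)
    partner_pos = rng.integers(1_000_000, 180_000_000, size=n_breakpoints)
    breakpoints = [
        ("3", int(positions[i]), str(partner_chroms[i]), int(partner_pos[i]))
        for i in range(n_breakpoints)
    ]
    if kind == "chromothripsis":
        orientations = list(rng.choice(ORIENTATIONS, size=n_breakpoints))
        low = int(rng.integers(1, 3))
        track = np.array([low if i % 2 == 0 else low + 1 for i in range(n_breakpoints + 1)])
    elif kind == "sequential":
        probs = np.array([0.7, 0.1, 0.1, 0.1])
        orientations = list(rng.choice(ORIENTATIONS, size=n_breakpoints, p=probs))
        track = np.array([2 + i // 2 for i in range(n_breakpoints + 1)])
    else:
        raise ValueError(f"unknown cluster kind {kind!r}")
    return RearrangementCluster(
        breakpoints=breakpoints,
        orientations=orientations,
        cn_track=track,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# emulated published-curve shapes
# ---------------------------------------------------------------------------


def incidence_table_from_model(
    nu: float,
    mu: float,
    z1_shape: float,
    z1_rate: float,
    z3_shape: float,
    z3_rate: float,
    band_width: float = 5.0,
    max_age: float = 90.0,
    n_mc: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Age-banded annual incidence per 100,000, emulated from the model.

    Monte-Carlo draws of sporadic onset ages are converted to per-band annual
    hazard estimates; mirrors the shape of published population incidence
    tables without shipping any external data.
    """
    rng = np.random.default_rng(seed)
    z1 = rng.gamma(z1_shape, 1.0 / z1_rate, size=n_mc)
    z3 = rng.gamma(z3_shape, 1.0 / z3_rate, size=n_mc)
    z2 = rng.exponential(1.0 / (nu * mu), size=n_mc)
    onset = z1 + z2 + z3
    edges = np.arange(0.0, max_age + band_width, band_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        at_risk = int(np.sum(onset >= lo))
        events = int(np.sum((onset >= lo) & (onset < hi)))
        hazard = events / (band_width * at_risk) if at_risk else 0.0
        rows.append({"age_lo": lo, "age_hi": hi, "rate_per_100k": hazard * 1e5})
    return pd.DataFrame.from_records(rows)


def survival_curve_from_model(
    z1_shape: float,
    z1_rate: float,
    z3_shape: float,
    z3_rate: float,
    max_age: float = 85.0,
    step: float = 1.0,
    n_mc: int = 200_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Event-free survival of carriers (Z1 + Z3), emulated from the model."""
    rng = np.random.default_rng(seed)
    onset = rng.gamma(z1_shape, 1.0 / z1_rate, size=n_mc) + rng.gamma(
        z3_shape, 1.0 / z3_rate, size=n_mc
    )
    ages = np.arange(0.0, max_age + step, step)
    surv = [(onset > a).mean() for a in ages]
    return pd.DataFrame({"age": ages, "survival": surv})
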