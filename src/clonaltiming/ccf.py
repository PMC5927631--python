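"""Mutation copy number from read counts, and pre/post-gain classification.

A variant allele fraction observed in an impure tumor sample is converted to
the expected number of mutated copies per cancer cell,

    copies = vaf * (purity * cn_tumor + (1 - purity) * cn_normal) / purity,

which equals multiplicity x CCF under the standard model.  In a region with a
clonal single-copy gain (total CN 3), clonal mutations acquired before the
gain sit on two of the three copies (copies ~ 2) and mutations acquired after
sit on one (copies ~ 1); thresholding the copies estimate therefore times
each mutation relative to the gain, and a per-sample vote gives a consensus
call for multi-region data.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default (low, high) boundaries on the copies estimate: <= low -> post,
#: >= high -> pre, in between -> uncertain
DEFAULT_BOUNDARIES = (1.25, 1.75)


@dataclass
class MutationTable:
    """Long-format per-mutation, per-sample read counts.

    ``df`` columns: mutation_id, sample, chrom, pos (0-based), ref, alt,
    alt_reads, total_reads, context (pyrimidine-centred trinucleotide).
    ``truth``, if present, carries generator-side ground truth per mutation
    (clone, multiplicity, category); it is never written to disk.
    """

    df: pd.DataFrame
    truth: pd.DataFrame | None = None

    def validate(self) -> "MutationTable":
        df = self.df
        required = {"mutation_id", "sample", "chrom", "pos", "alt_reads", "total_reads"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"mutation table missing columns: {sorted(missing)}")
        if (df["total_reads"] < 0).any():
            raise ValueError("total_reads must be >= 0")
        if (df["alt_reads"] > df["total_reads"]).any():
            raise ValueError("alt_reads must be <= total_reads")
        if "context" in df.columns:
            ctx = df["context"].dropna()
            bad = ~(ctx.str.len().eq(3) & ctx.str[1].isin(["C", "T"]))
            if bad.any():
                raise ValueError("contexts must be 3 bases with a pyrimidine middle base")
        return self

    @property
    def samples(self) -> list:
        return sorted(self.df["sample"].unique())

    def vaf(self) -> pd.Series:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.df["alt_reads"] / self.df["total_reads"]


@dataclass
class CopyNumberProfile:
    """Allele-specific copy-number segments plus per-sample purity.

    ``df`` columns: sample, chrom, start, end (0-based half-open), major_cn,
    minor_cn, purity.
    """

    df: pd.DataFrame

    def validate(self) -> "CopyNumberProfile":
        df = self.df
        required = {"sample", "chrom", "start", "end", "major_cn", "minor_cn", "purity"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"copy-number profile missing columns: {sorted(missing)}")
        if ((df["purity"] <= 0) | (df["purity"] > 1)).any():
            raise ValueError("purity must lie in (0, 1]")
        if (df["major_cn"] < df["minor_cn"]).any():
            raise ValueError("major_cn must be >= minor_cn")
        if (df["minor_cn"] < 0).any():
            raise ValueError("minor_cn must be >= 0")
        for (_, _), grp in df.groupby(["sample", "chrom"]):
            srt = grp.sort_values("start")
            if (srt["end"].values[:-1] > srt["start"].values[1:]).any():
                raise ValueError("segments overlap within a sample")
        return self

    def purity_of(self, sample: str) -> float:
        vals = self.df.loc[self.df["sample"] == sample, "purity"].unique()
        if len(vals) != 1:
            raise ValueError(f"ambiguous purity for sample {sample}")
        return float(vals[0])


def _frame(obj):
    return obj.df if hasattr(obj, "df") else obj


class TimingLabel(str, Enum):
    """Timing of a mutation relative to a clonal copy-number gain."""

    PRE = "pre"
    POST = "post"
    UNCERTAIN = "uncertain"


@dataclass(frozen=True)
class TimingCall:
    """A timing label together with the continuous copies estimate."""

    label: TimingLabel
    copies: float


def mutation_copies(
    vaf,
    purity,
    tumor_total_cn,
    normal_cn=2.0,
):
    """Expected mutated copies per cancer cell (multiplicity x CCF).

    Parameters
    ----------
    vaf:
        Variant allele fraction(s) in [0, 1]; scalar or array.
    purity:
        Tumor cell fraction of the sample, in (0, 1].
    tumor_total_cn:
        Total (major + minor) copy number at the locus in tumor cells.
    normal_cn:
        Copy number in contaminating normal cells (2 off the allosomes).

    Returns
    -------
    float or ndarray
        ``vaf * (purity * tumor_total_cn + (1 - purity) * normal_cn) / purity``.

    Notes
    -----
    A VAF above the attainable maximum (all tumor copies mutated) triggers a
    warning; the value is still returned so callers can inspect outliers.
    """
    vaf = np.asarray(vaf, dtype=float)
    purity = np.asarray(purity, dtype=float)
    tumor_total_cn = np.asarray(tumor_total_cn, dtype=float)
    normal_cn = np.asarray(normal_cn, dtype=float)
    if np.any(purity <= 0):
        raise ValueError("purity must be > 0")
    if np.any(purity > 1):
        raise ValueError("purity must be <= 1")
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("vaf must lie in [0, 1]")
    if np.any(tumor_total_cn < 1):
        raise ValueError("tumor_total_cn must be >= 1")

    denom = purity * tumor_total_cn + (1.0 - purity) * normal_cn
    vaf_max = purity * tumor_total_cn / denom
    if np.any(vaf > vaf_max + 1e-12):
        warnings.warn(
            "VAF exceeds the maximum attainable for the given purity and copy "
            "number; copies estimate will exceed the total tumor copy number",
            stacklevel=2,
        )
    out = vaf * denom / purity
    if out.ndim == 0:
        return float(out)
    return out


def classify_pre_post(copies, boundaries=DEFAULT_BOUNDARIES):
    """Label a copies estimate as pre- or post-gain, abstaining in between."""
    low, high = boundaries
    if not (0 < low < high):
        raise ValueError("boundaries must satisfy 0 < low < high")
    copies = float(copies)
    if copies >= high:
        label = TimingLabel.PRE
    elif copies <= low:
        label = TimingLabel.POST
    else:
        label = TimingLabel.UNCERTAIN
    return TimingCall(label=label, copies=copies)


def consensus_vote(labels):
    """Strict-majority vote over per-sample timing labels.

    Uncertain labels carry no vote; ties and all-uncertain inputs return
    :attr:`TimingLabel.UNCERTAIN`.
    """
    labels = [lab.label if isinstance(lab, TimingCall) else TimingLabel(lab) for lab in labels]
    if not labels:
        raise ValueError("consensus_vote requires at least one label")
    counts = Counter(lab for lab in labels if lab is not TimingLabel.UNCERTAIN)
    n_pre = counts.get(TimingLabel.PRE, 0)
    n_post = counts.get(TimingLabel.POST, 0)
    if n_pre > n_post:
        return TimingLabel.PRE
    if n_post > n_pre:
        return TimingLabel.POST
    return TimingLabel.UNCERTAIN


def _segment_lookup(cn: pd.DataFrame, sample: str, chrom, pos: int):
    """Return (purity, major, minor) for a position, or None outside segments."""
    rows = cn[(cn["sample"] == sample) & (cn["chrom"].astype(str) == str(chrom))]
    hit = rows[(rows["start"] <= pos) & (pos < rows["end"])]
    if hit.empty:
        return None
    row = hit.iloc[0]
    return float(row["purity"]), int(row["major_cn"]), int(row["minor_cn"])


def annotate_copies(
    mutations,
    cn_segments,
    normal_cn: float = 2.0,
) -> pd.DataFrame:
    """Attach per-row copies estimates to a long-format mutation table.

    ``mutations`` needs columns sample, chrom, pos, alt_reads, total_reads;
    ``cn_segments`` needs sample, chrom, start, end (0-based half-open),
    major_cn, minor_cn, purity.  Rows falling outside any copy-number
    segment get NaN copies.
    """
    mutations = _frame(mutations)
    cn_segments = _frame(cn_segments)
    copies = np.full(len(mutations), np.nan)
    total_cn = np.full(len(mutations), np.nan)
    for i, row in enumerate(mutations.itertuples(index=False)):
        seg = _segment_lookup(cn_segments, row.sample, row.chrom, row.pos)
        if seg is None:
            continue
        purity, major, minor = seg
        cn_tot = major + minor
        total_cn[i] = cn_tot
        if row.total_reads <= 0:
            continue
        vaf = min(row.alt_reads / row.total_reads, 1.0)
        with warnings.catch_warnings():
            # read-sampling noise routinely pushes single VAFs past the
            # attainable maximum; not informative at table scale
            warnings.simplefilter("ignore")
            copies[i] = mutation_copies(vaf, purity, cn_tot, normal_cn)
    out = mutations.copy()
    out["tumor_total_cn"] = total_cn
    out["copies"] = copies
    return out


def consensus_gain_timing(
    annotated: pd.DataFrame,
    boundaries=DEFAULT_BOUNDARIES,
    min_alt_reads: int = 1,
) -> pd.DataFrame:
    """Per-mutation consensus pre/post-gain labels across samples.

    Only rows with at least ``min_alt_reads`` alternate reads vote — a
    mutation absent from a sample carries no timing information about the
    gain.  Returns one row per mutation_id with columns ``label`` and
    ``n_votes``.
    """
    records = []
    for mut_id, grp in annotated.groupby("mutation_id", sort=False):
        votes = []
        for row in grp.itertuples(index=False):
            if row.alt_reads < min_alt_reads or not np.isfinite(row.copies):
                continue
            votes.append(classify_pre_post(row.copies, boundaries))
        label = consensus_vote(votes) if votes else TimingLabel.UNCERTAIN
        records.append({"mutation_id": mut_id, "label": label.value, "n_votes": len(votes)})
    return pd.DataFrame.from_records(records)
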