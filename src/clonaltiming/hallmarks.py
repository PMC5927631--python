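"""Quantitative hallmark checks for chromothripsis-like rearrangement clusters.

Two statistics are computed on a cluster of rearrangement joins: a
goodness-of-fit test of the four join orientation classes against the uniform
multinomial (shattering joins fragments in random orientation), and the
degree to which the segment copy-number track oscillates between two states.
A simple rule over both, plus a minimum number of joins, classifies a cluster
as chromothripsis-consistent or not.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: the four join orientation classes
ORIENTATIONS = ("del", "dup", "head_head", "tail_tail")

DEFAULT_THRESHOLDS = {
    "orientation_p": 0.05,  # verdict requires p > this (cannot reject uniformity)
    "oscillation_fraction": 0.7,
    "min_breakpoints": 8,
}


@dataclass
class RearrangementCluster:
    """A cluster of rearrangement joins plus the segment copy-number track."""

    breakpoints: list  # (chrom, pos, partner_chrom, partner_pos) tuples
    orientations: list  # one of ORIENTATIONS per join
    cn_track: np.ndarray  # ordered total copy number per segment
    kind: str | None = field(default=None)  # generator label, if synthetic

    def __post_init__(self):
        bad = set(self.orientations) - set(ORIENTATIONS)
        if bad:
            raise ValueError(f"unknown orientation classes: {sorted(bad)}")
        self.cn_track = np.asarray(self.cn_track)
        if np.any(self.cn_track < 0):
            raise ValueError("copy number states must be >= 0")

    @property
    def n_breakpoints(self) -> int:
        return len(self.orientations)


@dataclass(frozen=True)
class OrientationTest:
    counts: dict
    statistic: float
    p_value: float
    sufficient: bool


def orientation_uniformity(cluster: RearrangementCluster, min_breakpoints: int = 8) -> OrientationTest:
    """Chi-square test of the 4 orientation classes against uniformity.

    Clusters with fewer joins than ``min_breakpoints`` are reported as
    insufficient rather than tested (no power).
    """
    counter = Counter(cluster.orientations)
    counts = {o: counter.get(o, 0) for o in ORIENTATIONS}
    n = sum(counts.values())
    if n < min_breakpoints:
        return OrientationTest(counts=counts, statistic=np.nan, p_value=np.nan, sufficient=False)
    observed = np.array([counts[o] for o in ORIENTATIONS], dtype=float)
    statistic, p_value = stats.chisquare(observed)
    return OrientationTest(counts=counts, statistic=float(statistic), p_value=float(p_value), sufficient=True)


def cn_oscillation(cn_track) -> tuple[int, float]:
    """(number of distinct CN states, fraction of transitions between the two modal states).

    The fraction counts adjacent segment transitions that alternate between
    the two most frequent states (ties broken by lower state value), over all
    transitions.  A constant track has 1 state and fraction 0 by convention.
    """
    track = np.asarray(cn_track)
    if track.size == 0:
        raise ValueError("empty copy-number track")
    if track.size < 3:
        raise ValueError("copy-number track must have length >= 3")
    states, counts = np.unique(track, return_counts=True)
    n_states = len(states)
    if n_states == 1:
        return 1, 0.0
    # two modal states; ties resolved toward the smaller state value
    order = np.lexsort((states, -counts))
    modal = {states[order[0]], states[order[1]]}
    transitions = list(zip(track[:-1], track[1:]))
    alternating = sum(1 for a, b in transitions if a != b and {a, b} == modal)
    return n_states, alternating / len(transitions)


def hallmark_classify(cluster: RearrangementCluster, thresholds=None) -> dict:
    """Classify a cluster as chromothripsis-consistent or not.

    Verdict requires: enough joins; orientation uniformity not rejected
    (p > threshold); and a predominantly two-state oscillating CN track.
    Returns a report dict carrying all sub-statistics.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    orient = orientation_uniformity(cluster, min_breakpoints=thr["min_breakpoints"])
    n_states, osc_fraction = cn_oscillation(cluster.cn_track)
    verdict = (
        orient.sufficient
        and orient.p_value > thr["orientation_p"]
        and osc_fraction > thr["oscillation_fraction"]
    )
    return {
        "verdict": "chromothripsis-consistent" if verdict else "not-consistent",
        "consistent": bool(verdict),
        "n_breakpoints": cluster.n_breakpoints,
        "orientation_counts": orient.counts,
        "orientation_statistic": orient.statistic,
        "orientation_p": orient.p_value,
        "orientation_sufficient": orient.sufficient,
        "cn_states": n_states,
        "oscillation_fraction": osc_fraction,
        "thresholds": thr,
    }
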