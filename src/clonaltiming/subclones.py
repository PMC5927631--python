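"""Subclone reconstruction: CCF clustering, clone trees, branch burdens.

Mutations are clustered across samples on cancer cell fraction with a
truncated stick-breaking Dirichlet-process mixture.  The emission is the
Binomial read count at the expected VAF implied by a cluster's per-sample
CCF (through purity and local copy number, assuming multiplicity one), and
cluster prior mass is down-weighted by the probability that a mutation at
that CCF would reach the variant-calling threshold at the observed depth —
the sensitivity adjustment for low tumor fractions.

Clusters are then ordered into a clone tree by the pigeonhole principle: a
cluster can only descend from one whose CCF dominates it in every sample,
and siblings' CCFs may not sum above their parent's.  Cumulative root-to-leaf
mutation counts give the per-branch burdens used for rate estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ccf import _frame

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 0.05
_EPS = 1e-12


@dataclass
class SubcloneClusterSet:
    """Occupied clusters with per-sample CCF centres and hard assignments."""

    centers: pd.DataFrame  # index: cluster id, columns: samples
    assignments: pd.Series  # mutation_id -> cluster id
    sizes: Mapping[int, int]
    patient: str = "P1"
    n_dropped: int = 0

    def validate(self) -> "SubcloneClusterSet":
        if (self.centers.values < -1e-9).any() or (self.centers.values > 1.0 + 1e-6).any():
            raise ValueError("CCF centres must lie in [0, 1]")
        if set(self.assignments.unique()) - set(self.centers.index):
            raise ValueError("assignments refer to unknown clusters")
        if sum(self.sizes.values()) != len(self.assignments):
            raise ValueError("cluster sizes do not sum to the number of assigned mutations")
        return self

    @property
    def clusters(self) -> list:
        return list(self.centers.index)


@dataclass
class CloneTree:
    """Parent mapping over clusters; the root is the clonal cluster."""

    parent: Mapping[int, Optional[int]]

    def __post_init__(self):
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError("clone tree must have exactly one root")
        self._root = roots[0]
        # acyclicity: walking up from every node must terminate at the root
        for node in self.parent:
            seen = set()
            cur = node
            while cur is not None:
                if cur in seen:
                    raise ValueError("clone tree contains a cycle")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def root(self):
        return self._root

    def children_of(self, cluster) -> list:
        return [c for c, p in self.parent.items() if p == cluster]

    def leaves(self) -> list:
        return [c for c in self.parent if not self.children_of(c)]

    def path_to_root(self, cluster) -> list:
        path = [cluster]
        while self.parent[path[-1]] is not None:
            path.append(self.parent[path[-1]])
        return path


@dataclass(frozen=True)
class BranchBurden:
    """Cumulative mutation count from root to a terminal subclone."""

    patient: str
    subclone: int
    burden: float
    age: float


# ---------------------------------------------------------------------------
# Dirichlet-process clustering
# ---------------------------------------------------------------------------


def _prepare_matrices(muts, cn):
    """Pivot the long tables to (alt, tot, c) matrices; c maps CCF -> VAF."""
    mdf = _frame(muts)
    cdf = _frame(cn)
    samples = sorted(mdf["sample"].unique())
    alt = mdf.pivot_table(index="mutation_id", columns="sample", values="alt_reads", aggfunc="first")
    tot = mdf.pivot_table(index="mutation_id", columns="sample", values="total_reads", aggfunc="first")
    if alt.isna().any().any():
        raise ValueError("samples do not share the mutation set")
    pos = mdf.drop_duplicates("mutation_id").set_index("mutation_id")[["chrom", "pos"]]
    pos = pos.loc[alt.index]

    c = np.zeros((len(alt), len(samples)))
    for j, s in enumerate(samples):
        segs = cdf[cdf["sample"] == s]
        purity = float(segs["purity"].iloc[0])
        cn_tot = np.full(len(alt), np.nan)
        for seg in segs.itertuples(index=False):
            mask = (pos["chrom"].astype(str) == str(seg.chrom)) & (pos["pos"] >= seg.start) & (pos["pos"] < seg.end)
            cn_tot[mask.values] = seg.major_cn + seg.minor_cn
        if np.isnan(cn_tot).any():
            raise ValueError(f"mutations outside copy-number segments in sample {s}")
        c[:, j] = purity / (purity * cn_tot + (1 - purity) * 2.0)
    return alt, tot, c, samples


def _binom_loglik(alt, tot, p):
    """Binomial log-likelihood without the constant binomial coefficient."""
    p = np.clip(p, _EPS, 1 - _EPS)
    return alt * np.log(p) + (tot - alt) * np.log1p(-p)


def fit_subclone_clusters(
    muts,
    cn,
    max_clusters: int = 10,
    iterations: int = 300,
    seed: int = 0,
    alpha: float = 1.0,
    min_alt_reads: int = 3,
    grid_size: int = 51,
    patient: str = "P1",
) -> SubcloneClusterSet:
    """Cluster mutations on CCF with a truncated DP mixture (Gibbs sampling).

    ``max_clusters`` is the truncation level of the stick-breaking
    approximation; ``min_alt_reads`` is the calling threshold used by the
    sensitivity adjustment.  The final hard assignment is maximum-posterior
    under the last sampled state, so the result is deterministic per seed.
    """
    alt_df, tot_df, c, samples = _prepare_matrices(muts, cn)
    keep = (tot_df.values.sum(axis=1) > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropping %d mutations with zero depth in all samples", n_dropped)
    alt = alt_df.values[keep].astype(float)
    tot = tot_df.values[keep].astype(float)
    c = c[keep]
    mut_ids = alt_df.index[keep]
    n, S = alt.shape
    if n < 2:
        raise ValueError("need at least 2 mutations to cluster")
    K = max_clusters
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.0, 1.0, grid_size)

    # sensitivity adjustment uses sample-average depth and CCF->VAF factor
    depth_bar = tot.mean(axis=0)
    c_bar = c.mean(axis=0)

    z = rng.integers(0, K, size=n)
    phi = rng.uniform(0.2, 1.0, size=(K, S))

    def cluster_log_weights(phi_now, counts):
        # stick-breaking weights
        greater = counts[::-1].cumsum()[::-1] - counts
        v = rng.beta(1.0 + counts, alpha + greater)
        v = np.clip(v, _EPS, 1 - _EPS)
        logw = np.log(v) + np.concatenate([[0.0], np.cumsum(np.log1p(-v))[:-1]])
        # detection probability of a mutation at each cluster's CCF
        p_exp = np.clip(phi_now * c_bar[None, :], _EPS, 1 - _EPS)
        miss = np.ones(K)
        for j in range(S):
            miss *= stats.binom.cdf(min_alt_reads - 1, int(round(depth_bar[j])), p_exp[:, j])
        detect = np.clip(1.0 - miss, _EPS, 1.0)
        return logw + np.log(detect)

    logw = None
    for _ in range(iterations):
        counts = np.bincount(z, minlength=K).astype(float)
        # update CCF centres on a grid, per occupied cluster and sample
        for k in range(K):
            members = z == k
            if not members.any():
                phi[k] = rng.uniform(0.0, 1.0, size=S)
                continue
            for j in range(S):
                p = grid[:, None] * c[members, j][None, :]
                ll = _binom_loglik(alt[members, j][None, :], tot[members, j][None, :], p).sum(axis=1)
                ll -= ll.max()
                probs = np.exp(ll)
                probs /= probs.sum()
                phi[k, j] = grid[rng.choice(grid_size, p=probs)]
        logw = cluster_log_weights(phi, counts)
        # assignment step
        logp = np.empty((n, K))
        for k in range(K):
            p = phi[k][None, :] * c
            logp[:, k] = logw[k] + _binom_loglik(alt, tot, p).sum(axis=1)
        gumbel = rng.gumbel(size=(n, K))
        z = np.argmax(logp + gumbel, axis=1)

    # maximum-posterior hard assignment under the final state
    logp = np.empty((n, K))
    for k in range(K):
        p = phi[k][None, :] * c
        logp[:, k] = logw[k] + _binom_loglik(alt, tot, p).sum(axis=1)
    z = np.argmax(logp, axis=1)

    # merge occupied clusters whose centres coincide within the grid's
    # resolving power (the truncated DP happily splits one true cluster
    # across two sticks)
    merge_tol = max(2.0 / (grid_size - 1), 0.04)
    pre_counts = np.bincount(z, minlength=K).astype(float)
    occupied = list(np.unique(z))
    merged_into = {}
    for i, k in enumerate(occupied):
        for k2 in occupied[:i]:
            target = merged_into.get(k2, k2)
            if np.all(np.abs(phi[k] - phi[target]) <= merge_tol):
                merged_into[k] = target
                break
    if merged_into:
        z = np.array([merged_into.get(k, k) for k in z])
        for k in np.unique(z):
            donors = [k] + [src for src, dst in merged_into.items() if dst == k]
            if len(donors) > 1:
                w = pre_counts[donors]
                phi[k] = (phi[donors] * w[:, None]).sum(axis=0) / w.sum()

    occupied = np.unique(z)
    order = occupied[np.argsort(-phi[occupied].mean(axis=1))]
    relabel = {old: new for new, old in enumerate(order)}
    centers = pd.DataFrame(phi[order], index=range(len(order)), columns=samples)
    assignments = pd.Series([relabel[k] for k in z], index=mut_ids, name="cluster")
    sizes = assignments.value_counts().to_dict()
    return SubcloneClusterSet(
        centers=centers,
        assignments=assignments,
        sizes=sizes,
        patient=patient,
        n_dropped=n_dropped,
    ).validate()


# ---------------------------------------------------------------------------
# pigeonhole ordering and branch burdens
# ---------------------------------------------------------------------------


def order_clusters_pigeonhole(
    clusters: SubcloneClusterSet,
    tolerance: float = DEFAULT_TOLERANCE,
    parent_rule: str = "most_recent",
) -> CloneTree:
    """Order clusters into a clone tree by the pigeonhole principle.

    A cluster may descend from another only if the candidate parent's CCF is
    at least the child's minus ``tolerance`` in every sample, and attaching
    it may not push the parent's children's summed CCF above the parent's
    plus ``tolerance`` in any sample.  When several parents remain
    admissible, ``parent_rule`` picks one: ``"most_recent"`` takes the
    admissible parent with the smallest mean CCF (deepest nesting),
    ``"shallowest"`` the largest (nest only when the sum constraint forces
    it).  Single-sample data cannot distinguish the two.
    """
    if parent_rule not in ("most_recent", "shallowest"):
        raise ValueError("parent_rule must be 'most_recent' or 'shallowest'")
    centers = clusters.centers
    order = centers.mean(axis=1).sort_values(ascending=False).index.tolist()
    root = order[0]
    if (centers.loc[root] < 1.0 - 2 * tolerance).any():
        raise ValueError(
            "no clonal cluster: the largest cluster has CCF "
            f"{centers.loc[root].min():.3f} < 1 in some sample"
        )
    parent: dict = {root: None}
    children: dict = {root: []}
    violations = []
    for child in order[1:]:
        child_ccf = centers.loc[child]
        candidates = []
        for cand in parent:
            cand_ccf = centers.loc[cand]
            if (cand_ccf < child_ccf - tolerance).any():
                violations.append(f"{cand} cannot parent {child}: CCF not dominant in all samples")
                continue
            sib_sum = child_ccf.copy()
            for sib in children[cand]:
                sib_sum = sib_sum + centers.loc[sib]
            if (sib_sum > cand_ccf + tolerance).any():
                violations.append(f"{cand} cannot parent {child}: sibling CCFs would exceed parent")
                continue
            candidates.append(cand)
        if not candidates:
            raise ValueError(
                f"no valid parent for cluster {child}; constraints violated:\n  "
                + "\n  ".join(violations)
            )
        means = centers.loc[candidates].mean(axis=1)
        chosen = means.idxmin() if parent_rule == "most_recent" else means.idxmax()
        parent[child] = chosen
        children[chosen].append(child)
        children[child] = []
    return CloneTree(parent=parent)


def branch_burdens(
    tree: CloneTree,
    clusters: SubcloneClusterSet,
    ages: Mapping[str, float],
) -> list[BranchBurden]:
    """Cumulative mutation burden from root to each leaf subclone."""
    if clusters.patient not in ages:
        raise KeyError(f"no age for patient {clusters.patient}")
    age = float(ages[clusters.patient])
    if age <= 0:
        raise ValueError("age must be positive")
    out = []
    for leaf in tree.leaves():
        burden = sum(clusters.sizes.get(c, 0) for c in tree.path_to_root(leaf))
        out.append(BranchBurden(patient=clusters.patient, subclone=leaf, burden=float(burden), age=age))
    return out


def burdens_to_frame(burdens: list[BranchBurden]) -> pd.DataFrame:
    """Burden records as the (patient, branch, burden, age) table."""
    return pd.DataFrame(
        [
            {"patient": b.patient, "branch": b.subclone, "burden": b.burden, "age": b.age}
            for b in burdens
        ]
    )
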