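"""Cluster-solution metrics: variation of information, split-half stability,
the optimal-K decision rule, hierarchy, and hemispheric symmetry.

The central quantity is the variation of information (VI) between two
partitions C and C' of the same voxels,

    VI(C, C') = H(C) + H(C') - 2 I(C, C'),

with entropies H and mutual information I computed from cluster occupancy
proportions.  VI is a true metric on partitions (zero iff the clusterings
are identical up to relabeling, symmetric, triangle inequality) and is
bounded by log(n).  Logarithms are base 10 by default, matching the study
protocol (its printed bound for 93 elements, 1.96, is log10(93)); natural
logs are available through the log_base argument.

The split-half procedure repeatedly divides the cohort into two random
halves, clusters each half's averaged profile at every K, and records the VI
between the two half-solutions.  The optimal K is the smallest K greater
than 2 for which VI did not significantly increase relative to K-1 (paired
one-sided t-test over repetitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import Parcellation, contingency_table, kmeans_replicates, match_labels
from .connectivity import CorrelationProfile, average_group
from .errors import AlignmentError, DomainError
from .io import SeedMask

DEFAULT_LOG_BASE = 10.0


@dataclass(frozen=True)
class Clustering:
    """A partition of n elements into clusters 1..K."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise DomainError("a clustering needs at least one element")

    @classmethod
    def from_labels(cls, labels) -> "Clustering":
        return cls(labels=np.asarray(labels))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def K(self) -> int:
        return len(np.unique(self.labels))


def _as_clustering(c) -> Clustering:
    if isinstance(c, Clustering):
        return c
    if isinstance(c, Parcellation):
        return Clustering(labels=c.labels)
    return Clustering(labels=np.asarray(c))


def _proportions(labels: np.ndarray) -> np.ndarray:
    _, counts = np.unique(labels, return_counts=True)
    return counts / len(labels)


def entropy(c, log_base: float = DEFAULT_LOG_BASE) -> float:
    """H(C) = -sum_k P(k) log P(k), with P(k) the cluster occupancy."""
    p = _proportions(_as_clustering(c).labels)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(log_base))


def mutual_information(c, c2, log_base: float = DEFAULT_LOG_BASE) -> float:
    """I(C, C') = sum_{k,k'} P(k,k') log[P(k,k') / (P(k) P(k'))].

    P(k,k') is the number of voxels shared by cluster k of C and cluster k'
    of C', divided by the total voxel count; empty cells contribute zero.
    """
    a, b = _as_clustering(c), _as_clustering(c2)
    if a.n != b.n:
        raise AlignmentError("clusterings cover different element counts")
    # reindex to dense 1..K ids for the contingency table
    la = np.unique(a.labels, return_inverse=True)[1] + 1
    lb = np.unique(b.labels, return_inverse=True)[1] + 1
    joint = contingency_table(la, lb) / a.n
    pk = joint.sum(axis=1, keepdims=True)
    pk2 = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = np.ones_like(joint)
    ratio[mask] = joint[mask] / (pk @ pk2)[mask]
    mi = (joint[mask] * np.log(ratio[mask])).sum() / np.log(log_base)
    return float(max(mi, 0.0))


def variation_of_information(c, c2, log_base: float = DEFAULT_LOG_BASE) -> float:
    """VI(C, C') = H(C) + H(C') - 2 I(C, C'); zero iff identical partitions.

    Evaluated in the equivalent conditional-entropy form
    H(C|C') + H(C'|C), whose terms vanish exactly (not just to rounding) when
    the partitions coincide up to relabeling.
    """
    a, b = _as_clustering(c), _as_clustering(c2)
    if a.n != b.n:
        raise AlignmentError("clusterings cover different element counts")
    la = np.unique(a.labels, return_inverse=True)[1] + 1
    lb = np.unique(b.labels, return_inverse=True)[1] + 1
    joint = contingency_table(la, lb) / a.n
    pk = joint.sum(axis=1, keepdims=True)
    pk2 = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(mask, joint * (np.log(joint / pk) + np.log(joint / pk2)), 0.0)
    vi = -cond[mask].sum() / np.log(log_base)
    return float(max(vi, 0.0))


def vi_upper_bound(n: int, log_base: float = DEFAULT_LOG_BASE) -> float:
    """log(n): the largest VI attainable between partitions of n elements."""
    if n < 1:
        raise DomainError("n must be positive")
    return float(np.log(n) / np.log(log_base))


# ------------------------------------------------------------ split-half


@dataclass(frozen=True)
class VICurve:
    """Split-half VI per K: repetition values, means, CIs and paired tests.

    repetition_values has one row per repetition and one column per K.
    t_stats[j] / p_values[j] test "VI at k_values[j] increased over
    k_values[j-1]" (paired, one-sided); the first entry is NaN.
    """

    k_values: tuple[int, ...]
    repetition_values: np.ndarray
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    t_stats: np.ndarray
    p_values: np.ndarray
    log_base: float = DEFAULT_LOG_BASE


@dataclass(frozen=True)
class KSelection:
    """Outcome of the optimal-K rule.

    When every step shows a significant VI increase the rule selects nothing;
    k then falls back to the largest K examined and no_selection is set.
    """

    k: int
    no_selection: bool = False


def _paired_curve_stats(vi: np.ndarray, k_values, confidence: float = 0.95):
    n_rep, n_k = vi.shape
    mean = vi.mean(axis=0)
    if n_rep > 1:
        sem = vi.std(axis=0, ddof=1) / np.sqrt(n_rep)
        half = stats.t.ppf(0.5 + confidence / 2.0, df=n_rep - 1) * sem
    else:
        half = np.zeros(n_k)
    t_stats = np.full(n_k, np.nan)
    p_values = np.full(n_k, np.nan)
    for j in range(1, n_k):
        diff = vi[:, j] - vi[:, j - 1]
        if n_rep < 2:
            continue
        if np.ptp(diff) == 0.0:
            # zero-variance step: a constant increase is an unambiguous one,
            # a constant zero/decrease is unambiguously not
            if diff[0] > 0:
                t_stats[j], p_values[j] = np.inf, 0.0
            elif diff[0] < 0:
                t_stats[j], p_values[j] = -np.inf, 1.0
            continue
        res = stats.ttest_rel(vi[:, j], vi[:, j - 1], alternative="greater")
        t_stats[j], p_values[j] = res.statistic, res.pvalue
    return mean, mean - half, mean + half, t_stats, p_values


def split_half_vi(
    group_profiles: list[CorrelationProfile],
    k_range=(2, 3, 4, 5, 6, 7, 8),
    n_repetitions: int = 100,
    n_replicates: int = 1000,
    rng_seed: int = 0,
    log_base: float = DEFAULT_LOG_BASE,
) -> VICurve:
    """Split-half VI stability curve over K.

    Each repetition randomly splits the participants into disjoint halves of
    sizes floor(N/2) and ceil(N/2), averages each half's Fisher-Z profiles,
    clusters both averages at every K with replicated k-means, and records
    the VI between the two half-solutions.  The same splits are reused across
    all K within a run so the per-K paired t-tests are well defined.
    """
    n_part = len(group_profiles)
    if n_part < 2:
        raise DomainError("split-half needs at least 2 participants")
    k_values = tuple(int(k) for k in k_range)
    ss = np.random.SeedSequence(rng_seed)
    split_rng = np.random.default_rng(ss.spawn(1)[0])
    km_seeds = ss.generate_state(n_repetitions * len(k_values) * 2).reshape(
        n_repetitions, len(k_values), 2
    ) % (2**31 - 1)

    vi = np.empty((n_repetitions, len(k_values)))
    for rep in range(n_repetitions):
        perm = split_rng.permutation(n_part)
        half_a = [group_profiles[i] for i in perm[: n_part // 2]]
        half_b = [group_profiles[i] for i in perm[n_part // 2 :]]
        avg_a = average_group(half_a)
        avg_b = average_group(half_b)
        for j, k in enumerate(k_values):
            pa = kmeans_replicates(avg_a, k, n_replicates, int(km_seeds[rep, j, 0]))
            pb = kmeans_replicates(avg_b, k, n_replicates, int(km_seeds[rep, j, 1]))
            vi[rep, j] = variation_of_information(pa, pb, log_base)
    mean, lo, hi, t_stats, p_values = _paired_curve_stats(vi, k_values)
    return VICurve(
        k_values=k_values,
        repetition_values=vi,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        t_stats=t_stats,
        p_values=p_values,
        log_base=log_base,
    )


def select_optimal_k(curve: VICurve, alpha: float = 0.05) -> KSelection:
    """Smallest K >= 3 whose VI did not significantly increase over K-1.

    A step counts as a significant increase when the paired one-sided t-test
    (VI(K) > VI(K-1)) rejects at level alpha.  A degenerate step (no
    variation across repetitions, NaN test) is not an increase.  If every
    step increases significantly, the largest K is returned flagged.
    """
    ks = curve.k_values
    if ks[0] != 2 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise DomainError("curve must cover contiguous K starting at 2")
    for j in range(1, len(ks)):
        p = curve.p_values[j]
        significant_increase = np.isfinite(p) and p < alpha
        if not significant_increase:
            return KSelection(k=ks[j])
    return KSelection(k=ks[-1], no_selection=True)


# ------------------------------------------------------------- hierarchy


def hierarchy_index(parent, child) -> float:
    """Mean over child clusters of the largest fraction inherited from a
    single parent cluster.

    With x_ij the number of child-cluster-i voxels coming from parent cluster
    j, each cluster contributes max_j(x_ij) / sum_j(x_ij); the index is 1 iff
    every child cluster nests inside one parent cluster (perfect hierarchy)
    and is bounded below by 1/(K-1).
    """
    pa, ch = _as_clustering(parent), _as_clustering(child)
    if pa.n != ch.n:
        raise DomainError("clusterings cover different element counts")
    if ch.K != pa.K + 1:
        raise DomainError(
            f"child must have exactly one more cluster than parent "
            f"(parent K={pa.K}, child K={ch.K})"
        )
    lp = np.unique(pa.labels, return_inverse=True)[1] + 1
    lc = np.unique(ch.labels, return_inverse=True)[1] + 1
    x = contingency_table(lc, lp)  # rows: child clusters, cols: parents
    return float(np.mean(x.max(axis=1) / x.sum(axis=1)))


def hierarchy_curve(parcellations: dict[int, Parcellation]) -> dict[int, float]:
    """Hierarchy index for every consecutive K -> K+1 pair present."""
    out = {}
    for k in sorted(parcellations):
        if k + 1 in parcellations:
            out[k + 1] = hierarchy_index(parcellations[k], parcellations[k + 1])
    return out


# -------------------------------------------------------------- symmetry


@dataclass(frozen=True)
class SymmetryResult:
    """Proportion of overlap-domain voxels whose labels agree across
    hemispheres after optimal cluster pairing."""

    proportion: float
    overlap_domain_size: int
    mapping: dict[int, int]  # right cluster id -> matched left cluster id


def _mirror_overlap(
    left_mask: SeedMask, right_mask: SeedMask
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (into each mask's voxel list) of voxels present in both
    hemispheres after mirroring the right mask across the midsagittal plane
    (world x -> -x)."""
    left_world = left_mask.world_coordinates()
    right_world = right_mask.world_coordinates()
    right_world[:, 0] *= -1.0
    lut = {tuple(np.round(c, 3)): i for i, c in enumerate(left_world)}
    left_idx, right_idx = [], []
    for j, c in enumerate(np.round(right_world, 3)):
        i = lut.get(tuple(c))
        if i is not None:
            left_idx.append(i)
            right_idx.append(j)
    return np.asarray(left_idx, dtype=np.int64), np.asarray(right_idx, dtype=np.int64)


def symmetry_index(
    left: Parcellation,
    right: Parcellation,
    left_mask: SeedMask,
    right_mask: SeedMask,
) -> SymmetryResult:
    """Label agreement between hemispheres over mirrored homologous voxels.

    Right-hemisphere voxels are reflected across world x = 0; the overlap
    domain is the intersection of the left mask with the mirrored right mask
    (mask sizes differ, so only shared voxels enter).  Right clusters are
    paired to left clusters by optimal assignment on that domain; symmetry is
    the fraction of domain voxels whose left label equals the matched label.
    """
    li, ri = _mirror_overlap(left_mask, right_mask)
    if li.size == 0:
        raise DomainError("hemisphere masks have no mirrored overlap")
    left_labels = left.labels[li]
    right_labels = right.labels[ri]
    mapping = match_labels(left_labels, right_labels)
    mapped = np.array([mapping.get(int(l), -1) for l in right_labels])
    agree = int((mapped == left_labels).sum())
    return SymmetryResult(
        proportion=agree / li.size,
        overlap_domain_size=int(li.size),
        mapping=mapping,
    )
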