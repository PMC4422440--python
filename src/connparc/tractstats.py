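"""Group-level tract-map aggregation and cluster-vs-rest contrasts.

After parcellation, each cluster is used as a tractography seed, giving one
3D streamline-visitation map per participant per cluster.  Maps are
normalized by the number of total possible streamlines (seed voxels x
samples per seed voxel), thresholded at a small proportion to remove noise,
binarized, and averaged into overlap maps showing where tracts are
consistent across the group.  A cluster's connectivity is contrasted against
the average of the remaining clusters with a one-sample sign-flipping
permutation test on the within-participant difference maps, with
family-wise error controlled by the permutation distribution of the maximum
statistic across voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError


@dataclass(frozen=True)
class TractMapSet:
    """Per-participant, per-cluster 3D tract maps on a common grid.

    volumes is an array of shape (n_participants, n_clusters, X, Y, Z).
    """

    volumes: np.ndarray
    normalization: str = "raw_counts"  # "raw_counts" | "proportion"
    threshold_applied: float | None = None
    binarized: bool = False
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.volumes.ndim != 5:
            raise DomainError(
                "volumes must be (participants, clusters, X, Y, Z)"
            )
        if np.any(self.volumes < 0):
            raise DomainError("tract maps must be nonnegative")
        if self.normalization == "proportion" and np.any(self.volumes > 1):
            raise DomainError("proportion maps must lie in [0, 1]")

    @property
    def n_participants(self) -> int:
        return self.volumes.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.volumes.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[2:]


@dataclass(frozen=True)
class OverlapMap:
    """Per-cluster fraction of participants with a suprathreshold tract."""

    values: np.ndarray  # (n_clusters, X, Y, Z) in [0, 1]
    consistency_cutoff: float


@dataclass(frozen=True)
class ContrastResult:
    """Voxelwise cluster-vs-rest contrast with max-statistic FWE correction."""

    stat_map: np.ndarray
    p_fwe: np.ndarray
    p_uncorrected: np.ndarray
    sig_mask: np.ndarray
    alpha: float
    n_permutations: int


def normalize_tracts(raw: TractMapSet, total_possible) -> TractMapSet:
    """Divide every map by its participant-cluster total possible streamlines.

    total_possible is a positive scalar or an (n_participants, n_clusters)
    array (seed-voxel count x samples drawn per seed voxel).
    """
    if raw.normalization != "raw_counts":
        raise DomainError("maps are already normalized")
    total = np.asarray(total_possible, dtype=float)
    if np.any(total <= 0):
        raise DomainError("total possible streamlines must be positive")
    if total.ndim == 0:
        scaled = raw.volumes / total
    elif total.shape == (raw.n_participants, raw.n_clusters):
        scaled = raw.volumes / total[:, :, None, None, None]
    else:
        raise DomainError(
            "total_possible must be scalar or (participants, clusters)"
        )
    if np.any(scaled > 1.0):
        raise DomainError("counts exceed the stated total possible streamlines")
    return replace(raw, volumes=scaled, normalization="proportion")


def threshold_maps(t: TractMapSet, cutoff: float) -> TractMapSet:
    """Zero values below cutoff, keeping suprathreshold values continuous."""
    _check_cutoff(cutoff)
    if t.normalization != "proportion":
        raise DomainError("threshold applies to proportion maps")
    vols = np.where(t.volumes >= cutoff, t.volumes, 0.0)
    return replace(t, volumes=vols, threshold_applied=cutoff)


def threshold_binarize(t: TractMapSet, cutoff: float) -> TractMapSet:
    """Voxel -> 1 where value >= cutoff else 0 (boundary value survives)."""
    _check_cutoff(cutoff)
    if t.normalization != "proportion":
        raise DomainError("threshold applies to proportion maps")
    vols = (t.volumes >= cutoff).astype(float)
    return replace(t, volumes=vols, threshold_applied=cutoff, binarized=True)


def _check_cutoff(cutoff: float) -> None:
    if not 0 < cutoff < 1:
        raise DomainError("cutoff must lie in (0, 1)")


def overlap_map(t: TractMapSet, consistency_cutoff: float) -> OverlapMap:
    """Fraction of participants suprathreshold per voxel; fractions below the
    consistency cutoff are zeroed in the displayed map."""
    if not t.binarized:
        raise DomainError("overlap maps are computed from binarized maps")
    frac = t.volumes.mean(axis=0)
    display = np.where(frac >= consistency_cutoff, frac, 0.0)
    return OverlapMap(values=display, consistency_cutoff=consistency_cutoff)


def _one_sample_t(data: np.ndarray, signs: np.ndarray | None = None) -> np.ndarray:
    """Vectorized one-sample t over columns, optionally under sign flips.

    data is (n, v); signs is (m, n) of +-1 giving m flipped datasets at once.
    Sign flips leave x^2 unchanged, so only the mean needs recomputing.
    """
    n = data.shape[0]
    msq = (data**2).sum(axis=0)
    if signs is None:
        means = data.mean(axis=0)[None, :]
    else:
        means = signs @ data / n
    var = (msq[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = means / np.sqrt(var / n)
    t[~np.isfinite(t) & (means == 0)] = 0.0
    return t


def contrast_cluster_vs_rest(
    t: TractMapSet,
    cluster: int,
    alpha: float = 0.01,
    n_permutations: int = 1000,
    rng_seed: int = 0,
) -> ContrastResult:
    """Permutation contrast of one cluster's tract maps against the rest.

    Per participant the difference map is (cluster map - mean of the other
    clusters' maps); the test is a two-sided one-sample sign-flipping
    permutation test on the group mean difference.  Family-wise error across
    voxels is controlled by comparing each |t| with the permutation
    distribution of the maximum |t|; the identity flip is included in the
    null distribution so p-values are never zero.  Expects normalized,
    thresholded (but not binarized) maps.

    cluster is the 1-based cluster id, matching Parcellation labels.
    """
    if t.n_clusters < 2:
        raise DomainError("contrast needs at least 2 clusters")
    if t.n_participants < 2:
        raise DomainError("contrast needs at least 2 participants")
    if t.binarized:
        raise DomainError("contrast runs on continuous (non-binarized) maps")
    if not 1 <= cluster <= t.n_clusters:
        raise DomainError(f"cluster id {cluster} out of range")
    c = cluster - 1
    others = [j for j in range(t.n_clusters) if j != c]
    diff = t.volumes[:, c] - t.volumes[:, others].mean(axis=1)
    n = t.n_participants
    flat = diff.reshape(n, -1)

    observed = _one_sample_t(flat)[0]
    rng = np.random.default_rng(rng_seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    signs[0] = 1.0  # identity permutation anchors the null
    perm_t = _one_sample_t(flat, signs)
    abs_obs = np.abs(observed)
    max_null = np.abs(perm_t).max(axis=1)  # (n_permutations,)
    p_fwe = (max_null[:, None] >= abs_obs[None, :]).mean(axis=0)
    p_unc = (np.abs(perm_t) >= abs_obs[None, :]).mean(axis=0)

    shape = t.grid_shape
    return ContrastResult(
        stat_map=observed.reshape(shape),
        p_fwe=p_fwe.reshape(shape),
        p_uncorrected=p_unc.reshape(shape),
        sig_mask=(p_fwe < alpha).reshape(shape),
        alpha=alpha,
        n_permutations=n_permutations,
    )
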