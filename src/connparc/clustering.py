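"""Replicated k-means parcellation of seed voxels, plus label matching and
spatial summaries.

Each seed voxel's feature vector is its row of the group-averaged Fisher-Z
cross-correlation matrix.  k-means is run many times from random initial
centroids (Forgy: k distinct data rows) and the replicate with the smallest
total within-cluster squared point-to-centroid distance wins.  No spatial
contiguity constraint is imposed on clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .connectivity import CorrelationProfile
from .errors import DomainError, InvalidConfigError
from .io import SeedMask

_MAX_ITER = 300
_MAX_RESTARTS = 5


@dataclass(frozen=True)
class Parcellation:
    """Assignment of each seed voxel to a cluster id 1..k."""

    labels: np.ndarray
    k: int
    inertia: float
    n_replicates: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise InvalidConfigError(
                f"labels must use every id 1..{self.k}; found {present}"
            )

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster voxel counts and centers of gravity in world mm."""

    centers_of_gravity: np.ndarray  # k x 3, mm
    sizes: np.ndarray  # k


def _features(p: CorrelationProfile | np.ndarray) -> np.ndarray:
    if isinstance(p, CorrelationProfile):
        return np.asarray(p.values, dtype=float)
    return np.asarray(p, dtype=float)


def kmeans_replicates(
    p: CorrelationProfile | np.ndarray,
    k: int,
    n_replicates: int = 1000,
    rng_seed: int = 0,
    init: str = "random",
) -> Parcellation:
    """Best-of-n_replicates k-means on correlation-profile rows.

    init='random' (the default) draws k data rows as initial centroids each
    replicate, matching the classic replicated procedure; init='k-means++' is
    available but changes the initialization distribution.  Deterministic
    given rng_seed.  Every cluster id is realized in the returned solution.
    """
    x = _features(p)
    n = x.shape[0]
    if not 2 <= k <= n:
        raise DomainError(f"k={k} must lie in [2, {n}]")
    # A winning run can realize fewer than k clusters when the data contain
    # exact duplicate rows (centroids coincide and Lloyd cannot separate
    # them); restart the whole replicate batch with fresh centroids a
    # bounded number of times before giving up.
    for attempt in range(_MAX_RESTARTS):
        km = KMeans(
            n_clusters=k,
            init=init,
            n_init=n_replicates,
            max_iter=_MAX_ITER,
            algorithm="lloyd",
            random_state=int(rng_seed + attempt * 1_000_003) % (2**32 - 1),
        )
        km.fit(x)
        labels = km.labels_.astype(np.int64) + 1
        if len(np.unique(labels)) == k:
            return Parcellation(
                labels=labels,
                k=k,
                inertia=float(km.inertia_),
                n_replicates=n_replicates,
                rng_seed=rng_seed,
            )
    raise DomainError(
        f"no replicate realized all {k} clusters after {_MAX_RESTARTS} restarts"
    )


def contingency_table(labels_a: np.ndarray, labels_b: np.ndarray) -> np.ndarray:
    """Voxel-count table, rows = a's clusters (1..Ka), cols = b's (1..Kb)."""
    if len(labels_a) != len(labels_b):
        raise DomainError("label vectors differ in length")
    ka, kb = int(labels_a.max()), int(labels_b.max())
    table = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(table, (labels_a - 1, labels_b - 1), 1)
    return table


def match_labels(
    a: Parcellation | np.ndarray,
    b: Parcellation | np.ndarray,
    overlap_domain: np.ndarray | None = None,
) -> dict[int, int]:
    """Optimal one-to-one pairing of b's cluster ids onto a's.

    Solves the assignment problem on the voxel-overlap contingency table
    (Hungarian algorithm), maximizing total shared voxels; injective on the
    smaller id set.  overlap_domain optionally restricts to a voxel subset.
    """
    la = a.labels if isinstance(a, Parcellation) else np.asarray(a)
    lb = b.labels if isinstance(b, Parcellation) else np.asarray(b)
    if overlap_domain is not None:
        overlap_domain = np.asarray(overlap_domain)
        if overlap_domain.size == 0:
            raise DomainError("empty overlap domain")
        la, lb = la[overlap_domain], lb[overlap_domain]
    table = contingency_table(la, lb)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return {int(c + 1): int(r + 1) for r, c in zip(rows, cols)}


def summarize_clusters(p: Parcellation, mask: SeedMask) -> ClusterSummary:
    """Center of gravity (mean member world coordinate) and size per cluster."""
    if p.n != mask.n_voxels:
        raise DomainError("parcellation does not align with mask voxel list")
    world = mask.world_coordinates()
    cogs = np.empty((p.k, 3))
    sizes = np.empty(p.k, dtype=np.int64)
    for c in range(1, p.k + 1):
        members = p.labels == c
        sizes[c - 1] = members.sum()
        cogs[c - 1] = world[members].mean(axis=0)
    return ClusterSummary(centers_of_gravity=cogs, sizes=sizes)


def dilate_labels(
    p: Parcellation, mask: SeedMask, radius_mm: float
) -> np.ndarray:
    """Propagate each voxel's label to all grid voxels within radius_mm.

    Distances are world-space Euclidean (anisotropic spacings respected);
    conflicts go to the nearest labeled voxel, ties to the lower label id.
    Returns a full-grid integer label volume (0 = unlabeled).
    """
    if radius_mm < 0:
        raise DomainError("radius must be nonnegative")
    vol = mask.label_volume(p.labels)
    if radius_mm == 0:
        return vol
    spacing = np.linalg.norm(mask.affine[:3, :3], axis=0)
    out = np.zeros_like(vol)
    best = np.full(vol.shape, np.inf)
    eps = 1e-9
    # per-label distance transforms: iterating ids in increasing order with a
    # strict '<' update realizes the lower-label tie rule exactly
    for label in range(1, p.k + 1):
        dist = ndimage.distance_transform_edt(vol != label, sampling=spacing)
        take = (dist <= radius_mm + eps) & (dist < best - eps)
        out[take] = label
        best[take] = dist[take]
    return out
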