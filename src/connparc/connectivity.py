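"""From per-participant streamline-count matrices to the clustering substrate.

Each participant contributes a seed-voxel x target-voxel matrix of streamline
visit counts from probabilistic tractography.  The pipeline (i) downsamples
the target space to coarse cells, (ii) turns each matrix into a seed x seed
Pearson cross-correlation matrix (every seed voxel's connectivity fingerprint
correlated with every other's), (iii) applies the Fisher-Z transform
(arctanh), and (iv) averages the Z matrices across participants.  The rows of
the averaged matrix are the feature vectors handed to k-means.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import AlignmentError, GridError, ZeroVarianceError

DEFAULT_CLIP_EPSILON = 1e-7


@dataclass(frozen=True)
class TargetGrid:
    """Target-space grid: shape, grid-to-world affine, and cell size in mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    cell_mm: float

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One participant's seed-voxel x target-cell streamline counts.

    Columns follow the grid flattening convention used package-wide: x varies
    fastest, i.e. column index = ix + nx*iy + nx*ny*iz.
    """

    counts: np.ndarray
    seed_index: np.ndarray | None = None
    target_grid: TargetGrid | None = None
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.counts.ndim != 2:
            raise AlignmentError("counts must be a 2-D seed x target matrix")
        if np.any(self.counts < 0):
            raise AlignmentError("streamline counts must be nonnegative")
        if self.target_grid is not None and self.counts.shape[1] != self.target_grid.n_cells:
            raise GridError(
                f"counts have {self.counts.shape[1]} target columns but grid "
                f"holds {self.target_grid.n_cells} cells"
            )

    @property
    def n_seed(self) -> int:
        return self.counts.shape[0]

    @property
    def n_targets(self) -> int:
        return self.counts.shape[1]


@dataclass(frozen=True)
class CorrelationProfile:
    """Seed x seed cross-correlation matrix, raw r or Fisher-Z.

    The full symmetric matrix row (diagonal included) is the feature vector
    used by clustering; the constant diagonal adds no between-row contrast.
    """

    values: np.ndarray
    transform: str  # "raw_r" | "fisher_z"
    n_averaged: int = 1
    seed_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.transform not in ("raw_r", "fisher_z"):
            raise AlignmentError(f"unknown transform {self.transform!r}")

    @property
    def n_seed(self) -> int:
        return self.values.shape[0]


def downsample_targets(m: ConnectivityMatrix, cell_mm: float) -> ConnectivityMatrix:
    """Sum counts over non-overlapping blocks of target voxels.

    Blocks are anchored at the grid origin voxel (0,0,0); a trailing partial
    block is kept, so the total count per seed row is conserved exactly.
    cell_mm must be a positive integer multiple of the source cell size.
    """
    if m.target_grid is None:
        raise GridError("downsampling requires a target grid descriptor")
    src = m.target_grid
    ratio = cell_mm / src.cell_mm
    if cell_mm <= 0 or abs(ratio - round(ratio)) > 1e-9:
        raise GridError(
            f"cell size {cell_mm} mm is not a positive integer multiple of "
            f"the source spacing {src.cell_mm} mm"
        )
    f = int(round(ratio))
    if f == 1:
        return m
    nx, ny, nz = src.shape
    # columns are x-fastest, so a C-ordered reshape puts axes as (seed, z, y, x)
    vol = m.counts.reshape(m.n_seed, nz, ny, nx)
    out_shape = (-(-nx // f), -(-ny // f), -(-nz // f))
    padded = np.zeros((m.n_seed, out_shape[2] * f, out_shape[1] * f, out_shape[0] * f),
                      dtype=m.counts.dtype)
    padded[:, :nz, :ny, :nx] = vol
    ns = m.n_seed
    blocks = padded.reshape(ns, out_shape[2], f, out_shape[1], f, out_shape[0], f)
    summed = blocks.sum(axis=(2, 4, 6))
    new_counts = summed.reshape(ns, -1)

    scale = np.eye(4)
    scale[:3, :3] *= f
    scale[:3, 3] = (f - 1) / 2.0  # block center in source-index units
    new_affine = src.affine @ scale
    new_grid = TargetGrid(shape=out_shape, affine=new_affine, cell_mm=cell_mm)
    return ConnectivityMatrix(
        counts=new_counts,
        seed_index=m.seed_index,
        target_grid=new_grid,
        participant_id=m.participant_id,
    )


def cross_correlate(
    m: ConnectivityMatrix, zero_variance: str = "error"
) -> CorrelationProfile:
    """Pearson cross-correlation of every pair of seed connectivity rows.

    A seed voxel with a constant row (no streamlines anywhere, typically) has
    undefined correlations; by default this raises ZeroVarianceError naming
    the offending voxels, since silently imputing them would distort the
    clusters.  zero_variance='drop' removes those voxels instead, shrinking
    the profile (and the parcellation domain) accordingly.
    """
    if m.n_targets < 2:
        raise AlignmentError("correlation needs at least 2 target cells")
    counts = np.asarray(m.counts, dtype=float)
    variances = counts.var(axis=1)
    flat = np.flatnonzero(variances == 0.0)
    seed_index = m.seed_index
    if flat.size:
        if zero_variance == "drop":
            keep = np.flatnonzero(variances > 0.0)
            counts = counts[keep]
            if seed_index is not None:
                seed_index = seed_index[keep]
        else:
            raise ZeroVarianceError(flat.tolist())
    values = np.corrcoef(counts)
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return CorrelationProfile(values=values, transform="raw_r", n_averaged=1,
                              seed_index=seed_index)


def fisher_z(
    p: CorrelationProfile, clip_epsilon: float = DEFAULT_CLIP_EPSILON
) -> CorrelationProfile:
    """arctanh of every entry, with |r| clipped to 1 - clip_epsilon.

    Clipping keeps the diagonal (r = 1) finite; the default epsilon changes no
    value at float precision for |r| <= 1 - 1e-6.
    """
    if p.transform != "raw_r":
        raise AlignmentError("fisher_z expects a raw_r profile")
    z = np.arctanh(np.clip(p.values, -1.0 + clip_epsilon, 1.0 - clip_epsilon))
    return replace(p, values=z, transform="fisher_z")


def average_group(profiles: list[CorrelationProfile]) -> CorrelationProfile:
    """Entrywise mean of Fisher-Z profiles over participants."""
    if not profiles:
        raise AlignmentError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.transform != first.transform:
            raise AlignmentError("cannot average profiles with mixed transforms")
        if p.values.shape != first.values.shape:
            raise AlignmentError("profiles have mismatched seed counts")
        if (
            p.seed_index is not None
            and first.seed_index is not None
            and not np.array_equal(p.seed_index, first.seed_index)
        ):
            raise AlignmentError("profiles have mismatched seed-voxel orderings")
    if first.transform != "fisher_z":
        raise AlignmentError("group averaging is defined on Fisher-Z profiles")
    mean = np.mean([p.values for p in profiles], axis=0)
    return CorrelationProfile(
        values=mean,
        transform="fisher_z",
        n_averaged=len(profiles),
        seed_index=first.seed_index,
    )


def participant_profiles(
    matrices: list[ConnectivityMatrix],
    clip_epsilon: float = DEFAULT_CLIP_EPSILON,
    zero_variance: str = "error",
) -> list[CorrelationProfile]:
    """Cross-correlate and Fisher-Z transform each participant's matrix."""
    return [
        fisher_z(cross_correlate(m, zero_variance=zero_variance), clip_epsilon)
        for m in matrices
    ]
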