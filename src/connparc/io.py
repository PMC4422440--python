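"""File formats, seed-mask construction, and run configuration.

Conventions used package-wide:

* seed voxels are ordered by grid index with x varying fastest; that ordering
  is the contract for the rows of every connectivity matrix and profile;
* grid indices are 0-based internally; coordinates are reported in world mm
  under the mask affine (MNI-style RAS+, x increasing rightward);
* dense matrices are whitespace-separated integer text; sparse matrices are
  coordinate-triplet text, one "row column value" per line with 1-based
  indices and absent entries zero (the layout common tractography tools emit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import GridError, InvalidConfigError, ParseError


@dataclass(frozen=True)
class SeedMask:
    """The set of seed voxels defining the region to parcellate."""

    voxels: np.ndarray  # n x 3 grid indices
    shape: tuple[int, int, int]
    affine: np.ndarray
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        v = self.voxels
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidConfigError("voxels must be an n x 3 index array")
        if np.any(v < 0) or np.any(v >= np.array(self.shape)):
            raise InvalidConfigError("voxel indices fall outside the grid")

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    def world_coordinates(self) -> np.ndarray:
        """World-space mm coordinates of every voxel under the affine."""
        homog = np.column_stack([self.voxels, np.ones(self.n_voxels)])
        return (self.affine @ homog.T).T[:, :3]

    def label_volume(self, labels: np.ndarray) -> np.ndarray:
        """Embed per-voxel labels into a full-grid integer volume (0 outside)."""
        if len(labels) != self.n_voxels:
            raise InvalidConfigError("labels do not align with the voxel list")
        vol = np.zeros(self.shape, dtype=np.int32)
        vol[tuple(self.voxels.T)] = labels
        return vol


def _canonical_voxel_order(voxels: np.ndarray) -> np.ndarray:
    """Sort indices so x varies fastest, then y, then z."""
    return np.lexsort((voxels[:, 0], voxels[:, 1], voxels[:, 2]))


def build_seed_mask(
    prob_maps: list[nib.Nifti1Image],
    threshold: float,
    hemisphere: str = "left",
) -> SeedMask:
    """Union of voxels where any probability map reaches the threshold.

    Maps may be scaled 0-1 or 0-100; a value above 1 anywhere flags the
    percent convention and the map is rescaled.  Voxels exactly at the
    threshold are included.
    """
    if not prob_maps:
        raise InvalidConfigError("no probability maps supplied")
    if not 0 < threshold <= 1:
        raise InvalidConfigError("threshold must be a fraction in (0, 1]")
    ref = prob_maps[0]
    mask = np.zeros(ref.shape, dtype=bool)
    for img in prob_maps:
        if img.shape != ref.shape or not np.allclose(img.affine, ref.affine):
            raise GridError("probability maps do not share a grid and affine")
        data = np.asarray(img.dataobj, dtype=float)
        if np.nanmax(data) > 1.0:  # percent-scaled map
            data = data / 100.0
        mask |= data >= threshold
    voxels = np.argwhere(mask)
    voxels = voxels[_canonical_voxel_order(voxels)]
    return SeedMask(
        voxels=voxels,
        shape=tuple(ref.shape),
        affine=np.asarray(ref.affine),
        hemisphere=hemisphere,
    )


def load_seed_mask(path: str | Path, hemisphere: str = "left") -> SeedMask:
    """Read a binary/label NIfTI volume as a seed mask (nonzero = in mask)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxels = np.argwhere(data != 0)
    voxels = voxels[_canonical_voxel_order(voxels)]
    return SeedMask(
        voxels=voxels,
        shape=tuple(img.shape),
        affine=np.asarray(img.affine),
        hemisphere=hemisphere,
    )


def write_mask_nifti(mask: SeedMask, path: str | Path) -> None:
    vol = np.zeros(mask.shape, dtype=np.uint8)
    vol[tuple(mask.voxels.T)] = 1
    nib.save(nib.Nifti1Image(vol, mask.affine), str(path))


def write_labels_nifti(labels: np.ndarray, mask: SeedMask, path: str | Path) -> None:
    """Write a parcellation as an integer label volume in the seed grid."""
    nib.save(nib.Nifti1Image(mask.label_volume(labels), mask.affine), str(path))


def write_volume_nifti(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), str(path))


# ---------------------------------------------------------------- matrices


def write_connectivity(
    counts: np.ndarray, path: str | Path, format: str = "dense"
) -> None:
    counts = np.asarray(counts)
    if format == "dense":
        np.savetxt(path, counts, fmt="%d")
    elif format == "sparse_triplet":
        rows, cols = np.nonzero(counts)
        with open(path, "w") as fh:
            fh.write(f"# shape {counts.shape[0]} {counts.shape[1]}\n")
            for r, c in zip(rows, cols):
                fh.write(f"{r + 1} {c + 1} {counts[r, c]}\n")
    else:
        raise InvalidConfigError(f"unknown matrix format {format!r}")


def read_connectivity(
    path: str | Path,
    format: str = "dense",
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Read a count matrix; round-trips write_connectivity bit-exactly.

    Sparse triplets are 1-based "row column value" lines; absent entries are
    zero.  The matrix shape is taken from a leading "# shape R C" comment when
    present, from the shape argument otherwise, else inferred from the largest
    indices seen.
    """
    path = Path(path)
    if format == "dense":
        try:
            counts = np.loadtxt(path, dtype=np.int64, ndmin=2)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if np.any(counts < 0):
            raise ParseError(f"{path}: negative streamline counts")
        return counts
    if format != "sparse_triplet":
        raise InvalidConfigError(f"unknown matrix format {format!r}")

    entries: list[tuple[int, int, int]] = []
    header_shape = shape
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[:1] == ["shape"] and len(parts) == 3:
                    header_shape = (int(parts[1]), int(parts[2]))
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 'row column value'")
            try:
                r, c = int(parts[0]), int(parts[1])
                v = int(round(float(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if r < 1 or c < 1:
                raise ParseError(f"{path}:{lineno}: indices are 1-based")
            if v < 0:
                raise ParseError(f"{path}:{lineno}: negative streamline count")
            entries.append((r - 1, c - 1, v))
    if header_shape is None:
        if not entries:
            raise ParseError(f"{path}: empty sparse file with no shape header")
        header_shape = (
            max(e[0] for e in entries) + 1,
            max(e[1] for e in entries) + 1,
        )
    counts = np.zeros(header_shape, dtype=np.int64)
    for r, c, v in entries:
        if r >= header_shape[0] or c >= header_shape[1]:
            raise ParseError(f"{path}: entry ({r + 1},{c + 1}) outside shape {header_shape}")
        counts[r, c] = v
    return counts


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Tab-separated table with a fixed float format for byte-stable output."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ------------------------------------------------------------------ config


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; defaults mirror the study protocol:
    K = 2..8, 1000 k-means replicates, 100 split-half repetitions, 1% tract
    threshold, 50% participant-consistency cutoff, FWE alpha 0.01, base-10
    logs for the information metrics."""

    out_dir: str = "connparc_out"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    n_replicates: int = 1000
    n_repetitions: int = 100
    alpha_optimal_k: float = 0.05
    alpha_fwe: float = 0.01
    n_permutations: int = 1000
    tract_threshold: float = 0.01
    consistency_cutoff: float = 0.5
    log_base: float = 10.0
    clip_epsilon: float = 1e-7
    rng_seed: int = 0
    mask_paths: dict = field(default_factory=dict)  # hemisphere -> nifti path
    matrix_paths: dict = field(default_factory=dict)  # hemisphere -> list of paths
    matrix_format: str = "dense"
    tract_paths: dict = field(default_factory=dict)
    synthetic: dict | None = None  # SyntheticConfig fields, used when no inputs

    def __post_init__(self) -> None:
        ks = tuple(int(k) for k in self.k_range)
        if not ks or ks[0] != 2 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
            raise InvalidConfigError(
                "k_range must be contiguous and start at 2 (the K-1 = 2 "
                "baseline anchors the optimal-K rule)"
            )
        self.k_range = ks
        for name, value in [
            ("tract_threshold", self.tract_threshold),
            ("consistency_cutoff", self.consistency_cutoff),
            ("alpha_optimal_k", self.alpha_optimal_k),
            ("alpha_fwe", self.alpha_fwe),
        ]:
            if not 0 < value < 1:
                raise InvalidConfigError(f"{name} must lie in (0, 1)")
        if self.log_base <= 1:
            raise InvalidConfigError("log_base must exceed 1")


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a plain key-value (YAML) text file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError(f"{path}: config must be a key-value mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    if "k_range" in raw:
        raw["k_range"] = tuple(raw["k_range"])
    return RunConfig(**raw)
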