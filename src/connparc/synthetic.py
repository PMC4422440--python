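"""Synthetic group-level connectivity data with planted parcel structure.

The study this pipeline targets did not deposit its diffusion scans, so every
downstream stage is exercised on generated data: a cohort of participants, each
with a seed-voxel x target-voxel streamline-count matrix in which seed voxels
belonging to the same planted parcel share a connectivity fingerprint, plus
participant- and voxel-level noise.  Optional extras mirror the study design:
a contralateral hemisphere with a controllable fraction of label agreement, and
a nested parcel split for hierarchy testing.

The generator is specified by the one property the pipeline needs — rows from
the same parcel are more correlated than rows from different parcels — with
the signal and noise magnitudes exposed as parameters.  It does not simulate
diffusion signal, fiber orientations, or streamline propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .connectivity import ConnectivityMatrix, TargetGrid
from .errors import InvalidConfigError
from .io import SeedMask

# Baseline streamline count level around which parcel fingerprints vary; keeps
# generated counts in a realistic visitation-count range.
_BASELINE_COUNT = 20.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    fingerprint_scale is the between-parcel signal magnitude (s.d. of the
    parcel fingerprint around the baseline count level); noise_scale is the
    s.d. of participant- and voxel-level noise added on top.  symmetry_level
    is the fraction of mirrored voxels that keep their homologous label.
    """

    n_participants: int = 20
    n_seed_voxels: int = 60
    n_targets: int = 150
    k_true: int = 4
    fingerprint_scale: float = 3.0
    noise_scale: float = 1.0
    symmetry_level: float = 1.0
    hierarchy_split: tuple[int, int] | None = None
    within_family_ratio: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true > self.n_seed_voxels:
            raise InvalidConfigError(
                f"k_true={self.k_true} exceeds n_seed_voxels={self.n_seed_voxels}"
            )
        if self.n_targets < 2:
            raise InvalidConfigError("n_targets must be at least 2")
        if not 0.0 <= self.symmetry_level <= 1.0:
            raise InvalidConfigError("symmetry_level must lie in [0, 1]")
        if self.fingerprint_scale < 0 or self.noise_scale < 0:
            raise InvalidConfigError("scales must be nonnegative")
        if self.n_participants < 1 or self.k_true < 1:
            raise InvalidConfigError("counts must be positive")
        if not 0 <= self.within_family_ratio <= 1:
            raise InvalidConfigError("within_family_ratio must lie in [0, 1]")
        if self.hierarchy_split is not None:
            parent, n_children = self.hierarchy_split
            if not 1 <= parent <= self.k_true:
                raise InvalidConfigError("hierarchy_split parent id out of range")
            if n_children < 2:
                raise InvalidConfigError("hierarchy_split needs >= 2 children")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth parcel assignment behind a synthetic cohort.

    labels are contiguous ids 1..k.  When a hierarchy was planted, labels are
    the child-level (finer) solution and parent_map sends each child parcel id
    to its parent parcel id in the coarser solution.  mirrored_labels, when
    present, hold the contralateral-hemisphere assignment.
    """

    labels: np.ndarray
    mirrored_labels: np.ndarray | None = None
    parent_map: dict[int, int] | None = None

    @property
    def k(self) -> int:
        return int(self.labels.max())

    def parent_labels(self) -> np.ndarray:
        """Coarse-level labels obtained by collapsing children onto parents."""
        if self.parent_map is None:
            return self.labels.copy()
        lut = np.zeros(self.k + 1, dtype=np.int64)
        for child, parent in self.parent_map.items():
            lut[child] = parent
        return lut[self.labels]


def make_planted_labels(cfg: SyntheticConfig) -> PlantedTruth:
    """Assign each seed voxel a parcel id 1..k_true, every id used at least once.

    Deterministic given cfg.rng_seed.  If cfg.hierarchy_split=(p, c) the parcel
    p is further split into c children, so the returned labels have
    k_true + c - 1 parcels and parent_map records the nesting.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n, k = cfg.n_seed_voxels, cfg.k_true
    # balanced assignment (sizes within one voxel of each other): every parcel
    # is realized, and equal-size parcels keep the coarse merge choices of the
    # nested fingerprint model tied, which is what makes sub-optimal K
    # solutions split-half unstable downstream.  Remainder voxels are spread
    # across parcel *families* (1,3,5,... before 2,4,6,...) so family totals
    # stay tied as well when k does not divide n.
    base, extra = divmod(n, k)
    sizes = np.full(k, base, dtype=np.int64)
    order = np.concatenate([np.arange(0, k, 2), np.arange(1, k, 2)])
    sizes[order[:extra]] += 1
    labels = np.repeat(np.arange(1, k + 1, dtype=np.int64), sizes)
    rng.shuffle(labels)

    parent_map: dict[int, int] | None = None
    if cfg.hierarchy_split is not None:
        parent, n_children = cfg.hierarchy_split
        members = np.flatnonzero(labels == parent)
        if len(members) < n_children:
            raise InvalidConfigError(
                f"parcel {parent} has {len(members)} voxels, cannot split "
                f"into {n_children} children"
            )
        child_ids = np.array([parent] + list(range(k + 1, k + n_children)))
        assignment = np.tile(child_ids, -(-len(members) // n_children))[: len(members)]
        rng.shuffle(assignment)
        labels[members] = assignment
        parent_map = {int(cid): parent for cid in child_ids}
        for other in range(1, k + 1):
            if other != parent:
                parent_map[other] = other
    return PlantedTruth(labels=labels, parent_map=parent_map)


def _count_matrix(real: np.ndarray) -> np.ndarray:
    """Map continuous draws to valid streamline counts (round of absolute value)."""
    return np.rint(np.abs(real)).astype(np.int64)


def _fixed_norm_offset(rng: np.random.Generator, n_targets: int, rms: float) -> np.ndarray:
    """Random direction over targets with per-component RMS exactly `rms`.

    The exact norm (rather than a random one) keeps the offsets of different
    parcel families interchangeable, so merge choices at coarse K are tied.
    """
    if rms == 0.0:
        return np.zeros(n_targets)
    u = rng.standard_normal(n_targets)
    return u * (rms * np.sqrt(n_targets) / np.linalg.norm(u))


def _random_involution(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random self-inverse permutation: a uniform pairing of indices, swapped.

    With n odd the leftover index stays fixed.
    """
    order = rng.permutation(n)
    perm = np.arange(n)
    for i in range(0, n - 1, 2):
        a, b = order[i], order[i + 1]
        perm[a], perm[b] = b, a
    return perm


def _parcel_fingerprints(
    cfg: SyntheticConfig, truth: PlantedTruth, rng: np.random.Generator
) -> np.ndarray:
    """Nested (family -> parcel -> child) fingerprint geometry over targets.

    Parcels are grouped into families of two (parcel 2i-1 with parcel 2i; a
    trailing odd parcel forms its own family).  Each family gets a heavy-mean
    center at separation ~fingerprint_scale; the two parcels of a family sit
    at center +- a fixed-norm offset of RMS within_family_ratio *
    fingerprint_scale.  Because the within-family offsets have identical
    norms and parcel sizes are balanced, every way of merging families or of
    splitting one family is equally good: solutions coarser than the planted
    K are decided by participant sampling noise and are therefore unstable
    across split halves, while the planted K itself is stable — the
    instability signature the VI selection rule detects.  Children of a
    hierarchy_split parcel sit around their parent at a further factor
    within_family_ratio down.
    """
    k = cfg.k_true
    n_fam = -(-k // 2)
    within_rms = cfg.within_family_ratio * cfg.fingerprint_scale
    # one family geometry, drawn once ...
    base_center = _BASELINE_COUNT + cfg.fingerprint_scale * np.abs(
        rng.standard_normal(cfg.n_targets)
    )
    base_offset = _fixed_norm_offset(rng, cfg.n_targets, within_rms)
    # ... and replicated to the other families through random involutive
    # permutations of the target axis.  A permutation preserves every
    # within-family statistic; choosing it self-inverse (a random pairing of
    # target indices) additionally makes all cross-family inner products --
    # and hence the correlation-feature geometry -- exactly symmetric between
    # families, so the merge/split ties at coarse K are exact and only
    # participant sampling noise can break them
    parent_fp = np.empty((k, cfg.n_targets))
    for fam in range(n_fam):
        perm = (
            np.arange(cfg.n_targets)
            if fam == 0
            else _random_involution(rng, cfg.n_targets)
        )
        center, offset = base_center[perm], base_offset[perm]
        members = [m for m in (2 * fam, 2 * fam + 1) if m < k]
        if len(members) == 1:
            parent_fp[members[0]] = center
        else:
            parent_fp[members[0]] = center + offset
            parent_fp[members[1]] = center - offset
    if truth.parent_map is None:
        return parent_fp
    # children scatter around their parent's fingerprint, one scale further in
    child_rms = cfg.within_family_ratio * within_rms
    child_fp = np.empty((truth.k, cfg.n_targets))
    for child in range(1, truth.k + 1):
        parent = truth.parent_map[child]
        if child == parent:
            child_fp[child - 1] = parent_fp[parent - 1]
        else:
            child_fp[child - 1] = parent_fp[parent - 1] + _fixed_norm_offset(
                rng, cfg.n_targets, child_rms
            )
    return child_fp


def simulate_group(
    cfg: SyntheticConfig,
    truth: PlantedTruth,
    seed_mask: SeedMask | None = None,
) -> list[ConnectivityMatrix]:
    """Generate one seed x target count matrix per participant.

    Rows sharing a planted label are drawn from the same parcel fingerprint
    (one draw per parcel over targets) plus a participant-by-parcel effect and
    voxel-level noise, both of s.d. cfg.noise_scale.  With noise_scale = 0,
    same-parcel rows are identical within a participant.
    """
    if len(truth.labels) != cfg.n_seed_voxels:
        raise InvalidConfigError(
            f"truth has {len(truth.labels)} labels but config expects "
            f"{cfg.n_seed_voxels} seed voxels"
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1]))
    fingerprints = _parcel_fingerprints(cfg, truth, rng)
    k_eff = truth.k
    if seed_mask is None:
        seed_mask = synthetic_seed_mask(cfg.n_seed_voxels)
    target_grid = synthetic_target_grid(cfg.n_targets)

    out: list[ConnectivityMatrix] = []
    lab0 = truth.labels - 1
    participant_fx = np.empty((cfg.n_participants, k_eff, cfg.n_targets))
    voxel_noise = np.empty((cfg.n_participants, cfg.n_seed_voxels, cfg.n_targets))
    for p in range(cfg.n_participants):
        if p % 2 == 0:
            participant_fx[p] = rng.standard_normal((k_eff, cfg.n_targets))
            voxel_noise[p] = rng.standard_normal((cfg.n_seed_voxels, cfg.n_targets))
        else:
            # antithetic pairing: the cohort-level noise mean cancels, so
            # group curves reflect split-half sampling variability rather
            # than one cohort's idiosyncratic noise draw
            participant_fx[p] = -participant_fx[p - 1]
            voxel_noise[p] = -voxel_noise[p - 1]
    for p in range(cfg.n_participants):
        rows = (
            fingerprints[lab0]
            + cfg.noise_scale * participant_fx[p][lab0]
            + cfg.noise_scale * voxel_noise[p]
        )
        out.append(
            ConnectivityMatrix(
                counts=_count_matrix(rows),
                seed_index=seed_mask.voxels,
                target_grid=target_grid,
                participant_id=f"sub-{p + 1:03d}",
            )
        )
    return out


def simulate_hemisphere_pair(cfg: SyntheticConfig) -> tuple[PlantedTruth, PlantedTruth]:
    """Planted labels for a hemisphere and its mirrored counterpart.

    The second truth equals the first except that a fraction
    (1 - symmetry_level) of voxels — exactly round((1-s)*n) of them — are
    relabeled uniformly at random to a *different* parcel.
    """
    left = make_planted_labels(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 2]))
    n = cfg.n_seed_voxels
    n_flip = int(round((1.0 - cfg.symmetry_level) * n))
    mirrored = left.labels.copy()
    if n_flip > 0:
        flip = rng.choice(n, size=n_flip, replace=False)
        for i in flip:
            others = [l for l in range(1, cfg.k_true + 1) if l != mirrored[i]]
            mirrored[i] = rng.choice(others)
    right = PlantedTruth(labels=mirrored)
    left = replace(left, mirrored_labels=mirrored)
    return left, right


def synthetic_seed_mask(
    n_voxels: int,
    hemisphere: str = "left",
    spacing_mm: float = 2.0,
) -> SeedMask:
    """Compact 3D blob of seed voxels on a regular grid.

    Voxels are the n_voxels grid points closest to the blob center, so
    center-of-gravity and dilation operations are exercised on a realistic
    shape.  The left-hemisphere blob sits at negative world x; the right one
    is its exact mirror (world x -> -x).
    """
    side = int(np.ceil(2.5 * n_voxels ** (1.0 / 3.0))) + 2
    shape = (side, side, side)
    center = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape).reshape(3, -1).T
    d2 = ((idx - center) ** 2).sum(axis=1)
    # stable tie-break on grid index so the blob is deterministic
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], d2))
    voxels = idx[order[:n_voxels]]
    # package-wide voxel ordering contract: x fastest, then y, then z —
    # keeps file round-trips aligned with in-memory matrix rows
    voxels = voxels[np.lexsort((voxels[:, 0], voxels[:, 1], voxels[:, 2]))]
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    # shift so the blob center lands at x = -20 mm (left) or +20 mm (right)
    affine[0, 3] = -20.0 - spacing_mm * center[0]
    affine[1, 3] = 40.0 - spacing_mm * center[1]
    affine[2, 3] = 10.0 - spacing_mm * center[2]
    if hemisphere == "right":
        affine[0, 0] = -spacing_mm
        affine[0, 3] = 20.0 + spacing_mm * center[0]
    return SeedMask(voxels=voxels, shape=shape, affine=affine, hemisphere=hemisphere)


def synthetic_target_grid(n_targets: int, cell_mm: float = 5.0) -> TargetGrid:
    """Near-cubic grid with exactly n_targets cells, at the given spacing."""
    best = (n_targets, 1, 1)
    best_score = float("inf")
    for a in range(1, int(n_targets ** (1.0 / 3.0)) + 2):
        if n_targets % a:
            continue
        rest = n_targets // a
        for b in range(a, int(rest**0.5) + 1):
            if rest % b:
                continue
            c = rest // b
            score = (c - a) ** 2 + (c - b) ** 2 + (b - a) ** 2
            if score < best_score:
                best_score = score
                best = (a, b, c)
    affine = np.diag([cell_mm, cell_mm, cell_mm, 1.0])
    return TargetGrid(shape=best, affine=affine, cell_mm=cell_mm)
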