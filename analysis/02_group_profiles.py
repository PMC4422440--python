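#!/usr/bin/env python
"""Build the group-averaged connectivity fingerprints.

For each hemisphere: read the per-participant seed x target count matrices,
cross-correlate every pair of seed rows (Pearson), Fisher-Z transform, and
average across participants.  Saves the averaged profile and prints the
within- vs between-parcel correlation contrast that the clustering will
exploit.
"""

from pathlib import Path

import numpy as np
import nibabel as nib

import connparc as cp
from connparc.io import read_connectivity

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "scratch" / "cohort"
OUT = ROOT / "scratch" / "profiles"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for hemi in ("left", "right"):
        paths = sorted(COHORT.glob(f"{hemi}_sub-*.txt"))
        matrices = [
            cp.ConnectivityMatrix(counts=read_connectivity(p)) for p in paths
        ]
        profiles = cp.participant_profiles(matrices)
        avg = cp.average_group(profiles)
        np.savetxt(OUT / f"{hemi}_group_profile.txt", avg.values)

        truth = np.asarray(
            nib.load(COHORT / f"{hemi}_planted_labels.nii.gz").dataobj
        )
        mask = cp.io.load_seed_mask(COHORT / f"{hemi}_seed_mask.nii.gz", hemi)
        labels = truth[tuple(mask.voxels.T)].astype(int)
        r = np.tanh(avg.values)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(r), dtype=bool)
        print(
            f"{hemi}: averaged {avg.n_averaged} participants; mean r "
            f"within parcels {r[same & off].mean():.3f}, "
            f"between parcels {r[~same].mean():.3f}"
        )
    print(f"profiles written to {OUT}")


if __name__ == "__main__":
    main()
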