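"""End-to-end run: connectivity -> clustering -> metrics (-> tract stats).

Given a RunConfig pointing at seed masks and per-participant matrices (or at
a synthetic-cohort description), the pipeline computes per-participant
Fisher-Z cross-correlation profiles, averages them, parcellates the seed at
every K, runs the split-half VI procedure and the optimal-K rule, computes
hierarchy indices between consecutive solutions and (when both hemispheres
are present) the symmetry index, and writes label volumes, metric tables and
a structured plain-text log.  Identical configurations produce identical
outputs.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import Parcellation, kmeans_replicates, summarize_clusters
from .connectivity import average_group, participant_profiles
from .errors import ConnparcError, InvalidConfigError
from .io import (
    RunConfig,
    SeedMask,
    load_seed_mask,
    read_connectivity,
    write_labels_nifti,
    write_mask_nifti,
    write_table,
)
from .metrics import (
    hierarchy_curve,
    select_optimal_k,
    split_half_vi,
    symmetry_index,
)


def _log_lines(cfg: RunConfig) -> list[str]:
    lines = [f"connparc_version={__version__}"]
    for key in (
        "k_range", "n_replicates", "n_repetitions", "alpha_optimal_k",
        "alpha_fwe", "tract_threshold", "consistency_cutoff", "log_base",
        "clip_epsilon", "rng_seed",
    ):
        lines.append(f"{key}={getattr(cfg, key)}")
    return lines


def _load_hemisphere_inputs(cfg: RunConfig):
    """Resolve (mask, matrices) per hemisphere from files or simulation."""
    from .connectivity import ConnectivityMatrix  # local: avoid cycles

    data: dict[str, tuple[SeedMask, list[ConnectivityMatrix]]] = {}
    truths: dict[str, np.ndarray] = {}
    if cfg.synthetic is not None:
        from .synthetic import (
            SyntheticConfig,
            simulate_group,
            simulate_hemisphere_pair,
            synthetic_seed_mask,
        )

        syn = dict(cfg.synthetic)
        hemispheres = syn.pop("hemispheres", ["left"])
        scfg = SyntheticConfig(**syn)
        if set(hemispheres) == {"left", "right"}:
            t_left, t_right = simulate_hemisphere_pair(scfg)
            planted = {"left": t_left, "right": t_right}
        else:
            planted = {h: None for h in hemispheres}
        for h in hemispheres:
            mask = synthetic_seed_mask(scfg.n_seed_voxels, hemisphere=h)
            truth = planted[h]
            if truth is None:
                from .synthetic import make_planted_labels

                truth = make_planted_labels(scfg)
            data[h] = (mask, simulate_group(scfg, truth, seed_mask=mask))
            truths[h] = truth.labels
        return data, truths

    for h, mask_path in cfg.mask_paths.items():
        mask = load_seed_mask(mask_path, hemisphere=h)
        matrices = []
        for i, mpath in enumerate(cfg.matrix_paths.get(h, [])):
            counts = read_connectivity(mpath, format=cfg.matrix_format)
            matrices.append(
                ConnectivityMatrix(
                    counts=counts,
                    seed_index=mask.voxels,
                    participant_id=f"sub-{i + 1:03d}",
                )
            )
        if not matrices:
            raise InvalidConfigError(f"no connectivity matrices for {h}")
        data[h] = (mask, matrices)
    if not data:
        raise InvalidConfigError("config supplies neither inputs nor a synthetic block")
    return data, truths


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns a report dict mirroring the files."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"hemispheres": {}}
    log = _log_lines(cfg)

    try:
        data, _truths = _load_hemisphere_inputs(cfg)
    except ConnparcError as exc:
        raise type(exc)(f"[inputs] {exc}") from exc

    parcellations: dict[str, dict[int, Parcellation]] = {}
    masks: dict[str, SeedMask] = {}
    for h, (mask, matrices) in sorted(data.items()):
        masks[h] = mask
        write_mask_nifti(mask, out / f"{h}_seed_mask.nii.gz")
        log.append(f"{h}.n_seed_voxels={mask.n_voxels}")
        log.append(f"{h}.n_participants={len(matrices)}")

        try:
            profiles = participant_profiles(matrices, clip_epsilon=cfg.clip_epsilon)
            group_avg = average_group(profiles)
        except ConnparcError as exc:
            raise type(exc)(f"[connectivity:{h}] {exc}") from exc

        # stable per-hemisphere stream (str hash() is salted per process)
        h_tag = int.from_bytes(h.encode()[:4].ljust(4, b"\0"), "big") % (2**31)
        ss = np.random.SeedSequence([cfg.rng_seed, h_tag])
        km_seeds = ss.generate_state(len(cfg.k_range)) % (2**31 - 1)
        parcellations[h] = {}
        summary_rows = []
        for j, k in enumerate(cfg.k_range):
            parc = kmeans_replicates(
                group_avg, k, n_replicates=cfg.n_replicates, rng_seed=int(km_seeds[j])
            )
            parcellations[h][k] = parc
            write_labels_nifti(parc.labels, mask, out / f"{h}_parcellation_K{k}.nii.gz")
            summary = summarize_clusters(parc, mask)
            for c in range(k):
                x, y, z = summary.centers_of_gravity[c]
                summary_rows.append(
                    {"K": k, "cluster": c + 1, "size": int(summary.sizes[c]),
                     "x_mm": x, "y_mm": y, "z_mm": z}
                )
        write_table(pd.DataFrame(summary_rows), out / f"{h}_cluster_summary.tsv")

        curve = split_half_vi(
            profiles,
            k_range=cfg.k_range,
            n_repetitions=cfg.n_repetitions,
            n_replicates=cfg.n_replicates,
            rng_seed=cfg.rng_seed,
            log_base=cfg.log_base,
        )
        selection = select_optimal_k(curve, alpha=cfg.alpha_optimal_k)
        vi_df = pd.DataFrame(
            {
                "K": curve.k_values,
                "mean_vi": curve.mean,
                "ci_low": curve.ci_low,
                "ci_high": curve.ci_high,
                "t_vs_prev": curve.t_stats,
                "p_vs_prev": curve.p_values,
            }
        )
        write_table(vi_df, out / f"{h}_vi_curve.tsv")

        hi = hierarchy_curve(parcellations[h])
        write_table(
            pd.DataFrame(
                {"K": list(hi.keys()), "hierarchy_index": list(hi.values())}
            ),
            out / f"{h}_hierarchy.tsv",
        )

        log.append(f"{h}.optimal_k={selection.k}")
        log.append(f"{h}.no_selection={selection.no_selection}")
        report["hemispheres"][h] = {
            "optimal_k": selection.k,
            "no_selection": selection.no_selection,
            "mean_vi": dict(zip(curve.k_values, curve.mean.tolist())),
            "hierarchy_index": hi,
            "n_seed_voxels": mask.n_voxels,
        }

    if set(parcellations) >= {"left", "right"}:
        sym_rows = []
        for k in cfg.k_range:
            res = symmetry_index(
                parcellations["left"][k], parcellations["right"][k],
                masks["left"], masks["right"],
            )
            sym_rows.append(
                {"K": k, "symmetry": res.proportion,
                 "overlap_voxels": res.overlap_domain_size}
            )
        write_table(pd.DataFrame(sym_rows), out / "symmetry.tsv")
        report["symmetry"] = {r["K"]: r["symmetry"] for r in sym_rows}

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    report["out_dir"] = str(out)
    return report
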