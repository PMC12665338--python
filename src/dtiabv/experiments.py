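"""Canned simulation experiments used for validation and benchmarking.

Each function generates phantom cohorts from scratch, runs the relevant
pipeline stages, and measures a recovery or error-control property:

* :func:`null_cluster_rate` — voxel-wise type-I control under the global null;
* :func:`harmonization_residual_rate` — residual site effects after
  control-anchored harmonization;
* :func:`effect_recovery` — spatial (Dice) and quantitative (TFAS) recovery
  of an injected tract FA reduction;
* :func:`volumetry_recovery` — recovery of an injected structure erosion;
* :func:`forest_separable`, :func:`forest_permutation`,
  :func:`forest_elimination_recovery` — classifier sanity checks.

Problem sizes default to what a laptop-scale reanalysis can afford; every
function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dtiabv import forest as forest_mod
from dtiabv import phantom as ph
from dtiabv import preprocess as pre
from dtiabv import toi as toi_mod
from dtiabv import wbss as wbss_mod
from dtiabv.tensors import control_average_tensor, fit_tensor


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    inter = (a & b).sum()
    total = a.sum() + b.sum()
    return 2.0 * inter / total if total else 0.0


def null_cluster_rate(n_seeds: int = 100, n_per_group: int = 10,
                      noise_sigma: float = 0.02, seed: int = 0,
                      fwhm_mm: float = 8.0, q: float = 0.05,
                      cluster_mm3: float = 256.0) -> dict:
    """Fraction of null cohorts with any surviving WBSS cluster.

    Two groups of ``n_per_group`` subjects are generated with *no* injected
    effect (Rician noise only) on the default 48^3 phantom; smoothed FA maps
    are compared with the Welch test, BH-FDR and the cluster-extent
    threshold.  Under valid error control at most a small fraction of seeds
    should show any surviving cluster.
    """
    spec = ph.default_phantom()
    anatomy = ph.build_tensor_phantom(spec)
    effects = ph.EffectSpec(noise_sigma=noise_sigma)
    n_hit = 0
    for s in range(n_seeds):
        cohort = ph.build_cohort(spec, effects,
                                 {"control": n_per_group, "bvFTD": n_per_group},
                                 seed=(seed * 100003 + s) % 2**31, anatomy=anatomy)
        fa, _ = cohort.fa_md_maps()
        fa = pre.smooth_stack(fa, fwhm_mm, spec.grid.voxel_size)
        is_ctrl = (cohort.table.group == "control").to_numpy()
        mask = wbss_mod.analysis_mask(fa[is_ctrl])
        sm = wbss_mod.welch_map(fa[~is_ctrl], fa[is_ctrl], mask, spec.grid)
        _, report = wbss_mod.fdr_cluster_correct(sm, q=q, min_volume_mm3=cluster_mm3)
        n_hit += int(len(report) > 0)
    return {"n_seeds": n_seeds, "n_with_cluster": n_hit,
            "rate": n_hit / n_seeds}


def harmonization_residual_rate(n_seeds: int = 100, n_per_site: int = 10,
                                offset: float = 0.03, noise_sigma: float = 0.02,
                                seed: int = 0, fwhm_mm: float = 8.0,
                                q: float = 0.05, cluster_mm3: float = 256.0) -> dict:
    """Fraction of seeds with zero residual site-difference clusters.

    Controls from two sites, the second carrying an additive FA offset, are
    harmonized with the control-anchored offset correction; a site-vs-site
    Welch WBSS afterwards should find nothing.
    """
    spec = ph.default_phantom()
    anatomy = ph.build_tensor_phantom(spec)
    effects = ph.EffectSpec(site_fa_offset={"A": 0.0, "B": offset},
                            noise_sigma=noise_sigma)
    n_clean = 0
    for s in range(n_seeds):
        cohort = ph.build_cohort(spec, effects, {"control": 2 * n_per_site},
                                 seed=(seed * 99991 + s) % 2**31, anatomy=anatomy)
        fa, _ = cohort.fa_md_maps()
        fa = pre.smooth_stack(fa, fwhm_mm, spec.grid.voxel_size)
        fa, _ = pre.site_harmonize(fa, cohort.table)
        site_a = (cohort.table.site == "A").to_numpy()
        mask = wbss_mod.analysis_mask(fa)
        sm = wbss_mod.welch_map(fa[site_a], fa[~site_a], mask, spec.grid)
        _, report = wbss_mod.fdr_cluster_correct(sm, q=q, min_volume_mm3=cluster_mm3)
        n_clean += int(len(report) == 0)
    return {"n_seeds": n_seeds, "n_clean": n_clean, "rate_clean": n_clean / n_seeds}


def effect_recovery(n_per_group: int = 40, reduction: float = 0.15,
                    tract: str = "genu_cc", noise_sigma: float = 0.02,
                    fa_scale_sd: float = 0.04, seed: int = 0,
                    fwhm_mm: float = 8.0, q: float = 0.05,
                    cluster_mm3: float = 256.0, n_controls_average: int = 10) -> dict:
    """Recovery of an injected tract FA reduction by WBSS and TFAS.

    Returns the Dice overlap between the surviving WBSS cluster map and the
    injected tract mask, plus the TFAS group difference against the injected
    absolute FA drop (relative error).
    """
    spec = ph.default_phantom()
    anatomy = ph.build_tensor_phantom(spec)
    effects = ph.EffectSpec(fa_reduction={tract: {"bvFTD": reduction}},
                            noise_sigma=noise_sigma, fa_scale_sd=fa_scale_sd)
    cohort = ph.build_cohort(spec, effects,
                             {"control": n_per_group, "bvFTD": n_per_group},
                             seed=seed, anatomy=anatomy)
    fa, _ = cohort.fa_md_maps()
    is_ctrl = (cohort.table.group == "control").to_numpy()

    fa_s = pre.smooth_stack(fa, fwhm_mm, spec.grid.voxel_size)
    mask = wbss_mod.analysis_mask(fa_s[is_ctrl])
    sm = wbss_mod.welch_map(fa_s[~is_ctrl], fa_s[is_ctrl], mask, spec.grid)
    sm, report = wbss_mod.fdr_cluster_correct(sm, q=q, min_volume_mm3=cluster_mm3)
    dice = _dice(sm.reject, anatomy.tract_masks[tract])

    # TOI from the averaged control tensor dataset, then tract-wise means
    ctrl_rows = np.where(is_ctrl)[0][:n_controls_average]
    fields = [fit_tensor(cohort.subject_dwi(i), cohort.gradients, grid=spec.grid)
              for i in ctrl_rows]
    avg = control_average_tensor(fields)
    from dtiabv.pipeline import endpoint_masks

    seed_mask, target_mask = endpoint_masks(anatomy, tract)
    streams = toi_mod.track_streamlines(avg, seed_mask, spec.grid)
    toi = toi_mod.seed_to_target_filter(
        streams, toi_mod.SeedTargetSpec(tract, seed_mask, target_mask), spec.grid)
    vals = np.array([toi_mod.tfas(toi, fa[i])[0] for i in range(len(cohort.table))])
    measured_drop = vals[is_ctrl].mean() - vals[~is_ctrl].mean()
    injected_drop = reduction * vals[is_ctrl].mean()
    return {
        "dice": dice,
        "n_clusters": int(len(report)),
        "tfas_control_mean": float(vals[is_ctrl].mean()),
        "tfas_patient_mean": float(vals[~is_ctrl].mean()),
        "measured_drop": float(measured_drop),
        "injected_drop": float(injected_drop),
        "relative_error": float(abs(measured_drop - injected_drop)
                                / injected_drop),
    }


def volumetry_recovery(atrophy: float = 0.20, structure: str = "caudate_L",
                       n_per_group: int = 5, seed: int = 0) -> dict:
    """Recovery of an injected structure erosion as a volume ratio.

    Noise-free generation, so the standardized patient/control volume ratio
    should equal ``1 - atrophy`` up to the fractional-boundary voxelization
    (strictly below one voxel volume).  Also checks that re-standardizing a
    standardized table is the identity.
    """
    from dtiabv import abv as abv_mod

    spec = ph.default_phantom()
    anatomy = ph.build_tensor_phantom(spec)
    effects = ph.EffectSpec(volume_atrophy={structure: {"bvFTD": atrophy}})
    cohort = ph.build_cohort(spec, effects,
                             {"control": n_per_group, "bvFTD": n_per_group},
                             seed=seed, anatomy=anatomy)
    table = cohort.table
    comps = (cohort.subject_compartments(i) for i in range(len(table)))
    volumes, icv = abv_mod.soi_volumes(comps, anatomy.structure_masks,
                                       spec.grid.voxel_volume, table.subject)
    ctrl_ids = table.subject[table.group == "control"]
    std = abv_mod.standardize_icv(volumes, icv, ctrl_ids)
    std_icv = icv.copy()
    std_icv[:] = float(icv.loc[ctrl_ids].mean())
    twice = abv_mod.standardize_icv(std, std_icv, ctrl_ids)
    ratio = (std.loc[table.subject[table.group == "bvFTD"], structure].mean()
             / std.loc[ctrl_ids, structure].mean())
    return {
        "ratio": float(ratio),
        "target_ratio": 1.0 - atrophy,
        "ratio_error_ml": float(abs(
            std.loc[table.subject[table.group == "bvFTD"], structure].mean()
            - (1 - atrophy) * std.loc[ctrl_ids, structure].mean())),
        "voxel_volume_ml": spec.grid.voxel_volume / 1000.0,
        "restandardize_max_abs_diff": float((twice - std).abs().to_numpy().max()),
    }


def _noise_features(rng, n, k):
    return rng.standard_normal((n, k))


def forest_separable(seed: int = 0, n_per_class: int = 30) -> forest_mod.ForestResult:
    """One feature cleanly separating the classes: CV accuracy must be 1."""
    rng = np.random.default_rng(seed)
    sep = np.concatenate([rng.uniform(0, 0.4, n_per_class),
                          rng.uniform(0.6, 1.0, n_per_class)])
    x = pd.DataFrame({"separating": sep,
                      "noise": rng.standard_normal(2 * n_per_class)})
    y = pd.Series(["control"] * n_per_class + ["bvFTD"] * n_per_class)
    fm = forest_mod.FeatureMatrix(x, y, positive_class="bvFTD")
    return forest_mod.train_eval_cv(fm, seed=seed)


def forest_permutation(n_seeds: int = 20, n_per_class: int = 100,
                       n_features: int = 30, seed: int = 0) -> dict:
    """Label-permuted null: mean CV accuracy should hover near chance."""
    accs = []
    for s in range(n_seeds):
        rng = np.random.default_rng((seed * 7919 + s) % 2**31)
        x = pd.DataFrame(_noise_features(rng, 2 * n_per_class, n_features),
                         columns=[f"f{i}" for i in range(n_features)])
        labels = np.array(["control"] * n_per_class + ["bvFTD"] * n_per_class)
        rng.shuffle(labels)
        fm = forest_mod.FeatureMatrix(x, pd.Series(labels), positive_class="bvFTD")
        accs.append(forest_mod.train_eval_cv(fm, seed=s).cv_accuracy)
    return {"mean_accuracy": float(np.mean(accs)), "accuracies": accs}


def forest_elimination_recovery(n_seeds: int = 20, n_per_class: int = 40,
                                n_noise: int = 9, seed: int = 0) -> dict:
    """Elimination should keep the single informative feature."""
    kept = 0
    for s in range(n_seeds):
        rng = np.random.default_rng((seed * 104729 + s) % 2**31)
        informative = np.concatenate([rng.normal(0, 1, n_per_class),
                                      rng.normal(2.0, 1, n_per_class)])
        x = pd.DataFrame(_noise_features(rng, 2 * n_per_class, n_noise),
                         columns=[f"noise{i}" for i in range(n_noise)])
        x["informative"] = informative
        y = pd.Series(["control"] * n_per_class + ["bvFTD"] * n_per_class)
        fm = forest_mod.FeatureMatrix(x, y, positive_class="bvFTD")
        final, _, _ = forest_mod.gini_eliminate(fm, seed=s)
        kept += int("informative" in final.X.columns)
    return {"n_seeds": n_seeds, "n_kept": kept, "rate": kept / n_seeds}
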