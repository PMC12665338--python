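"""End-to-end orchestration: config, stage sequencing, provenance, report.

A single YAML config governs every stage; all analysis thresholds (FA floor
0.2, q = 0.05, 256 mm^3 cluster extent, 8 mm FWHM smoothing, the forest
hyperparameters) are config keys with those defaults.  ``run_pipeline``
executes phantom -> tensors -> preprocess -> wbss / toi / abv -> forest into
a run directory and hashes every output file into a provenance manifest, so
identical configs give identical manifests.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dtiabv import abv as abv_mod
from dtiabv import forest as forest_mod
from dtiabv import phantom as ph
from dtiabv import preprocess as pre
from dtiabv import toi as toi_mod
from dtiabv import wbss as wbss_mod
from dtiabv.grids import Grid, save_volume
from dtiabv.tensors import control_average_tensor, fit_tensor

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "phantom": {"grid_shape": [48, 48, 48], "voxel_size": [2.0, 2.0, 2.0]},
    "cohort": {
        "n_per_group": {"control": 10, "bvFTD": 10, "ALS-FTD": 10},
        "n_followup": 4,
        "noise_sigma": 0.02,
    },
    "preprocess": {"fwhm_mm": 8.0, "gain": False},
    "wbss": {"fa_threshold": 0.2, "q": 0.05, "cluster_mm3": 256.0,
             "connectivity": 26, "roi_radius_mm": 6.0},
    "toi": {"fa_stop": 0.2, "angle_stop_deg": 40.0, "step_factor": 0.5,
            "endpoint_fraction": 0.18},
    "abv": {"q": 0.05},
    "forest": {"k_folds": 5, "validation_fraction": 0.2, "tolerance": 0.0},
    "stages": {"wbss": True, "toi": True, "abv": True, "forest": True},
}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys."""
    def merge(defaults, user, path=""):
        out = copy.deepcopy(defaults)
        for key, val in (user or {}).items():
            if key not in defaults:
                raise ValueError(f"unknown config key: {path + key!r}")
            if isinstance(defaults[key], dict) and key != "n_per_group":
                out[key] = merge(defaults[key], val, path + key + ".")
            else:
                out[key] = copy.deepcopy(val)
        return out

    return merge(DEFAULT_CONFIG, config)


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def endpoint_masks(anatomy: ph.PhantomAnatomy, tract_name: str,
                   fraction: float = 0.18):
    """Seed/target slabs at the two ends of a named phantom tract.

    Tract voxels are ranked by their arclength position along the
    centerline; the first ``fraction`` form the seed, the last the target.
    """
    geometry = next(t for t in anatomy.spec.tracts if t.name == tract_name)
    mask = anatomy.tract_masks[tract_name]
    pts = geometry.centerline_mm
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    vox_mm = anatomy.grid.voxel_to_world(np.argwhere(mask))
    d = np.linalg.norm(vox_mm[:, None, :] - pts[None, :, :], axis=2)
    t_arc = cum[np.argmin(d, axis=1)] / cum[-1]
    seed = np.zeros(mask.shape, bool)
    target = np.zeros(mask.shape, bool)
    idx = np.argwhere(mask)
    lo = t_arc <= fraction
    hi = t_arc >= 1.0 - fraction
    seed[tuple(idx[lo].T)] = True
    target[tuple(idx[hi & ~lo].T)] = True
    return seed, target


def _present_pairs(table: pd.DataFrame, min_n: int = 3):
    counts = table[table.timepoint == "baseline"].group.value_counts()
    have = {g for g, n in counts.items() if n >= min_n}
    pairs = [("bvFTD", "control"), ("ALS-FTD", "control"), ("ALS-FTD", "bvFTD")]
    return tuple(p for p in pairs if set(p) <= have)


def _write_tsv(df: pd.DataFrame, path: Path, index=False):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict, out_dir, write_subject_volumes: bool = False) -> Path:
    """Execute all enabled stages and write outputs + provenance manifest."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- phantom ------------------------------------------------------
    stage = "phantom"
    try:
        grid = Grid(tuple(cfg["phantom"]["grid_shape"]),
                    tuple(cfg["phantom"]["voxel_size"]))
        spec = ph.default_phantom(grid.shape, grid.voxel_size)
        effects = ph.default_effects(noise_sigma=cfg["cohort"]["noise_sigma"])
        cohort = ph.build_cohort(spec, effects, cfg["cohort"]["n_per_group"],
                                 seed=seed, n_followup=cfg["cohort"]["n_followup"])
        if cohort.table.empty:
            raise ValueError("generated cohort is empty")
        table = cohort.table
        _write_tsv(table, out / "cohort.tsv")
        cohort.gradients.save(out / "dwi.bval", out / "dwi.bvec")
        save_volume(cohort.anatomy.atlas, grid, out / "atlas.nii")
        for comp in ("gm", "wm", "csf"):
            save_volume(getattr(cohort.anatomy, comp).astype(np.float32), grid,
                        out / f"{comp}_template.nii")
        if write_subject_volumes:
            dwi_dir = out / "dwi"
            dwi_dir.mkdir(exist_ok=True)
            for i, row in table.iterrows():
                save_volume(cohort.subject_dwi(i), grid,
                            dwi_dir / f"{row.subject}_{row.timepoint}.nii")

        # --- tensors --------------------------------------------------
        stage = "tensors"
        fa_maps, md_maps = cohort.fa_md_maps()
        base = table.reset_index(drop=True)
        ctrl_rows = base.index[(base.group == "control")
                               & (base.timepoint == "baseline")].to_numpy()
        ctrl_fields = [fit_tensor(cohort.subject_dwi(i), cohort.gradients, grid=grid)
                       for i in ctrl_rows]
        avg_tensors = control_average_tensor(ctrl_fields)
        save_volume(fa_maps.mean(axis=0), grid, out / "fa_group_mean.nii")

        # --- preprocess -----------------------------------------------
        stage = "preprocess"
        fwhm = cfg["preprocess"]["fwhm_mm"]
        fa_s = pre.smooth_stack(fa_maps, fwhm, grid.voxel_size)
        fa_s, slopes, ref_age = pre.age_correct(fa_s, table)
        fa_s, corrections = pre.site_harmonize(fa_s, table,
                                               gain=cfg["preprocess"]["gain"])
        fa_u, _, _ = pre.age_correct(fa_maps, table, reference_age=ref_age)
        fa_u, _ = pre.site_harmonize(fa_u, table, gain=cfg["preprocess"]["gain"])
        for site, corr in corrections.items():
            field = corr[1] if isinstance(corr, tuple) else corr
            save_volume(field.astype(np.float32), grid,
                        out / f"site_correction_{site}.nii")

        results = {}

        # --- wbss -----------------------------------------------------
        if cfg["stages"]["wbss"]:
            stage = "wbss"
            wcfg = cfg["wbss"]
            mask = wbss_mod.analysis_mask(fa_s[ctrl_rows], wcfg["fa_threshold"])
            for g1 in ("bvFTD", "ALS-FTD"):
                sel = base.index[(base.group == g1)
                                 & (base.timepoint == "baseline")].to_numpy()
                if sel.size < 2:
                    continue
                sm = wbss_mod.welch_map(fa_s[sel], fa_s[ctrl_rows], mask, grid,
                                        test_name=f"{g1}_vs_control")
                sm, report = wbss_mod.fdr_cluster_correct(
                    sm, q=wcfg["q"], min_volume_mm3=wcfg["cluster_mm3"],
                    connectivity=wcfg["connectivity"])
                _write_tsv(report, out / f"wbss_clusters_{g1}_vs_control.tsv")
                save_volume(sm.stat.astype(np.float32), grid,
                            out / f"wbss_t_{g1}_vs_control.nii")
                save_volume(sm.reject.astype(np.uint8), grid,
                            out / f"wbss_reject_{g1}_vs_control.nii")
                results[f"wbss_{g1}"] = report
            pat = base.index[(base.group != "control")
                             & (base.timepoint == "baseline")].to_numpy()
            scores = base.loc[pat, "cdr_sob"].to_numpy()
            cm = wbss_mod.corr_map(fa_s[pat], scores, mask, grid,
                                   test_name="fa_vs_cdr")
            cm, corr_report = wbss_mod.fdr_cluster_correct(
                cm, q=wcfg["q"], min_volume_mm3=wcfg["cluster_mm3"],
                connectivity=wcfg["connectivity"])
            _write_tsv(corr_report, out / "wbss_clusters_fa_vs_cdr.tsv")
            if len(corr_report):
                rois = wbss_mod.place_spherical_rois(
                    corr_report, wcfg["roi_radius_mm"], grid, mask=mask)
                roi_vol = np.zeros(grid.shape, np.uint8)
                for k, (name, m) in enumerate(rois.items(), start=1):
                    roi_vol[m] = k
                save_volume(roi_vol, grid, out / "wbss_peak_rois.nii")

        # --- toi ------------------------------------------------------
        tfas_values = None
        if cfg["stages"]["toi"]:
            stage = "toi"
            tcfg = cfg["toi"]
            step = tcfg["step_factor"] * min(grid.voxel_size)
            tois = {}
            for tract in spec.tracts:
                seed_mask, target_mask = endpoint_masks(
                    cohort.anatomy, tract.name, tcfg["endpoint_fraction"])
                streams = toi_mod.track_streamlines(
                    avg_tensors, seed_mask, grid, fa_stop=tcfg["fa_stop"],
                    angle_stop_deg=tcfg["angle_stop_deg"], step_mm=step)
                if not streams:
                    continue
                st_spec = toi_mod.SeedTargetSpec(tract.name, seed_mask, target_mask)
                tois[tract.name] = toi_mod.seed_to_target_filter(streams, st_spec, grid)
            subjects = table.subject + "_" + table.timepoint
            tfas_values = toi_mod.tfas_table(tois, fa_u, subjects)
            base_ids = table.subject.where(table.timepoint == "baseline")
            tfas_baseline = tfas_values.copy()
            tfas_baseline.index = subjects.to_numpy()
            keep = (table.timepoint == "baseline").to_numpy()
            tfas_baseline = tfas_baseline[keep]
            tfas_baseline.index = table.subject[keep].to_numpy()
            _write_tsv(tfas_values.reset_index(), out / "tfas_values.tsv")
            toi_stats = toi_mod.toi_group_stats(tfas_baseline, table,
                                                group_pairs=_present_pairs(table))
            _write_tsv(toi_stats, out / "toi_group_stats.tsv")
            tfas_values = tfas_baseline

        # --- abv ------------------------------------------------------
        volumes_std = None
        if cfg["stages"]["abv"]:
            stage = "abv"
            comps = (cohort.subject_compartments(i) for i in range(len(table)))
            idx = pd.MultiIndex.from_frame(table[["subject", "timepoint"]])
            volumes, icv = abv_mod.soi_volumes(
                comps, cohort.anatomy.structure_masks, grid.voxel_volume, idx)
            ctrl_idx = [(s, "baseline") for s in
                        table.subject[(table.group == "control")
                                      & (table.timepoint == "baseline")]]
            volumes_std = abv_mod.standardize_icv(volumes, icv, ctrl_idx)
            vol_base = volumes_std.xs("baseline", level="timepoint")
            _write_tsv(volumes_std.reset_index(), out / "soi_volumes.tsv")
            soi_stats = abv_mod.soi_group_stats(vol_base, table, q=cfg["abv"]["q"],
                                                group_pairs=_present_pairs(table))
            _write_tsv(soi_stats, out / "soi_group_stats.tsv")
            if cfg["cohort"]["n_followup"] >= 2:
                longi = abv_mod.longitudinal_change(volumes_std, table,
                                                    q=cfg["abv"]["q"])
                _write_tsv(longi, out / "soi_longitudinal.tsv")
            pat_base = table[(table.group != "control")
                             & (table.timepoint == "baseline")]
            corr = abv_mod.soi_partial_corr(
                vol_base.loc[pat_base.subject],
                pat_base.set_index("subject").cdr_sob,
                pat_base.set_index("subject").age, q=cfg["abv"]["q"])
            _write_tsv(corr, out / "soi_score_correlation.tsv")
            volumes_std = vol_base

        # --- forest ---------------------------------------------------
        if cfg["stages"]["forest"] and tfas_values is not None and volumes_std is not None:
            stage = "forest"
            fcfg = cfg["forest"]
            forest_out = {}
            tasks = [("bvFTD", "control"), ("ALS-FTD", "control"),
                     ("bvFTD", "ALS-FTD")]
            counts = table[table.timepoint == "baseline"].group.value_counts()
            have = {g for g, n in counts.items() if n >= 5}
            for task in [t for t in tasks if set(t) <= have]:
                features = forest_mod.build_feature_matrix(
                    tfas_values, volumes_std, table, task)
                train, val = forest_mod.split_cohort(
                    features, seed, validation_fraction=fcfg["validation_fraction"])
                k = min(fcfg["k_folds"], int(train.y.value_counts().min()))
                if k < fcfg["k_folds"]:
                    log.warning("forest %s: reducing folds to %d (small classes)",
                                task, k)
                final, result, trail = forest_mod.gini_eliminate(
                    train, seed, k_folds=k, tolerance=fcfg["tolerance"])
                full = forest_mod.train_eval_cv(train, seed, k_folds=k,
                                                validation=val)
                forest_out["_vs_".join(task)] = {
                    "cv_accuracy": full.cv_accuracy,
                    "cv_sensitivity": full.cv_sensitivity,
                    "cv_specificity": full.cv_specificity,
                    "validation_accuracy": full.validation_accuracy,
                    "validation_sensitivity": full.validation_sensitivity,
                    "validation_specificity": full.validation_specificity,
                    "ranking": full.ranking,
                    "selected_features": list(final.X.columns),
                    "selected_cv_accuracy": result.cv_accuracy,
                    "elimination_trail": trail.to_dict(orient="records"),
                }
                _write_tsv(full.importances.rename_axis("feature").reset_index(),
                           out / f"forest_importances_{'_vs_'.join(task)}.tsv")
            with open(out / "forest_results.json", "w") as fh:
                json.dump(forest_out, fh, indent=2)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config": cfg,
        "files": {p.relative_to(out).as_posix(): _sha256(p)
                  for p in sorted(out.rglob("*")) if p.is_file()
                  and p.name != "manifest.json"},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


REPORT_SECTIONS = {
    "TOI group statistics": "toi_group_stats.tsv",
    "SOI group statistics": "soi_group_stats.tsv",
    "SOI longitudinal change": "soi_longitudinal.tsv",
    "SOI clinical-score correlation": "soi_score_correlation.tsv",
    "Classification": "forest_results.json",
}


def make_report(run_dir) -> Path:
    """Summarize a completed run's tables into one markdown report.

    Missing stage outputs are flagged as explicit gaps rather than silently
    skipped; an empty or absent cohort is an error.
    """
    run = Path(run_dir)
    cohort_path = run / "cohort.tsv"
    if not cohort_path.exists() or pd.read_csv(cohort_path, sep="\t").empty:
        raise ValueError("run directory has no (non-empty) cohort table")
    lines = ["# Pipeline report", ""]
    cohort = pd.read_csv(cohort_path, sep="\t")
    counts = cohort[cohort.timepoint == "baseline"].group.value_counts().to_dict()
    lines += [f"Cohort: {counts}, follow-up rows: "
              f"{int((cohort.timepoint == 'followup').sum())}", ""]
    for title, fname in REPORT_SECTIONS.items():
        path = run / fname
        lines.append(f"## {title}")
        if not path.exists():
            lines += ["*Stage output absent.*", ""]
            continue
        if fname.endswith(".json"):
            with open(path) as fh:
                data = json.load(fh)
            for task, res in data.items():
                lines.append(
                    f"- {task}: CV accuracy {res['cv_accuracy']:.3f}, "
                    f"sensitivity {res['cv_sensitivity']:.3f}, "
                    f"specificity {res['cv_specificity']:.3f}; "
                    f"{len(res['selected_features'])} features retained")
        else:
            df = pd.read_csv(path, sep="\t")
            lines.append("```\n" + df.to_string(index=False) + "\n```")
        lines.append("")
    for g1 in ("bvFTD", "ALS-FTD"):
        path = run / f"wbss_clusters_{g1}_vs_control.tsv"
        lines.append(f"## WBSS clusters: {g1} vs control")
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            lines.append("```\n" + df.to_string(index=False) + "\n```" if len(df)
                         else "*No surviving clusters.*")
        else:
            lines.append("*Stage output absent.*")
        lines.append("")
    report = run / "report.md"
    report.write_text("\n".join(lines))
    return report
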