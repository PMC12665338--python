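"""Whole-brain-based spatial statistics (WBSS).

Voxel-wise two-group Welch tests or Pearson correlations with a clinical
score, corrected by Benjamini–Hochberg FDR over the analysis mask and a
cluster-extent threshold, with cluster reporting and automatic spherical
peak ROIs.  The analysis mask is conventionally the set of voxels whose
smoothed control-mean FA exceeds 0.2, restricting inference to coherent
white matter while keeping the mask independent of the patient groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from dtiabv._stats import bh_adjust
from dtiabv.grids import Grid

log = logging.getLogger(__name__)

FA_MASK_THRESHOLD = 0.2


@dataclass
class StatMap:
    """Voxel-wise statistic + p map with rejection flags inside a mask."""

    stat: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    grid: Grid
    test: str = ""
    reject: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.reject is None:
            self.reject = np.zeros(self.mask.shape, bool)


def analysis_mask(control_fa_maps: np.ndarray,
                  threshold: float = FA_MASK_THRESHOLD) -> np.ndarray:
    """Voxels where the (smoothed) control-mean FA exceeds the threshold."""
    return control_fa_maps.mean(axis=0) > threshold


def welch_map(group_a: np.ndarray, group_b: np.ndarray, mask: np.ndarray,
              grid: Grid, test_name: str = "welch") -> StatMap:
    """Voxel-wise two-sided Welch t-test between two subject stacks.

    Welch–Satterthwaite degrees of freedom; voxels where both groups are
    constant get t=0, p=1 by convention (counted in the log).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 subjects")
    a = group_a[:, mask].astype(float)
    b = group_b[:, mask].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=False)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        log.info("welch_map: %d zero-variance voxels set to t=0, p=1",
                 int(degenerate.sum()))
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    stat = np.zeros(mask.shape)
    pval = np.ones(mask.shape)
    stat[mask] = t
    pval[mask] = p
    return StatMap(stat, pval, mask, grid, test=test_name)


def corr_map(maps: np.ndarray, scores: np.ndarray, mask: np.ndarray,
             grid: Grid, test_name: str = "pearson") -> StatMap:
    """Voxel-wise Pearson correlation of subject maps with a clinical score.

    The statistic is the signed r (the report distinguishes negative from
    positive clusters); p is the two-sided t-transform p-value.
    """
    scores = np.asarray(scores, float)
    if scores.size < 4:
        raise ValueError("correlation needs >= 4 subjects with scores")
    if np.ptp(scores) == 0:
        raise ValueError("scores are constant; correlation undefined")
    y = maps[:, mask].astype(float)
    n = scores.size
    s = scores - scores.mean()
    yc = y - y.mean(axis=0)
    denom = np.sqrt((s @ s) * (yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s @ yc) / denom
    r = np.clip(np.where(denom > 0, r, 0.0), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    stat = np.zeros(mask.shape)
    pval = np.ones(mask.shape)
    stat[mask] = r
    pval[mask] = p
    return StatMap(stat, pval, mask, grid, test=test_name)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError("connectivity must be 6, 18 or 26")


def fdr_cluster_correct(stat_map: StatMap, q: float = 0.05,
                        min_volume_mm3: float = 256.0,
                        connectivity: int = 26):
    """BH-FDR over in-mask voxels, then a cluster-extent threshold.

    Surviving voxels are labeled into connected components (26-neighbor by
    default); components smaller than ``min_volume_mm3`` are removed.
    Returns the StatMap with rejection flags filled and a cluster table
    sorted by size (label, voxel count, volume, peak-|stat| voxel in grid
    and world coordinates, peak statistic, peak p).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    columns = ["label", "n_voxels", "volume_mm3", "peak_i", "peak_j", "peak_k",
               "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_stat", "peak_p"]
    empty = pd.DataFrame(columns=columns)
    if not stat_map.mask.any():
        stat_map.reject = np.zeros(stat_map.mask.shape, bool)
        return stat_map, empty
    pvals = stat_map.p[stat_map.mask]
    rej, _ = bh_adjust(pvals, q=q)
    reject = np.zeros(stat_map.mask.shape, bool)
    reject[stat_map.mask] = rej
    voxel_volume = stat_map.grid.voxel_volume
    labels, n_lab = ndimage.label(reject, structure=_connectivity_structure(connectivity))
    rows = []
    for lab in range(1, n_lab + 1):
        comp = labels == lab
        n_vox = int(comp.sum())
        vol = n_vox * voxel_volume
        if vol < min_volume_mm3:
            reject[comp] = False
            continue
        sub_stat = np.where(comp, np.abs(stat_map.stat), -np.inf)
        peak = np.unravel_index(np.argmax(sub_stat), comp.shape)
        world = stat_map.grid.voxel_to_world(np.asarray(peak))
        rows.append([lab, n_vox, vol, *map(int, peak), *world,
                     float(stat_map.stat[peak]), float(stat_map.p[peak])])
    report = pd.DataFrame(rows, columns=columns)
    if len(report):
        report = report.sort_values("n_voxels", ascending=False).reset_index(drop=True)
    stat_map.reject = reject
    return stat_map, report


def place_spherical_rois(report: pd.DataFrame, radius_mm: float, grid: Grid,
                         mask: np.ndarray | None = None) -> dict:
    """Spheres at each cluster peak plus the left-right mirrored twin.

    The mirror reflects the peak across the grid's midsagittal plane (the
    mid-plane of the first axis).  Spheres are clipped to the analysis mask
    when one is given; a midline peak yields a single deduplicated ROI.
    Returns ``{roi_name: boolean mask}``.
    """
    if radius_mm <= 0:
        raise ValueError("radius_mm must be positive")
    if report is None or len(report) == 0:
        raise ValueError("cluster report is empty; no ROIs to place")
    centers_mm = grid.voxel_centers_mm()
    rois = {}
    for _, row in report.iterrows():
        peak = np.array([row.peak_i, row.peak_j, row.peak_k], float)
        mirror = peak.copy()
        mirror[0] = grid.shape[0] - 1 - peak[0]
        placed = [("", peak)] if np.allclose(mirror, peak) else [("", peak), ("_mirror", mirror)]
        for suffix, ctr in placed:
            world = grid.voxel_to_world(ctr)
            ball = np.linalg.norm(centers_mm - world, axis=-1) <= radius_mm
            if mask is not None:
                ball &= mask
            rois[f"cluster{int(row.label)}{suffix}"] = ball
    return rois
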