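"""Tract-of-interest analysis: deterministic tractography and TFAS.

Streamlines are integrated on the averaged control tensor field with a
fixed-step Euler scheme along the trilinearly interpolated principal
eigenvector, bidirectionally from every seed, with the conventional
termination criteria (local FA below a floor, turning angle above a cap,
leaving the grid).  A seed-to-target filter retains the streamlines that
touch both masks; the union of traversed voxels defines the tract of
interest (TOI).  Tract-wise FA statistics (TFAS) then average each
subject's FA over the TOI voxels, and group tables compare those means with
Welch tests, BH correction across tracts, and pooled-SD z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from dtiabv._stats import bh_adjust, pooled_z, welch_p
from dtiabv.grids import Grid
from dtiabv.tensors import TensorField

log = logging.getLogger(__name__)

_SIX = ([0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2])


@dataclass(frozen=True)
class Streamline:
    """Ordered 3-D world-coordinate points (mm) with a fixed step length."""

    points_mm: np.ndarray
    step_mm: float

    def __len__(self):
        return len(self.points_mm)

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1).sum())


@dataclass(frozen=True)
class SeedTargetSpec:
    """Named seed/target mask pair defining one TOI."""

    toi_name: str
    seed_mask: np.ndarray
    target_mask: np.ndarray
    allow_overlap: bool = False

    def __post_init__(self):
        if not self.seed_mask.any() or not self.target_mask.any():
            raise ValueError(f"TOI {self.toi_name!r}: seed and target masks must be non-empty")
        if not self.allow_overlap and (self.seed_mask & self.target_mask).any():
            raise ValueError(f"TOI {self.toi_name!r}: seed and target masks overlap")


@dataclass
class TractOfInterest:
    """Retained streamlines plus the voxel set they traverse."""

    toi_name: str
    streamlines: list = field(default_factory=list)
    voxel_mask: np.ndarray | None = None

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)


class _FieldSampler:
    """Trilinear sampling of tensors and FA at world points."""

    def __init__(self, tensors: TensorField, grid: Grid):
        from dtiabv.tensors import scalar_maps

        self.grid = grid
        self.comp = [np.ascontiguousarray(tensors.data[..., i, j])
                     for i, j in zip(*_SIX)]
        fa, _ = scalar_maps(tensors)
        self.fa = fa

    def tensors_at(self, points_mm: np.ndarray) -> np.ndarray:
        vox = (points_mm / np.asarray(self.grid.voxel_size)).T
        vals = [map_coordinates(c, vox, order=1, mode="constant", cval=0.0)
                for c in self.comp]
        d = np.zeros((points_mm.shape[0], 3, 3))
        for v, (i, j) in zip(vals, zip(*_SIX)):
            d[:, i, j] = v
            d[:, j, i] = v
        return d

    def fa_at(self, points_mm: np.ndarray) -> np.ndarray:
        vox = (points_mm / np.asarray(self.grid.voxel_size)).T
        return map_coordinates(self.fa, vox, order=1, mode="constant", cval=0.0)

    def principal_at(self, points_mm: np.ndarray) -> np.ndarray:
        d = self.tensors_at(points_mm)
        _, vecs = np.linalg.eigh(d)
        return vecs[:, :, 2]


def _integrate(sampler: _FieldSampler, starts: np.ndarray, dirs: np.ndarray,
               fa_stop: float, cos_stop: float, step_mm: float, max_steps: int):
    """March all seeds in lockstep; returns a list of point arrays."""
    n = starts.shape[0]
    pos = starts.copy()
    prev = dirs.copy()
    paths = [[p.copy()] for p in pos]
    active = np.ones(n, bool)
    upper = (np.asarray(sampler.grid.shape) - 1) * np.asarray(sampler.grid.voxel_size)
    for _ in range(max_steps):
        if not active.any():
            break
        idx = np.where(active)[0]
        v = sampler.principal_at(pos[idx])
        flip = (v * prev[idx]).sum(axis=1) < 0
        v[flip] *= -1.0
        cos = (v * prev[idx]).sum(axis=1)
        new_pos = pos[idx] + step_mm * v
        inside = np.all((new_pos >= 0) & (new_pos <= upper), axis=1)
        fa_ok = np.zeros(idx.size, bool)
        fa_ok[inside] = sampler.fa_at(new_pos[inside]) >= fa_stop
        ok = inside & fa_ok & (cos >= cos_stop)
        for j, i in enumerate(idx):
            if ok[j]:
                paths[i].append(new_pos[j].copy())
        pos[idx[ok]] = new_pos[ok]
        prev[idx[ok]] = v[ok]
        active[idx[~ok]] = False
    return [np.asarray(p) for p in paths]


def track_streamlines(tensors: TensorField, seeds, grid: Grid | None = None,
                      fa_stop: float = 0.2, angle_stop_deg: float = 40.0,
                      step_mm: float | None = None,
                      max_steps: int | None = None) -> list[Streamline]:
    """Deterministic bidirectional Euler tractography from seed voxels.

    ``seeds`` is a boolean voxel mask (seeds at voxel centers) or an
    (n, 3) array of world points.  Seeds whose local FA is below ``fa_stop``
    are dropped (a warning is logged if none remain).  The two half-tracks
    share the seed point; the backward half is integrated along the negated
    principal axis and reversed, so each streamline's points are in
    consecutive order with a fixed step.
    """
    if not 0 < fa_stop < 1:
        raise ValueError("fa_stop must be in (0, 1)")
    grid = grid or tensors.grid
    if grid is None:
        raise ValueError("a Grid is required (on the TensorField or as argument)")
    if step_mm is None:
        step_mm = 0.5 * min(grid.voxel_size)
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    if max_steps is None:
        max_steps = int(2 * np.linalg.norm(np.asarray(grid.shape)
                                           * np.asarray(grid.voxel_size)) / step_mm)
    sampler = _FieldSampler(tensors, grid)
    if isinstance(seeds, np.ndarray) and seeds.dtype == bool:
        pts = grid.voxel_to_world(np.argwhere(seeds))
    else:
        pts = np.asarray(seeds, float).reshape(-1, 3)
    keep = sampler.fa_at(pts) >= fa_stop
    pts = pts[keep]
    if pts.size == 0:
        log.warning("track_streamlines: no seed points at or above fa_stop=%.2f", fa_stop)
        return []
    v0 = sampler.principal_at(pts)
    fwd = _integrate(sampler, pts, v0, fa_stop, np.cos(np.radians(angle_stop_deg)),
                     step_mm, max_steps)
    bwd = _integrate(sampler, pts, -v0, fa_stop, np.cos(np.radians(angle_stop_deg)),
                     step_mm, max_steps)
    streams = []
    for f, b in zip(fwd, bwd):
        pts_all = np.vstack([b[::-1], f[1:]]) if len(b) > 1 else f
        if len(pts_all) >= 2:
            streams.append(Streamline(pts_all, step_mm))
    return streams


def _stream_voxels(stream: Streamline, grid: Grid) -> np.ndarray:
    idx = np.rint(stream.points_mm / np.asarray(grid.voxel_size)).astype(int)
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1)
    return np.unique(idx, axis=0)


def seed_to_target_filter(streams: list[Streamline], spec: SeedTargetSpec,
                          grid: Grid) -> TractOfInterest:
    """Retain streamlines touching both the seed and the target mask.

    The criterion is symmetric in seed and target.  An empty retention is a
    legitimate negative result (warning, not an error).  The TOI voxel mask
    is the union of voxels traversed by retained streamlines.
    """
    if not streams:
        raise ValueError("no streamlines to filter")
    retained = []
    voxel_mask = np.zeros(grid.shape, bool)
    for s in streams:
        vox = _stream_voxels(s, grid)
        hits_seed = spec.seed_mask[vox[:, 0], vox[:, 1], vox[:, 2]].any()
        hits_target = spec.target_mask[vox[:, 0], vox[:, 1], vox[:, 2]].any()
        if hits_seed and hits_target:
            retained.append(s)
            voxel_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    if not retained:
        log.warning("TOI %r: no streamline connects seed and target", spec.toi_name)
    return TractOfInterest(spec.toi_name, retained, voxel_mask)


def tfas(toi: TractOfInterest | np.ndarray, scalar_map: np.ndarray,
         fa_floor: float = 0.2, floor_map: np.ndarray | None = None):
    """Arithmetic mean of a subject's map over the TOI voxel set.

    Only voxels where the subject's FA exceeds ``fa_floor`` contribute (for
    MD averaging pass the subject's FA as ``floor_map``).  Returns
    ``(mean, n_contributing)``; an empty contribution yields ``(nan, 0)``.
    """
    mask = toi.voxel_mask if isinstance(toi, TractOfInterest) else toi
    if mask is None or not mask.any():
        raise ValueError("TOI voxel set is empty")
    gate = scalar_map if floor_map is None else floor_map
    contrib = mask & (gate > fa_floor)
    n = int(contrib.sum())
    if n == 0:
        log.warning("tfas: no voxels above the FA floor; value undefined")
        return float("nan"), 0
    return float(scalar_map[contrib].mean()), n


def tfas_table(tois: dict, maps: np.ndarray, subjects, fa_floor: float = 0.2,
               floor_maps: np.ndarray | None = None) -> pd.DataFrame:
    """Per-subject x per-TOI mean values (rows=subjects, columns=TOI names)."""
    out = {}
    for name, toi in tois.items():
        vals = []
        for i in range(maps.shape[0]):
            gate = None if floor_maps is None else floor_maps[i]
            v, _ = tfas(toi, maps[i], fa_floor=fa_floor, floor_map=gate)
            vals.append(v)
        out[name] = vals
    return pd.DataFrame(out, index=pd.Index(subjects, name="subject"))


def toi_group_stats(values: pd.DataFrame, cohort: pd.DataFrame,
                    group_pairs=(("bvFTD", "control"), ("ALS-FTD", "control"),
                                 ("ALS-FTD", "bvFTD")),
                    q: float = 0.05) -> pd.DataFrame:
    """Group comparison of per-subject tract means.

    For every (patient, reference) pair and every TOI: group means and SDs,
    a two-sided Welch p (BH-corrected across TOIs within the pair), and the
    pooled-SD z-score ``(mean_1 - mean_2) / s_pooled`` with the
    Bessel-weighted pooled SD.  Subjects with a missing value are dropped
    per-TOI (logged).
    """
    cohort = cohort.set_index("subject") if "subject" in cohort.columns else cohort
    rows = []
    for g1, g2 in group_pairs:
        ids1 = cohort.index[(cohort.group == g1) & (cohort.timepoint == "baseline")]
        ids2 = cohort.index[(cohort.group == g2) & (cohort.timepoint == "baseline")]
        for toi_name in values.columns:
            v1 = values.loc[values.index.intersection(ids1), toi_name].dropna()
            v2 = values.loc[values.index.intersection(ids2), toi_name].dropna()
            n_drop = (len(ids1) - len(v1)) + (len(ids2) - len(v2))
            if n_drop:
                log.info("toi_group_stats: %s %s-vs-%s dropped %d subjects",
                         toi_name, g1, g2, n_drop)
            if len(v1) < 2 or len(v2) < 2:
                raise ValueError(f"pair {g1} vs {g2}: needs >= 2 subjects per group")
            rows.append(dict(
                toi=toi_name, group1=g1, group2=g2,
                mean1=v1.mean(), sd1=v1.std(ddof=1), n1=len(v1),
                mean2=v2.mean(), sd2=v2.std(ddof=1), n2=len(v2),
                z=pooled_z(v1.mean(), v1.std(ddof=1), len(v1),
                           v2.mean(), v2.std(ddof=1), len(v2)),
                p=welch_p(v1.to_numpy(), v2.to_numpy()),
            ))
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for (g1, g2), sub in table.groupby(["group1", "group2"]):
        _, p_adj = bh_adjust(sub.p.to_numpy(), q=q)
        table.loc[sub.index, "q"] = p_adj
    return table
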