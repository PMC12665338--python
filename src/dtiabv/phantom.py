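"""Synthetic DTI + volumetry phantom cohorts.

The generator produces everything the downstream analysis consumes — 4-D
diffusion-weighted volumes with a gradient table, tissue-compartment
probability maps, an integer atlas, and a cohort table — with a controlled
statistical structure:

* named white-matter tracts carrying anisotropic tensors aligned with the
  tract centerline, embedded in an isotropic brain;
* group-wise FA reductions injected per tract by shrinking the axial
  eigenvalue toward the mean diffusivity (MD is preserved, so FA and MD
  effects stay dissociable);
* group-wise volume loss injected per gray-matter structure by morphological
  erosion with a fractional boundary shell, so any target percentage is
  realizable on a coarse grid;
* an additive inter-site FA offset, a linear FA-vs-age slope, per-patient
  severity coupling to the clinical score, and an extended effect at the
  longitudinal follow-up timepoint;
* Rician magnitude noise on the simulated signal.

All randomness derives from one master seed; every subject/timepoint row
draws from its own `numpy` seed sequence ``[master_seed, row_index, stream]``
so regeneration is bit-identical and order-independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dtiabv.grids import Grid

GROUPS = ("control", "bvFTD", "ALS-FTD")

# ---------------------------------------------------------------------------
# gradient tables


@dataclass(frozen=True)
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bvals", np.asarray(self.bvals, float))
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, float))
        if self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError("bvecs must have shape (n, 3) matching bvals")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted bvecs must be unit vectors")
        if not (~dw).any():
            raise ValueError("gradient table needs at least one b=0 entry")
        if dw.sum() < 6:
            raise ValueError("tensor fitting needs >= 6 diffusion directions")

    @property
    def n_directions(self) -> int:
        return int((self.bvals > 0).sum())

    def save(self, bval_path, bvec_path) -> None:
        """Write FSL-style plain-text bval/bvec files (3 rows of x, y, z)."""
        np.savetxt(str(bval_path), self.bvals[None, :], fmt="%g")
        np.savetxt(str(bvec_path), self.bvecs.T, fmt="%.8f")

    @classmethod
    def load(cls, bval_path, bvec_path) -> "GradientTable":
        bvals = np.loadtxt(str(bval_path)).ravel()
        bvecs = np.loadtxt(str(bvec_path))
        if bvecs.shape[0] == 3:
            bvecs = bvecs.T
        return cls(bvals, bvecs)


def default_gradient_table(n_directions: int = 31, b: float = 1000.0) -> GradientTable:
    """One b=0 volume plus ``n_directions`` roughly uniform directions.

    Directions follow a Fibonacci spiral on the half-sphere, the standard
    construction for well-spread single-shell schemes.
    """
    i = np.arange(n_directions)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n_directions  # upper half-sphere suffices for DTI
    r = np.sqrt(1 - z**2)
    phi = 2 * np.pi * i / golden
    vecs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([[0.0], np.full(n_directions, float(b))])
    bvecs = np.vstack([[0.0, 0.0, 0.0], vecs])
    return GradientTable(bvals, bvecs)


# ---------------------------------------------------------------------------
# phantom geometry


@dataclass(frozen=True)
class TractGeometry:
    """A named tract: polyline centerline (world mm) and a tube radius."""

    name: str
    centerline_mm: np.ndarray  # (n_points, 3)
    radius_mm: float

    def __post_init__(self):
        object.__setattr__(self, "centerline_mm", np.asarray(self.centerline_mm, float))
        if self.centerline_mm.ndim != 2 or self.centerline_mm.shape[1] != 3:
            raise ValueError("centerline_mm must be (n, 3)")
        if self.centerline_mm.shape[0] < 2:
            raise ValueError("centerline needs at least 2 points")
        if self.radius_mm <= 0:
            raise ValueError("tract radius must be positive")


@dataclass(frozen=True)
class StructureGeometry:
    """A named gray-matter structure: ellipsoid with an atlas label id."""

    name: str
    label: int
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]


def straight_tract(name, start_mm, end_mm, radius_mm) -> TractGeometry:
    pts = np.linspace(np.asarray(start_mm, float), np.asarray(end_mm, float), 32)
    return TractGeometry(name, pts, radius_mm)


def arc_tract(name, center_mm, arc_radius_mm, radius_mm, angle_start=0.0,
              angle_end=90.0, plane="xy", n_points=64) -> TractGeometry:
    """Circular-arc centerline in an axis-aligned plane (angles in degrees)."""
    th = np.radians(np.linspace(angle_start, angle_end, n_points))
    u = np.cos(th) * arc_radius_mm
    v = np.sin(th) * arc_radius_mm
    axes = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    pts = np.tile(np.asarray(center_mm, float), (n_points, 1))
    pts[:, axes[0]] += u
    pts[:, axes[1]] += v
    return TractGeometry(name, pts, radius_mm)


@dataclass(frozen=True)
class PhantomSpec:
    """Full anatomical description of a phantom brain."""

    grid: Grid = Grid((48, 48, 48), (2.0, 2.0, 2.0))
    tracts: tuple[TractGeometry, ...] = ()
    structures: tuple[StructureGeometry, ...] = ()
    tract_eigenvalues: tuple[float, float, float] = (1.7e-3, 0.3e-3, 0.3e-3)
    background_diffusivity: float = (1.7e-3 + 0.3e-3 + 0.3e-3) / 3.0
    brain_center_mm: tuple[float, float, float] | None = None
    brain_semi_axes_mm: tuple[float, float, float] = (42.0, 40.0, 40.0)
    s0: float = 1000.0

    def __post_init__(self):
        ev = np.asarray(self.tract_eigenvalues, float)
        if np.any(ev <= 0) or np.any(np.diff(ev) > 0):
            raise ValueError("eigenvalues must be positive and sorted descending")
        names = [t.name for t in self.tracts]
        if len(set(names)) != len(names):
            raise ValueError("tract names must be unique")
        if self.background_diffusivity <= 0:
            raise ValueError("background diffusivity must be positive")

    @property
    def tract_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.tracts)

    @property
    def structure_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.structures)

    @property
    def brain_center(self) -> np.ndarray:
        if self.brain_center_mm is not None:
            return np.asarray(self.brain_center_mm, float)
        return (np.asarray(self.grid.shape) - 1) * np.asarray(self.grid.voxel_size) / 2.0


@dataclass(frozen=True)
class EffectSpec:
    """Generative group / site / age / longitudinal effects.

    ``fa_reduction[tract][group]`` and ``volume_atrophy[structure][group]``
    are fractional reductions in [0, 1).  ``site_fa_offset`` is an additive
    FA shift per acquisition site.  ``age_fa_slope`` is FA units per year,
    applied relative to ``reference_age``.  ``severity_coupling`` scales a
    patient's injected effect by its clinical score relative to the group
    mean (0 = uniform effects, 1 = fully score-driven).

    Between-subject biological variability: ``fa_scale_sd`` is the SD of a
    per-subject multiplicative FA scale (persistent across timepoints) and
    ``volume_scale_sd`` the SD of an independent per-structure volume
    jitter (segmentation-style noise).  Both default to 0 so noiseless
    generation realizes every injected effect exactly.
    """

    fa_reduction: dict = field(default_factory=dict)
    volume_atrophy: dict = field(default_factory=dict)
    site_fa_offset: dict = field(default_factory=dict)
    age_fa_slope: float = 0.0
    longitudinal_extension: dict = field(default_factory=dict)
    volume_atrophy_followup: dict = field(default_factory=dict)
    noise_sigma: float = 0.0
    severity_coupling: float = 0.0
    reference_age: float = 60.0
    fa_scale_sd: float = 0.0
    volume_scale_sd: float = 0.0

    def __post_init__(self):
        for d in (self.fa_reduction, self.longitudinal_extension):
            for vals in d.values():
                for v in vals.values() if isinstance(vals, dict) else [vals]:
                    if not 0 <= v < 1:
                        raise ValueError("fractional reductions must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def validate_names(self, spec: PhantomSpec) -> None:
        unknown = [n for n in itertools.chain(self.fa_reduction, self.longitudinal_extension)
                   if n not in spec.tract_names]
        unknown += [n for n in itertools.chain(self.volume_atrophy, self.volume_atrophy_followup)
                    if n not in spec.structure_names]
        if unknown:
            raise ValueError(f"effect names not in phantom spec: {sorted(set(unknown))}")


# ---------------------------------------------------------------------------
# tensor construction helpers


def fa_of_eigenvalues(ev: np.ndarray) -> np.ndarray:
    ev = np.asarray(ev, float)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt((( ev - md) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    return np.where(den > 0, fa, 0.0)


def _fa_to_delta(fa):
    """Axial asymmetry of an axially symmetric tensor with the given FA.

    With eigenvalues ``md*(1+2d), md*(1-d), md*(1-d)`` one has
    ``FA = sqrt(3)*d / sqrt(1+2d^2)``, hence ``d = FA / sqrt(3-2FA^2)``;
    any FA in [0, 1) maps to d in [0, 1) and positive eigenvalues.
    """
    fa = np.asarray(fa, float)
    return fa / np.sqrt(3.0 - 2.0 * fa**2)


def tensors_from_fa_md(fa, md, directions) -> np.ndarray:
    """Axially symmetric tensors (..., 3, 3) with the given FA, MD and axis."""
    fa = np.asarray(fa, float)
    md = np.broadcast_to(np.asarray(md, float), fa.shape)
    n = np.asarray(directions, float)
    n = n / np.maximum(np.linalg.norm(n, axis=-1, keepdims=True), 1e-30)
    d = _fa_to_delta(np.clip(fa, 0.0, 0.999))
    lam_perp = md * (1.0 - d)
    lam_axial = md * (1.0 + 2.0 * d)
    eye = np.eye(3)
    outer = n[..., :, None] * n[..., None, :]
    return lam_perp[..., None, None] * eye + (lam_axial - lam_perp)[..., None, None] * outer


# ---------------------------------------------------------------------------
# anatomy voxelization


def _point_segment_distance(points, a, b):
    """Distance from each point to segment ab, plus the segment tangent."""
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip((points - a) @ ab / max(denom, 1e-30), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _voxelize_tract(grid: Grid, tract: TractGeometry):
    """Boolean mask + per-voxel unit tangent for a tube around a polyline."""
    centers = grid.voxel_centers_mm().reshape(-1, 3)
    pts = tract.centerline_mm
    lo = pts.min(axis=0) - tract.radius_mm - 1.0
    hi = pts.max(axis=0) + tract.radius_mm + 1.0
    box = np.all((centers >= lo) & (centers <= hi), axis=1)
    cand = np.where(box)[0]
    if cand.size == 0:
        return np.zeros(grid.shape, bool), np.zeros(grid.shape + (3,))
    sub = centers[cand]
    best = np.full(cand.size, np.inf)
    best_seg = np.zeros(cand.size, int)
    for s in range(len(pts) - 1):
        dist = _point_segment_distance(sub, pts[s], pts[s + 1])
        closer = dist < best
        best[closer] = dist[closer]
        best_seg[closer] = s
    inside = best <= tract.radius_mm
    mask = np.zeros(grid.shape, bool)
    tangents = np.zeros(grid.shape + (3,))
    idx = cand[inside]
    mask.reshape(-1)[idx] = True
    seg_dirs = np.diff(pts, axis=0)
    seg_dirs /= np.linalg.norm(seg_dirs, axis=1, keepdims=True)
    tangents.reshape(-1, 3)[idx] = seg_dirs[best_seg[inside]]
    return mask, tangents


def _ellipsoid_mask(grid: Grid, center_mm, semi_axes_mm) -> np.ndarray:
    centers = grid.voxel_centers_mm()
    rel = (centers - np.asarray(center_mm)) / np.asarray(semi_axes_mm)
    return (rel**2).sum(axis=-1) <= 1.0


@dataclass
class PhantomAnatomy:
    """Static (effect-free) anatomy shared by every subject of a cohort."""

    spec: PhantomSpec
    brain_mask: np.ndarray
    tract_masks: dict
    tangents: np.ndarray            # (X, Y, Z, 3) unit vectors on tract voxels
    base_fa: np.ndarray             # control FA before any injected effect
    md: np.ndarray                  # mean diffusivity (uniform inside brain)
    atlas: np.ndarray               # int labels, 0 = unlabeled
    structure_masks: dict           # name -> boolean mask
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    @property
    def grid(self) -> Grid:
        return self.spec.grid

    def tensor_field(self):
        """Control-subject tensors (no effects, no noise)."""
        from dtiabv.tensors import TensorField

        dirs = np.where(self.tangents.any(axis=-1, keepdims=True), self.tangents,
                        np.array([1.0, 0.0, 0.0]))
        d = tensors_from_fa_md(self.base_fa, self.md, dirs)
        d[~self.brain_mask] = 0.0
        return TensorField(d, self.grid, mask=self.brain_mask.copy())


def build_tensor_phantom(spec: PhantomSpec, blend: str | None = None,
                         conflict_angle_deg: float = 30.0) -> PhantomAnatomy:
    """Voxelize a phantom spec into tensors, atlas labels and tissue maps.

    Overlapping tracts whose local orientations disagree by more than
    ``conflict_angle_deg`` are rejected unless ``blend='first'`` keeps the
    orientation of the earlier-listed tract.
    """
    grid = spec.grid
    brain = _ellipsoid_mask(grid, spec.brain_center, spec.brain_semi_axes_mm)

    tract_masks = {}
    tangents = np.zeros(grid.shape + (3,))
    claimed = np.zeros(grid.shape, bool)
    for tract in spec.tracts:
        mask, tang = _voxelize_tract(grid, tract)
        mask &= brain
        overlap = mask & claimed
        if overlap.any():
            cosang = np.abs((tangents[overlap] * tang[overlap]).sum(axis=-1))
            if (cosang < np.cos(np.radians(conflict_angle_deg))).any() and blend != "first":
                raise ValueError(
                    f"tract '{tract.name}' overlaps an earlier tract with a "
                    "conflicting orientation; pass blend='first' to keep the "
                    "first tract's orientation"
                )
        new = mask & ~claimed
        tangents[new] = tang[new]
        claimed |= mask
        tract_masks[tract.name] = mask

    tract_fa = fa_of_eigenvalues(np.asarray(spec.tract_eigenvalues))
    base_fa = np.where(claimed, float(tract_fa), 0.0)
    base_fa[~brain] = 0.0
    md = np.where(claimed, float(np.mean(spec.tract_eigenvalues)),
                  spec.background_diffusivity)
    md[~brain] = 0.0

    atlas = np.zeros(grid.shape, np.int32)
    structure_masks = {}
    for s in spec.structures:
        smask = _ellipsoid_mask(grid, s.center_mm, s.semi_axes_mm) & brain
        structure_masks[s.name] = smask
        atlas[smask] = s.label

    any_structure = np.zeros(grid.shape, bool)
    for m in structure_masks.values():
        any_structure |= m
    gm = np.zeros(grid.shape)
    wm = np.zeros(grid.shape)
    csf = np.zeros(grid.shape)
    plain = brain & ~claimed & ~any_structure
    gm[plain], wm[plain], csf[plain] = 0.45, 0.35, 0.15
    gm[any_structure & ~claimed] = 0.85
    wm[any_structure & ~claimed] = 0.05
    csf[any_structure & ~claimed] = 0.05
    wm[claimed] = 0.85
    gm[claimed] = 0.05
    csf[claimed] = 0.05

    return PhantomAnatomy(spec, brain, tract_masks, tangents, base_fa, md,
                          atlas, structure_masks, gm, wm, csf)


# ---------------------------------------------------------------------------
# signal simulation


_QUAD_IDX = ([0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2])
_QUAD_W = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


def _tensor6(d):
    """Pack (..., 3, 3) symmetric tensors to (..., 6): xx yy zz xy xz yz."""
    return np.stack([d[..., i, j] for i, j in zip(*_QUAD_IDX)], axis=-1)


def simulate_dwi(tensors, gradients: GradientTable, s0: float = 1000.0,
                 noise_sigma: float = 0.0, rng=None, mask=None) -> np.ndarray:
    """Single-tensor DWI signal ``S = S0 * exp(-b g^T D g)`` with Rician noise.

    ``tensors`` may be a TensorField or a plain (..., 3, 3) array; the result
    has one trailing measurement axis.  ``noise_sigma`` is relative to the
    b=0 signal; noise is applied as magnitude of two independent Gaussian
    channels.  With ``mask`` given, out-of-mask voxels get zero signal.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    d = getattr(tensors, "data", tensors)
    d6 = _tensor6(np.asarray(d))
    coeff = (gradients.bvecs[:, _QUAD_IDX[0]] * gradients.bvecs[:, _QUAD_IDX[1]]
             * _QUAD_W) * gradients.bvals[:, None]       # (n_meas, 6)
    expo = d6 @ coeff.T.astype(d6.dtype)                 # (..., n_meas)
    signal = s0 * np.exp(-expo)
    if mask is not None:
        signal[~mask] = 0.0
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        sig = noise_sigma * s0
        re = signal + sig * rng.standard_normal(signal.shape)
        im = sig * rng.standard_normal(signal.shape)
        signal = np.sqrt(re**2 + im**2)
    return signal


# ---------------------------------------------------------------------------
# atrophy injection


def erosion_weights(mask: np.ndarray, fraction: float,
                    density: np.ndarray | None = None) -> np.ndarray:
    """Fractional erosion of a mask removing ``fraction`` of its volume.

    Voxels are ranked by depth (Euclidean distance to the mask boundary)
    and removed shallowest-first; the voxel at the cut gets a fractional
    weight, so the retained volume hits the target exactly.  With a
    ``density`` map (e.g. a tissue probability image) the cut is placed on
    cumulative density mass rather than voxel count, so the target fraction
    applies to the integrated volume even when the compartment is
    inhomogeneous inside the mask.  Ties break by flat voxel index.
    """
    from scipy.ndimage import distance_transform_edt

    if not 0 <= fraction < 1:
        raise ValueError("atrophy fraction must be in [0, 1)")
    w = mask.astype(float)
    if fraction == 0 or not mask.any():
        return w
    depth = distance_transform_edt(mask)
    flat = np.where(mask.reshape(-1))[0]
    order = np.lexsort((flat, depth.reshape(-1)[flat]))  # shallow first
    weight = (np.ones(flat.size) if density is None
              else np.maximum(density.reshape(-1)[flat[order]], 1e-12))
    if density is not None:
        cum = np.cumsum(weight)
        target = fraction * cum[-1]
        k = int(np.searchsorted(cum, target))
    else:
        cum = np.arange(1.0, flat.size + 1)
        target = fraction * flat.size
        k = int(np.floor(target))
    wf = w.reshape(-1)
    wf[flat[order[:k]]] = 0.0
    if k < flat.size:
        already = cum[k - 1] if k > 0 else 0.0
        wf[flat[order[k]]] = 1.0 - (target - already) / weight[k]
    return w


# ---------------------------------------------------------------------------
# defaults emulating the study conditions


def default_phantom(grid_shape=(48, 48, 48), voxel_size=(2.0, 2.0, 2.0)) -> PhantomSpec:
    """Demo anatomy: five named tracts and six gray-matter structures.

    Geometry is schematic (the grid center plays the role of the anterior
    commissure); names mirror the anatomy whose group effects the cohort
    generator injects.  All sizes are in millimetres.
    """
    grid = Grid(tuple(grid_shape), tuple(voxel_size))
    cx, cy, cz = (np.asarray(grid_shape) - 1) * np.asarray(voxel_size) / 2.0
    r = 8.0  # tube radius; tract axes are laid out > 2r apart
    tracts = (
        # frontal-temporal hook, curved in the x-z plane, anterior left
        arc_tract("uncinate_L", (cx - 19, cy + 25, cz - 17), 9.0, r,
                  angle_start=20.0, angle_end=170.0, plane="xz"),
        # anterior callosal arc crossing the midline
        arc_tract("genu_cc", (cx, cy + 9, cz + 5), 12.0, r,
                  angle_start=-20.0, angle_end=200.0, plane="xy"),
        # long anterior-posterior association tracts, left hemisphere
        straight_tract("superior_longitudinal_L",
                       (cx - 23, cy - 28, cz + 17), (cx - 23, cy + 28, cz + 17), r),
        straight_tract("inferior_longitudinal_L",
                       (cx - 23, cy - 28, cz - 19), (cx - 23, cy + 5, cz - 19), r),
        # superior-inferior projection tract, right hemisphere
        straight_tract("corticospinal_R",
                       (cx + 19, cy - 11, cz - 30), (cx + 19, cy - 11, cz + 30), r),
    )
    structures = (
        StructureGeometry("frontal_lobe_L", 1, (cx - 17, cy + 29, cz + 5), (10, 9, 10)),
        StructureGeometry("frontal_lobe_R", 2, (cx + 17, cy + 29, cz + 5), (10, 9, 10)),
        StructureGeometry("temporal_lobe_L", 3, (cx - 29, cy, cz - 17), (9, 12, 8)),
        StructureGeometry("caudate_L", 4, (cx - 8, cy + 9, cz), (5, 7, 6)),
        StructureGeometry("caudate_R", 5, (cx + 8, cy + 9, cz), (5, 7, 6)),
        StructureGeometry("amygdala_L", 6, (cx - 21, cy + 15, cz - 25), (5, 5, 5)),
    )
    return PhantomSpec(grid=grid, tracts=tracts, structures=structures)


def default_effects(noise_sigma: float = 0.02) -> EffectSpec:
    """Group effects of a magnitude comparable to the reported cohort.

    FA reductions of 6%–14% over the affected tracts and structure volume
    losses of 10%–27% produce pooled-SD z-scores in the -1 to -3 range at the
    default noise level, the regime the cross-sectional tables report; the
    ALS-FTD pattern adds the projection (corticospinal) tract.  The
    follow-up timepoint extends effects posteriorly.
    """
    return EffectSpec(
        fa_reduction={
            "uncinate_L": {"bvFTD": 0.12, "ALS-FTD": 0.14},
            "genu_cc": {"bvFTD": 0.10, "ALS-FTD": 0.12},
            "superior_longitudinal_L": {"bvFTD": 0.06, "ALS-FTD": 0.07},
            "inferior_longitudinal_L": {"bvFTD": 0.08, "ALS-FTD": 0.09},
            "corticospinal_R": {"ALS-FTD": 0.10},
        },
        volume_atrophy={
            "frontal_lobe_L": {"bvFTD": 0.13, "ALS-FTD": 0.20},
            "frontal_lobe_R": {"bvFTD": 0.13, "ALS-FTD": 0.20},
            "temporal_lobe_L": {"bvFTD": 0.10, "ALS-FTD": 0.14},
            "caudate_L": {"bvFTD": 0.26, "ALS-FTD": 0.35},
            "caudate_R": {"bvFTD": 0.27, "ALS-FTD": 0.36},
            "amygdala_L": {"bvFTD": 0.12, "ALS-FTD": 0.24},
        },
        site_fa_offset={"A": 0.0, "B": 0.02},
        age_fa_slope=-0.001,
        fa_scale_sd=0.04,
        volume_scale_sd=0.03,
        longitudinal_extension={
            "genu_cc": 0.05,
            "inferior_longitudinal_L": 0.05,
            "superior_longitudinal_L": 0.03,
        },
        volume_atrophy_followup={
            "temporal_lobe_L": 0.03,
            "caudate_L": 0.06,
            "caudate_R": 0.06,
            "amygdala_L": 0.05,
        },
        noise_sigma=noise_sigma,
        severity_coupling=0.5,
        reference_age=60.0,
    )


_AGE_PARAMS = {"control": (58.0, 11.6), "bvFTD": (64.0, 10.0), "ALS-FTD": (64.0, 9.7)}
_CDR_PARAMS = {"bvFTD": (5.1, 3.6), "ALS-FTD": (6.3, 5.8)}


# ---------------------------------------------------------------------------
# cohort generation


class Cohort:
    """A generated phantom cohort.

    Holds the shared anatomy, the cohort table (one row per subject and
    timepoint) and lazily generates per-row DWI signals and compartment maps.
    Noiseless signals and erosion weights are cached across rows that share
    identical effect parameters, which makes large null simulations cheap
    without affecting determinism (noise is drawn from per-row streams).
    """

    def __init__(self, spec: PhantomSpec, effects: EffectSpec, table: pd.DataFrame,
                 anatomy: PhantomAnatomy, gradients: GradientTable, seed: int):
        self.spec = spec
        self.effects = effects
        self.table = table
        self.anatomy = anatomy
        self.gradients = gradients
        self.seed = int(seed)
        self._signal_cache: dict = {}
        self._erosion_cache: dict = {}

    # -- per-row effect realization ------------------------------------

    def _severity(self, row) -> float:
        c = self.effects.severity_coupling
        if c == 0 or row.group == "control" or not np.isfinite(row.cdr_sob):
            return 1.0
        ref = _CDR_PARAMS.get(row.group, (5.0, 1.0))[0]
        return float(np.clip(1.0 - c + c * row.cdr_sob / ref, 0.2, 2.0))

    def target_fa(self, row) -> np.ndarray:
        """The row's noiseless FA map on the full grid, after all effects."""
        fa = self.anatomy.base_fa * float(getattr(row, "fa_scale", 1.0))
        sev = self._severity(row)
        for name, per_group in self.effects.fa_reduction.items():
            red = per_group.get(row.group, 0.0) * sev
            if row.timepoint == "followup":
                red += self.effects.longitudinal_extension.get(name, 0.0) * sev
            if red > 0:
                m = self.anatomy.tract_masks[name]
                fa[m] *= max(0.0, 1.0 - red)
        off = self.effects.site_fa_offset.get(row.site, 0.0)
        off += self.effects.age_fa_slope * (row.age - self.effects.reference_age)
        if off != 0.0:
            brain = self.anatomy.brain_mask
            fa[brain] = fa[brain] + off
        np.clip(fa, 0.0, 0.95, out=fa)
        fa[~self.anatomy.brain_mask] = 0.0
        return fa

    def _noiseless_signal(self, row) -> np.ndarray:
        """Masked (n_brain_voxels, n_meas) float32 noiseless signal, cached."""
        fa = self.target_fa(row)
        brain = self.anatomy.brain_mask
        key = hash(fa.tobytes())
        if key not in self._signal_cache:
            dirs = np.where(self.anatomy.tangents[brain].any(axis=-1, keepdims=True),
                            self.anatomy.tangents[brain], np.array([1.0, 0.0, 0.0]))
            d = tensors_from_fa_md(fa[brain], self.anatomy.md[brain], dirs)
            sig = simulate_dwi(d, self.gradients, s0=self.spec.s0)
            self._signal_cache[key] = np.asarray(sig, np.float32)
        return self._signal_cache[key]

    def _row_rng(self, row_index: int, stream: int):
        return np.random.default_rng([self.seed, int(row_index), int(stream)])

    def subject_signal(self, row_index: int) -> np.ndarray:
        """Noisy masked signal (n_brain_voxels, n_meas) for one table row."""
        row = self.table.iloc[row_index]
        signal = self._noiseless_signal(row).astype(np.float64)
        if self.effects.noise_sigma > 0:
            rng = self._row_rng(row_index, stream=1)
            sig = self.effects.noise_sigma * self.spec.s0
            re = signal + sig * rng.standard_normal(signal.shape)
            im = sig * rng.standard_normal(signal.shape)
            signal = np.sqrt(re**2 + im**2)
        return signal

    def subject_dwi(self, row_index: int) -> np.ndarray:
        """Full-grid 4-D DWI volume (zeros outside the head)."""
        full = np.zeros(self.spec.grid.shape + (self.gradients.bvals.size,), np.float32)
        full[self.anatomy.brain_mask] = self.subject_signal(row_index)
        return full

    def subject_compartments(self, row_index: int) -> dict:
        """GM/WM/CSF probability maps for one row, with atrophy applied.

        Eroded gray matter is converted to CSF so the intracranial total is
        driven only by the per-subject head-size factor.
        """
        row = self.table.iloc[row_index]
        sev = self._severity(row)
        f = row.icv_factor
        gm = self.anatomy.gm * f
        wm = self.anatomy.wm * f
        csf = self.anatomy.csf * f
        if self.effects.volume_scale_sd > 0:
            rng = self._row_rng(row_index, stream=2)
            for name, m in self.anatomy.structure_masks.items():
                jitter = 1.0 + self.effects.volume_scale_sd * rng.standard_normal()
                gm[m] = gm[m] * max(jitter, 0.1)
        for name, per_group in self.effects.volume_atrophy.items():
            a = per_group.get(row.group, 0.0) * sev
            if row.timepoint == "followup":
                a += self.effects.volume_atrophy_followup.get(name, 0.0) * sev
            a = min(a, 0.99)
            if a <= 0:
                continue
            m = self.anatomy.structure_masks[name]
            key = (name, round(float(a), 12))
            if key not in self._erosion_cache:
                # density = the static anatomy GM map: per-subject scalings
                # inside the mask are uniform, so the cut is subject-invariant
                self._erosion_cache[key] = erosion_weights(m, a, density=self.anatomy.gm)
            w = self._erosion_cache[key]
            lost = gm[m] * (1.0 - w[m])
            gm[m] = gm[m] * w[m]
            csf[m] = csf[m] + lost
        return {"gm": gm, "wm": wm, "csf": csf}

    # -- cohort-level conveniences -------------------------------------

    def fa_md_maps(self, progress: bool = False):
        """Fit every row's DWI and return stacked full-grid FA and MD maps.

        Returns float32 arrays of shape ``(n_rows,) + grid.shape``; voxels
        outside the head are zero.
        """
        from dtiabv.tensors import fit_masked_signals

        n = len(self.table)
        brain = self.anatomy.brain_mask
        fa = np.zeros((n,) + self.spec.grid.shape, np.float32)
        md = np.zeros_like(fa)
        for i in range(n):
            fa_v, md_v = fit_masked_signals(self.subject_signal(i), self.gradients)
            fa[i][brain] = fa_v
            md[i][brain] = md_v
        return fa, md

    def noiseless_fa_map(self, row_index: int) -> np.ndarray:
        return self.target_fa(self.table.iloc[row_index])


def build_cohort(spec: PhantomSpec, effects: EffectSpec,
                 n_per_group: dict | int, seed: int,
                 gradients: GradientTable | None = None,
                 n_followup: int = 0,
                 sites: tuple[str, ...] = ("A", "B"),
                 anatomy: PhantomAnatomy | None = None) -> Cohort:
    """Generate a cohort table plus the machinery to realize each subject.

    ``n_per_group`` is either one integer for all three groups or a mapping
    ``{group: n}``; groups with n=0 are omitted.  ``n_followup`` bvFTD
    subjects additionally receive a follow-up row with extended effects.
    Deterministic given ``seed``: identical inputs give bit-identical data.
    """
    if isinstance(n_per_group, int):
        n_per_group = {g: n_per_group for g in GROUPS}
    for g, n in n_per_group.items():
        if g not in GROUPS:
            raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
        if 0 < n < 2:
            raise ValueError("each requested group needs >= 2 subjects")
    effects.validate_names(spec)
    if n_followup > n_per_group.get("bvFTD", 0):
        raise ValueError("n_followup exceeds the number of bvFTD subjects")
    if gradients is None:
        gradients = default_gradient_table()
    if anatomy is None:
        anatomy = build_tensor_phantom(spec)

    demo_rng = np.random.default_rng([int(seed), 0])
    rows = []
    sid = 0
    for group in GROUPS:
        for j in range(n_per_group.get(group, 0)):
            sid += 1
            age_mu, age_sd = _AGE_PARAMS[group]
            age = float(np.clip(demo_rng.normal(age_mu, age_sd), 30.0, 90.0))
            sex = "M" if demo_rng.random() < 0.5 else "F"
            if group == "control":
                cdr = np.nan
            else:
                mu, sd = _CDR_PARAMS[group]
                cdr = float(np.clip(np.round(demo_rng.normal(mu, sd) * 2) / 2, 0.0, 24.0))
            icv_f = float(np.clip(demo_rng.normal(1.0, 0.04), 0.9, 1.1))
            fa_scale = float(np.clip(demo_rng.normal(1.0, effects.fa_scale_sd), 0.7, 1.2))
            rows.append(dict(subject=f"sub-{sid:03d}", group=group,
                             site=sites[j % len(sites)], age=age, sex=sex,
                             timepoint="baseline", cdr_sob=cdr, icv_factor=icv_f,
                             fa_scale=fa_scale))
    base = pd.DataFrame(rows)
    fu_rows = []
    bv = base[base.group == "bvFTD"]
    for _, r in bv.head(n_followup).iterrows():
        fu = dict(r)
        fu["timepoint"] = "followup"
        fu["age"] = r.age + 1.0
        fu["cdr_sob"] = float(np.clip(r.cdr_sob + abs(demo_rng.normal(2.0, 1.0)), 0, 24))
        fu_rows.append(fu)
    table = pd.concat([base, pd.DataFrame(fu_rows)], ignore_index=True)
    return Cohort(spec, effects, table, anatomy, gradients, seed)
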