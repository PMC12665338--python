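"""Diffusion-tensor estimation and scalar maps.

The estimator is ordinary (unweighted) log-linear least squares on
``ln S = ln S0 - b g^T D g``: with at least six non-collinear diffusion
directions and one b=0 measurement the design is full rank and noiseless
signals invert exactly.  FA and MD come from the eigenvalues via the
standard closed forms; negative eigenvalues (a noise artifact) are clamped
to zero for the scalar maps while the voxel stays valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from dtiabv.grids import Grid
from dtiabv.phantom import GradientTable

_DESIGN_COLS = ([0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2])
_DESIGN_W = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


@dataclass
class TensorField:
    """Voxel-wise symmetric diffusion tensors (mm^2/s) with a validity mask."""

    data: np.ndarray          # (..., 3, 3)
    grid: Grid | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        if self.data.shape[-2:] != (3, 3):
            raise ValueError("tensor data must end in (3, 3)")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:-2], bool)

    @property
    def shape(self):
        return self.data.shape[:-2]

    def eigenvalues(self, clamp: bool = True) -> np.ndarray:
        """Ascending eigenvalues per voxel; negatives clamped to 0 if asked."""
        ev = np.linalg.eigvalsh(self.data)
        return np.maximum(ev, 0.0) if clamp else ev

    def principal_directions(self):
        """(eigenvalues ascending, eigenvectors); principal axis = [..., :, 2]."""
        return np.linalg.eigh(self.data)


def design_matrix(gradients: GradientTable) -> np.ndarray:
    """(n_meas, 7) design for [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    g = gradients.bvecs
    quad = g[:, _DESIGN_COLS[0]] * g[:, _DESIGN_COLS[1]] * _DESIGN_W
    return np.column_stack([np.ones(len(g)), -gradients.bvals[:, None] * quad])


def _coeffs_to_tensors(coef: np.ndarray) -> np.ndarray:
    """(..., 6) [Dxx Dyy Dzz Dxy Dxz Dyz] to full (..., 3, 3)."""
    d = np.zeros(coef.shape[:-1] + (3, 3), coef.dtype)
    d[..., 0, 0] = coef[..., 0]
    d[..., 1, 1] = coef[..., 1]
    d[..., 2, 2] = coef[..., 2]
    d[..., 0, 1] = d[..., 1, 0] = coef[..., 3]
    d[..., 0, 2] = d[..., 2, 0] = coef[..., 4]
    d[..., 1, 2] = d[..., 2, 1] = coef[..., 5]
    return d


def fit_tensor(dwi: np.ndarray, gradients: GradientTable,
               exclude_directions=None, grid: Grid | None = None) -> TensorField:
    """Fit one tensor per voxel from a (..., n_meas) signal array.

    ``exclude_directions`` is a boolean flag per measurement (quality-control
    stand-in for corrupted gradient directions); flagged measurements are
    dropped before fitting.  Voxels with any non-positive retained signal are
    masked invalid and get a zero tensor.
    """
    dwi = np.asarray(dwi, float)
    keep = np.ones(gradients.bvals.size, bool)
    if exclude_directions is not None:
        keep = ~np.asarray(exclude_directions, bool)
    sub = GradientTable(gradients.bvals[keep], gradients.bvecs[keep])  # revalidates
    x = design_matrix(sub)
    signals = dwi[..., keep]
    valid = (signals > 0).all(axis=-1)
    logs = np.where(signals > 0, np.log(np.maximum(signals, 1e-300)), 0.0)
    pinv = np.linalg.pinv(x)
    coef = logs @ pinv.T
    tensors = _coeffs_to_tensors(coef[..., 1:])
    tensors[~valid] = 0.0
    return TensorField(tensors, grid=grid, mask=valid)


def fit_masked_signals(signals: np.ndarray, gradients: GradientTable):
    """Fast path: (n_vox, n_meas) signals to per-voxel (FA, MD) vectors."""
    x = design_matrix(gradients)
    pinv = np.linalg.pinv(x)
    valid = (signals > 0).all(axis=-1)
    logs = np.log(np.maximum(signals, 1e-300))
    coef = logs @ pinv.T
    d = _coeffs_to_tensors(coef[:, 1:])
    ev = np.maximum(np.linalg.eigvalsh(d), 0.0)
    fa, md = _fa_md_from_eigenvalues(ev)
    fa[~valid] = 0.0
    md[~valid] = 0.0
    return fa, md


def _fa_md_from_eigenvalues(ev: np.ndarray):
    md = ev.mean(axis=-1)
    dev = ev - md[..., None]
    num = (dev**2).sum(axis=-1)
    den = (ev**2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * num / den)
    fa = np.where(den > 0, fa, 0.0)
    return fa, md


def scalar_maps(tensors: TensorField):
    """FA and MD arrays from a tensor field.

    FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, MD = mean eigenvalue;
    eigenvalues are clamped at zero first, keeping FA in [0, 1] without
    discarding voxels.  Invalid voxels propagate as 0 with the mask retained.
    """
    ev = tensors.eigenvalues(clamp=True)
    fa, md = _fa_md_from_eigenvalues(ev)
    fa = np.where(tensors.mask, fa, 0.0)
    md = np.where(tensors.mask, md, 0.0)
    return fa, md


def control_average_tensor(controls: list[TensorField]) -> TensorField:
    """Component-wise (Euclidean) mean tensor field over control subjects.

    Used as the shared substrate for group fiber tracking, so that tract
    geometry is not biased by single-subject noise or pathology.  The
    validity mask is the intersection of the inputs' masks.
    """
    if len(controls) < 2:
        raise ValueError("averaging needs at least 2 control tensor fields")
    shape = controls[0].shape
    for c in controls[1:]:
        if c.shape != shape:
            raise ValueError(f"grid mismatch: {c.shape} vs {shape}")
    data = np.mean([c.data for c in controls], axis=0)
    mask = np.logical_and.reduce([c.mask for c in controls])
    return TensorField(data, grid=controls[0].grid, mask=mask)


def save_tensor_field(tf: TensorField, grid: Grid, path) -> None:
    """Persist the six unique components as a 4-D NIfTI (xx yy zz xy xz yz)."""
    six = np.stack([tf.data[..., i, j] for i, j in zip(*_DESIGN_COLS)], axis=-1)
    nib.save(nib.Nifti1Image(np.asarray(six, np.float32), grid.affine), str(path))
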