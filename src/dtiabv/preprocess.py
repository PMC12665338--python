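"""Scalar-map preprocessing: smoothing, age correction, site harmonization.

Order of operations in the pipeline is fixed: smooth, then age-correct, then
harmonize across sites.  All three corrections are linear in the data, so
their effect on affinely transformed inputs is predictable, and the
correction fields can be persisted for audit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_map(data: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Separable isotropic Gaussian smoothing specified in mm FWHM.

    ``fwhm_mm = 0`` is the identity.  Boundaries use nearest-edge
    replication, which preserves the mean of constant images.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return np.array(data, float, copy=True)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size]
    return gaussian_filter(np.asarray(data, float), sigma_vox, mode="nearest")


def smooth_stack(maps: np.ndarray, fwhm_mm: float, voxel_size) -> np.ndarray:
    """Smooth a (n_subjects, X, Y, Z) stack subject by subject."""
    return np.stack([smooth_map(m, fwhm_mm, voxel_size) for m in maps])


def _site_control_index(cohort: pd.DataFrame):
    base = cohort.reset_index(drop=True)
    ctrl = (base.group == "control") & (base.timepoint == "baseline")
    return base, ctrl


def fit_age_slopes(maps: np.ndarray, cohort: pd.DataFrame):
    """Per-site voxel-wise linear regression of the map value on age.

    Fitted on each site's baseline controls; returns ``{site: slope_map}``.
    Raises if any site's control ages are all equal (slope unidentifiable).
    """
    base, ctrl = _site_control_index(cohort)
    slopes = {}
    for site, sub in base[ctrl].groupby("site"):
        if len(sub) < 3:
            raise ValueError(f"site {site!r} needs >= 3 controls for age correction")
        ages = sub.age.to_numpy()
        if np.ptp(ages) == 0:
            raise ValueError(f"site {site!r}: all control ages equal; slope unidentifiable")
        y = maps[sub.index.to_numpy()].reshape(len(sub), -1)
        a = ages - ages.mean()
        slope = (a @ (y - y.mean(axis=0))) / (a @ a)
        slopes[site] = slope.reshape(maps.shape[1:])
    return slopes


def age_correct(maps: np.ndarray, cohort: pd.DataFrame,
                reference_age: float | None = None):
    """Adjust every subject's map to a common reference age.

    The voxel-wise slope is estimated from each site's controls only (so
    pathology does not bias the aging model) and
    ``slope * (age - reference_age)`` is subtracted from every subject of
    that site.  Default reference age: mean age of all baseline controls.
    Returns ``(corrected maps, {site: slope map}, reference_age)``.
    """
    base, ctrl = _site_control_index(cohort)
    if reference_age is None:
        reference_age = float(base[ctrl].age.mean())
    slopes = fit_age_slopes(maps, cohort)
    out = np.array(maps, float, copy=True)
    for i, row in base.iterrows():
        out[i] -= slopes[row.site] * (row.age - reference_age)
    return out, slopes, reference_age


def site_harmonize(maps: np.ndarray, cohort: pd.DataFrame, gain: bool = False):
    """Control-anchored linear (first-order) inter-site harmonization.

    For each site a voxel-wise correction maps the site's control mean onto
    the pooled control mean; it is then applied to every subject of the
    site.  The default is an additive offset
    ``delta(v) = pooled_control_mean(v) - site_control_mean(v)``, the
    minimal first-order model; with ``gain=True`` a multiplicative term
    matching the control SDs is added.  Returns
    ``(corrected maps, {site: offset map})`` (with gain, the dict holds
    ``(gain map, offset map)`` tuples).  A single site is the identity.
    """
    base, ctrl = _site_control_index(cohort)
    sites = base.site.unique()
    for site in sites:
        if ((base.site == site) & ctrl).sum() < (2 if len(sites) > 1 else 1):
            raise ValueError(f"site {site!r} has too few controls to harmonize")
    out = np.array(maps, float, copy=True)
    corrections = {}
    if len(sites) == 1:
        zero = np.zeros(maps.shape[1:])
        corrections[sites[0]] = (np.ones_like(zero), zero) if gain else zero
        return out, corrections
    pooled_mean = maps[ctrl.to_numpy()].mean(axis=0)
    pooled_sd = maps[ctrl.to_numpy()].std(axis=0, ddof=1)
    for site in sites:
        sel = ((base.site == site) & ctrl).to_numpy()
        site_mean = maps[sel].mean(axis=0)
        rows = (base.site == site).to_numpy()
        if gain:
            site_sd = maps[sel].std(axis=0, ddof=1)
            g = np.where(site_sd > 0, pooled_sd / np.maximum(site_sd, 1e-30), 1.0)
            out[rows] = (out[rows] - site_mean) * g + pooled_mean
            corrections[site] = (g, pooled_mean - site_mean)
        else:
            delta = pooled_mean - site_mean
            out[rows] += delta
            corrections[site] = delta
    return out, corrections
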