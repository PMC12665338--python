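"""Atlas-based volumetry (ABV).

Structure volumes are obtained by voxel-wise multiplication of a tissue
compartment probability map with an atlas structure mask and integration
over the grid, then linearly standardized to the mean intracranial volume
(ICV) of the control group.  Group statistics use a per-structure linear
model with age as covariate, BH correction across structures, and pooled-SD
z-scores; longitudinal change is reported as percent change of the group
means; clinical correlation uses an age-partialled Pearson correlation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from dtiabv._stats import bh_adjust, pooled_z, welch_p

log = logging.getLogger(__name__)

MM3_PER_ML = 1000.0


def structure_volume(prob_map: np.ndarray, structure_mask: np.ndarray,
                     voxel_volume_mm3: float) -> float:
    """Integrated compartment probability under a mask, in mL."""
    return float((prob_map * structure_mask).sum() * voxel_volume_mm3 / MM3_PER_ML)


def icv_ml(compartments: dict, voxel_volume_mm3: float) -> float:
    """Intracranial volume: total GM + WM + CSF, in mL."""
    total = compartments["gm"] + compartments["wm"] + compartments["csf"]
    return float(total.sum() * voxel_volume_mm3 / MM3_PER_ML)


def soi_volumes(compartments_per_subject, structure_masks: dict,
                voxel_volume_mm3: float, subjects,
                compartment: str = "gm") -> tuple[pd.DataFrame, pd.Series]:
    """Raw structure volumes and ICV per subject.

    ``compartments_per_subject`` is an iterable of ``{'gm','wm','csf'}``
    probability-map dicts aligned with ``subjects``.  A structure whose mask
    is empty gets volume 0 with a warning.  Returns ``(volumes, icv)`` with
    volumes in mL, rows indexed by subject.
    """
    records, icvs = [], []
    for comp in compartments_per_subject:
        row = {}
        for name, mask in structure_masks.items():
            if not mask.any():
                log.warning("structure %r has an empty mask; volume set to 0", name)
                row[name] = 0.0
            else:
                row[name] = structure_volume(comp[compartment], mask, voxel_volume_mm3)
        records.append(row)
        icvs.append(icv_ml(comp, voxel_volume_mm3))
    idx = subjects if isinstance(subjects, pd.Index) else pd.Index(subjects, name="subject")
    return pd.DataFrame(records, index=idx), pd.Series(icvs, index=idx, name="icv_ml")


def standardize_icv(volumes: pd.DataFrame, icv: pd.Series,
                    control_subjects) -> pd.DataFrame:
    """Linear ICV standardization: raw * (mean control ICV / subject ICV).

    Idempotent in the sense that re-standardizing with the standardized
    table's own ICV column (all equal to the control mean) is the identity.
    """
    ref = float(icv.loc[control_subjects].mean())
    factor = ref / icv.loc[volumes.index]
    return volumes.mul(factor, axis=0)


def soi_group_stats(volumes: pd.DataFrame, cohort: pd.DataFrame,
                    group_pairs=(("bvFTD", "control"), ("ALS-FTD", "control"),
                                 ("ALS-FTD", "bvFTD")),
                    q: float = 0.05) -> pd.DataFrame:
    """Per-structure group contrast with age as covariate.

    For each pair a two-level linear model ``volume ~ group + age`` is fit
    per structure; the two-sided p of the group contrast is BH-corrected
    across structures within the pair.  Pooled-SD z-scores accompany the
    model p-values.  Raises on a rank-deficient design, naming the columns.
    """
    cohort = cohort.set_index("subject") if "subject" in cohort.columns else cohort
    base = cohort[cohort.timepoint == "baseline"]
    rows = []
    for g1, g2 in group_pairs:
        sel = base[base.group.isin([g1, g2])]
        ids = volumes.index.intersection(sel.index)
        sel = sel.loc[ids]
        if min((sel.group == g1).sum(), (sel.group == g2).sum()) < 3:
            raise ValueError(f"pair {g1} vs {g2}: needs >= 3 subjects per group")
        indicator = (sel.group == g1).astype(float)
        design = sm.add_constant(pd.DataFrame({"group": indicator, "age": sel.age}))
        if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
            corr = design.corr().abs()
            np.fill_diagonal(corr.values, 0)
            pair = corr.stack().idxmax()
            raise ValueError(f"rank-deficient design; collinear columns: {pair}")
        for name in volumes.columns:
            y = volumes.loc[ids, name]
            v1 = y[sel.group == g1]
            v2 = y[sel.group == g2]
            if np.ptp(y.to_numpy()) == 0.0:
                # constant response: no effect by convention (p = 1)
                rows.append(dict(structure=name, group1=g1, group2=g2,
                                 mean1=v1.mean(), sd1=0.0, n1=len(v1),
                                 mean2=v2.mean(), sd2=0.0, n2=len(v2),
                                 z=0.0, coef_group=0.0, p=1.0))
                continue
            fit = sm.OLS(y, design).fit()
            rows.append(dict(
                structure=name, group1=g1, group2=g2,
                mean1=v1.mean(), sd1=v1.std(ddof=1), n1=len(v1),
                mean2=v2.mean(), sd2=v2.std(ddof=1), n2=len(v2),
                z=pooled_z(v1.mean(), v1.std(ddof=1), len(v1),
                           v2.mean(), v2.std(ddof=1), len(v2)),
                coef_group=fit.params["group"],
                # degenerate fit (zero residual variance) -> p undefined;
                # report 1 by the same convention as the voxel-wise tests
                p=(1.0 if not np.isfinite(fit.pvalues["group"])
                   else float(fit.pvalues["group"])),
            ))
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    for (g1, g2), sub in table.groupby(["group1", "group2"]):
        _, p_adj = bh_adjust(sub.p.to_numpy(), q=q)
        table.loc[sub.index, "q"] = p_adj
    return table


def percent_change(baseline_mean, followup_mean) -> np.ndarray:
    """Signed percent change of group means, to 2 decimals.

    ``100 * (followup - baseline) / baseline``; an increase is positive.
    """
    baseline_mean = np.asarray(baseline_mean, float)
    followup_mean = np.asarray(followup_mean, float)
    return np.round(100.0 * (followup_mean - baseline_mean) / baseline_mean, 2)


def longitudinal_change(volumes: pd.DataFrame, cohort: pd.DataFrame,
                        patient_group: str = "bvFTD", q: float = 0.05) -> pd.DataFrame:
    """Baseline-to-follow-up percent change plus follow-up-vs-control tests.

    ``volumes`` must be indexed by (subject, timepoint) or contain both a
    baseline and a follow-up row per paired subject via the cohort table.
    Percent change is computed on the paired group means (per-subject paired
    change is also reported); the follow-up group is compared to controls
    per structure with Welch tests, BH-corrected.  An unpaired follow-up
    row is an error naming the subject.
    """
    cohort = cohort.reset_index() if "subject" not in cohort.columns else cohort
    fu = cohort[(cohort.group == patient_group) & (cohort.timepoint == "followup")]
    bl = cohort[(cohort.group == patient_group) & (cohort.timepoint == "baseline")]
    missing = set(fu.subject) - set(bl.subject)
    if missing:
        raise ValueError(f"follow-up rows without a baseline: {sorted(missing)}")
    if fu.empty:
        raise ValueError("no follow-up rows found")
    paired = sorted(set(fu.subject))
    ctrl_ids = cohort[(cohort.group == "control")
                      & (cohort.timepoint == "baseline")].subject
    if isinstance(volumes.index, pd.MultiIndex):
        vol_bl = volumes.loc[[(s, "baseline") for s in paired]]
        vol_fu = volumes.loc[[(s, "followup") for s in paired]]
        vol_ct = volumes.loc[[(s, "baseline") for s in ctrl_ids]]
    else:
        raise ValueError("volumes must be indexed by (subject, timepoint)")
    rows = []
    for name in volumes.columns:
        b = vol_bl[name].to_numpy()
        f = vol_fu[name].to_numpy()
        c = vol_ct[name].to_numpy()
        rows.append(dict(
            structure=name,
            baseline_mean=b.mean(), baseline_sd=b.std(ddof=1),
            followup_mean=f.mean(), followup_sd=f.std(ddof=1),
            control_mean=c.mean(), control_sd=c.std(ddof=1),
            pct_change=float(percent_change(b.mean(), f.mean())),
            pct_change_subjectwise=float(np.mean(100.0 * (f - b) / b)),
            z_baseline=pooled_z(b.mean(), b.std(ddof=1), len(b),
                                c.mean(), c.std(ddof=1), len(c)),
            z_followup=pooled_z(f.mean(), f.std(ddof=1), len(f),
                                c.mean(), c.std(ddof=1), len(c)),
            p_followup_vs_control=welch_p(f, c),
        ))
    table = pd.DataFrame(rows)
    _, table["q_followup_vs_control"] = bh_adjust(
        table.p_followup_vs_control.to_numpy(), q=q)
    return table


def partial_corr(x: np.ndarray, y: np.ndarray, covar: np.ndarray):
    """Pearson correlation of x and y with a covariate partialled out.

    Both variables are residualized on ``[1, covar]`` and the residuals are
    correlated; this equals the recursive partial-correlation formula.  A
    constant covariate degrades to the plain correlation with a warning.
    Returns ``(r, two-sided p)`` with n-3 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    covar = np.asarray(covar, float)
    if x.size < 5:
        raise ValueError("partial correlation needs >= 5 subjects")
    if np.ptp(covar) == 0:
        log.warning("constant covariate; falling back to plain correlation")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)
    design = np.column_stack([np.ones_like(covar), covar])
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    r = float(np.clip(r, -1.0, 1.0))
    dof = x.size - 3
    t = r * np.sqrt(dof / max(1.0 - r**2, 1e-300))
    p = float(2 * stats.t.sf(abs(t), df=dof))
    return r, p


def soi_partial_corr(volumes: pd.DataFrame, scores: pd.Series, ages: pd.Series,
                     q: float = 0.05) -> pd.DataFrame:
    """Per-structure partial correlation of volume with the clinical score.

    Age is the covariate; BH correction across structures.  Subjects with a
    missing score are dropped.
    """
    ids = volumes.index.intersection(scores.dropna().index)
    if len(ids) < 5:
        raise ValueError("needs >= 5 subjects with scores")
    rows = []
    for name in volumes.columns:
        r, p = partial_corr(volumes.loc[ids, name].to_numpy(),
                            scores.loc[ids].to_numpy(), ages.loc[ids].to_numpy())
        rows.append(dict(structure=name, r=r, p=p, n=len(ids)))
    table = pd.DataFrame(rows)
    _, table["q"] = bh_adjust(table.p.to_numpy(), q=q)
    return table
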