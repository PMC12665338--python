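"""Small statistical helpers shared by the TOI and ABV group tables."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def pooled_sd(s1: float, n1: int, s2: float, n2: int) -> float:
    """Bessel-weighted pooled standard deviation of two groups."""
    if n1 < 2 or n2 < 2:
        raise ValueError("pooled SD needs at least 2 subjects per group")
    return float(np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)))


def pooled_z(mean1: float, s1: float, n1: int, mean2: float, s2: float, n2: int) -> float:
    """Group-separation z-score: mean difference over the pooled SD.

    Convention: group 1 is the patient group, group 2 the reference, so a
    lower patient mean yields a negative z.
    """
    sp = pooled_sd(s1, n1, s2, n2)
    if sp == 0.0:
        return 0.0
    return float((mean1 - mean2) / sp)


def welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test p-value; p=1 when both groups are constant."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def bh_adjust(pvals, q: float = 0.05):
    """Benjamini–Hochberg step-up: (reject flags, adjusted p-values)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, bool), np.zeros(0)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj
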