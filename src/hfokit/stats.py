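"""Agreement and correlation statistics used across the pipeline."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as spst

__all__ = ["cohen_kappa", "spearman_rank"]


def cohen_kappa(marks_a, marks_b) -> float:
    """Cohen's kappa between two equal-length categorical labelings.

    kappa = (p_o - p_e) / (1 - p_e).  When chance agreement p_e = 1 the
    statistic is undefined: returns 1.0 if the observed agreement is also
    perfect, NaN otherwise.
    """
    a = np.asarray(marks_a)
    b = np.asarray(marks_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("need two equal-length non-empty label vectors")
    n = a.size
    p_o = float(np.mean(a == b))
    cats = np.union1d(a, b)
    p_e = float(sum((np.mean(a == c)) * (np.mean(b == c)) for c in cats))
    if abs(1.0 - p_e) < 1e-12:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def spearman_rank(x, y) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(spst.spearmanr(x, y).statistic)
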