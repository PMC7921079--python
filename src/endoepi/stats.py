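"""Shared statistical helpers: BH adjustment and Stouffer combination."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values.

    NaN entries are excluded from the multiplicity count and returned as
    NaN.  Delegates to statsmodels' step-up implementation.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def stouffer_z(z_scores) -> float:
    """Unweighted Stouffer combination: sum(z_i) / sqrt(k)."""
    z = np.asarray(z_scores, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one z-score")
    return float(z.sum() / np.sqrt(z.size))


def z_from_p(p, sign) -> np.ndarray:
    """Signed normal quantile of a two-sided p-value.

    The magnitude is the upper-tail quantile at p/2; the sign is taken
    from the supplied effect direction.
    """
    p = np.asarray(p, dtype=float)
    mag = sps.norm.isf(np.clip(p, 1e-300, 1.0) / 2.0)
    return np.sign(np.asarray(sign, dtype=float)) * mag
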