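"""Shared statistical helpers: specificity scores and BH correction."""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests


def specificity_score(group_means: np.ndarray) -> tuple[float, int]:
    """Concentration of a nonnegative mean-expression vector in one group.

    Returns (score in [0, 1], argmax group index).  The score is
    1 - normalized Jensen-Shannon distance (base 2) between the normalized
    mean-expression distribution and the indicator of its largest group: 1
    when expression is confined to a single group, small when uniform.
    """
    v = np.asarray(group_means, dtype=np.float64)
    total = v.sum()
    best = int(np.argmax(v))
    if total <= 0:
        return 0.0, best
    p = v / total
    e = np.zeros_like(p)
    e[best] = 1.0
    d = jensenshannon(p, e, base=2)
    if np.isnan(d):  # identical distributions
        d = 0.0
    return float(1.0 - d), best


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values stay NaN and are
    excluded from the correction family."""
    p = np.asarray(pvals, dtype=np.float64)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q
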