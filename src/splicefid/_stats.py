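"""Small shared statistical helpers (two-sample t with degenerate handling,
Benjamini-Hochberg adjustment)."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


def two_sample_t_p(a, b, equal_var: bool = True) -> float:
    """Two-sided t-test p-value on two small replicate vectors.

    Pooled variance by default: replicate groups compared here are sampled at
    matched depth, and at n=3 per group the pooled test holds the nominal
    level while the Welch correction is markedly conservative. Degenerate
    inputs are handled explicitly: if the pooled values are all identical the
    p-value is 1.0 (no evidence of difference); if both groups have zero
    variance but different means the p-value is 0.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("two-sample t-test needs >=2 replicates per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    p = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
    return float(p) if np.isfinite(p) else 1.0


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def fraction_pct(n_hit: int, n_total: int, decimals: int = 1) -> float:
    """Percentage of n_hit out of n_total rounded to `decimals` places."""
    if n_total <= 0:
        raise ValueError("fraction of an empty set is undefined")
    return round(100.0 * n_hit / n_total, decimals)
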