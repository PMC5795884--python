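"""Paired signed-rank comparison shared by the EOG and detection analyses."""

from __future__ import annotations

import numpy as np
import scipy.stats

__all__ = ["signed_rank_test"]


def signed_rank_test(a, b) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking; the exact null
    distribution is used for n <= 25 pairs.  If every difference is zero
    the test is vacuous and ``p = 1`` is returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n_nonzero": 0}
    method = "exact" if d.size <= 25 else "approx"
    res = scipy.stats.wilcoxon(d, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "n_nonzero": int(d.size),
    }
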