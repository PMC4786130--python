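"""Multiple-testing corrections shared by all test modules.

NaN entries (degenerate genes) are excluded from the effective number of
tests and propagate as NaN adjusted values, so a handful of dead probes
never distorts the correction for the rest.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bonferroni", "bh_qvalues"]


def _validated(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    ok = np.isnan(p) | ((p >= 0.0) & (p <= 1.0))
    if not ok.all():
        raise ValueError("p-values must lie in [0, 1] (or be NaN)")
    return p


def bonferroni(p) -> np.ndarray:
    """Bonferroni adjustment min(1, m * p), m = number of non-NaN tests."""
    p = _validated(p)
    m = int(np.sum(~np.isnan(p)))
    return np.minimum(1.0, m * p)


def bh_qvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j) over the ascending-sorted non-NaN
    p-values, capped at 1, then restored to input order.
    """
    p = _validated(p)
    q = np.full_like(p, np.nan)
    idx = np.where(~np.isnan(p))[0]
    m = idx.size
    if m == 0:
        return q
    order = idx[np.argsort(p[idx], kind="stable")]
    ranked = p[order] * m / np.arange(1, m + 1)
    q[order] = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    return q
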