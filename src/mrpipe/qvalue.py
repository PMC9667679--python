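"""Storey q-values for FDR control across an exposure panel.

The q-value of a test is the minimum FDR at which it would be called
significant.  The null proportion pi0 is estimated from the flat right
tail of the p-value histogram: pi0(lambda) = #{p > lambda} / (m (1 -
lambda)) on a lambda grid, smoothed and read off at the last grid point.
With pi0 forced to 1 the procedure reduces exactly to Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["QvalueResult", "qvalues"]

_LAMBDA_GRID = np.arange(0.05, 0.96, 0.05)

#: Below this many p-values the tail estimator is too noisy; fall back to
#: pi0 = 1 (conservative, BH-equivalent).
_MIN_M_FOR_SMOOTHER = 12


@dataclass(frozen=True)
class QvalueResult:
    pi0: float
    qvalues: np.ndarray
    lambda_grid: np.ndarray
    method: str


def qvalues(pvals, method: str = "smoother") -> QvalueResult:
    """Compute q-values for a vector of p-values in (0, 1].

    ``method="smoother"`` estimates pi0 by a cubic fit to pi0(lambda)
    evaluated at lambda = 0.95 (clamped into (0, 1]); ``"fixed_pi0_1"``
    forces pi0 = 1, reproducing Benjamini-Hochberg.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("pvals must be a nonempty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if method not in ("smoother", "fixed_pi0_1"):
        raise ValidationError(f"unknown q-value method {method!r}")
    m = len(p)
    if method == "smoother" and m >= _MIN_M_FOR_SMOOTHER:
        counts = np.array([(p > lam).sum() for lam in _LAMBDA_GRID])
        pi0_lambda = counts / (m * (1.0 - _LAMBDA_GRID))
        # var(pi0(lambda)) ~ pi0 / (m (1 - lambda)); weight by 1/sd
        coef = np.polyfit(_LAMBDA_GRID, pi0_lambda, deg=3,
                          w=np.sqrt(1.0 - _LAMBDA_GRID))
        pi0 = float(np.polyval(coef, _LAMBDA_GRID[-1]))
        pi0 = min(pi0, 1.0)
        if pi0 <= 0:
            pi0 = 1.0  # degenerate fit; fall back to the conservative bound
    else:
        pi0 = 1.0

    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    q_sorted = np.empty(m)
    q_sorted[m - 1] = pi0 * ps[m - 1]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(pi0 * m * ps[i] / (i + 1), q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return QvalueResult(pi0=pi0, qvalues=q, lambda_grid=_LAMBDA_GRID.copy(),
                        method=method)
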