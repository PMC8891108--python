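"""Multiple-testing procedures shared by every omics stage.

Three false-discovery-rate controllers are exposed:

* :func:`bh_adjust` — the Benjamini–Hochberg linear step-up procedure,
  returning monotone adjusted q-values and the rejection set.
* :func:`by_adjust` — the Benjamini–Yekutieli variant, valid under arbitrary
  dependence; BH inflated by the harmonic sum ``sum(1/i for i in 1..m)``.
* :func:`bky_two_stage` — the Benjamini–Krieger–Yekutieli two-stage adaptive
  procedure.  Stage 1 runs BH at ``q' = q / (1 + q)``; the number of
  stage-1 rejections estimates the null proportion (``m0 = m - r1``); stage 2
  reruns BH at the inflated level ``q' * m / m0``.  The adaptive step gives
  extra power when many features are truly non-null while still controlling
  the FDR at ``q`` for independent p-values.

BH/BY adjusted values are delegated to
:func:`statsmodels.stats.multitest.multipletests`; the two-stage procedure is
implemented directly because callers need its stage counts and its
level-dependent adjusted values.

Missing p-values are never handled silently: inputs must be finite and in
``[0, 1]``; callers drop NaNs explicitly (the CLI does so with a record of how
many were dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["BkyResult", "bh_adjust", "by_adjust", "bky_two_stage"]


def _validate_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d vector")
    if p.size and (not np.all(np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0):
        raise ValueError(
            "p-values must be finite and in [0, 1]; exclude missing values "
            "explicitly before adjustment"
        )
    return p


def bh_adjust(p, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjustment.

    Parameters
    ----------
    p : array-like
        Raw p-values, finite, in ``[0, 1]``.
    q : float
        Target FDR level for the rejection set.

    Returns
    -------
    (qvalues, reject)
        Adjusted q-values (monotone in the order statistics) and the boolean
        rejection set ``qvalues <= q``.
    """
    p = _validate_p(p)
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    if p.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def by_adjust(p) -> np.ndarray:
    """Benjamini–Yekutieli adjusted q-values (BH with harmonic inflation)."""
    p = _validate_p(p)
    if p.size == 0:
        return np.empty(0)
    _, qvals, _, _ = multipletests(p, alpha=0.05, method="fdr_by")
    return qvals


def _bh_reject_at(p: np.ndarray, level: float) -> np.ndarray:
    """Step-up BH rejection set at an arbitrary level (ties: stable order)."""
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = level * np.arange(1, m + 1) / m
    below = np.nonzero(p[order] <= thresh)[0]
    k = int(below[-1]) + 1 if below.size else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject


@dataclass(frozen=True)
class BkyResult:
    """Outcome of the two-stage adaptive step-up procedure."""

    reject: np.ndarray
    adjusted: np.ndarray
    q: float
    stage1_rejections: int
    m0_estimate: int
    stage2_level: float

    @property
    def n_discoveries(self) -> int:
        return int(self.reject.sum())


def bky_two_stage(p, q: float = 0.01) -> BkyResult:
    """Two-stage adaptive FDR control (Benjamini–Krieger–Yekutieli).

    The returned ``adjusted`` values satisfy ``reject[i] == (adjusted[i] <= q)``
    exactly; because the procedure is adaptive they are specific to the target
    level ``q`` (the estimated null proportion depends on it).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    p = _validate_p(p)
    m = p.size
    if m == 0:
        return BkyResult(np.empty(0, bool), np.empty(0), q, 0, 0, float("nan"))
    q_prime = q / (1.0 + q)
    r1 = int(_bh_reject_at(p, q_prime).sum())
    m0 = m - r1
    bh_q, _ = bh_adjust(p, q=0.5)  # adjusted values do not depend on the level
    if m0 == 0:
        # every hypothesis rejected in stage 1: reject all
        return BkyResult(np.ones(m, bool), np.zeros(m), q, r1, 0, float("inf"))
    stage2_level = q_prime * m / m0
    reject = _bh_reject_at(p, stage2_level)
    adjusted = np.minimum(bh_q * (m0 / m) * (1.0 + q), 1.0)
    return BkyResult(reject, adjusted, q, r1, m0, stage2_level)
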