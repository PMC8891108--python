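"""Plate-level quality control and screen/compound acceptance rules.

A screening plate carries two control populations: a maximum-signal control
(in an anti-proliferative absorbance screen this is the vehicle-treated,
fully-growing well) and a minimum-signal control (maximal inhibition).  From
their means and standard deviations four standard assay-quality statistics
are derived:

* ``Z' = 1 - 3 * (sd_max + sd_min) / |mean_max - mean_min|``
* ``S:B = mean_max / mean_min`` (signal-to-background)
* ``S:N = (mean_max - mean_min) / sd_min`` (signal-to-noise)
* ``SW`` (signal window), replicate-adjusted by default:
  ``(|mean_max - mean_min| - 3*(sd_max/sqrt(n_max) + sd_min/sqrt(n_min)))
  / (sd_max / sqrt(n_max))``; the plain (non-sqrt-n) variant is available via
  ``sw_replicate_adjusted=False``.

Acceptance thresholds follow the screening protocol: a single plate is
rejected if ``Z' < 0.3`` or ``SW < 1`` (strict inequalities), and the screen
as a whole is accepted when the mean ``Z' >= 0.5`` and mean ``SW >= 2`` over
the retained plates.  A compound is called "active" when it was measured in
at least three biological repetitions and its summary EC50 (geometric mean
over repetitions) is below 10 µM in both the proliferation (BrdU) and the
metabolic-activity (WST-1) assay.

Control orientation is never inferred from the data: callers state which
wells are the maximum-signal controls (see :func:`plate_metrics_from_table`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlateQC",
    "ScreenDecision",
    "ActivityCall",
    "plate_metrics",
    "plate_metrics_from_table",
    "screen_acceptance",
    "call_active",
    "write_qc_tsv",
]

#: default thresholds, matching the screening protocol
PLATE_ZPRIME_MIN = 0.3
PLATE_SW_MIN = 1.0
SCREEN_ZPRIME_MIN = 0.5
SCREEN_SW_MIN = 2.0
ACTIVITY_EC50_MAX = 1e-5  # molar (10 µM)
ACTIVITY_MIN_REPETITIONS = 3


@dataclass(frozen=True)
class PlateQC:
    """Per-plate control summaries and quality metrics."""

    plate_id: str
    zprime: float
    sw: float
    sb: float
    sn: float
    n_pos: int
    n_neg: int
    usable: bool = True
    plate_accepted: bool = False
    reason: str = ""


@dataclass(frozen=True)
class ScreenDecision:
    plate_accepted: dict
    screen_accepted: bool
    mean_zprime: float
    mean_sw: float
    n_retained: int
    reason: str = ""


def plate_metrics(
    pos_control_values: Sequence[float],
    neg_control_values: Sequence[float],
    *,
    plate_id: str = "",
    sw_replicate_adjusted: bool = True,
    zprime_min: float = PLATE_ZPRIME_MIN,
    sw_min: float = PLATE_SW_MIN,
) -> PlateQC:
    """Compute Z', SW, S:B and S:N from the two control populations.

    ``pos_control_values`` is the maximum-signal control group and
    ``neg_control_values`` the minimum-signal group.  Standard deviations are
    sample SDs (ddof=1).  Plates whose control means coincide are returned
    with NaN metrics and ``usable=False``.
    """
    pos = np.asarray(pos_control_values, dtype=float)
    neg = np.asarray(neg_control_values, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 wells per control group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    if mu_p == mu_n:
        return PlateQC(
            plate_id, math.nan, math.nan, math.nan, math.nan,
            pos.size, neg.size, usable=False, plate_accepted=False,
            reason="control means equal; metrics undefined",
        )
    delta = abs(mu_p - mu_n)
    zprime = 1.0 - 3.0 * (sd_p + sd_n) / delta
    sb = mu_p / mu_n if mu_n != 0 else math.inf
    with np.errstate(divide="ignore"):
        sn = (mu_p - mu_n) / sd_n if sd_n > 0 else math.inf
    if sw_replicate_adjusted:
        se_p = sd_p / math.sqrt(pos.size)
        se_n = sd_n / math.sqrt(neg.size)
        sw = (delta - 3.0 * (se_p + se_n)) / se_p if se_p > 0 else math.inf
    else:
        sw = (delta - 3.0 * (sd_p + sd_n)) / sd_p if sd_p > 0 else math.inf
    accepted = not (zprime < zprime_min or sw < sw_min)
    return PlateQC(plate_id, zprime, sw, sb, sn, pos.size, neg.size,
                   usable=True, plate_accepted=accepted)


def plate_metrics_from_table(
    plate: pd.DataFrame,
    *,
    max_signal_role: str = "negative-control",
    min_signal_role: str = "positive-control",
    value_col: str = "value",
    **kwargs,
) -> PlateQC:
    """Compute plate metrics from a plate table (see synthetic plate CSV).

    In the anti-proliferative screen the vehicle ("negative") control gives
    the maximum signal and the full-inhibition ("positive") control the
    minimum; orientation is taken from the plate map roles, never inferred.
    """
    pid = str(plate["plate_id"].iloc[0]) if "plate_id" in plate else ""
    hi = plate.loc[plate["role"] == max_signal_role, value_col].to_numpy()
    lo = plate.loc[plate["role"] == min_signal_role, value_col].to_numpy()
    return plate_metrics(hi, lo, plate_id=kwargs.pop("plate_id", pid), **kwargs)


def screen_acceptance(
    plates: Sequence[PlateQC],
    *,
    plate_zprime_min: float = PLATE_ZPRIME_MIN,
    plate_sw_min: float = PLATE_SW_MIN,
    screen_zprime_min: float = SCREEN_ZPRIME_MIN,
    screen_sw_min: float = SCREEN_SW_MIN,
    include_rejected_in_mean: bool = False,
) -> ScreenDecision:
    """Apply the plate and screen acceptance rules.

    A plate is rejected iff ``Z' < plate_zprime_min`` or ``SW < plate_sw_min``
    (strict) or its metrics are unusable.  The screen is accepted iff the mean
    Z' and SW over the retained plates (default; rejected plates can be
    included via a flag) reach the screen thresholds.
    """
    if not plates:
        raise ValueError("need at least one plate")
    flags: dict = {}
    for qc in plates:
        ok = qc.usable and not (qc.zprime < plate_zprime_min or qc.sw < plate_sw_min)
        flags[qc.plate_id] = ok
    pool = [qc for qc in plates if (flags[qc.plate_id] or include_rejected_in_mean)]
    if not pool:
        return ScreenDecision(flags, False, math.nan, math.nan, 0,
                              reason="all plates rejected")
    mean_z = float(np.mean([qc.zprime for qc in pool]))
    mean_sw = float(np.mean([qc.sw for qc in pool]))
    accepted = mean_z >= screen_zprime_min and mean_sw >= screen_sw_min
    reason = "" if accepted else (
        f"mean Z'={mean_z:.3f} (need >= {screen_zprime_min}) or "
        f"mean SW={mean_sw:.3f} (need >= {screen_sw_min}) below threshold"
    )
    return ScreenDecision(flags, accepted, mean_z, mean_sw, len(pool), reason)


@dataclass(frozen=True)
class ActivityCall:
    """Per-compound activity categorization from repeated EC50 estimates."""

    compound_id: str
    n_repetitions: int
    ec50_brdu: float
    ec50_wst: float
    active: bool
    reason: str = ""


def _geomean(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.any(v <= 0):
        raise ValueError("EC50s must be positive")
    return float(np.exp(np.mean(np.log(v))))


def call_active(
    compound_id: str,
    ec50s_by_assay: Mapping[str, Sequence[float]],
    *,
    threshold: float = ACTIVITY_EC50_MAX,
    min_repetitions: int = ACTIVITY_MIN_REPETITIONS,
    required_assays: tuple[str, str] = ("BrdU", "WST-1"),
) -> ActivityCall:
    """Categorize a compound as active.

    ``ec50s_by_assay`` maps assay label to the per-biological-repetition EC50
    estimates (molar).  The summary EC50 per assay is the geometric mean over
    repetitions (EC50s are log-distributed).  Active requires >=
    ``min_repetitions`` repetitions in every required assay and summary EC50
    below ``threshold`` in both.
    """
    missing = [a for a in required_assays if not ec50s_by_assay.get(a)]
    if missing:
        return ActivityCall(compound_id, 0, math.nan, math.nan, False,
                            reason=f"insufficient evidence: missing assay(s) {missing}")
    summaries = {a: _geomean(ec50s_by_assay[a]) for a in required_assays}
    n_rep = min(len(ec50s_by_assay[a]) for a in required_assays)
    if n_rep < min_repetitions:
        return ActivityCall(compound_id, n_rep, summaries[required_assays[0]],
                            summaries[required_assays[1]], False,
                            reason=f"only {n_rep} repetitions (need >= {min_repetitions})")
    active = all(summaries[a] < threshold for a in required_assays)
    reason = "" if active else "summary EC50 at or above threshold in some assay"
    return ActivityCall(compound_id, n_rep, summaries[required_assays[0]],
                        summaries[required_assays[1]], active, reason)


def write_qc_tsv(plates: Sequence[PlateQC], decision: ScreenDecision,
                 tsv_path, json_path=None) -> None:
    """Write the per-plate QC TSV and (optionally) the screen-level JSON."""
    df = pd.DataFrame(
        {
            "plate_id": [q.plate_id for q in plates],
            "zprime": [q.zprime for q in plates],
            "sw": [q.sw for q in plates],
            "sb": [q.sb for q in plates],
            "sn": [q.sn for q in plates],
            "accepted": [decision.plate_accepted[q.plate_id] for q in plates],
        }
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "screen_accepted": decision.screen_accepted,
            "mean_zprime": decision.mean_zprime,
            "mean_sw": decision.mean_sw,
            "n_retained": decision.n_retained,
            "reason": decision.reason,
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2)
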