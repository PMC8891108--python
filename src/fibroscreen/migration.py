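"""Scratch-assay migration quantification.

A scratch (wound) is introduced into a confluent fibroblast monolayer and the
open wound area is measured at the start and at later imaging timepoints
(here 17 h and 24 h by default, but any grid is accepted).  Cell migration
closes the wound, so the fractional closure at time t is

    c(t) = 1 - area(t) / area(t0)

with c(t0) = 0 and c = 1 for a fully closed wound.  The migrative index (MI)
reported by default is this closure normalized to the mean closure of the
vehicle-control wells at the same timepoint (MI = 1: migrates like control;
MI = 0: no migration); the unnormalized closure is always reported alongside.

A scratch cannot widen biologically; measured areas exceeding the starting
area (segmentation jitter) are clamped to zero closure, with a warning when
the excess passes a relative tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["MigrationSeries", "closure", "migrative_index", "migration_table"]


@dataclass(frozen=True)
class MigrationSeries:
    """Open-area measurements of one scratch well over time."""

    well_id: str
    treatment: str
    areas: Mapping[float, float]  # t_hours -> open area (any consistent unit)
    is_control: bool = False

    def t0(self) -> float:
        return min(self.areas)

    def __post_init__(self):
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("areas must be non-negative")
        if self.areas[min(self.areas)] <= 0:
            raise ValueError("starting open area must be positive")


def closure(series: MigrationSeries, *, widen_tol: float = 0.05) -> dict[float, float]:
    """Fractional wound closure per timepoint; c(t0) = 0, clamped at 0."""
    a0 = series.areas[series.t0()]
    out: dict[float, float] = {}
    for t, area in sorted(series.areas.items()):
        c = 1.0 - area / a0
        if c < 0.0:
            if area > a0 * (1.0 + widen_tol):
                warnings.warn(
                    f"well {series.well_id}: open area at t={t} exceeds the "
                    f"starting area by more than {widen_tol:.0%}; closure clamped to 0",
                    stacklevel=2,
                )
            c = 0.0
        out[t] = c
    return out


def migrative_index(
    series: MigrationSeries,
    normalize_to: Mapping[float, float] | None = None,
    *,
    widen_tol: float = 0.05,
) -> dict[float, float]:
    """MI per timepoint: closure, optionally normalized to control closure.

    ``normalize_to`` maps timepoint to the mean vehicle-control closure; when
    omitted the raw closure itself is returned.  A zero control closure at a
    later timepoint yields NaN (index undefined) with a warning.
    """
    c = closure(series, widen_tol=widen_tol)
    if normalize_to is None:
        return c
    out: dict[float, float] = {}
    for t, ct in c.items():
        if t == series.t0():
            out[t] = 0.0
            continue
        ref = normalize_to.get(t)
        if ref is None:
            raise KeyError(f"no control closure supplied for t={t}")
        if ref == 0.0:
            warnings.warn(f"control closure 0 at t={t}; MI undefined", stacklevel=2)
            out[t] = math.nan
        else:
            out[t] = ct / ref
    return out


def migration_table(
    df: pd.DataFrame,
    *,
    control_treatment: str = "vehicle",
    normalize: bool = True,
    widen_tol: float = 0.05,
) -> pd.DataFrame:
    """Compute closure and MI for a tidy area table.

    Expects columns ``well_id, treatment, t_hours, open_area``.  Control
    closure per timepoint is the mean over wells of ``control_treatment``.
    Returns a tidy frame with ``closure`` and ``mi`` columns (``mi`` equals
    ``closure`` when ``normalize=False``).
    """
    required = {"well_id", "treatment", "t_hours", "open_area"}
    if not required.issubset(df.columns):
        raise ValueError(f"area table needs columns {sorted(required)}")
    series = {}
    for (wid, trt), sub in df.groupby(["well_id", "treatment"], sort=False):
        areas = dict(zip(sub["t_hours"].astype(float), sub["open_area"].astype(float)))
        series[wid] = MigrationSeries(str(wid), str(trt), areas,
                                      is_control=(trt == control_treatment))
    control_closure: dict[float, list[float]] = {}
    for s in series.values():
        if s.is_control:
            for t, c in closure(s, widen_tol=widen_tol).items():
                control_closure.setdefault(t, []).append(c)
    control_mean = {t: float(np.mean(v)) for t, v in control_closure.items()}
    if normalize and not control_mean:
        raise ValueError(f"no wells with control treatment {control_treatment!r}")
    rows = []
    for s in series.values():
        c = closure(s, widen_tol=widen_tol)
        mi = migrative_index(s, control_mean if normalize else None, widen_tol=widen_tol)
        for t in sorted(c):
            rows.append({"well_id": s.well_id, "treatment": s.treatment,
                         "t_hours": t, "closure": c[t], "mi": mi[t]})
    return pd.DataFrame(rows)
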