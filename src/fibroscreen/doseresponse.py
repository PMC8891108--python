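"""Four-parameter logistic dose-response inference.

The screening readout (reference-wavelength-corrected absorbance) for a well
treated at dose ``d`` is modelled with the four-parameter logistic (4PL)

    y(d) = bottom + (top - bottom) / (1 + (d / EC50) ** hill)

With ``hill > 0`` the response falls from ``top`` (no inhibition, the vehicle
plateau) to ``bottom`` as the dose rises — the sign convention used for
inhibition curves throughout this package.  Raw wells are first normalized to
the vehicle plateau ("TOP"), mapping the vehicle-control mean to 1 and the
blank-corrected zero to 0, so fitted tops sit near 1.

The EC50 is optimized in log10 space with bounds spanning the tested doses
plus/minus two decades, initialized from the dose bracketing half-maximal
response; this stabilizes the otherwise ill-conditioned fit.  95% confidence
intervals are asymptotic (curvature-based, Student-t with ``n - 4`` degrees of
freedom) by default, with a case-resampling bootstrap behind
``ci_method="bootstrap"``.

From a converged fit, the dose producing any relative effect level f in
(0, 100) has the closed form

    EC_f = EC50 * (f / (100 - f)) ** (1 / hill)

where the effect is measured between the fitted top and bottom (the relative
definition; an absolute variant measuring f% of the top plateau is exposed via
``mode="absolute"``).  EC_50 is the EC50 exactly.

The therapeutic index is the ratio of the toxic to the effective EC50
(T.i. = IC50 / EC50); when no toxicity is reached within the tested range the
index is reported as a censored lower bound ``max_tested / EC50``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CurveFit",
    "TherapeuticIndex",
    "four_pl",
    "normalize_to_top",
    "fit_4pl",
    "ec_f",
    "working_dose",
    "therapeutic_index",
    "assay_concordance",
    "fit_screen",
]

PARAM_NAMES = ("top", "bottom", "hill", "ec50")


class PlateError(ValueError):
    """Raised when a plate cannot be normalized (unusable reference)."""


def four_pl(dose, top: float, bottom: float, hill: float, ec50: float):
    """Evaluate the 4PL curve; decreasing in dose for hill > 0."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def normalize_to_top(values, reference_values, blank: float = 0.0) -> np.ndarray:
    """Normalize raw wells to the vehicle plateau (TOP).

    The vehicle-control mean maps to 1.0 and the blank-corrected zero to 0.0.
    Raises :class:`PlateError` when the blank-corrected reference mean is not
    positive (unusable plate).
    """
    values = np.asarray(values, dtype=float)
    ref = float(np.mean(reference_values)) - blank
    if not ref > 0:
        raise PlateError(f"blank-corrected reference mean {ref} <= 0; plate unusable")
    return (values - blank) / ref


@dataclass(frozen=True)
class CurveFit:
    """A fitted 4PL curve: the unit of dose-response inference."""

    top: float
    bottom: float
    hill: float
    ec50: float
    ci: dict = field(default_factory=dict)  # param -> (low, high), 95%
    converged: bool = True
    reason: str = ""
    n_points: int = 0
    assay: str = ""
    residual_sd: float = math.nan

    def ci_for(self, param: str) -> tuple[float, float]:
        return self.ci.get(param, (math.nan, math.nan))

    @property
    def ec50_ci(self) -> tuple[float, float]:
        return self.ci_for("ec50")

    def predict(self, dose):
        return four_pl(dose, self.top, self.bottom, self.hill, self.ec50)


def _initial_guess(doses: np.ndarray, responses: np.ndarray) -> tuple[float, float, float, float]:
    order = np.argsort(doses)
    d, y = doses[order], responses[order]
    uniq = np.unique(d)
    means = np.array([y[d == u].mean() for u in uniq])
    top0 = float(means[0])
    bottom0 = float(means[-1])
    if top0 < bottom0:  # tolerate noise; keep the decreasing convention
        top0, bottom0 = bottom0, top0
    half = 0.5 * (top0 + bottom0)
    # dose bracketing the half-maximal response
    below = np.nonzero(means <= half)[0]
    if below.size and below[0] > 0:
        i = below[0]
        lec50 = 0.5 * (math.log10(uniq[i - 1]) + math.log10(uniq[i]))
    else:
        lec50 = 0.5 * (math.log10(uniq[0]) + math.log10(uniq[-1]))
    return top0, max(bottom0, 0.0), 1.0, lec50


def fit_4pl(
    doses,
    responses,
    *,
    assay: str = "",
    bottom_min: float | None = 0.0,
    top_max: float | None = None,
    hill_bounds: tuple[float, float] = (1e-2, 20.0),
    ci_method: str = "asymptotic",
    n_boot: int = 500,
    seed: int | None = None,
) -> CurveFit:
    """Fit the 4PL by least squares.

    Parameters
    ----------
    doses, responses : array-like
        Paired observations; doses in molar, > 0; >= 4 distinct doses.
    bottom_min : float or None
        Lower bound for the bottom plateau (default 0 on the normalized
        scale; ``None`` leaves it free).
    top_max : float or None
        Optional upper bound for the top plateau (e.g. 1 after
        normalization); free by default.
    ci_method : {"asymptotic", "bootstrap"}
        95% CI construction.  Asymptotic uses the curvature (covariance)
        estimate with a t(n-4) quantile; bootstrap case-resamples wells.

    Non-convergence (flat data, optimizer failure, EC50 pinned at the search
    boundary) is reported via ``converged=False`` with a reason, never
    silently.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError("doses and responses must be matching 1-d arrays")
    if np.any(d <= 0):
        raise ValueError("doses must be positive (molar)")
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite")
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct doses")

    def unconverged(reason: str) -> CurveFit:
        return CurveFit(math.nan, math.nan, math.nan, math.nan, {}, False,
                        reason, d.size, assay)

    if np.ptp(y) == 0.0:
        return unconverged("responses carry no dose information (constant)")

    top0, bottom0, hill0, lec0 = _initial_guess(d, y)
    llo = math.log10(d.min()) - 2.0
    lhi = math.log10(d.max()) + 2.0
    lo = [-np.inf if top_max is None else -np.inf,
          -np.inf if bottom_min is None else bottom_min,
          hill_bounds[0], llo]
    hi = [np.inf if top_max is None else top_max, np.inf, hill_bounds[1], lhi]
    p0 = [min(max(top0, lo[0]), hi[0]), max(bottom0, lo[1]), hill0,
          min(max(lec0, llo), lhi)]

    def model(dd, top, bottom, hill, lec50):
        return four_pl(dd, top, bottom, hill, 10.0 ** lec50)

    try:
        popt, pcov = optimize.curve_fit(
            model, d, y, p0=p0, bounds=(lo, hi), method="trf",
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except (RuntimeError, optimize.OptimizeWarning, ValueError) as exc:
        return unconverged(f"optimizer failure: {exc}")

    top, bottom, hill, lec50 = (float(v) for v in popt)
    margin = 1e-6
    if lec50 <= llo + margin or lec50 >= lhi - margin:
        return unconverged("EC50 pinned at search boundary; not identifiable")

    resid = y - model(d, *popt)
    dof = d.size - 4
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof)) if dof > 0 else math.nan
    # identifiability: a dynamic range indistinguishable from the residual
    # noise means the EC50 is not determined by the data
    if math.isfinite(residual_sd) and abs(top - bottom) < 2.0 * residual_sd:
        return unconverged("dynamic range below noise; EC50 not identifiable")

    ci: dict = {}
    if ci_method == "asymptotic":
        if dof > 0 and np.all(np.isfinite(pcov)):
            tcrit = stats.t.ppf(0.975, dof)
            se = np.sqrt(np.diag(pcov))
            ci["top"] = (top - tcrit * se[0], top + tcrit * se[0])
            ci["bottom"] = (bottom - tcrit * se[1], bottom + tcrit * se[1])
            ci["hill"] = (hill - tcrit * se[2], hill + tcrit * se[2])
            ci["ec50"] = (10.0 ** (lec50 - tcrit * se[3]),
                          10.0 ** (lec50 + tcrit * se[3]))
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots: list[list[float]] = []
        for _ in range(n_boot):
            idx = rng.integers(0, d.size, d.size)
            if np.unique(d[idx]).size < 4:
                continue
            try:
                bopt, _ = optimize.curve_fit(
                    model, d[idx], y[idx], p0=popt, bounds=(lo, hi),
                    method="trf", maxfev=5000)
            except (RuntimeError, ValueError):
                continue
            boots.append([bopt[0], bopt[1], bopt[2], 10.0 ** bopt[3]])
        if len(boots) >= max(20, n_boot // 10):
            arr = np.asarray(boots)
            for k, name in enumerate(PARAM_NAMES):
                lo_q, hi_q = np.percentile(arr[:, k], [2.5, 97.5])
                ci[name] = (float(lo_q), float(hi_q))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")

    return CurveFit(top, bottom, hill, 10.0 ** lec50, ci, True, "",
                    d.size, assay, residual_sd)


def ec_f(fit: CurveFit, f: float, mode: str = "relative") -> float:
    """Dose (molar) producing f% effect on a converged fit.

    ``mode="relative"`` measures the effect between the fitted plateaus:
    ``EC_f = EC50 * (f / (100 - f)) ** (1 / hill)``, so ``ec_f(fit, 50)`` is
    the EC50 exactly.  ``mode="absolute"`` measures f% suppression of the top
    plateau itself (target response ``top * (100 - f) / 100``), which must lie
    strictly between the plateaus.
    """
    if not fit.converged:
        raise ValueError("ec_f requires a converged fit")
    if not 0.0 < f < 100.0:
        raise ValueError("f must lie strictly between 0 and 100")
    if mode == "relative":
        return fit.ec50 * (f / (100.0 - f)) ** (1.0 / fit.hill)
    if mode == "absolute":
        target = fit.top * (100.0 - f) / 100.0
        lo, hi = sorted((fit.bottom, fit.top))
        if not lo < target < hi:
            raise ValueError("absolute effect level outside the fitted plateaus")
        return fit.ec50 * ((fit.top - target) / (target - fit.bottom)) ** (1.0 / fit.hill)
    raise ValueError(f"unknown mode {mode!r}")


def working_dose(fit: CurveFit, factor: float = 10.0) -> float:
    """Follow-up dosing rule: a multiple of the fitted EC50 (default 10x)."""
    if not fit.converged:
        raise ValueError("working dose requires a converged fit")
    return factor * fit.ec50


@dataclass(frozen=True)
class TherapeuticIndex:
    """Ratio of toxic to effective concentration; censored => lower bound."""

    ratio: float
    censored: bool
    toxicity_endpoint: str = ""


def therapeutic_index(
    effective: CurveFit,
    toxic: CurveFit | None,
    max_tested: float,
    *,
    toxicity_endpoint: str = "",
) -> TherapeuticIndex:
    """T.i. = toxic EC50 / effective EC50, censored at the tested range.

    When the toxicity fit did not converge (no response up to the highest
    tested dose) or its EC50 exceeds ``max_tested``, the index is the lower
    bound ``max_tested / effective EC50`` with ``censored=True``.
    """
    if not effective.converged:
        raise ValueError("effective fit did not converge; therapeutic index undefined")
    if max_tested <= 0:
        raise ValueError("max_tested must be positive")
    endpoint = toxicity_endpoint or (toxic.assay if toxic is not None else "")
    if toxic is None or not toxic.converged or toxic.ec50 > max_tested:
        return TherapeuticIndex(max_tested / effective.ec50, True, endpoint)
    return TherapeuticIndex(toxic.ec50 / effective.ec50, False, endpoint)


def assay_concordance(
    ec50s_assay_a: Mapping[str, float],
    ec50s_assay_b: Mapping[str, float],
) -> tuple[float, float]:
    """Mean and SD of paired log10 EC50 differences between two assays.

    Compounds present in only one assay are excluded with a warning.  Returns
    ``(mean, sd)`` of ``log10(a) - log10(b)`` over the paired compounds (sample
    SD; 0.0 for a single pair).
    """
    shared = sorted(set(ec50s_assay_a) & set(ec50s_assay_b))
    dropped = sorted(set(ec50s_assay_a) ^ set(ec50s_assay_b))
    if dropped:
        warnings.warn(f"excluding unpaired compounds: {dropped}", stacklevel=2)
    if not shared:
        raise ValueError("no paired compounds")
    a = np.array([ec50s_assay_a[c] for c in shared], dtype=float)
    b = np.array([ec50s_assay_b[c] for c in shared], dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("EC50s must be positive")
    diff = np.log10(a) - np.log10(b)
    sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
    return float(diff.mean()), sd


def fit_screen(
    plate_table: pd.DataFrame,
    *,
    assay: str = "BrdU",
    vehicle_role: str = "negative-control",
    blank: float = 0.0,
    ec_levels: tuple[float, float] = (5.0, 95.0),
    **fit_kwargs,
) -> pd.DataFrame:
    """Normalize and fit every compound on every plate of a screen table.

    ``plate_table`` uses the plate CSV layout (columns ``plate_id, well, row,
    col, role, compound_id, dose_molar, value``).  Each plate is normalized to
    its own vehicle-control mean; one fit is produced per (plate, compound),
    i.e. per biological repetition.  Returns the per-compound fit table with
    EC5/EC95 columns and a ``fit`` object column.
    """
    rows = []
    for pid, plate in plate_table.groupby("plate_id", sort=False):
        ref = plate.loc[plate["role"] == vehicle_role, "value"].to_numpy()
        if ref.size == 0:
            raise PlateError(f"plate {pid} has no {vehicle_role} wells")
        compounds = plate[plate["role"] == "compound"]
        for cid, sub in compounds.groupby("compound_id", sort=False):
            norm = normalize_to_top(sub["value"].to_numpy(), ref, blank=blank)
            fit = fit_4pl(sub["dose_molar"].to_numpy(), norm, assay=assay,
                          **fit_kwargs)
            lo_f, hi_f = ec_levels
            rows.append({
                "plate_id": pid, "compound_id": cid, "assay": assay,
                "top": fit.top, "bottom": fit.bottom, "hill": fit.hill,
                "ec50_molar": fit.ec50,
                "ec50_ci_low": fit.ec50_ci[0], "ec50_ci_high": fit.ec50_ci[1],
                "ec5": ec_f(fit, lo_f) if fit.converged else math.nan,
                "ec95": ec_f(fit, hi_f) if fit.converged else math.nan,
                "converged": fit.converged, "fit": fit,
            })
    return pd.DataFrame(rows)
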