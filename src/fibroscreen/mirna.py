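"""qPCR miRNA-array analysis: cT filtering, normalization, discovery.

The input is a cT matrix (features in rows, samples in columns; lower cT =
higher expression) with a sample annotation table giving each sample's
treatment and replicate.  The analysis stages mirror the screening protocol:

1. **Low-expression filter** — a feature is excluded when, within any
   treatment group, more than ``max_fail`` replicates have cT above the
   detection ceiling (default 32 cycles).  Undetected reactions should be
   encoded as ``ceiling + 1`` before filtering.  Exclusion is global: a
   feature unmeasurable in one arm cannot be compared across arms (an
   ``scope="all"`` switch requires failure in every group instead).
2. **Column-mean normalization** — each sample column is centered on its own
   mean over the retained features (shift-invariant, idempotent).
3. **Discovery** — per-feature unpaired t-tests, treated vs control, with
   two-stage adaptive FDR (BKY) at 1%.  Fold-changes follow the qPCR
   convention: lower cT means higher expression, so
   ``log2FC = mean(control cT) - mean(treated cT)``.
4. **Grouping and top candidates** — discovery sets are unioned across
   related treatments (e.g. "bufalin-like" vs "lycorine-like"), and the top
   candidates are taken by absolute fold-change among discoveries.

No baseline correction with relative thresholds is applied; the analysis
operates on raw exported cT values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bky_two_stage

__all__ = [
    "filter_low_expressed",
    "normalize_column_mean",
    "discover_deregulated",
    "group_discoveries",
    "top_candidates",
    "run_mirna_pipeline",
]

DETECTION_CEILING = 32.0
#: pooled-SD floor used when a feature has zero within-group variance
EPSILON_SD = 1e-9


def _groups(annotations: pd.DataFrame, columns) -> dict[str, list[str]]:
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns else annotations
    missing = [c for c in columns if c not in ann.index]
    if missing:
        raise ValueError(f"samples without annotation: {missing}")
    out: dict[str, list[str]] = {}
    for s in columns:
        out.setdefault(str(ann.loc[s, "treatment"]), []).append(s)
    return out


def filter_low_expressed(
    ct: pd.DataFrame,
    annotations: pd.DataFrame,
    *,
    ceiling: float = DETECTION_CEILING,
    max_fail: int = 1,
    scope: str = "any",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude features with cT above the ceiling in too many replicates.

    A feature fails a treatment group when strictly more than ``max_fail``
    of that group's replicates have ``cT > ceiling``.  With ``scope="any"``
    (default) failing any group excludes the feature; ``scope="all"``
    requires failure in every group.  Returns ``(retained, exclusion_log)``
    with conservation ``len(retained) + len(excluded) == len(input)``.
    """
    if scope not in ("any", "all"):
        raise ValueError("scope must be 'any' or 'all'")
    groups = _groups(annotations, ct.columns)
    for trt, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"treatment {trt!r} has fewer than 2 replicates; "
                             "exclusion rule undefined")
    fails = pd.DataFrame(
        {trt: (ct[cols] > ceiling).sum(axis=1) > max_fail for trt, cols in groups.items()}
    )
    excluded_mask = fails.any(axis=1) if scope == "any" else fails.all(axis=1)
    retained = ct.loc[~excluded_mask]
    log = fails.loc[excluded_mask].copy()
    log.insert(0, "feature_id", log.index)
    return retained, log.reset_index(drop=True)


def normalize_column_mean(ct: pd.DataFrame) -> pd.DataFrame:
    """Center every sample column on its mean over the retained features."""
    if ct.shape[0] == 0:
        raise ValueError("no retained features to normalize")
    return ct - ct.mean(axis=0)


def discover_deregulated(
    normalized: pd.DataFrame,
    annotations: pd.DataFrame,
    treatment: str,
    control: str,
    *,
    q: float = 0.01,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-feature unpaired t-tests with BKY discovery flags.

    Returns a discovery table with columns ``feature_id, log2fc, p, q,
    discovery, direction, treatment, zero_variance``.  ``log2fc`` is the cT
    difference control − treated (lower cT in the treated arm = upregulation,
    positive log2 fold-change).  Features with zero variance in both groups
    get their t-statistic from a documented pooled-SD floor (``1e-9``) and are
    flagged.
    """
    groups = _groups(annotations, normalized.columns)
    for name in (treatment, control):
        if name not in groups:
            raise ValueError(f"no samples annotated with treatment {name!r}")
        if len(groups[name]) < 2:
            raise ValueError(f"treatment {name!r} needs >= 2 replicates")
    a = normalized[groups[treatment]].to_numpy(dtype=float)  # treated
    b = normalized[groups[control]].to_numpy(dtype=float)    # control
    res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    zero_var = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    if zero_var.any():
        na, nb = a.shape[1], b.shape[1]
        se = EPSILON_SD * np.sqrt(1.0 / na + 1.0 / nb)
        t_eps = diff[zero_var] / se
        dof = na + nb - 2
        p[zero_var] = 2.0 * stats.t.sf(np.abs(t_eps), dof)
    log2fc = -diff  # control cT minus treated cT
    result = bky_two_stage(p, q=q)
    table = pd.DataFrame({
        "feature_id": normalized.index,
        "log2fc": log2fc,
        "p": p,
        "q": result.adjusted,
        "discovery": result.reject,
        "direction": np.where(log2fc >= 0, "up", "down"),
        "treatment": treatment,
        "zero_variance": zero_var,
    }).reset_index(drop=True)
    return table


def group_discoveries(
    tables: dict[str, pd.DataFrame],
    grouping: dict[str, list[str]],
) -> dict[str, pd.DataFrame]:
    """Union the discovery sets of related treatments.

    ``grouping`` maps a group label (e.g. ``"bufalin-like"``) to its member
    treatments.  Each returned table lists the union of discovered features
    with per-feature provenance (which member treatments discovered it).
    """
    out: dict[str, pd.DataFrame] = {}
    for label, members in grouping.items():
        missing = [m for m in members if m not in tables]
        if missing:
            raise KeyError(f"group {label!r} references unknown treatments {missing}")
        provenance: dict[str, list[str]] = {}
        for m in members:
            t = tables[m]
            for fid in t.loc[t["discovery"], "feature_id"]:
                provenance.setdefault(fid, []).append(m)
        out[label] = pd.DataFrame({
            "feature_id": list(provenance),
            "n_members": [len(v) for v in provenance.values()],
            "members": [",".join(v) for v in provenance.values()],
        })
    return out


def top_candidates(table: pd.DataFrame, k: int = 7) -> pd.DataFrame:
    """Top-k discoveries by |log2FC| (ties: smaller q, then feature id)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    disc = table.loc[table["discovery"]].copy()
    disc["_abs"] = disc["log2fc"].abs()
    disc = disc.sort_values(["_abs", "q", "feature_id"],
                            ascending=[False, True, True], kind="stable")
    return disc.drop(columns="_abs").head(k).reset_index(drop=True)


def run_mirna_pipeline(
    ct: pd.DataFrame,
    annotations: pd.DataFrame,
    control: str,
    *,
    ceiling: float = DETECTION_CEILING,
    max_fail: int = 1,
    q: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """Filter, normalize and test every non-control treatment vs control."""
    retained, _ = filter_low_expressed(ct, annotations, ceiling=ceiling,
                                       max_fail=max_fail)
    norm = normalize_column_mean(retained)
    treatments = sorted(set(_groups(annotations, ct.columns)) - {control})
    return {t: discover_deregulated(norm, annotations, t, control, q=q)
            for t in treatments}
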