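"""Targeted expression-panel and RNA-seq count analysis.

Covers the downstream expression stages of the pipeline:

* **Reference-gene normalization** (targeted panel): each sample is scaled by
  the geometric mean of a supplied stable reference-gene set, so the
  reference geometric means are equalized across samples; the scale factors
  are reported.
* **Blocked DEG calling**: genes are tested on ``log2(normalized + 0.5)``
  with a per-gene linear model containing the treatment contrast and donor
  (lot) indicator terms.  Adjusting for donor indicators is per-donor
  centering with the correct residual degrees of freedom, a transparent
  blocked substitute for a vendor covariate model; the unblocked test is
  available via ``block=None``.  A gene is a DEG when it passes both an FDR
  gate (two-stage adaptive BKY at 5% for the panel; BY at 5% for RNA-seq) and
  a fold-change gate (|log2FC| >= 1 for the panel, >= 1.3 for RNA-seq); the
  two gates are recorded separately.
* **Shared-DEG set logic**: genes consistently up- or down-regulated across
  all treatment tables, and "near-consistent" genes hitting at least
  ``min_conditions`` of them; direction conflicts are excluded and logged.
* **Pathway-signature scoring**: a pathway is scored per condition by the
  mean expression of its member genes, then centered on the signature's
  across-condition mean.
* **RNA-seq preprocessing**: CPM filtering (> 0.25 CPM in >= 3 samples) and
  TMM (trimmed mean of M-values) library-size normalization with 30% trim on
  M, 5% trim on A, precision weighting, and the upper-quartile reference
  sample, factors normalized to geometric mean 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .multitest import bky_two_stage, by_adjust

__all__ = [
    "normalize_reference_genes",
    "call_degs",
    "shared_deg_sets",
    "pathway_signature_scores",
    "cpm_filter",
    "tmm_factors",
    "log_cpm",
    "rnaseq_degs",
    "top_expressed_fraction",
    "read_gmt",
]

LOG_PSEUDOCOUNT = 0.5


# ---------------------------------------------------------------------------
# normalization

def normalize_reference_genes(
    counts: pd.DataFrame,
    reference_genes,
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale samples so reference-gene geometric means are equal.

    The per-sample factor is the geometric mean of the reference-gene counts
    in that sample divided by the across-sample (arithmetic) mean of those
    geometric means; counts are divided by the factor.  Reference genes with
    a zero count in any sample are excluded from the factor computation with
    a warning; at least two usable reference genes are required.
    """
    refs = [g for g in reference_genes if g in counts.index]
    missing = sorted(set(reference_genes) - set(refs))
    if missing:
        raise ValueError(f"reference genes absent from matrix: {missing}")
    usable = [g for g in refs if (counts.loc[g] > 0).all()]
    dropped = sorted(set(refs) - set(usable))
    if dropped:
        warnings.warn(f"reference genes with zero counts excluded from factors: {dropped}",
                      stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need >= 2 reference genes with nonzero counts in every sample")
    geo = np.exp(np.log(counts.loc[usable].to_numpy(dtype=float)).mean(axis=0))
    factors = pd.Series(geo / geo.mean(), index=counts.columns, name="factor")
    return counts / factors, factors


# ---------------------------------------------------------------------------
# blocked differential expression

def _design(ann: pd.DataFrame, samples, treatment: str, control: str,
            block: str | None):
    ann = ann.set_index("sample_id") if "sample_id" in ann.columns else ann
    cols = [s for s in samples
            if str(ann.loc[s, "treatment"]) in (treatment, control)]
    if not cols:
        raise ValueError("no samples in the requested conditions")
    treat = np.array([1.0 if str(ann.loc[s, "treatment"]) == treatment else 0.0
                      for s in cols])
    if treat.sum() < 2 or (len(cols) - treat.sum()) < 2:
        raise ValueError("need >= 2 samples per condition")
    X = [np.ones(len(cols)), treat]
    if block is not None:
        donors = [str(ann.loc[s, block]) for s in cols]
        levels = sorted(set(donors))
        if len(levels) < 2:
            raise ValueError("blocking requires >= 2 donors")
        for d in levels:
            arms = {treat[i] for i, dd in enumerate(donors) if dd == d}
            if arms != {0.0, 1.0}:
                raise ValueError(f"donor {d!r} does not contribute both conditions; "
                                 "cannot block")
        for d in levels[1:]:
            X.append(np.array([1.0 if dd == d else 0.0 for dd in donors]))
    return cols, np.column_stack(X)


def _lm_treatment_test(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene OLS; returns (beta_treat, t, p).

    Y is genes x samples; X is samples x p with the treatment contrast in
    column 1.  p-values are two-sided Student-t with n - p residual df.
    """
    n, p_dim = X.shape
    dof = n - p_dim
    if dof < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    H = xtx_inv @ X.T                       # p x n
    B = Y @ H.T                             # genes x p
    resid = Y - B @ X.T
    sigma2 = (resid ** 2).sum(axis=1) / dof
    c_tt = xtx_inv[1, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * c_tt)
        t = B[:, 1] / se
        t = np.where(se == 0,
                     np.where(B[:, 1] == 0, 0.0, np.inf * np.sign(B[:, 1])), t)
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return B[:, 1], t, pvals


def _deg_table(normalized: pd.DataFrame, ann: pd.DataFrame, treatment: str,
               control: str, q: float, min_abs_log2fc: float,
               block: str | None, adjust: str,
               already_log: bool) -> pd.DataFrame:
    cols, X = _design(ann, normalized.columns, treatment, control, block)
    sub = normalized[cols]
    keep = ~(sub == 0).all(axis=1) if not already_log else pd.Series(True, index=sub.index)
    dropped = sub.index[~keep].tolist()
    sub = sub.loc[keep]
    Y = sub.to_numpy(dtype=float)
    if not already_log:
        Y = np.log2(Y + LOG_PSEUDOCOUNT)
    lfc, _, p = _lm_treatment_test(Y, X)
    if adjust == "bky":
        res = bky_two_stage(p, q=q)
        qvals, sig_q = res.adjusted, res.reject
    elif adjust == "by":
        qvals = by_adjust(p)
        sig_q = qvals <= q
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    sig_fc = np.abs(lfc) >= min_abs_log2fc
    table = pd.DataFrame({
        "feature_id": sub.index,
        "log2fc": lfc,
        "p": p,
        "q": qvals,
        "sig_q": sig_q,
        "sig_fc": sig_fc,
        "discovery": sig_q & sig_fc,
        "direction": np.where(lfc >= 0, "up", "down"),
        "treatment": treatment,
    }).reset_index(drop=True)
    table.attrs["excluded_all_zero"] = dropped
    return table


def call_degs(
    normalized: pd.DataFrame,
    annotations: pd.DataFrame,
    treatment: str,
    control: str,
    *,
    q: float = 0.05,
    min_abs_log2fc: float = 1.0,
    block: str | None = "donor",
    adjust: str = "bky",
) -> pd.DataFrame:
    """Panel DEG calling: blocked t-tests on log2 counts, dual gate.

    Genes that are all-zero across both conditions are excluded (recorded in
    ``table.attrs["excluded_all_zero"]``).  ``discovery`` requires both
    ``q <= level`` (two-stage adaptive FDR by default) and
    ``|log2FC| >= min_abs_log2fc``; the two gates are reported separately as
    ``sig_q`` and ``sig_fc``.
    """
    return _deg_table(normalized, annotations, treatment, control, q,
                      min_abs_log2fc, block, adjust, already_log=False)


def shared_deg_sets(
    tables: dict[str, pd.DataFrame],
    min_conditions: int = 5,
) -> dict[str, object]:
    """Classify genes by the consistency of their DEG calls across treatments.

    Returns ``{"all": set, "near": set, "conflicts": set, "table": DataFrame}``:
    a gene is in ``all`` when it is a same-direction DEG in every table, in
    ``near`` when it is a same-direction DEG in at least ``min_conditions``
    (but not all), and in ``conflicts`` when called up in one treatment and
    down in another (excluded from both sets).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 treatment tables")
    n_tables = len(tables)
    direction: dict[str, set[str]] = {}
    count: dict[str, int] = {}
    for t in tables.values():
        hits = t.loc[t["discovery"]]
        for fid, direc in zip(hits["feature_id"], hits["direction"]):
            direction.setdefault(fid, set()).add(direc)
            count[fid] = count.get(fid, 0) + 1
    conflicts = {f for f, dirs in direction.items() if len(dirs) > 1}
    all_set = {f for f, c in count.items()
               if c == n_tables and f not in conflicts}
    near_set = {f for f, c in count.items()
                if min_conditions <= c < n_tables and f not in conflicts}
    rows = [{"feature_id": f, "direction": sorted(direction[f])[0] if f not in conflicts else "conflict",
             "n_conditions": count[f],
             "set": "all" if f in all_set else "near" if f in near_set else
                    "conflict" if f in conflicts else "other"}
            for f in sorted(count)]
    return {"all": all_set, "near": near_set, "conflicts": conflicts,
            "table": pd.DataFrame(rows)}


def pathway_signature_scores(
    normalized: pd.DataFrame,
    gene_sets: dict[str, set],
    annotations: pd.DataFrame,
    *,
    condition_col: str = "treatment",
) -> pd.DataFrame:
    """Score pathway signatures per condition, centered per signature.

    The per-condition score is the mean over member genes of the gene's mean
    expression in that condition; the normalized score subtracts the
    signature's across-condition mean, so normalized scores sum to zero over
    conditions.  Pathways with no measured member genes are skipped with a
    warning.
    """
    ann = annotations.set_index("sample_id") if "sample_id" in annotations.columns else annotations
    conditions: dict[str, list[str]] = {}
    for s in normalized.columns:
        conditions.setdefault(str(ann.loc[s, condition_col]), []).append(s)
    cond_names = sorted(conditions)
    cond_means = pd.DataFrame(
        {c: normalized[cols].mean(axis=1) for c, cols in conditions.items()}
    )
    rows = []
    for pathway, genes in gene_sets.items():
        members = [g for g in genes if g in normalized.index]
        if not members:
            warnings.warn(f"pathway {pathway!r} shares no genes with the matrix; skipped",
                          stacklevel=2)
            continue
        score = cond_means.loc[members, cond_names].mean(axis=0)
        centered = score - score.mean()
        for c in cond_names:
            rows.append({"pathway": pathway, "condition": c, "n_genes": len(members),
                         "score": float(score[c]), "normalized_score": float(centered[c])})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# RNA-seq preprocessing

def cpm_filter(
    counts: pd.DataFrame,
    *,
    min_cpm: float = 0.25,
    min_samples: int = 3,
) -> tuple[pd.DataFrame, int]:
    """Retain genes with CPM strictly above ``min_cpm`` in >= ``min_samples``.

    Library sizes are the column sums and must be positive.  Returns the
    retained matrix and the number of excluded genes (conservation:
    retained + excluded = total).
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    cpm = counts.to_numpy(dtype=float) / lib * 1e6
    keep = (cpm > min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep], int((~keep).sum())


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Weighted trimmed log2 ratio of one sample against the reference."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("sample shares no expressed genes with the reference")
    o, r = obs[mask], ref[mask]
    po, pr = o / n_obs, r / n_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    # asymptotic (delta-method) precision weights
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    n = m.size
    if n == 0:
        return 0.0
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - (np.floor(n * trim_m) + 1)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - (np.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    f = float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return f


def tmm_factors(
    counts: pd.DataFrame,
    *,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM library-composition scaling factors (geometric mean 1).

    The reference is the sample whose 75th count percentile (scaled by
    library size) is closest to the mean of those percentiles.  Each sample's
    factor is two to the precision-weighted, doubly-trimmed mean of the
    per-gene log2 expression ratios (M) against the reference, trimming 30%
    of the most extreme M values and 5% of the most extreme average
    abundances (A) by default.
    """
    Y = counts.to_numpy(dtype=float)
    lib = Y.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("every sample needs a positive library size")
    uq = np.array([np.quantile(Y[:, j] / lib[j], 0.75) for j in range(Y.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    logf = np.array([
        _tmm_pair(Y[:, j], Y[:, ref_idx], lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(Y.shape[1])
    ])
    factors = 2.0 ** logf
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None,
            pseudocount: float = LOG_PSEUDOCOUNT) -> pd.DataFrame:
    """log2 counts-per-million on TMM-adjusted library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    return np.log2(counts / lib * 1e6 + pseudocount)


def rnaseq_degs(
    logcpm: pd.DataFrame,
    annotations: pd.DataFrame,
    treatment: str,
    control: str,
    *,
    q: float = 0.05,
    min_abs_log2fc: float = 1.3,
    block: str | None = None,
    adjust: str = "by",
) -> pd.DataFrame:
    """RNA-seq DEG calling on TMM-normalized log-CPM values.

    Same per-gene linear-model machinery as :func:`call_degs` but on an
    already-log matrix, with Benjamini–Yekutieli adjustment and the stricter
    fold-change gate (|log2FC| >= 1.3) by default.  Blocking on a donor
    column is available; with only a few libraries per arm the unblocked test
    is the default (donor terms would consume most residual degrees of
    freedom).
    """
    return _deg_table(logcpm, annotations, treatment, control, q,
                      min_abs_log2fc, block, adjust, already_log=True)


def top_expressed_fraction(counts: pd.DataFrame, k: int) -> float:
    """Fraction of all reads carried by the k highest-expressed features."""
    if k <= 0:
        raise ValueError("k must be positive")
    totals = counts.sum(axis=1).to_numpy(dtype=float)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("empty count matrix")
    k = min(k, totals.size)
    top = np.sort(totals)[::-1][:k].sum()
    return float(top / grand)


def read_gmt(path) -> dict[str, set]:
    """Read GMT gene sets: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
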