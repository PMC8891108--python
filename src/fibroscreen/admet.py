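"""Weighted ADMET prediction scoring and candidate ranking.

Each predicted ADMET parameter (consumed from an external prediction table;
this package never computes descriptors from structure) is scored on a 0-30
scale: 0 for the negative/poor end of its rubric, 30 for the positive/optimal
end, with numeric parameters linearly interpolated between anchor points.
Parameters belong to exactly one of five categories — physicochemical,
pharmacokinetics, drug-likeness, medicinal chemistry, bioavailability — and
the compound-level prediction score is the weighted average of the category
means with weights (2, 3, 2, 1, 1):

    score = sum(w_c * mean(scores in c)) / sum(w_c)            in [0, 30]

The rubric itself is a versioned configuration (YAML-loadable); a documented
default covering common prediction outputs ships with the package, but any
analysis can supply its own.

Candidate selection combines potency with the prediction score: compounds are
ranked by the product of their ascending-EC50 rank and descending-score rank
(rank product), ties broken by the lower EC50; a Pareto-front alternative is
available via ``method="pareto"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

__all__ = [
    "CATEGORIES",
    "SCORE_MAX",
    "RubricEntry",
    "AdmetProfile",
    "CompoundRecord",
    "DEFAULT_RUBRIC",
    "load_rubric",
    "score_parameter",
    "build_profile",
    "prediction_score",
    "select_working_set",
]

SCORE_MAX = 30.0
CATEGORIES = (
    "physicochemical",
    "pharmacokinetics",
    "drug-likeness",
    "medicinal chemistry",
    "bioavailability",
)
DEFAULT_WEIGHTS = (2.0, 3.0, 2.0, 1.0, 1.0)


class RubricError(KeyError):
    """Unknown parameter or level for the active rubric."""


@dataclass(frozen=True)
class RubricEntry:
    """Scoring rule for one parameter: categorical levels or numeric anchors."""

    category: str
    levels: Mapping[str, float] | None = None
    anchors: Sequence[tuple[float, float]] | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}; expected one of {CATEGORIES}")
        if (self.levels is None) == (self.anchors is None):
            raise ValueError("exactly one of levels/anchors must be given")
        scores = (list(self.levels.values()) if self.levels is not None
                  else [s for _, s in self.anchors])
        if any(not 0.0 <= s <= SCORE_MAX for s in scores):
            raise ValueError("rubric scores must lie in [0, 30]")
        if self.anchors is not None and len(self.anchors) < 2:
            raise ValueError("numeric rubric needs at least two anchors")


def score_parameter(value, entry: RubricEntry) -> float:
    """Score one raw predicted value on the 0-30 scale.

    Categorical values are looked up; numeric values are linearly
    interpolated between anchors and clipped at the extreme anchors.
    """
    if entry.levels is not None:
        try:
            return float(entry.levels[value])
        except (KeyError, TypeError):
            raise RubricError(
                f"level {value!r} not in rubric (known: {sorted(entry.levels)})"
            ) from None
    xs, ys = zip(*sorted(entry.anchors))
    return float(np.interp(float(value), xs, ys))


@dataclass(frozen=True)
class AdmetProfile:
    """Scored ADMET parameter table for one compound."""

    values: Mapping[str, object]
    scores: Mapping[str, float]
    categories: Mapping[str, str]

    def category_means(self) -> dict[str, float]:
        means: dict[str, float] = {}
        for cat in CATEGORIES:
            vals = [s for p, s in self.scores.items() if self.categories[p] == cat]
            if vals:
                means[cat] = float(np.mean(vals))
        return means


def build_profile(values: Mapping[str, object], rubric: Mapping[str, RubricEntry]) -> AdmetProfile:
    """Score every parameter of a compound against the rubric."""
    unknown = sorted(set(values) - set(rubric))
    if unknown:
        raise RubricError(f"parameters missing from rubric: {unknown}")
    scores = {p: score_parameter(v, rubric[p]) for p, v in values.items()}
    cats = {p: rubric[p].category for p in values}
    return AdmetProfile(dict(values), scores, cats)


def prediction_score(profile: AdmetProfile, weights: Sequence[float] = DEFAULT_WEIGHTS) -> float:
    """Weighted category-average prediction score in [0, 30].

    Weights apply to the five categories in their canonical order
    (physicochemical, pharmacokinetics, drug-likeness, medicinal chemistry,
    bioavailability).  Every category must be populated.
    """
    if len(weights) != len(CATEGORIES):
        raise ValueError(f"need {len(CATEGORIES)} weights")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be positive")
    means = profile.category_means()
    empty = [c for c in CATEGORIES if c not in means]
    if empty:
        raise ValueError(f"cannot average empty categories: {empty}")
    num = sum(w * means[c] for w, c in zip(weights, CATEGORIES))
    return num / sum(weights)


@dataclass
class CompoundRecord:
    """One compound across the triage pipeline."""

    compound_id: str
    ec50: float = math.nan          # molar, summary effective concentration
    prediction_score: float = math.nan
    active: bool = True
    fingerprint: object = None
    ec50s: dict = field(default_factory=dict)     # assay -> EC50
    ic50s: dict = field(default_factory=dict)     # toxicity endpoint -> IC50
    rank: float = math.nan


def _pareto_fronts(ec50: np.ndarray, score: np.ndarray) -> np.ndarray:
    """Non-dominated sorting: front 0 = not dominated by any compound."""
    n = ec50.size
    front = np.full(n, -1)
    remaining = np.arange(n)
    level = 0
    while remaining.size:
        dominated = np.zeros(remaining.size, dtype=bool)
        for i, a in enumerate(remaining):
            for b in remaining:
                if b == a:
                    continue
                if (ec50[b] <= ec50[a] and score[b] >= score[a]
                        and (ec50[b] < ec50[a] or score[b] > score[a])):
                    dominated[i] = True
                    break
        front[remaining[~dominated]] = level
        remaining = remaining[dominated]
        level += 1
    return front


def select_working_set(
    compounds: Sequence[CompoundRecord],
    k: int = 6,
    *,
    method: str = "rank_product",
    require_active: bool = True,
) -> list[CompoundRecord]:
    """Rank compounds by combining low EC50 with high prediction score.

    Default: rank product of the ascending-EC50 rank and the descending-score
    rank (average ranks for ties), ordered ascending, ties broken by the lower
    EC50 then compound id.  ``method="pareto"`` orders by non-dominated front
    first, then by rank product within fronts.  Only active compounds are
    eligible unless ``require_active=False``.  Returns the top ``k`` (all,
    with a warning, when fewer are eligible); each returned record has its
    ``rank`` field set to the selection rank statistic.
    """
    pool = [c for c in compounds if c.active or not require_active]
    if not pool:
        return []
    ec50 = np.array([c.ec50 for c in pool], dtype=float)
    score = np.array([c.prediction_score for c in pool], dtype=float)
    if np.any(~np.isfinite(ec50)) or np.any(~np.isfinite(score)):
        raise ValueError("every eligible compound needs a finite EC50 and prediction score")
    rp = rankdata(ec50, method="average") * rankdata(-score, method="average")
    if method == "rank_product":
        keys = [(rp[i], ec50[i], pool[i].compound_id) for i in range(len(pool))]
    elif method == "pareto":
        fronts = _pareto_fronts(ec50, score)
        keys = [(fronts[i], rp[i], ec50[i], pool[i].compound_id) for i in range(len(pool))]
    else:
        raise ValueError(f"unknown method {method!r}")
    order = sorted(range(len(pool)), key=lambda i: keys[i])
    if len(pool) < k:
        warnings.warn(f"only {len(pool)} eligible compounds (requested {k})",
                      stacklevel=2)
    chosen = order[: min(k, len(pool))]
    for i in chosen:
        pool[i].rank = float(rp[i])
    return [pool[i] for i in chosen]


# ---------------------------------------------------------------------------
# rubric configuration

def _entry_from_dict(name: str, spec: Mapping) -> RubricEntry:
    cat = spec.get("category")
    if "levels" in spec:
        return RubricEntry(category=cat, levels=dict(spec["levels"]))
    if "anchors" in spec:
        anchors = [(float(x), float(s)) for x, s in spec["anchors"]]
        return RubricEntry(category=cat, anchors=anchors)
    raise ValueError(f"rubric entry {name!r} needs 'levels' or 'anchors'")


def load_rubric(source) -> dict[str, RubricEntry]:
    """Load a rubric from a YAML file path/stream or a plain mapping."""
    if isinstance(source, Mapping):
        raw = source
    else:
        if hasattr(source, "read"):
            raw = yaml.safe_load(source)
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
    return {name: _entry_from_dict(name, spec) for name, spec in raw.items()}


#: Documented default rubric for common in-silico prediction outputs.  The
#: anchors/levels encode conventional medicinal-chemistry preferences (e.g.
#: high gastrointestinal absorption is optimal; each Lipinski violation costs
#: a third of the scale).  Analyses with their own conventions should supply
#: an explicit rubric; nothing downstream depends on these defaults.
DEFAULT_RUBRIC: dict[str, RubricEntry] = {
    "mw": RubricEntry("physicochemical", anchors=[(150.0, 20.0), (300.0, 30.0), (500.0, 20.0), (700.0, 0.0)]),
    "tpsa": RubricEntry("physicochemical", anchors=[(20.0, 30.0), (140.0, 10.0), (200.0, 0.0)]),
    "logp": RubricEntry("physicochemical", anchors=[(-2.0, 0.0), (1.0, 30.0), (3.0, 30.0), (6.0, 0.0)]),
    "solubility_class": RubricEntry("physicochemical", levels={
        "Insoluble": 0.0, "Poorly soluble": 7.5, "Moderately soluble": 15.0,
        "Soluble": 22.5, "Very soluble": 30.0, "Highly soluble": 30.0}),
    "gi_absorption": RubricEntry("pharmacokinetics", levels={"High": 30.0, "Low": 0.0}),
    "bbb_permeant": RubricEntry("pharmacokinetics", levels={"No": 30.0, "Yes": 10.0}),
    "pgp_substrate": RubricEntry("pharmacokinetics", levels={"No": 30.0, "Yes": 10.0}),
    "cyp3a4_inhibitor": RubricEntry("pharmacokinetics", levels={"No": 30.0, "Yes": 0.0}),
    "lipinski_violations": RubricEntry("drug-likeness", anchors=[(0.0, 30.0), (1.0, 20.0), (2.0, 10.0), (3.0, 0.0)]),
    "bioavailability_score": RubricEntry("bioavailability", anchors=[(0.0, 0.0), (0.55, 22.5), (1.0, 30.0)]),
    "pains_alerts": RubricEntry("medicinal chemistry", anchors=[(0.0, 30.0), (1.0, 10.0), (2.0, 0.0)]),
    "synthetic_accessibility": RubricEntry("medicinal chemistry", anchors=[(1.0, 30.0), (6.0, 15.0), (10.0, 0.0)]),
}


def read_admet_table(path) -> dict[str, dict[str, object]]:
    """Read a long-format prediction TSV (compound_id, parameter, value).

    Numeric-looking values are coerced to float; everything else stays a
    categorical level string.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"compound_id", "parameter", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"ADMET table needs columns {sorted(expected)}")
    out: dict[str, dict[str, object]] = {}
    for _, row in df.iterrows():
        try:
            val: object = float(row["value"])
        except ValueError:
            val = row["value"]
        out.setdefault(row["compound_id"], {})[row["parameter"]] = val
    return out


def write_score_tsv(profiles: Mapping[str, AdmetProfile], path,
                    weights: Sequence[float] = DEFAULT_WEIGHTS) -> pd.DataFrame:
    """Write per-compound category means and prediction scores."""
    rows = []
    for cid, prof in profiles.items():
        means = prof.category_means()
        row = {"compound_id": cid}
        row.update({c: means.get(c, math.nan) for c in CATEGORIES})
        row["prediction_score"] = prediction_score(prof, weights)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
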