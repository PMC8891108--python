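"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here, so the whole
analysis is testable end-to-end without any external data:

* :func:`generate_screen` — 96-well dose-response plates.  Each compound well
  sits on a known 4PL curve (evaluated at the well's dose and scaled by the
  vehicle-control mean) with multiplicative log-normal noise of a stated CV;
  control wells are drawn around their role means with the same noise model.
  Plate-reader noise scales with signal, hence the multiplicative model.
* :func:`generate_ct_matrix` — qPCR-array cT matrices.  Expressed features
  get baseline cT in the quantifiable range; unexpressed features sit above
  the detection ceiling with high probability; a spiked deregulation of
  ``log2FC`` shifts the treated-group mean cT by ``-log2FC`` (lower cT =
  higher expression).
* :func:`generate_panel_counts` — negative-binomial counts with log-linear
  treatment and gene-specific donor (lot) effects, a stable reference-gene
  subset (no treatment or donor effect), and per-sample library-size factors.
* :func:`generate_rnaseq_counts` — long-tailed RNA-seq-like count matrices
  whose expression distribution is dominated by a few transcripts (top shares
  pinned by the preset), with optional spiked differential expression.

All generators draw exclusively from a ``numpy.random.default_rng`` seeded
from the truth object — identical truth (including seed) gives bit-identical
outputs; there is no global random state.

The default scenario presets mirror the scales of the screening campaign this
package targets: 7-point tenfold dilutions with 6 technical and 3 biological
replicates; 754 miRNA features of which 165 are expressed; a 770-gene panel
with 3 donors and 10 reference genes.  Every dimension is configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doseresponse import four_pl

__all__ = [
    "Curve4PL",
    "ScreenTruth",
    "OmicsTruth",
    "generate_screen",
    "generate_ct_matrix",
    "generate_panel_counts",
    "generate_rnaseq_counts",
    "mirna_truth",
    "panel_truth",
    "screen_truth",
    "write_plate_csv",
    "write_feature_matrix",
    "write_truth_json",
]

ROWS = "ABCDEFGH"
N_COLS = 12


@dataclass(frozen=True)
class Curve4PL:
    """True dose-response parameters on the normalized (TOP = 1) scale."""

    top: float = 1.0
    bottom: float = 0.05
    hill: float = 1.0
    ec50: float = 1e-7  # molar

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")
        if self.hill <= 0:
            raise ValueError("inhibition curves use hill > 0")


@dataclass(frozen=True)
class ScreenTruth:
    """Ground truth for a multi-plate dose-response screen."""

    compounds: Mapping[str, Curve4PL]
    dilutions: tuple[float, ...] = tuple(1e-5 * 10.0 ** -i for i in range(7))
    cv: float = 0.05
    n_technical: int = 6
    n_biological: int = 3
    vehicle_mean: float = 1.8     # raw absorbance of the vehicle control
    inhibited_frac: float = 0.05  # positive-control level relative to vehicle
    control_wells: int = 8        # wells per control role per plate
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.cv < 1.0:
            raise ValueError("CV must lie in [0, 1)")
        d = np.asarray(self.dilutions)
        if d.size < 2 or not np.all(np.diff(d) < 0) or np.any(d <= 0):
            raise ValueError("dilution series must be positive and strictly descending")
        if self.control_wells < 3:
            raise ValueError("every plate needs >= 3 wells of each control role")
        if not self.compounds:
            raise ValueError("no compounds in truth")


def _noise_factor(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-preserving multiplicative log-normal factors with the given CV."""
    if cv == 0.0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, n))


def generate_screen(truth: ScreenTruth) -> pd.DataFrame:
    """Generate the plate table of a screen.

    Returns a long-format frame with columns ``plate_id, well, row, col,
    role, compound_id, dose_molar, value``.  Control wells occupy the first
    (vehicle = maximum signal, role ``negative-control``) and last (full
    inhibition, role ``positive-control``) plate columns; compound wells fill
    the interior columns.  Compounds are split over as many plates per
    biological repetition as the interior capacity requires.
    """
    rng = np.random.default_rng(truth.seed)
    n_doses = len(truth.dilutions)
    wells_per_compound = n_doses * truth.n_technical
    capacity = (N_COLS - 2) * len(ROWS)
    if wells_per_compound > capacity:
        raise ValueError("a single compound does not fit on one plate")
    per_plate = max(1, capacity // wells_per_compound)
    compound_ids = list(truth.compounds)
    rows: list[dict] = []
    for b in range(1, truth.n_biological + 1):
        chunks = [compound_ids[i:i + per_plate]
                  for i in range(0, len(compound_ids), per_plate)]
        for p, chunk in enumerate(chunks, start=1):
            pid = f"B{b}P{p}"
            # control columns
            for role, col, mean in (
                ("negative-control", 1, truth.vehicle_mean),
                ("positive-control", N_COLS, truth.vehicle_mean * truth.inhibited_frac),
            ):
                noise = _noise_factor(rng, truth.cv, truth.control_wells)
                for i in range(truth.control_wells):
                    rows.append({
                        "plate_id": pid, "well": f"{ROWS[i]}{col:02d}",
                        "row": ROWS[i], "col": col, "role": role,
                        "compound_id": "", "dose_molar": np.nan,
                        "value": mean * noise[i],
                    })
            # compound wells, interior columns, row-major
            slot = 0
            for cid in chunk:
                curve = truth.compounds[cid]
                expected = truth.vehicle_mean * four_pl(
                    np.asarray(truth.dilutions), curve.top, curve.bottom,
                    curve.hill, curve.ec50)
                for di, dose in enumerate(truth.dilutions):
                    noise = _noise_factor(rng, truth.cv, truth.n_technical)
                    for t in range(truth.n_technical):
                        r, c = divmod(slot, N_COLS - 2)
                        rows.append({
                            "plate_id": pid, "well": f"{ROWS[r]}{c + 2:02d}",
                            "row": ROWS[r], "col": c + 2, "role": "compound",
                            "compound_id": cid, "dose_molar": dose,
                            "value": expected[di] * noise[t],
                        })
                        slot += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# omics truth

@dataclass(frozen=True)
class OmicsTruth:
    """Ground truth for a feature-by-sample omics experiment.

    Used by both the cT-matrix and the count-matrix generators; fields not
    relevant to a generator are ignored by it.  ``spiked`` maps feature id to
    its true log2 fold-change, applied to every non-control treatment.
    """

    feature_ids: tuple[str, ...]
    expressed: frozenset[str]
    spiked: Mapping[str, float]
    treatments: tuple[str, ...]
    control: str
    seed: int = 0
    # cT-matrix parameters
    n_replicates: int = 6              # per treatment (e.g. 2 technical x 3 passages)
    ct_baseline_range: tuple[float, float] = (22.0, 28.0)
    ct_undetected_mean: float = 35.0
    ct_undetected_sd: float = 1.0
    ct_noise_sd: float = 0.5           # cycles
    detection_ceiling: float = 32.0
    # count-matrix parameters
    n_donors: int = 3
    replicates_per_donor: int = 2
    log2_mean_range: tuple[float, float] = (5.0, 11.0)
    donor_sd: float = 0.5              # log2, gene-specific lot effect
    libsize_sd: float = 0.2            # log2, per-sample depth factor
    dispersion: float = 0.02           # NB dispersion (0 = Poisson limit)
    reference_genes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.control not in self.treatments:
            raise ValueError("control must be among the treatments")
        unknown = set(self.spiked) - set(self.feature_ids)
        if unknown:
            raise ValueError(f"spiked features not in the design: {sorted(unknown)}")
        if not set(self.spiked) <= self.expressed:
            bad = sorted(set(self.spiked) - self.expressed)
            raise ValueError(f"effects assigned to unexpressed features: {bad}")
        if set(self.spiked) & set(self.reference_genes):
            raise ValueError("reference genes must carry zero spiked effect")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")


def generate_ct_matrix(truth: OmicsTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cT matrix plus its sample-annotation table.

    Baseline cT per feature is uniform over ``ct_baseline_range`` for
    expressed features and normal around ``ct_undetected_mean`` (above the
    detection ceiling with high probability) otherwise; per-well noise is
    normal with SD ``ct_noise_sd`` cycles.  In non-control treatments a
    spiked feature's mean cT shifts by ``-log2FC``.
    """
    if truth.n_replicates < 2:
        raise ValueError("need >= 2 replicates per treatment")
    rng = np.random.default_rng(truth.seed)
    fids = list(truth.feature_ids)
    expressed = np.array([f in truth.expressed for f in fids])
    baseline = np.where(
        expressed,
        rng.uniform(*truth.ct_baseline_range, len(fids)),
        rng.normal(truth.ct_undetected_mean, truth.ct_undetected_sd, len(fids)),
    )
    effect = np.array([truth.spiked.get(f, 0.0) for f in fids])
    samples, ann_rows = [], []
    data = {}
    for trt in truth.treatments:
        shift = -effect if trt != truth.control else np.zeros(len(fids))
        for r in range(1, truth.n_replicates + 1):
            sid = f"{trt}_r{r}"
            samples.append(sid)
            ann_rows.append({"sample_id": sid, "treatment": trt, "replicate": r})
            data[sid] = baseline + shift + rng.normal(0.0, truth.ct_noise_sd, len(fids))
    ct = pd.DataFrame(data, index=pd.Index(fids, name="feature_id"))
    return ct, pd.DataFrame(ann_rows)


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0.0:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


def generate_panel_counts(truth: OmicsTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate negative-binomial panel counts with donor (lot) effects.

    The log2 mean of gene g in sample s is ``base_g + log2FC_g * treated(s) +
    donor_effect_{g, donor(s)} + depth_s``.  Reference genes are stable: high
    baseline, zero treatment and donor effect, so their geometric means track
    only the per-sample depth factor.  Counts are gamma-Poisson with the
    stated dispersion (Poisson in the ``dispersion = 0`` limit).
    """
    rng = np.random.default_rng(truth.seed)
    fids = list(truth.feature_ids)
    is_ref = np.array([f in set(truth.reference_genes) for f in fids])
    base = rng.uniform(*truth.log2_mean_range, len(fids))
    base[is_ref] = rng.uniform(9.0, 11.0, int(is_ref.sum()))
    effect = np.array([truth.spiked.get(f, 0.0) for f in fids])
    donors = [f"D{d}" for d in range(1, truth.n_donors + 1)]
    donor_eff = rng.normal(0.0, truth.donor_sd, (len(fids), truth.n_donors))
    donor_eff[is_ref, :] = 0.0
    samples, ann_rows, data = [], [], {}
    for trt in truth.treatments:
        treated = trt != truth.control
        for di, donor in enumerate(donors):
            for r in range(1, truth.replicates_per_donor + 1):
                sid = f"{trt}_{donor}_r{r}"
                depth = rng.normal(0.0, truth.libsize_sd)
                log2mu = base + (effect if treated else 0.0) + donor_eff[:, di] + depth
                mu = np.exp2(log2mu)
                data[sid] = _nb_counts(rng, mu, truth.dispersion)
                samples.append(sid)
                ann_rows.append({"sample_id": sid, "treatment": trt,
                                 "replicate": r, "donor": donor})
    counts = pd.DataFrame(data, index=pd.Index(fids, name="feature_id"))
    return counts, pd.DataFrame(ann_rows)


def generate_rnaseq_counts(
    seed: int,
    *,
    n_genes: int = 5000,
    top_shares: tuple[float, ...] = (0.033, 0.020, 0.013, 0.013, 0.012, 0.010),
    tail_sigma: float = 1.8,
    library_size: float = 5e6,
    n_per_group: int = 3,
    treatments: tuple[str, ...] = ("treated",),
    control: str = "control",
    n_spiked: int = 0,
    spike_log2fc: float = 2.0,
    dispersion: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Generate a long-tailed RNA-seq-like count matrix.

    The relative abundance vector pins the top transcripts to the preset
    shares (default: a 3.3% top gene and a top-6 total above 10%) and draws
    the tail from a log-normal with ``tail_sigma``.  Optionally ``n_spiked``
    genes, drawn from the upper half of the tail abundance distribution (a
    spiked gene must be quantifiable to be recoverable), receive a true
    |log2FC| of ``spike_log2fc`` with alternating sign in every non-control
    treatment.  Returns ``(counts, annotations, spiked)`` where ``spiked``
    maps gene id to its true log2 fold-change.
    """
    rng = np.random.default_rng(seed)
    fids = [f"gene{i:05d}" for i in range(n_genes)]
    k = len(top_shares)
    tail = np.exp(rng.normal(0.0, tail_sigma, n_genes - k))
    tail = tail / tail.sum() * (1.0 - sum(top_shares))
    shares = np.concatenate([np.asarray(top_shares, dtype=float), tail])
    spiked: dict[str, float] = {}
    if n_spiked:
        tail_idx = np.arange(k, n_genes)
        eligible = tail_idx[shares[tail_idx] >= np.median(shares[tail_idx])]
        chosen = rng.choice(eligible, size=n_spiked, replace=False)
        for j, g in enumerate(chosen):
            spiked[fids[g]] = spike_log2fc if j % 2 == 0 else -spike_log2fc
    effect = np.array([spiked.get(f, 0.0) for f in fids])
    samples, ann_rows, data = [], [], {}
    for trt in (control,) + tuple(treatments):
        treated = trt != control
        for r in range(1, n_per_group + 1):
            sid = f"{trt}_r{r}"
            mu = shares * library_size * (np.exp2(effect) if treated else 1.0)
            data[sid] = _nb_counts(rng, mu, dispersion)
            samples.append(sid)
            ann_rows.append({"sample_id": sid, "treatment": trt, "replicate": r})
    counts = pd.DataFrame(data, index=pd.Index(fids, name="feature_id"))
    return counts, pd.DataFrame(ann_rows), spiked


# ---------------------------------------------------------------------------
# scenario presets

def screen_truth(seed: int = 0, *, ec50s: Mapping[str, float] | None = None,
                 cv: float = 0.05, hill: float = 1.0, bottom: float = 0.05,
                 n_technical: int = 6, n_biological: int = 3) -> ScreenTruth:
    """Screen preset: 7-point tenfold dilutions, known 4PL per compound."""
    if ec50s is None:
        ec50s = {"cmpd-01": 5e-9, "cmpd-02": 5e-8, "cmpd-03": 5e-7}
    compounds = {cid: Curve4PL(top=1.0, bottom=bottom, hill=hill, ec50=e)
                 for cid, e in ec50s.items()}
    return ScreenTruth(compounds=compounds, cv=cv, n_technical=n_technical,
                       n_biological=n_biological, seed=seed)


def mirna_truth(seed: int = 0, *, n_features: int = 754, n_expressed: int = 165,
                n_spiked: int = 20, shift_cycles: float = 3.0,
                treatments: tuple[str, ...] = ("treated",),
                control: str = "control", n_replicates: int = 6) -> OmicsTruth:
    """miRNA-array preset: 754 features, 165 expressed, spiked deregulation.

    Spiked log2 fold-changes alternate sign with magnitude ``shift_cycles``
    (one cycle of cT shift per log2 unit).
    """
    rng = np.random.default_rng(seed)
    fids = tuple(f"mir{i:04d}" for i in range(n_features))
    expressed = rng.choice(n_features, size=n_expressed, replace=False)
    spiked_idx = rng.choice(expressed, size=n_spiked, replace=False)
    spiked = {fids[g]: (shift_cycles if j % 2 == 0 else -shift_cycles)
              for j, g in enumerate(spiked_idx)}
    return OmicsTruth(
        feature_ids=fids, expressed=frozenset(fids[g] for g in expressed),
        spiked=spiked, treatments=(control,) + treatments, control=control,
        seed=seed, n_replicates=n_replicates,
    )


def panel_truth(seed: int = 0, *, n_genes: int = 770, n_donors: int = 3,
                n_spiked: int = 60, log2fc: float = 2.0, n_reference: int = 10,
                treatments: tuple[str, ...] = ("treated",),
                control: str = "control", replicates_per_donor: int = 2,
                dispersion: float = 0.02) -> OmicsTruth:
    """Fibrosis-panel preset: 770 genes, 3 donors, 10 stable reference genes."""
    rng = np.random.default_rng(seed)
    fids = tuple(f"gene{i:04d}" for i in range(n_genes))
    refs = tuple(fids[i] for i in range(n_reference))
    candidates = np.arange(n_reference, n_genes)
    spiked_idx = rng.choice(candidates, size=n_spiked, replace=False)
    spiked = {fids[g]: (log2fc if j % 2 == 0 else -log2fc)
              for j, g in enumerate(spiked_idx)}
    return OmicsTruth(
        feature_ids=fids, expressed=frozenset(fids), spiked=spiked,
        treatments=(control,) + treatments, control=control, seed=seed,
        n_donors=n_donors, replicates_per_donor=replicates_per_donor,
        dispersion=dispersion, reference_genes=refs,
    )


# ---------------------------------------------------------------------------
# writers

def write_plate_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_feature_matrix(matrix: pd.DataFrame, annotations: pd.DataFrame,
                         matrix_path, annotation_path) -> None:
    matrix.to_csv(matrix_path, sep="\t")
    annotations.to_csv(annotation_path, sep="\t", index=False)


def write_truth_json(truth, path) -> None:
    """Serialize a truth object for use as a test oracle."""
    payload = asdict(truth)

    def default(o):
        if isinstance(o, (frozenset, set, tuple)):
            return sorted(o) if isinstance(o, (frozenset, set)) else list(o)
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"cannot serialize {type(o)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=default)
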