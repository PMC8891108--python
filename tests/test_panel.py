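import dataclasses

import numpy as np
import pandas as pd
import pytest

from fibroscreen.panel import (
    call_degs,
    cpm_filter,
    log_cpm,
    normalize_reference_genes,
    pathway_signature_scores,
    read_gmt,
    rnaseq_degs,
    shared_deg_sets,
    tmm_factors,
    top_expressed_fraction,
)
from fibroscreen.synth import generate_panel_counts, panel_truth


@pytest.fixture(scope="module")
def panel():
    truth = panel_truth(seed=20)
    counts, ann = generate_panel_counts(truth)
    return truth, counts, ann


class TestReferenceNormalization:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [100, 200, 50], "s2": [100, 200, 50]},
                              index=["r1", "r2", "g1"])
        norm, fac = normalize_reference_genes(counts, ["r1", "r2"])
        assert np.allclose(fac, 1.0)
        pd.testing.assert_frame_equal(norm, counts.astype(float))

    def test_scale_equivariance(self):
        counts = pd.DataFrame({"s1": [100.0, 200.0, 50.0],
                               "s2": [100.0, 200.0, 50.0],
                               "s3": [100.0, 200.0, 50.0]},
                              index=["r1", "r2", "g1"])
        doubled = counts.copy()
        doubled["s2"] = doubled["s2"] * 2
        norm0, fac0 = normalize_reference_genes(counts, ["r1", "r2"])
        norm1, fac1 = normalize_reference_genes(doubled, ["r1", "r2"])
        # the doubled sample's factor is 2x the others; after normalization
        # the matrices agree up to one global scale
        assert fac1["s2"] / fac1["s1"] == pytest.approx(2.0)
        ratio = (norm1 / norm0).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])

    def test_reference_geomeans_equalized(self, rng, panel):
        truth, counts, _ = panel
        norm, _ = normalize_reference_genes(counts, truth.reference_genes)
        geo = np.exp(np.log(norm.loc[list(truth.reference_genes)]).mean(axis=0))
        assert np.allclose(geo / geo.iloc[0], 1.0, rtol=1e-9)

    def test_zero_count_reference_excluded_with_warning(self):
        counts = pd.DataFrame({"s1": [100, 0, 50, 80], "s2": [90, 5, 60, 70]},
                              index=["r1", "r2", "r3", "g1"])
        with pytest.warns(UserWarning, match="r2"):
            _, fac = normalize_reference_genes(counts, ["r1", "r2", "r3"])
        assert fac.notna().all()

    def test_too_few_usable_references_is_error(self):
        counts = pd.DataFrame({"s1": [0, 50, 10], "s2": [5, 60, 10]},
                              index=["r1", "r2", "g1"])
        with pytest.raises(ValueError):
            normalize_reference_genes(counts, ["r1", "r2"])

    def test_missing_reference_gene_is_error(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError, match="absent"):
            normalize_reference_genes(counts, ["a", "zz"])


class TestCallDegs:
    def test_identical_conditions_no_degs(self, rng):
        genes = [f"g{i}" for i in range(60)]
        base = rng.uniform(100, 1000, 60)
        data, ann_rows = {}, []
        for trt in ("control", "treated"):
            for d in ("D1", "D2", "D3"):
                for r in (1, 2):
                    sid = f"{trt}_{d}_{r}"
                    data[sid] = rng.poisson(base)
                    ann_rows.append({"sample_id": sid, "treatment": trt,
                                     "donor": d, "replicate": r})
        counts = pd.DataFrame(data, index=genes)
        table = call_degs(counts, pd.DataFrame(ann_rows), "treated", "control")
        assert table.discovery.sum() == 0

    def test_effect_size_gate_blocks_small_fold_changes(self, rng):
        # a gene with tiny p but |log2FC| = 0.9 is not a DEG
        genes = [f"g{i}" for i in range(30)]
        data, ann_rows = {}, []
        for trt in ("control", "treated"):
            for d in ("D1", "D2", "D3"):
                for r in (1, 2):
                    sid = f"{trt}_{d}_{r}"
                    mu = np.full(30, 500.0)
                    if trt == "treated":
                        mu[0] *= 2 ** 0.9
                    data[sid] = mu * np.exp(rng.normal(0, 0.01, 30))
                    ann_rows.append({"sample_id": sid, "treatment": trt,
                                     "donor": d, "replicate": r})
        table = call_degs(pd.DataFrame(data, index=genes),
                          pd.DataFrame(ann_rows), "treated", "control")
        row = table[table.feature_id == "g0"].iloc[0]
        assert row.sig_q and not row.sig_fc and not row.discovery

    def test_recovery_on_panel_preset(self, panel):
        truth, counts, ann = panel
        norm, _ = normalize_reference_genes(counts, truth.reference_genes)
        table = call_degs(norm, ann, "treated", "control")
        hits = set(table.loc[table.discovery, "feature_id"])
        true = set(truth.spiked)
        assert len(hits & true) / len(true) >= 0.9
        assert len(hits - true) / max(len(hits), 1) <= 0.05

    def test_all_zero_genes_excluded_and_logged(self, rng):
        data, ann_rows = {}, []
        for trt in ("control", "treated"):
            for d in ("D1", "D2"):
                sid = f"{trt}_{d}"
                data[sid] = [0, 100, 200]
                ann_rows.append({"sample_id": sid, "treatment": trt, "donor": d})
        table = call_degs(pd.DataFrame(data, index=["dead", "g1", "g2"]),
                          pd.DataFrame(ann_rows), "treated", "control")
        assert "dead" not in set(table.feature_id)
        assert table.attrs["excluded_all_zero"] == ["dead"]

    def test_blocking_requires_complete_donors(self):
        data = {"control_D1": [1.0], "control_D2": [2.0],
                "treated_D2": [3.0], "treated_D3": [4.0]}
        ann = pd.DataFrame({
            "sample_id": list(data),
            "treatment": ["control", "control", "treated", "treated"],
            "donor": ["D1", "D2", "D2", "D3"],
        })
        with pytest.raises(ValueError, match="both conditions"):
            call_degs(pd.DataFrame(data, index=["g"]), ann, "treated", "control")

    def test_stricter_thresholds_give_subset(self, panel):
        truth, counts, ann = panel
        norm, _ = normalize_reference_genes(counts, truth.reference_genes)
        loose = call_degs(norm, ann, "treated", "control", q=0.05,
                          min_abs_log2fc=1.0)
        strict = call_degs(norm, ann, "treated", "control", q=0.01,
                           min_abs_log2fc=1.5)
        loose_set = set(loose.loc[loose.discovery, "feature_id"])
        strict_set = set(strict.loc[strict.discovery, "feature_id"])
        assert strict_set <= loose_set


class TestSharedDegSets:
    def table(self, hits):
        """hits: dict feature -> direction or None (non-DEG)."""
        feats = sorted(hits)
        return pd.DataFrame({
            "feature_id": feats,
            "log2fc": [2.0 if hits[f] == "up" else -2.0 for f in feats],
            "discovery": [hits[f] is not None for f in feats],
            "direction": [hits[f] or "up" for f in feats],
        })

    def test_all_and_near_and_conflict_cases(self):
        # 6 treatments: gene A up in all 6; gene B up in 5; gene C up in 3,
        # down in 3 (conflict)
        tables = {}
        for i in range(6):
            tables[f"t{i}"] = self.table({
                "A": "up",
                "B": "up" if i < 5 else None,
                "C": "up" if i < 3 else "down",
            })
        out = shared_deg_sets(tables, min_conditions=5)
        assert out["all"] == {"A"}
        assert out["near"] == {"B"}
        assert out["conflicts"] == {"C"}

    def test_sets_disjoint(self, rng):
        treatments = [f"t{i}" for i in range(4)]
        tables = {}
        feats = [f"g{i}" for i in range(30)]
        for t in treatments:
            hits = {f: rng.choice(["up", "down", None]) for f in feats}
            tables[t] = self.table(hits)
        out = shared_deg_sets(tables, min_conditions=3)
        assert not (out["all"] & out["near"])
        assert not (out["all"] | out["near"]) & out["conflicts"]

    def test_requires_two_tables(self):
        with pytest.raises(ValueError):
            shared_deg_sets({"a": self.table({"A": "up"})})


class TestSignatures:
    def ann(self):
        return pd.DataFrame({
            "sample_id": ["s1", "s2", "s3", "s4"],
            "treatment": ["c", "c", "t", "t"],
        })

    def test_single_gene_pathway_is_centered_condition_mean(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [3.0], "s3": [5.0], "s4": [7.0]},
                         index=["g1"])
        out = pathway_signature_scores(m, {"pw": {"g1"}}, self.ann())
        got = dict(zip(out.condition, out.normalized_score))
        assert got["c"] == pytest.approx(-2.0)
        assert got["t"] == pytest.approx(2.0)

    def test_identical_conditions_score_zero(self):
        m = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0],
                          "s3": [1.0, 2.0], "s4": [1.0, 2.0]},
                         index=["g1", "g2"])
        out = pathway_signature_scores(m, {"pw": {"g1", "g2"}}, self.ann())
        assert np.allclose(out.normalized_score, 0.0)

    def test_hand_computed_three_gene_case(self):
        m = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 3.0],
                          "s3": [4.0, 5.0, 9.0], "s4": [4.0, 5.0, 9.0]},
                         index=["g1", "g2", "g3"])
        out = pathway_signature_scores(m, {"pw": {"g1", "g2", "g3"}}, self.ann())
        got = dict(zip(out.condition, out.score))
        assert got["c"] == pytest.approx(2.0)
        assert got["t"] == pytest.approx(6.0)
        centered = dict(zip(out.condition, out.normalized_score))
        assert centered["c"] == pytest.approx(-2.0)

    def test_normalized_scores_sum_to_zero(self, rng):
        m = pd.DataFrame(rng.uniform(0, 10, (20, 4)),
                         index=[f"g{i}" for i in range(20)],
                         columns=["s1", "s2", "s3", "s4"])
        sets = {"a": {"g1", "g5", "g7"}, "b": {f"g{i}" for i in range(10)}}
        out = pathway_signature_scores(m, sets, self.ann())
        sums = out.groupby("pathway").normalized_score.sum()
        assert np.allclose(sums, 0.0, atol=1e-12)

    def test_empty_intersection_skipped_with_warning(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [1.0], "s3": [1.0], "s4": [1.0]},
                         index=["g1"])
        with pytest.warns(UserWarning, match="skipped"):
            out = pathway_signature_scores(m, {"pw": {"zz"}}, self.ann())
        assert out.empty


class TestCpmFilter:
    def matrix(self, cpm_targets, n_samples=6, lib=1e6):
        """Build counts whose CPM values are exactly the targets."""
        rows = {}
        for g, per_sample in cpm_targets.items():
            rows[g] = [c * lib / 1e6 for c in per_sample]
        df = pd.DataFrame(rows, index=[f"s{i}" for i in range(n_samples)]).T
        # pad with a fat constant gene so library size is dominated elsewhere
        df.loc["pad"] = lib - df.sum(axis=0)
        return df

    def test_boundary_three_samples_retained(self):
        counts = self.matrix({"g": [0.26, 0.26, 0.26, 0.0, 0.0, 0.0]})
        kept, _ = cpm_filter(counts)
        assert "g" in kept.index

    def test_boundary_two_samples_excluded(self):
        counts = self.matrix({"g": [0.26, 0.26, 0.0, 0.0, 0.0, 0.0]})
        kept, _ = cpm_filter(counts)
        assert "g" not in kept.index

    def test_threshold_is_strict(self):
        counts = self.matrix({"g": [0.25, 0.25, 0.25, 0.25, 0.25, 0.25]})
        kept, _ = cpm_filter(counts)
        assert "g" not in kept.index

    def test_all_zero_gene_excluded(self):
        counts = self.matrix({"g": [0.0] * 6})
        kept, n_excluded = cpm_filter(counts)
        assert "g" not in kept.index

    def test_conservation(self, rng):
        counts = pd.DataFrame(rng.poisson(2.0, (300, 6)),
                              index=[f"g{i}" for i in range(300)])
        counts.iloc[0] += 10000
        kept, n_excluded = cpm_filter(counts)
        assert len(kept) + n_excluded == 300

    def test_zero_library_is_error(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]})
        with pytest.raises(ValueError):
            cpm_filter(counts)


class TestTmm:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"s1": [100, 300, 50, 800],
                               "s2": [100, 300, 50, 800],
                               "s3": [100, 300, 50, 800]})
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_change_unit_factors(self, rng):
        base = rng.gamma(2.0, 100.0, 500)
        counts = pd.DataFrame({"s1": base.round(), "s2": (2 * base).round()})
        fac = tmm_factors(counts)
        # identical composition: factors stay at 1, depth handled by library size
        assert np.allclose(fac, 1.0, atol=0.02)

    def test_geometric_mean_is_one(self, rng):
        counts = pd.DataFrame(rng.poisson(rng.gamma(2, 50, (400, 5))),
                              index=[f"g{i}" for i in range(400)])
        fac = tmm_factors(counts + 1)
        assert np.exp(np.mean(np.log(fac))) == pytest.approx(1.0)

    def test_matches_edger_on_composition_biased_mix(self, rng, tmp_path):
        import subprocess

        n = 1500
        base = rng.gamma(2.0, 100.0, n)
        counts = pd.DataFrame({
            "s1": rng.poisson(base),
            "s2": rng.poisson(base * 2.0),
            "s3": rng.poisson(np.where(np.arange(n) < 80, base * 8, base)),
            "s4": rng.poisson(base * 0.7),
        }, index=[f"g{i}" for i in range(n)])
        mine = tmm_factors(counts).to_numpy()
        cpath = tmp_path / "c.tsv"
        counts.to_csv(cpath, sep="\t")
        script = (
            'suppressMessages(library(edgeR));'
            f'x <- read.delim("{cpath}", row.names=1);'
            'cat(paste(calcNormFactors(as.matrix(x), method="TMM"), collapse=","))'
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        theirs = np.array([float(v) for v in res.stdout.strip().split(",")])
        assert np.allclose(mine, theirs, rtol=0.05)

    def test_no_shared_expression_is_error(self):
        counts = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]})
        with pytest.raises(ValueError, match="shares no"):
            tmm_factors(counts)


class TestRnaseqDegs:
    def test_null_simulation_near_zero_degs(self, rng):
        from fibroscreen.synth import generate_rnaseq_counts

        counts, ann, _ = generate_rnaseq_counts(77, n_genes=2000, n_spiked=0)
        kept, _ = cpm_filter(counts)
        lc = log_cpm(kept, tmm_factors(kept))
        table = rnaseq_degs(lc, ann, "treated", "control")
        assert table.discovery.sum() <= 2

    def test_fold_change_gate_excludes_sub_threshold_spikes(self, rng):
        from fibroscreen.synth import generate_rnaseq_counts

        counts, ann, spiked = generate_rnaseq_counts(
            5, n_genes=2000, n_spiked=40, spike_log2fc=1.2)
        kept, _ = cpm_filter(counts)
        lc = log_cpm(kept, tmm_factors(kept))
        table = rnaseq_degs(lc, ann, "treated", "control")
        hits = set(table.loc[table.discovery, "feature_id"])
        # |log2FC| = 1.2 < 1.3: the effect gate removes them regardless of p
        assert len(hits & set(spiked)) / len(spiked) <= 0.2


def test_top_expressed_fraction_limits(rng):
    counts = pd.DataFrame(np.ones((10, 3)))
    assert top_expressed_fraction(counts, 10) == pytest.approx(1.0)
    assert top_expressed_fraction(counts, 5) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        top_expressed_fraction(counts, 0)


def test_read_gmt(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("pw1\tdesc\tg1\tg2\tg3\npw2\tdesc\tg9\n\n")
    sets = read_gmt(p)
    assert sets == {"pw1": {"g1", "g2", "g3"}, "pw2": {"g9"}}
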