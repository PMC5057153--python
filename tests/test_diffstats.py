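"""Empirical thresholds, per-gene t statistics, volcano calls and ratio medians."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polpause.diffstats import (ThresholdSpec, classify_volcano, differential_test,
                                empirical_threshold, expressed_mask, fold_change,
                                approx_fold, ratio_median)
from polpause.genome_model import ExperimentDesign
from polpause.synthetic_data import SimulationConfig, simulate_design, \
    simulate_annotation, simulate_rna_counts


def _rna_design(n=4):
    rows = [(f"v{i}", "rna", "vehicle", pd.NA) for i in range(n)] + \
           [(f"d{i}", "rna", "ddavp", pd.NA) for i in range(n)]
    return ExperimentDesign(pd.DataFrame(rows, columns=["sample_id", "assay",
                                                        "condition", "pair_id"]))


def _chip_design(n_pairs=3):
    rows = []
    for i in range(n_pairs):
        rows.append((f"cv{i}", "chip", "vehicle", i))
        rows.append((f"cd{i}", "chip", "ddavp", i))
    return ExperimentDesign(pd.DataFrame(rows, columns=["sample_id", "assay",
                                                        "condition", "pair_id"]))


class TestEmpiricalThreshold:
    def test_self_pairs_give_zero_threshold(self, rng):
        vals = rng.random(100) * 50
        spec = empirical_threshold([(vals, vals)] * 3)
        assert spec.se_cc == 0.0 and spec.ratio_threshold == 0.0

    def test_median_of_pair_sds(self):
        # two-gene pairs built so each pair's log2-ratio SD (ddof=1) is exact:
        # ratios (+x, -x) have SD x*sqrt(2), so x = target / sqrt(2)
        pairs = []
        base = np.array([64.0, 64.0])
        for target in (0.1, 0.2, 0.4):
            x = target / np.sqrt(2)
            pairs.append((base * 2.0 ** np.array([x, -x]), base))
        spec = empirical_threshold(pairs, pseudocount=0.0)
        assert spec.se_cc == pytest.approx(0.2)
        assert spec.ratio_threshold == pytest.approx(0.4)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            empirical_threshold([])

    def test_threshold_grows_with_noise(self):
        """More overdispersion in the counts widens the empirical null band."""
        meds = []
        for disp in (0.01, 0.05, 0.2):
            sds = []
            for seed in range(5):
                cfg = SimulationConfig(seed=seed, n_genes=150, noise_dispersion=disp,
                                       archetype_fractions={"unresponsive": 1.0,
                                                            "initiation_only": 0.0,
                                                            "elongation_up": 0.0,
                                                            "elongation_down": 0.0})
                genes, _, truth = simulate_annotation(cfg)
                counts = simulate_rna_counts(genes, truth, cfg)
                pairs = [(counts["rna_vehicle_1"].values, counts["rna_vehicle_2"].values),
                         (counts["rna_vehicle_3"].values, counts["rna_vehicle_4"].values),
                         (counts["rna_vehicle_5"].values, counts["rna_vehicle_6"].values)]
                sds.append(empirical_threshold(pairs).ratio_threshold)
            meds.append(np.median(sds))
        assert meds[0] < meds[1] < meds[2]


class TestDifferentialTest:
    def test_identical_groups_null(self, rng):
        vals = rng.random((20, 4)) * 100
        matrix = pd.DataFrame(np.hstack([vals, vals]),
                              columns=[f"v{i}" for i in range(4)] + [f"d{i}" for i in range(4)])
        out = differential_test(matrix, _rna_design(4), "rna")
        assert np.allclose(out["effect"], 0) and np.allclose(out["t"], 0)
        assert np.allclose(out["p"], 1.0)

    def test_label_swap_antisymmetry(self, rng):
        matrix = pd.DataFrame(rng.integers(1, 1000, size=(30, 8)).astype(float),
                              columns=[f"v{i}" for i in range(4)] + [f"d{i}" for i in range(4)])
        design = _rna_design(4)
        swapped = ExperimentDesign(design.table.assign(
            condition=design.table["condition"].map(
                {"vehicle": "ddavp", "ddavp": "vehicle"})))
        a = differential_test(matrix, design, "rna")
        b = differential_test(matrix, swapped, "rna")
        assert np.allclose(a["effect"], -b["effect"])
        assert np.allclose(a["p"], b["p"])

    def test_paired_chip_matches_one_sample_t(self, rng):
        matrix = pd.DataFrame(rng.integers(10, 2000, size=(25, 6)).astype(float),
                              columns=["cv0", "cd0", "cv1", "cd1", "cv2", "cd2"])
        out = differential_test(matrix, _chip_design(3), "chip", pseudocount=0.5)
        ratios = np.log2(matrix[["cd0", "cd1", "cd2"]].values + 0.5) - \
            np.log2(matrix[["cv0", "cv1", "cv2"]].values + 0.5)
        t_ref, p_ref = stats.ttest_1samp(ratios, 0.0, axis=1)
        assert np.allclose(out["t"], t_ref) and np.allclose(out["p"], p_ref)
        assert np.allclose(out["effect"], ratios.mean(axis=1))

    def test_welch_matches_scipy(self, rng):
        matrix = pd.DataFrame(rng.integers(1, 500, size=(40, 8)).astype(float),
                              columns=[f"v{i}" for i in range(4)] + [f"d{i}" for i in range(4)])
        out = differential_test(matrix, _rna_design(4), "rna", pseudocount=0.5)
        lv = np.log2(matrix[[f"v{i}" for i in range(4)]].values + 0.5)
        ld = np.log2(matrix[[f"d{i}" for i in range(4)]].values + 0.5)
        t_ref, p_ref = stats.ttest_ind(ld, lv, axis=1, equal_var=False)
        assert np.allclose(out["t"], t_ref) and np.allclose(out["p"], p_ref)

    def test_permuted_labels_give_uniform_pvalues(self):
        """With condition labels randomly reassigned, P values are null-distributed."""
        cfg = SimulationConfig(seed=5, n_genes=600)
        genes, _, truth = simulate_annotation(cfg)
        counts = simulate_rna_counts(genes, truth, cfg)
        design = simulate_design(cfg)
        rng = np.random.default_rng(99)
        perm = design.table.copy()
        rna_mask = perm["assay"] == "rna"
        perm.loc[rna_mask, "condition"] = rng.permutation(
            perm.loc[rna_mask, "condition"].values)
        out = differential_test(counts, ExperimentDesign(perm), "rna")
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_nonfinite_values_rejected(self):
        matrix = pd.DataFrame({"v0": [1.0], "v1": [2.0], "d0": [np.nan], "d1": [1.0]})
        with pytest.raises(ValueError, match="non-finite"):
            differential_test(matrix, _rna_design(2), "rna")


class TestClassifyVolcano:
    THRESHOLDS = ThresholdSpec(alpha=0.05, se_cc=0.25, ratio_threshold=0.5)

    @pytest.mark.parametrize("effect,p,expected", [
        (4.52, 1e-4, "up"),       # extreme-responder magnitudes
        (3.0, 0.2, "ns"),         # fails the P gate
        (0.5, 1e-4, "ns"),        # exactly at threshold: strict inequality
        (-0.9, 0.01, "down"),
        (-0.5, 0.01, "ns"),
    ])
    def test_dual_criterion_calls(self, effect, p, expected):
        table = pd.DataFrame({"effect": [effect], "se": [0.1], "t": [1.0], "p": [p]})
        assert classify_volcano(table, self.THRESHOLDS)["call"].iloc[0] == expected

    def test_calls_invariant_under_sample_rescaling(self, rng):
        """Rescaling every sample by its own factor is absorbed by TPM
        normalization, leaving effects, P values and calls unchanged."""
        from polpause.quantify import compute_tpm
        counts = pd.DataFrame(rng.integers(1, 2000, size=(50, 8)).astype(float),
                              columns=[f"v{i}" for i in range(4)] + [f"d{i}" for i in range(4)])
        lengths = pd.Series(rng.integers(500, 5000, size=50).astype(float),
                            index=counts.index)
        design = _rna_design(4)
        factors = rng.uniform(0.5, 2.0, size=8)
        t1 = compute_tpm(counts, lengths).tpm
        t2 = compute_tpm(counts * factors, lengths).tpm
        a = classify_volcano(differential_test(t1, design, "rna"), self.THRESHOLDS)
        b = classify_volcano(differential_test(t2, design, "rna"), self.THRESHOLDS)
        assert np.allclose(a["effect"], b["effect"]) and (a["call"] == b["call"]).all()


class TestRatioMedian:
    def test_odd_and_even(self):
        assert ratio_median([-1.0, 0.0, 1.0]) == 0.0
        assert ratio_median([0.2, 0.4, 0.9, 1.1]) == pytest.approx(0.65)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ratio_median([])


class TestHelpers:
    def test_expressed_mask_requires_all_samples(self):
        m = pd.DataFrame({"a": [1.0, 0.0], "b": [2.0, 3.0]})
        assert expressed_mask(m).tolist() == [True, False]

    def test_fold_change_presentation(self):
        assert fold_change(1.0) == 2.0
        # conventional 'approximately N-fold': integer part of the magnitude
        assert approx_fold(2.78) == 6  # and 2**2.78 = 6.87
        assert approx_fold(-1.0) == 2
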