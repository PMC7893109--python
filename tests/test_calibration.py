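"""Calibration: thresholds, emission fitting, end-to-end, platform port."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from pathsig import (
    CalibrationConfig,
    CalibrationError,
    CohortSpec,
    ConfigurationError,
    EmissionParameters,
    ExpressionMatrix,
    GroundTruthLabels,
    PriorParameters,
    ProbeEmission,
    build_model,
    calibrate,
    derive_thresholds,
    fit_emissions,
    infer,
    normalize_cq,
    port_platform,
    score_cohort,
    simulate_cohort,
    simulate_cq,
    simulate_from_model,
    uniform_panel,
)

from conftest import default_emissions


def _matrix(data: dict[str, list[float]], probes: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(values=pd.DataFrame(data, index=probes))


def _panel2():
    return uniform_panel("P", 2)


def _auc(model, matrix, labels) -> float:
    cohort = score_cohort(model, matrix)
    y = [1 if labels[r.sample_id] == "active" else 0 for r in cohort.results]
    return roc_auc_score(y, [r.score for r in cohort.results])


class TestDeriveThresholds:
    def test_midpoint_of_class_medians(self):
        m = _matrix(
            {"a1": [8.0, 8.0], "a2": [8.0, 8.0], "i1": [4.0, 4.0], "i2": [4.0, 4.0]},
            ["G1_p1", "G2_p1"],
        )
        labels = GroundTruthLabels(
            {"a1": "active", "a2": "active", "i1": "inactive", "i2": "inactive"}
        )
        t = derive_thresholds(m, labels, _panel2())
        assert t == {"G1_p1": 6.0, "G2_p1": 6.0}

    def test_identical_class_medians_give_that_value(self):
        m = _matrix(
            {"a1": [5.0, 5.0], "a2": [5.0, 5.0], "i1": [5.0, 5.0], "i2": [5.0, 5.0]},
            ["G1_p1", "G2_p1"],
        )
        labels = GroundTruthLabels(
            {"a1": "active", "a2": "active", "i1": "inactive", "i2": "inactive"}
        )
        t = derive_thresholds(m, labels, _panel2())
        assert t["G1_p1"] == 5.0

    def test_repressed_gene_same_threshold_flipped_lr(self):
        """A -1 gene with inverted class medians gets the same midpoint, but
        its downstream likelihood-ratio sign flips versus a +1 gene."""
        panel = uniform_panel("P", 2, directions=[+1, -1])
        # G1 (+1): active high; G2 (-1): active low
        m = _matrix(
            {
                "a1": [8.0, 4.0], "a2": [8.0, 4.0],
                "i1": [4.0, 8.0], "i2": [4.0, 8.0],
            },
            ["G1_p1", "G2_p1"],
        )
        labels = GroundTruthLabels(
            {"a1": "active", "a2": "active", "i1": "inactive", "i2": "inactive"}
        )
        t = derive_thresholds(m, labels, panel)
        assert t == {"G1_p1": 6.0, "G2_p1": 6.0}
        model = calibrate(panel, m, labels)
        r = infer(model, pd.Series({"G1_p1": 8.0, "G2_p1": 8.0}), "s")
        assert r.contributions["G1"] > 0
        assert r.contributions["G2"] == pytest.approx(
            -r.contributions["G1"], abs=1e-9
        )

    def test_missing_probe_is_configuration_error(self):
        m = _matrix({"a1": [8.0], "i1": [4.0]}, ["G1_p1"])
        labels = GroundTruthLabels({"a1": "active", "i1": "inactive"})
        with pytest.raises(ConfigurationError, match="G2_p1"):
            derive_thresholds(m, labels, _panel2())

    def test_empty_class_is_calibration_error(self):
        m = _matrix({"a1": [8.0, 8.0], "a2": [8.0, 8.0]}, ["G1_p1", "G2_p1"])
        labels = GroundTruthLabels({"a1": "active", "a2": "active"})
        with pytest.raises(CalibrationError):
            derive_thresholds(m, labels, _panel2())


class TestFitEmissions:
    def _labels(self, n_act: int, n_inact: int) -> GroundTruthLabels:
        d = {f"a{i}": "active" for i in range(n_act)}
        d.update({f"i{i}": "inactive" for i in range(n_inact)})
        return GroundTruthLabels(d)

    def test_laplace_smoothed_counts(self):
        # 90 of 100 up-class (active) samples above t, 0 of 10 down-class
        rng = np.random.default_rng(0)
        cols = {}
        for i in range(100):
            v = 8.0 if i < 90 else 4.0
            cols[f"a{i}"] = [v, v]
        for i in range(10):
            cols[f"i{i}"] = [4.0, 4.0]
        m = _matrix(cols, ["G1_p1", "G2_p1"])
        labels = self._labels(100, 10)
        em = fit_emissions(
            m, labels, _panel2(), {"G1_p1": 6.0, "G2_p1": 6.0},
            CalibrationConfig(smoothing_alpha=1.0),
        )
        assert em["G1_p1"].p_high_given_up == pytest.approx(91 / 102, abs=1e-12)
        assert em["G1_p1"].p_high_given_down == pytest.approx(1 / 12, abs=1e-12)

    def test_probabilities_never_exactly_zero_or_one(self):
        # all up-class samples above t: smoothing keeps p < 1
        cols = {f"a{i}": [9.0, 9.0] for i in range(5)}
        cols.update({f"i{i}": [3.0, 3.0] for i in range(5)})
        m = _matrix(cols, ["G1_p1", "G2_p1"])
        em = fit_emissions(
            m, self._labels(5, 5), _panel2(), {"G1_p1": 6.0, "G2_p1": 6.0}
        )
        for probe_em in em.probe_emissions.values():
            assert 0.0 < probe_em.p_high_given_up < 1.0
            assert 0.0 < probe_em.p_high_given_down < 1.0

    def test_single_sample_per_class_rejected(self):
        m = _matrix({"a0": [8.0, 8.0], "i0": [4.0, 4.0]}, ["G1_p1", "G2_p1"])
        with pytest.raises(CalibrationError, match=">= 2"):
            fit_emissions(
                m, self._labels(1, 1), _panel2(),
                {"G1_p1": 6.0, "G2_p1": 6.0},
                CalibrationConfig(min_samples_per_class=2),
            )

    def test_zero_smoothing_rejected(self):
        with pytest.raises(ConfigurationError, match="smoothing_alpha"):
            CalibrationConfig(smoothing_alpha=0.0)


class TestCalibrateEndToEnd:
    def test_heldout_separation_is_excellent(self):
        panel = uniform_panel("Wnt", 12)
        train, train_labels = simulate_cohort(
            CohortSpec(panel=panel, n_active=50, n_inactive=50, seed=7)
        )
        model = calibrate(panel, train, train_labels)
        test, test_labels = simulate_cohort(
            CohortSpec(panel=panel, n_active=50, n_inactive=50, seed=8)
        )
        assert _auc(model, test, test_labels) >= 0.99

    def test_shuffled_labels_destroy_signal(self):
        """Permutation control: the expected held-out AUC under label
        shuffling is 0.5. Any single permutation can give an extreme AUC
        (residual emission differences share the same permuted labels, so
        they are correlated across genes and still rank samples), so the
        expectation is estimated over many permutations."""
        panel = uniform_panel("Wnt", 12)
        matrix, labels = simulate_cohort(
            CohortSpec(panel=panel, n_active=50, n_inactive=50, seed=7)
        )
        rng = np.random.default_rng(1)
        aucs = []
        test, test_labels = simulate_cohort(
            CohortSpec(panel=panel, n_active=30, n_inactive=30, seed=8)
        )
        for _ in range(200):
            ids = list(labels.sample_ids)
            perm = rng.permutation([labels[s] for s in ids])
            shuffled = GroundTruthLabels(dict(zip(ids, perm)))
            model = calibrate(panel, matrix, shuffled)
            aucs.append(_auc(model, test, test_labels))
        assert abs(float(np.mean(aucs)) - 0.5) <= 0.1

    def test_shuffled_labels_give_near_zero_gene_lrs(self):
        panel = uniform_panel("Wnt", 12)
        matrix, labels = simulate_cohort(
            CohortSpec(panel=panel, n_active=100, n_inactive=100, seed=7)
        )
        rng = np.random.default_rng(2)
        ids = list(labels.sample_ids)
        perm = rng.permutation([labels[s] for s in ids])
        model = calibrate(panel, matrix, GroundTruthLabels(dict(zip(ids, perm))))
        sample = matrix.sample(ids[0])
        r = infer(model, sample, ids[0])
        informative = calibrate(panel, matrix, labels)
        r_inf = infer(informative, sample, ids[0])
        assert max(abs(v) for v in r.contributions.values()) < 0.5 * max(
            abs(v) for v in r_inf.contributions.values()
        )

    def test_provenance_recorded(self):
        panel = uniform_panel("Wnt", 12)
        matrix, labels = simulate_cohort(
            CohortSpec(panel=panel, n_active=10, n_inactive=12, seed=3)
        )
        model = calibrate(panel, matrix, labels)
        prov = model.metadata["calibration"]
        assert prov["n_active"] == 10
        assert prov["n_inactive"] == 12
        assert prov["smoothing_alpha"] == 1.0


class TestParameterRecovery:
    def test_recalibration_recovers_generating_parameters(self):
        """Simulating from a model's own parameters and recalibrating must
        recover each emission probability to +-0.05 and each threshold to
        +-0.2 at n = 500 per class."""
        panel = uniform_panel("P", 6)
        priors = PriorParameters.defaults(panel)
        rng = np.random.default_rng(17)
        ems = {
            p: ProbeEmission(
                float(rng.uniform(5.0, 8.0)),
                float(rng.uniform(0.7, 0.95)),
                float(rng.uniform(0.05, 0.3)),
            )
            for p in panel.probe_ids
        }
        truth = build_model(panel, priors, EmissionParameters(ems))
        matrix, labels = simulate_from_model(truth, 500, 500, seed=21)
        refit = calibrate(panel, matrix, labels)
        for probe in panel.probe_ids:
            got = refit.emissions[probe]
            want = truth.emissions[probe]
            assert got.threshold == pytest.approx(want.threshold, abs=0.2)
            assert got.p_high_given_up == pytest.approx(
                want.p_high_given_up, abs=0.05
            )
            assert got.p_high_given_down == pytest.approx(
                want.p_high_given_down, abs=0.05
            )


class TestPortPlatform:
    def test_cross_platform_score_correlation(self):
        from scipy.stats import spearmanr

        panel = uniform_panel("ER", 12, reference_gene_ids=["REFA", "REFB"])
        cal_spec = CohortSpec(panel=panel, n_active=50, n_inactive=50, seed=31)
        intensity, labels = simulate_cohort(cal_spec)
        model = calibrate(panel, intensity, labels)

        cq, _ = simulate_cq(cal_spec)
        cq_matrix = normalize_cq(cq)
        ported = port_platform(model, cq_matrix, labels)
        assert ported.platform_tag == "cq-normalized"

        test_spec = CohortSpec(panel=panel, n_active=40, n_inactive=40, seed=32)
        test_int, _ = simulate_cohort(test_spec)
        test_cq, _ = simulate_cq(test_spec)
        s_int = score_cohort(model, test_int).scores()
        s_cq = score_cohort(ported, normalize_cq(test_cq)).scores()
        rho = spearmanr(s_int, s_cq.reindex(s_int.index)).statistic
        assert rho >= 0.9

    def test_priors_and_directions_retained(self):
        panel = uniform_panel("P", 4, directions=[+1, +1, -1, -1])
        spec = CohortSpec(panel=panel, n_active=30, n_inactive=30, seed=5)
        matrix, labels = simulate_cohort(spec)
        model = calibrate(panel, matrix, labels)
        matrix2, _ = simulate_cohort(
            CohortSpec(panel=panel, n_active=30, n_inactive=30, seed=6)
        )
        ported = port_platform(model, matrix2, labels)
        assert ported.priors == model.priors
        assert ported.panel == model.panel

    def test_reduced_panel_subset(self):
        panel = uniform_panel("P", 6)
        spec = CohortSpec(panel=panel, n_active=30, n_inactive=30, seed=5)
        matrix, labels = simulate_cohort(spec)
        model = calibrate(panel, matrix, labels)
        reduced = uniform_panel("P", 3)
        ported = port_platform(model, matrix, labels, panel=reduced)
        assert ported.panel.gene_ids == ("G1", "G2", "G3")

    def test_empty_new_matrix_is_error(self):
        panel = uniform_panel("P", 2)
        spec = CohortSpec(panel=panel, n_active=5, n_inactive=5, seed=5)
        matrix, labels = simulate_cohort(spec)
        model = calibrate(panel, matrix, labels)
        empty = ExpressionMatrix(
            values=pd.DataFrame(index=["G1_p1", "G2_p1"], dtype=float)
        )
        with pytest.raises(CalibrationError, match="no samples"):
            port_platform(model, empty, labels)

    def test_missing_probe_in_new_matrix_is_error(self):
        panel = uniform_panel("P", 2)
        spec = CohortSpec(panel=panel, n_active=5, n_inactive=5, seed=5)
        matrix, labels = simulate_cohort(spec)
        model = calibrate(panel, matrix, labels)
        partial = ExpressionMatrix(values=matrix.values.iloc[[0]])
        with pytest.raises(ConfigurationError, match="G2_p1"):
            port_platform(model, partial, labels)

    def test_pure_noise_port_collapses_dynamic_range(self):
        """If the 'new platform' carries no label signal (shuffled labels),
        the ported model's achievable log2 odds collapse toward zero."""
        panel = uniform_panel("P", 12)
        spec = CohortSpec(panel=panel, n_active=50, n_inactive=50, seed=13)
        matrix, labels = simulate_cohort(spec)
        model = calibrate(panel, matrix, labels)
        rng = np.random.default_rng(14)
        ids = list(labels.sample_ids)
        perm = rng.permutation([labels[s] for s in ids])
        shuffled = GroundTruthLabels(dict(zip(ids, perm)))
        ported = port_platform(model, matrix, shuffled)
        assert ported.l_max < 0.2 * model.l_max
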