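import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from scmalig import (GeneratorConfig, PerfectSeparationError, ScoreModel,
                     attach_scaling, choose_cutoff, evaluate,
                     fit_final_logistic, lognormalize, reference_model,
                     score, synthgen)
from scmalig.qc_norm import ScalingStats
from scmalig.scms_model import coefficient_standard_errors
from conftest import make_matrix
from _oracles import grid_logistic_1d


def simulate_logistic(rng, beta0, beta, n):
    p = len(beta)
    X = rng.normal(size=(p, n))
    prob = expit(beta0 + np.asarray(beta) @ X)
    y = (rng.random(n) < prob).astype(int)
    return X, y


class TestFitFinalLogistic:
    def test_symmetric_balanced_toy_has_zero_intercept(self):
        # invariant under (x, y) -> (-x, 1 - y), so the MLE intercept is 0
        X = np.array([[-2.0, -1.0, 1.0, 2.0]])
        y = np.array([0, 1, 0, 1])
        model = fit_final_logistic(X, y, ["g"])
        assert model.intercept == pytest.approx(0.0, abs=1e-8)

    def test_matches_grid_search_oracle_on_tiny_toy(self, rng):
        x = rng.normal(size=20)
        y = (rng.random(20) < expit(0.5 + 1.0 * x)).astype(int)
        model = fit_final_logistic(x[None, :], y, ["g"])
        b0, b1 = grid_logistic_1d(x, y)
        assert model.intercept == pytest.approx(b0, abs=1e-3)
        assert model.coefficients["g"] == pytest.approx(b1, abs=1e-3)

    def test_parameter_recovery_within_three_se(self, rng):
        beta0, beta = -1.0, [0.8, -0.5, 1.2]
        X, y = simulate_logistic(rng, beta0, beta, 4000)
        model = fit_final_logistic(X, y, ["a", "b", "c"])
        se = coefficient_standard_errors(X, y, model)
        assert abs(model.intercept - beta0) < 3 * se["(intercept)"]
        for g, true in zip(["a", "b", "c"], beta):
            assert abs(model.coefficients[g] - true) < 3 * se[g]

    def test_perfect_separation_detected(self):
        X = np.array([[-3.0, -2.0, -1.0, 1.0, 2.0, 3.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(PerfectSeparationError):
            fit_final_logistic(X, y, ["g"])
        # ridge fallback returns a finite fit instead
        model = fit_final_logistic(X, y, ["g"], ridge=1.0)
        assert np.isfinite(model.coefficients["g"])


class TestScore:
    def _model(self, cutoff=0.5):
        return ScoreModel(
            intercept=0.0,
            coefficients={"A": 1.0},
            scaling=ScalingStats(["A"], [2.0], [1.0]),
            cutoff=cutoff,
        )

    def test_zero_linear_score_gives_half(self):
        m = make_matrix([[2.0, 2.0]], ["malignant", "normal"], genes=["A"],
                        normalized=True)
        out = score(self._model(), m)
        assert np.allclose(out["scms"], 0.5)

    def test_monotone_in_positive_coefficient_gene(self):
        m = make_matrix([[1.0, 2.0, 3.0]], ["normal"] * 3, genes=["A"],
                        normalized=True)
        s = score(self._model(), m)["scms"].to_numpy()
        assert np.all(np.diff(s) > 0)

    def test_missing_gene_error_and_imputation(self):
        m = make_matrix([[1.0, 2.0]], ["malignant", "normal"], genes=["B"],
                        normalized=True)
        with pytest.raises(KeyError, match="A"):
            score(self._model(), m)
        with pytest.warns(UserWarning, match="imputing"):
            out = score(self._model(), m, impute_missing=True)
        assert np.allclose(out["scms"], 0.5)  # scaled 0 -> x = 0

    def test_unnormalized_input_rejected(self):
        m = make_matrix([[1.0, 2.0]], ["malignant", "normal"], genes=["A"])
        with pytest.raises(ValueError, match="normalized"):
            score(self._model(), m)
        out = score(self._model(), m, assume_normalized=True)
        assert len(out) == 2

    def test_predicted_label_uses_inclusive_cutoff(self):
        model = self._model(cutoff=0.5)
        m = make_matrix([[2.0]], ["normal"], genes=["A"], normalized=True)
        out = score(model, m)
        assert out["scms"][0] == 0.5
        assert out["predicted_label"][0] == "malignant"


class TestChooseCutoff:
    def test_invariant_to_duplicating_cells(self, rng):
        s = rng.uniform(size=40)
        labels = np.array(["malignant"] * 10 + ["normal"] * 30)
        c1 = choose_cutoff(s, labels)
        c2 = choose_cutoff(np.r_[s, s], np.r_[labels, labels])
        assert c1 == c2

    def test_low_prevalence_pushes_cutoff_below_half(self):
        cfg = GeneratorConfig(n_malignant=150, n_normal=1350,
                              informative_genes=(("G", 0.9, "up"),),
                              n_noise_genes=0, seed=13)
        m = synthgen.generate(cfg)
        norm = lognormalize(m)
        from scmalig import apply_scaling, fit_scaling
        scaled = apply_scaling(norm, fit_scaling(norm))
        model = fit_final_logistic(scaled.values, norm.y, ["G"],
                                   scaling=fit_scaling(norm))
        s = score(model, norm)["scms"].to_numpy()
        cutoff = choose_cutoff(s, norm.labels)
        assert 0 < cutoff < 0.5


class TestEvaluate:
    def test_perfect_model(self):
        model = ScoreModel(intercept=0.0, coefficients={"A": 5.0},
                           scaling=ScalingStats(["A"], [0.0], [1.0]),
                           cutoff=0.5)
        m = make_matrix([[3.0, 4.0, -3.0, -4.0]],
                        ["malignant", "malignant", "normal", "normal"],
                        genes=["A"], normalized=True)
        assert evaluate(model, m) == (1.0, 1.0, 1.0)

    def test_uninformative_gene_near_half(self, rng):
        model = ScoreModel(intercept=0.0, coefficients={"A": 1.0},
                           scaling=ScalingStats(["A"], [0.0], [1.0]),
                           cutoff=0.5)
        values = rng.normal(size=(1, 2000))
        labels = np.array(["malignant"] * 1000 + ["normal"] * 1000)
        m = make_matrix(values, labels, genes=["A"], normalized=True)
        auc, _, _ = evaluate(model, m)
        assert auc == pytest.approx(0.5, abs=0.05)


class TestReferenceModel:
    def test_published_parameters(self):
        ref = reference_model()
        assert ref.intercept == -4.7082
        assert ref.coefficients == {
            "KRT18": 0.8449, "IRX2": 0.7221, "NAPSA": 1.2584,
            "SPINK13": 2.3251, "KRT7": 1.5488, "CAPN8": 0.4969,
            "GPRC5A": 0.6344,
        }
        assert ref.cutoff == 0.046

    def test_scoring_requires_scaling_population(self, small_cohort):
        ref = reference_model()
        with pytest.raises(ValueError, match="scaling"):
            score(ref, lognormalize(small_cohort))

    def test_zero_scaled_cell_is_normal(self):
        ref = reference_model()
        genes = ref.genes
        # population whose mean expression equals the scored cell's values
        stats = ScalingStats(genes, np.linspace(1, 2, 7), np.ones(7))
        model = attach_scaling(ref, stats)
        cell = make_matrix(np.linspace(1, 2, 7)[:, None], ["normal"],
                           genes=genes, normalized=True)
        out = score(model, cell)
        assert out["scms"][0] == pytest.approx(expit(-4.7082), abs=1e-12)
        assert out["scms"][0] == pytest.approx(0.00896, abs=5e-5)
        assert out["predicted_label"][0] == "normal"

    def test_serialization_roundtrip_preserves_scores(self, tmp_path,
                                                      small_cohort):
        norm = lognormalize(small_cohort)
        ref = attach_scaling(reference_model(),
                             ScalingStats(reference_model().genes,
                                          np.zeros(7), np.ones(7)))
        cells = make_matrix(np.random.default_rng(0).normal(size=(7, 5)),
                            ["normal"] * 5, genes=ref.genes, normalized=True)
        before = score(ref, cells)["scms"]
        path = tmp_path / "model.json"
        ref.save(path)
        loaded = ScoreModel.load(path)
        assert loaded.intercept == ref.intercept
        assert loaded.coefficients == ref.coefficients
        after = score(loaded, cells)["scms"]
        assert np.allclose(before, after, atol=1e-12)
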