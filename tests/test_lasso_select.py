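import numpy as np
import pytest
import statsmodels.api as sm_api
from scipy.special import expit

from scmalig import GeneratorConfig, apply_scaling, cross_validate, \
    fit_l1_logistic_path, fit_scaling, lognormalize, select, synthgen
from scmalig.lasso_select import binomial_deviance, default_lambda_grid, \
    lambda_max


def scaled_instance(rng, n=300, p=6, informative=2, effect=1.2):
    """Random scaled design with a few informative features."""
    X = rng.normal(size=(p, n))
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    beta = np.zeros(p)
    beta[:informative] = effect
    y = (rng.random(n) < expit(-0.5 + beta @ X)).astype(int)
    return X, y


def kkt_violation(X, y, lam, beta, b0):
    """Max violation of the L1 stationarity conditions at (beta, b0)."""
    n = len(y)
    p_hat = expit(b0 + beta @ X)
    g = X @ (p_hat - y) / n
    viol = abs(np.mean(p_hat - y))  # unpenalized intercept
    for j in range(len(beta)):
        if beta[j] == 0:
            viol = max(viol, max(abs(g[j]) - lam, 0.0))
        else:
            viol = max(viol, abs(g[j] + lam * np.sign(beta[j])))
    return viol


class TestPathFit:
    def test_all_zero_at_lambda_max(self, rng):
        X, y = scaled_instance(rng)
        lmax = lambda_max(np.asfortranarray(X.T), y.astype(float))
        path = fit_l1_logistic_path(X, y, lambdas=np.array([2 * lmax, lmax]))
        assert np.all(path.coefficients == 0)
        assert np.all(path.nonzero_counts == 0)

    def test_lambda_zero_matches_unpenalized_mle(self, rng):
        X, y = scaled_instance(rng, n=400, p=4)
        lmax = lambda_max(np.asfortranarray(X.T), y.astype(float))
        grid = np.r_[default_lambda_grid(lmax, 8, 1e-3), 0.0]
        path = fit_l1_logistic_path(X, y, lambdas=grid, tol=1e-9)
        ref = sm_api.Logit(y, sm_api.add_constant(X.T)).fit(disp=0)
        assert path.intercepts[-1] == pytest.approx(ref.params[0], abs=1e-4)
        assert np.allclose(path.coefficients[:, -1], ref.params[1:], atol=1e-4)

    def test_kkt_conditions_along_path(self, rng):
        X, y = scaled_instance(rng, n=250, p=10, informative=3)
        path = fit_l1_logistic_path(X, y, n_lambda=25, tol=1e-9)
        Xn = X  # genes-by-cells; kkt helper uses same orientation
        for li, lam in enumerate(path.lambdas):
            v = kkt_violation(Xn, y, lam, path.coefficients[:, li],
                              path.intercepts[li])
            assert v < 1e-4, f"KKT violated at lambda index {li}: {v}"

    def test_noise_gene_zeroed_before_informative(self, rng):
        X, y = scaled_instance(rng, n=500, p=2, informative=1, effect=1.5)
        path = fit_l1_logistic_path(X, y, n_lambda=40)
        inf_alive = path.coefficients[0] != 0
        noise_alive = path.coefficients[1] != 0
        assert inf_alive.sum() > noise_alive.sum()
        # wherever the noise gene is active, the informative one is too
        assert np.all(inf_alive[noise_alive])

    def test_rejects_unscaled_and_non_binary(self, rng):
        X, y = scaled_instance(rng)
        with pytest.raises(ValueError, match="scaled"):
            fit_l1_logistic_path(X * 5 + 2, y)
        with pytest.raises(ValueError, match="binary"):
            fit_l1_logistic_path(X, y + 1)

    def test_path_reproducible(self, rng):
        X, y = scaled_instance(rng)
        a = fit_l1_logistic_path(X, y, n_lambda=15)
        b = fit_l1_logistic_path(X, y, n_lambda=15)
        assert np.array_equal(a.coefficients, b.coefficients)


class TestCrossValidate:
    def test_deterministic_for_fixed_seed(self, rng):
        X, y = scaled_instance(rng, n=200)
        a = cross_validate(X, y, n_folds=5, seed=3, n_lambda=12)
        b = cross_validate(X, y, n_folds=5, seed=3, n_lambda=12)
        assert np.array_equal(a.cv_mean_deviance, b.cv_mean_deviance)

    def test_lambda_max_deviance_equals_null_model(self, rng):
        X, y = scaled_instance(rng, n=400)
        path = cross_validate(X, y, n_folds=5, seed=0, n_lambda=10)
        null_dev = binomial_deviance(y, np.full(len(y), y.mean()))
        assert path.cv_mean_deviance[0] == pytest.approx(null_dev, rel=0.05)

    def test_stratification_impossible_errors(self, rng):
        X, y = scaled_instance(rng, n=30)
        y = np.zeros(30, dtype=int)
        y[:3] = 1
        with pytest.raises(ValueError, match="stratification"):
            cross_validate(X, y, n_folds=10)


@pytest.fixture(scope="module")
def cv_path():
    r = np.random.default_rng(5)
    X, y = scaled_instance(r, n=400, p=8, informative=3)
    return cross_validate(X, y, n_folds=5, seed=1, n_lambda=30)


class TestSelect:

    def test_cv_1se_lambda_at_least_cv_min(self, cv_path):
        assert select(cv_path, "cv_1se").chosen_lambda >= \
            select(cv_path, "cv_min").chosen_lambda

    def test_selected_genes_match_nonzero_coefficients(self, cv_path):
        sel = select(cv_path, "cv_min")
        idx = list(cv_path.lambdas).index(sel.chosen_lambda)
        nz = cv_path.coefficients[:, idx] != 0
        assert set(sel.selected_genes) == set(cv_path.genes[nz])

    def test_target_support_unreachable_error(self, cv_path):
        with pytest.raises(ValueError, match="attained"):
            select(cv_path, "support:999")

    def test_unknown_rule(self, cv_path):
        with pytest.raises(ValueError, match="rule"):
            select(cv_path, "magic")


class TestSupportRecovery:
    def test_target_support_recovers_planted_genes(self):
        """With strong planted genes among noise, the largest-lambda point
        with exactly k active coefficients is exactly the planted set."""
        cfg = GeneratorConfig(n_malignant=400, n_normal=3600,
                              n_noise_genes=100, seed=21)
        m = synthgen.generate(cfg)
        norm = lognormalize(m)
        scaled = apply_scaling(norm, fit_scaling(norm))
        path = fit_l1_logistic_path(scaled.values, norm.y,
                                    genes=norm.gene_names,
                                    n_lambda=40, lambda_min_ratio=3e-3)
        sel = select(path, "support:7")
        planted = {g.name for g in cfg.informative_genes}
        assert set(sel.selected_genes) == planted

    def test_cv_min_model_beats_every_single_gene(self):
        from scmalig import gene_auc
        cfg = GeneratorConfig(n_malignant=300, n_normal=2700,
                              n_noise_genes=20, seed=8)
        m = synthgen.generate(cfg)
        norm = lognormalize(m)
        genes = [g.name for g in cfg.informative_genes]
        scaled = apply_scaling(norm.subset_genes(genes),
                               fit_scaling(norm.subset_genes(genes)))
        path = cross_validate(scaled.values, norm.y, genes=genes, n_folds=5,
                              seed=2, n_lambda=30)
        sel = select(path, "cv_min")
        idx = list(path.lambdas).index(sel.chosen_lambda)
        combined = path.coefficients[:, idx] @ scaled.values
        combined_auc = gene_auc(combined, norm.labels)
        single = max(gene_auc(scaled.values[i], norm.labels)
                     for i in range(len(genes)))
        assert combined_auc > single
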