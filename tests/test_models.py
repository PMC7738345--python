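import numpy as np
import pytest
from scipy.special import expit

import leafndiff as L
from leafndiff.models import GaParams, decode_individual, encode_individual


@pytest.fixture(scope="module")
def nonlinear_problem():
    X, y = L.make_nonlinear_problem(n_samples=200, seed=0)
    return X[:150], y[:150], X[150:], y[150:]


class TestPlsr:
    def test_noiseless_linear_signal_fits_exactly(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(80, 6))
        y = 2.0 * X[:, 0] - X[:, 1] + 0.5 * X[:, 2]
        m = L.plsr_fit(X, y)
        assert L.r_squared(y, m.predict(X)) > 0.999

    def test_one_latent_univariate_equals_simple_regression(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 2.0 * x + 0.3 * rng.normal(size=40)
        m = L.plsr_fit(x[:, None], y, n_latent=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        expect = (x - x.mean()) * slope + y.mean()
        assert np.allclose(m.predict(x[:, None]), expect, atol=1e-8)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 4))
        y = X @ [1, 2, 0, -1] + 0.1 * rng.normal(size=50)
        m1 = L.plsr_fit(X, y, n_latent=3)
        perm = rng.permutation(50)
        m2 = L.plsr_fit(X[perm], y[perm], n_latent=3)
        assert np.allclose(m1.coef, m2.coef, atol=1e-10)

    def test_underdetermined_raises(self):
        with pytest.raises(ValueError):
            L.plsr_fit(np.ones((1, 3)), np.ones(1))


class TestElm:
    def test_interpolation_regime(self):
        """With more hidden nodes than samples, training error vanishes."""
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        net = L.elm_fit(X, y, s2=60, seed=0)
        assert L.rmse(y, net.predict(X)) < 1e-6

    def test_seeded_reproducibility(self, nonlinear_problem):
        Xtr, ytr, Xva, _ = nonlinear_problem
        a = L.elm_fit(Xtr, ytr, s2=15, seed=11)
        b = L.elm_fit(Xtr, ytr, s2=15, seed=11)
        assert np.array_equal(a.input_weights, b.input_weights)
        assert np.allclose(a.predict(Xva), b.predict(Xva), atol=0)

    def test_output_weights_match_normal_equations(self, nonlinear_problem):
        """Least-squares layer agrees with explicitly solved normal
        equations on the hidden activations."""
        Xtr, ytr, _, _ = nonlinear_problem
        net = L.elm_fit(Xtr, ytr, s2=12, seed=5)
        H = net.hidden(Xtr)
        A = np.column_stack([H, np.ones(len(H))])
        beta = np.linalg.solve(A.T @ A, A.T @ ytr)
        assert np.allclose(net.output_weights, beta, atol=1e-8)

    def test_residuals_orthogonal_to_hidden_activations(self, nonlinear_problem):
        Xtr, ytr, _, _ = nonlinear_problem
        net = L.elm_fit(Xtr, ytr, s2=12, seed=5)
        resid = ytr - net.predict(Xtr)
        assert np.max(np.abs(net.hidden(Xtr).T @ resid)) < 1e-6

    def test_invalid_hidden_count_raises(self, nonlinear_problem):
        Xtr, ytr, _, _ = nonlinear_problem
        with pytest.raises(ValueError):
            L.elm_fit(Xtr, ytr, s2=0)


class TestGaAlgebra:
    @pytest.mark.parametrize("s1,s2,s3,l", [(5, 10, 1, 71), (1, 1, 1, 4),
                                            (15, 20, 1, 341)])
    def test_individual_length(self, s1, s2, s3, l):
        assert L.individual_length(s1, s2, s3) == l

    @pytest.mark.parametrize("E,f", [(0.0, 1.0), (1.0, 0.5), (3.0, 0.25)])
    def test_fitness(self, E, f):
        assert L.fitness(E) == pytest.approx(f)

    def test_fitness_rejects_negative_error(self):
        with pytest.raises(ValueError):
            L.fitness(-0.1)

    def test_selection_probability(self):
        assert np.allclose(L.selection_probability([1, 1, 2]),
                           [0.25, 0.25, 0.5])
        assert np.allclose(L.selection_probability([3.0]), [1.0])
        assert np.allclose(L.selection_probability([2, 2, 2, 2]), 0.25)

    def test_selection_probability_empty_raises(self):
        with pytest.raises(ValueError):
            L.selection_probability([])

    def test_adaptive_rate_branches(self):
        # fittest individual: numerator vanishes
        assert L.adaptive_rate(0.9, 0.9, 0.5, 0.5) == 0.0
        # below-average individual: constant gain
        assert L.adaptive_rate(0.3, 0.9, 0.5, 0.5) == 0.5
        # branch point: both formulas agree at f_op = f_bar
        upper = 0.5 * (0.9 - 0.5) / (0.9 - 0.5)
        assert L.adaptive_rate(0.5, 0.9, 0.5, 0.5) == pytest.approx(upper) == 0.5
        # degenerate uniform population
        assert L.adaptive_rate(0.7, 0.7, 0.7, 0.5) == 0.0

    def test_encode_decode_bijection(self):
        rng = np.random.default_rng(7)
        for s1, s2 in [(5, 10), (1, 1), (8, 3)]:
            v = rng.normal(size=L.individual_length(s1, s2, 1))
            assert np.array_equal(
                encode_individual(decode_individual(v, s1, s2, 1)), v)

    def test_decode_wrong_length_raises(self):
        with pytest.raises(ValueError):
            decode_individual(np.zeros(10), 5, 10, 1)


class TestGaElm:
    def test_no_evolution_equals_best_random_initialization(self, nonlinear_problem):
        Xtr, ytr, _, _ = nonlinear_problem
        res = L.ga_elm_fit(Xtr, ytr, s2=8,
                           ga_params=GaParams(population=10, generations=0),
                           seed=2)
        assert len(res.best_fitness_history) == 1
        # the returned network reproduces the recorded best fitness
        E = L.rmse(ytr, res.network.predict(Xtr))
        assert L.fitness(E) == pytest.approx(res.best_fitness_history[0],
                                             rel=1e-10)

    def test_best_fitness_monotone_non_decreasing(self, nonlinear_problem):
        Xtr, ytr, _, _ = nonlinear_problem
        res = L.ga_elm_fit(Xtr, ytr, s2=8,
                           ga_params=GaParams(population=12, generations=15),
                           seed=3)
        assert np.all(np.diff(res.best_fitness_history) >= 0)
        assert res.best_fitness_history[-1] > res.best_fitness_history[0]

    def test_zero_gain_operators_keep_population_pure_selection(self, nonlinear_problem):
        """With k_c = k_m = 0 offspring are copies, so the best individual
        (and fitness) can never improve."""
        Xtr, ytr, _, _ = nonlinear_problem
        res = L.ga_elm_fit(Xtr, ytr, s2=8,
                           ga_params=GaParams(population=10, generations=10,
                                              k_c=0.0, k_m=0.0),
                           seed=4)
        h = res.best_fitness_history
        assert np.all(h == h[0])

    def test_seeded_reproducibility(self, nonlinear_problem):
        Xtr, ytr, Xva, _ = nonlinear_problem
        p = GaParams(population=8, generations=5)
        a = L.ga_elm_fit(Xtr, ytr, s2=6, ga_params=p, seed=9)
        b = L.ga_elm_fit(Xtr, ytr, s2=6, ga_params=p, seed=9)
        assert np.array_equal(a.best_individual, b.best_individual)
        assert np.allclose(a.network.predict(Xva), b.network.predict(Xva))

    def test_tiny_population_raises(self, nonlinear_problem):
        Xtr, ytr, _, _ = nonlinear_problem
        with pytest.raises(ValueError):
            GaParams(population=1)


class TestPredictAndSerialization:
    def test_hand_built_single_node_network(self):
        """One hidden node: prediction equals the closed-form sigmoid."""
        net = L.ElmNetwork(input_weights=np.array([[2.0]]),
                           hidden_bias=np.array([-0.5]),
                           output_weights=np.array([3.0, 0.25]),
                           x_mean=np.array([1.0]), x_scale=np.array([2.0]))
        x = 4.0
        z = (x - 1.0) / 2.0
        expect = 3.0 * expit(2.0 * z - 0.5) + 0.25
        assert L.predict(net, np.array([[x]]))[0] == pytest.approx(expect)

    def test_serialization_round_trip(self, nonlinear_problem, tmp_path):
        Xtr, ytr, Xva, _ = nonlinear_problem
        for model in (L.plsr_fit(Xtr, ytr, n_latent=3),
                      L.elm_fit(Xtr, ytr, s2=7, seed=1)):
            path = tmp_path / "model.json"
            L.save_model(model, path)
            loaded = L.load_model(path)
            assert np.allclose(L.predict(loaded, Xva),
                               L.predict(model, Xva), atol=1e-12)

    def test_feature_width_mismatch_raises(self, nonlinear_problem):
        Xtr, ytr, _, _ = nonlinear_problem
        net = L.elm_fit(Xtr, ytr, s2=5, seed=0)
        with pytest.raises(ValueError):
            L.predict(net, Xtr[:, :3])
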