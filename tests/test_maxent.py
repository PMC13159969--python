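"""Pairwise maximum-entropy model: closed forms, recovery, KL evaluation."""

import numpy as np
import pytest

from meapop.datatypes import BinarizedRaster, IsingParameters
from meapop.entropy import word_entropy
from meapop.maxent import (
    PairwiseIsingModel,
    empirical_word_distribution,
    enumerate_states,
    evaluate_fit,
    model_word_distribution,
    params_vs_statistics,
    split_train_test,
)
from meapop.synthetic import sample_ising_exact


def logit(x):
    return np.log(x / (1 - x))


class TestSplit:
    def test_even_split(self):
        r = BinarizedRaster(np.zeros((2, 1000), dtype=np.int8))
        a, b = split_train_test(r)
        assert a.n_bins == b.n_bins == 500

    def test_odd_split_differs_by_one(self):
        r = BinarizedRaster(np.zeros((2, 1001), dtype=np.int8))
        a, b = split_train_test(r)
        assert {a.n_bins, b.n_bins} == {500, 501}
        assert a.n_bins + b.n_bins == 1001

    def test_halves_of_stationary_data_agree(self, random_ising_k3):
        r = sample_ising_exact(random_ising_k3, 40_000, seed=2)
        a, b = split_train_test(r)
        ma, mb = a.matrix.mean(axis=1), b.matrix.mean(axis=1)
        se = np.sqrt(ma * (1 - ma) / a.n_bins)
        assert np.all(np.abs(ma - mb) < 4 * se)


class TestModelDistribution:
    def test_zero_parameters_uniform(self):
        p = IsingParameters(h=np.zeros(3), J=np.zeros((3, 3)))
        d = model_word_distribution(p)
        assert np.allclose(d.dense(), 1 / 8)

    def test_single_unit_sigmoid(self):
        p = IsingParameters(h=np.array([np.log(3.0)]), J=np.zeros((1, 1)))
        d = model_word_distribution(p).dense()
        assert d[1] == pytest.approx(0.75)
        assert d[0] == pytest.approx(0.25)

    def test_maximum_entropy_among_moment_matched(self, rng):
        """The Boltzmann distribution has the largest entropy of any
        distribution with the same first and second moments (checked against
        randomly perturbed moment-preserving distributions at K = 3)."""
        p = IsingParameters(h=rng.normal(0, 1, 3),
                            J=np.zeros((3, 3)))
        d = model_word_distribution(p)
        probs = d.dense()
        S = enumerate_states(3).astype(float)
        # features whose expectations must stay fixed
        iu, ju = np.triu_indices(3, 1)
        F = np.hstack([S, S[:, iu] * S[:, ju]])
        h_model = -(probs * np.log2(probs)).sum()
        # perturb within the null space of the constraint matrix [1, F]
        A = np.hstack([np.ones((8, 1)), F])
        _, _, vt = np.linalg.svd(A.T, full_matrices=True)
        null = vt[A.shape[1]:]
        for _ in range(20):
            delta = null.T @ rng.normal(0, 1, null.shape[0])
            q = probs + 1e-3 * delta / np.abs(delta).max()
            if np.any(q <= 0):
                continue
            q = q / q.sum()
            h_q = -(q * np.log2(q)).sum()
            assert h_q <= h_model + 1e-12


class TestFitClosedForms:
    def test_independent_data_recovers_logits(self, rng):
        p = np.array([0.1, 0.3, 0.5, 0.7])
        n = 100_000
        m = (rng.random((4, n)) < p[:, None]).astype(np.int8)
        res = PairwiseIsingModel(m).fit()
        emp = m.mean(axis=1)
        assert np.all(np.abs(res.params.h - logit(emp)) < 0.05)
        iu = np.triu_indices(4, 1)
        assert np.all(np.abs(res.params.J[iu]) < 0.05)

    def test_two_unit_saturated_solution(self):
        """K=2 has the exact log-odds solution in terms of joint counts."""
        n00, n01, n10, n11 = 400, 150, 250, 200
        cols = ([[0, 0]] * n00 + [[0, 1]] * n01 + [[1, 0]] * n10
                + [[1, 1]] * n11)
        m = np.array(cols).T
        res = PairwiseIsingModel(m).fit(tol=1e-8)
        # unit 0 is bit 0: pattern [s0, s1]; n10 means s0=1, s1=0
        assert res.params.h[0] == pytest.approx(np.log(n10 / n00), abs=1e-6)
        assert res.params.h[1] == pytest.approx(np.log(n01 / n00), abs=1e-6)
        assert res.params.J[0, 1] == pytest.approx(
            np.log(n11 * n00 / (n10 * n01)), abs=1e-6)

    def test_parameter_recovery_within_3se(self, rng):
        k = 5
        h = rng.normal(-1.5, 0.5, k)
        J = rng.normal(0, 0.4, (k, k))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0)
        truth = IsingParameters(h=h, J=J)
        data = sample_ising_exact(truth, 100_000, seed=17)
        res = PairwiseIsingModel(data).fit()
        iu = np.triu_indices(k, 1)
        est = np.concatenate([res.params.h, res.params.J[iu]])
        true_vec = np.concatenate([truth.h, truth.J[iu]])
        assert np.all(np.abs(est - true_vec) <= 3 * res.bse)


class TestFitDiagnostics:
    def test_moment_matching_at_convergence(self, random_ising_k3):
        data = sample_ising_exact(random_ising_k3, 20_000, seed=23)
        res = PairwiseIsingModel(data).fit(tol=1e-6)
        assert res.max_moment_residual <= 1e-6

    def test_model_entropy_at_least_empirical(self, random_ising_k3):
        data = sample_ising_exact(random_ising_k3, 20_000, seed=29)
        res = PairwiseIsingModel(data).fit()
        emp_h = word_entropy(data).value_bits
        assert res.entropy_bits() >= emp_h - 1e-9

    def test_silent_unit_clipped_with_warning(self):
        m = np.zeros((2, 1000), dtype=np.int8)
        m[0, ::10] = 1
        with pytest.warns(UserWarning, match="never or always"):
            model = PairwiseIsingModel(m)
        res = model.fit()
        assert np.all(np.isfinite(res.params.h))

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="K <= 14"):
            PairwiseIsingModel(np.zeros((15, 100), dtype=np.int8))

    def test_summary_mentions_units_and_residual(self, random_ising_k3):
        data = sample_ising_exact(random_ising_k3, 5_000, seed=31)
        res = PairwiseIsingModel(data).fit()
        s = res.summary()
        assert "Units (K):            3" in s
        assert "Max moment residual" in s

    def test_fit_deterministic(self, random_ising_k3):
        data = sample_ising_exact(random_ising_k3, 10_000, seed=37)
        r1 = PairwiseIsingModel(data).fit()
        r2 = PairwiseIsingModel(data).fit()
        assert np.array_equal(r1.params.h, r2.params.h)
        assert np.array_equal(r1.params.J, r2.params.J)


class TestEvaluateFit:
    def test_model_equal_to_empirical_gives_zero(self):
        m = np.array([[0, 0, 1, 1], [0, 1, 0, 1]] * 1, dtype=np.int8)
        emp = empirical_word_distribution(m)
        kld = evaluate_fit(emp, m)
        assert kld == pytest.approx(0.0, abs=1e-12)

    def test_synchronous_pair_vs_uniform_model_one_bit(self):
        m = np.array([[0, 1] * 500, [0, 1] * 500], dtype=np.int8)
        uniform = model_word_distribution(
            IsingParameters(h=np.zeros(2), J=np.zeros((2, 2))))
        assert evaluate_fit(uniform, m) == pytest.approx(1.0)

    def test_pairwise_data_beats_higher_order_data(self, rng):
        """Held-out KL-D is near zero for data truly generated by a pairwise
        model and bounded away from zero under planted triplet synchrony."""
        from meapop.synthetic import generate_triplet_synchrony_raster
        k, n = 6, 40_000
        h = np.full(k, logit(0.04))
        truth = IsingParameters(h=h, J=np.zeros((k, k)))
        pair_raster = sample_ising_exact(truth, n, seed=41)
        tri_raster = generate_triplet_synchrony_raster(
            k, n, background_p=0.03, sync_p=0.02, seed=43)
        klds = {}
        for name, raster in [("pair", pair_raster), ("tri", tri_raster)]:
            tr, te = split_train_test(raster)
            res = PairwiseIsingModel(tr).fit()
            klds[name] = res.evaluate(te)
        assert klds["tri"] > 3 * klds["pair"]
        assert klds["pair"] < 0.02


class TestParamsVsStatistics:
    def test_h_tracks_firing_rate(self, rng):
        from scipy.stats import spearmanr
        rates = np.linspace(0.01, 0.20, 8)
        m = (rng.random((8, 50_000)) < rates[:, None]).astype(np.int8)
        res = PairwiseIsingModel(m).fit()
        table = params_vs_statistics([res])
        hrows = table[table.kind == "h"]
        rho = spearmanr(hrows.param, hrows.statistic).statistic
        assert rho > 0.9

    def test_equal_rates_give_flat_h(self, rng):
        m = (rng.random((5, 100_000)) < 0.1).astype(np.int8)
        res = PairwiseIsingModel(m).fit()
        assert np.ptp(res.params.h) < 0.15

    def test_planted_positive_j_pairs_more_correlated(self, rng):
        k = 4
        J = np.zeros((k, k))
        J[0, 1] = J[1, 0] = 1.2
        truth = IsingParameters(h=np.full(k, -2.0), J=J)
        data = sample_ising_exact(truth, 50_000, seed=47)
        res = PairwiseIsingModel(data).fit()
        table = params_vs_statistics([res])
        jrows = table[table.kind == "J"].set_index(["i", "j"])
        coupled = jrows.loc[(0, 1)]
        others = jrows.drop(index=(0, 1))
        assert coupled.statistic > others.statistic.max()
        assert coupled.param > others.param.max()
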