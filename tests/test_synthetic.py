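"""Generators: exact Ising sampler, dichotomized Gaussian, voltage synthesis."""

import numpy as np
import pytest
from scipy import stats as sps

from meapop.datatypes import IsingParameters, check_correlation_matrix
from meapop.maxent import empirical_word_distribution, model_word_distribution
from meapop.synthetic import (
    WaveformTemplate,
    default_template,
    dichotomized_gaussian_correlation,
    generate_correlated_trains,
    generate_triplet_synchrony_raster,
    planted_recording,
    sample_ising_exact,
    synthesize_voltage,
    GroundTruth,
)


class TestIsingSampler:
    def test_single_unit_symmetry(self):
        # h = 0 makes spiking and silence equally likely
        p = IsingParameters(h=np.zeros(1), J=np.zeros((1, 1)))
        r = sample_ising_exact(p, 1_000_000, seed=7)
        assert abs(r.matrix.mean() - 0.5) < 0.002

    def test_independent_pair_marginals(self):
        logit = lambda x: np.log(x / (1 - x))
        p = IsingParameters(h=np.array([logit(0.2), logit(0.7)]),
                            J=np.zeros((2, 2)))
        r = sample_ising_exact(p, 200_000, seed=3)
        m = r.matrix.astype(float)
        assert np.allclose(m.mean(axis=1), [0.2, 0.7], atol=0.01)
        cov = np.cov(m)[0, 1]
        assert abs(cov) < 0.005

    def test_word_frequencies_match_enumeration(self, random_ising_k3):
        """Empirical word frequencies converge to the Boltzmann probabilities."""
        n = 1_000_000
        r = sample_ising_exact(random_ising_k3, n, seed=11)
        emp = empirical_word_distribution(r).dense()
        truth = model_word_distribution(random_ising_k3).dense()
        mc_se = np.sqrt(truth * (1 - truth) / n)
        assert np.all(np.abs(emp - truth) <= 3 * mc_se + 1e-12)

    def test_chi_square_goodness_of_fit(self, random_ising_k3):
        n = 1_000_000
        r = sample_ising_exact(random_ising_k3, n, seed=19)
        counts = np.bincount(
            r.matrix.astype(np.int64).T @ (1 << np.arange(3)), minlength=8)
        expected = model_word_distribution(random_ising_k3).dense() * n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert sps.chi2.sf(chi2, df=7) > 0.001

    def test_reproducible(self, random_ising_k3):
        a = sample_ising_exact(random_ising_k3, 1000, seed=5)
        b = sample_ising_exact(random_ising_k3, 1000, seed=5)
        assert np.array_equal(a.matrix, b.matrix)

    def test_k_too_large_refused(self):
        p = IsingParameters(h=np.zeros(17), J=np.zeros((17, 17)))
        with pytest.raises(ValueError, match="K <= 16"):
            sample_ising_exact(p, 10, seed=0)

    def test_asymmetric_j_rejected(self):
        J = np.zeros((2, 2))
        J[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            IsingParameters(h=np.zeros(2), J=J)


class TestDichotomizedGaussian:
    def test_independent_units_uncorrelated(self):
        trains, raster = generate_correlated_trains(
            [1.0, 1.0], np.eye(2), duration_s=1000.0, seed=21)
        r = np.corrcoef(raster.matrix.astype(float))[0, 1]
        assert abs(r) < 0.05

    def test_perfect_coupling_identical_trains(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]])
        trains, raster = generate_correlated_trains(
            [2.0, 2.0], corr, duration_s=500.0, seed=2)
        assert np.array_equal(raster.matrix[0], raster.matrix[1])
        assert np.array_equal(trains[0], trains[1])
        assert np.corrcoef(raster.matrix.astype(float))[0, 1] == pytest.approx(1.0)

    def test_measured_correlation_matches_orthant_formula(self):
        """Binarized correlation agrees with the bivariate-normal closed form."""
        lam = 0.5
        corr = np.full((3, 3), lam)
        np.fill_diagonal(corr, 1.0)
        rates = np.full(3, 2.0)
        _, raster = generate_correlated_trains(rates, corr, duration_s=2000.0,
                                               bin_s=0.010, seed=9)
        expected = dichotomized_gaussian_correlation(0.02, 0.02, lam)
        m = raster.matrix.astype(float)
        obs = np.corrcoef(m)
        iu = np.triu_indices(3, 1)
        assert np.all(np.abs(obs[iu] - expected) < 0.02)

    def test_rates_match_targets(self):
        rates = np.array([0.5, 2.0, 5.0])
        trains, _ = generate_correlated_trains(rates, np.eye(3),
                                               duration_s=2000.0, seed=4)
        measured = np.array([t.size for t in trains]) / 2000.0
        # binomial SE on rate·bin over n bins
        se = np.sqrt(rates * 0.01 * (1 - rates * 0.01) / 200_000) / 0.01
        assert np.all(np.abs(measured - rates) < 4 * se)

    def test_correlation_monotone_in_latent(self):
        obs = []
        for lam in [0.0, 0.2, 0.4, 0.6, 0.8]:
            corr = np.array([[1.0, lam], [lam, 1.0]])
            _, raster = generate_correlated_trains(
                [2.0, 2.0], corr, duration_s=1500.0, seed=33)
            obs.append(np.corrcoef(raster.matrix.astype(float))[0, 1])
        assert np.all(np.diff(obs) > 0)

    def test_infeasible_rate_rejected(self):
        with pytest.raises(ValueError, match="infeasible rate"):
            generate_correlated_trains([150.0], np.eye(1), 10.0, bin_s=0.01)

    def test_invalid_correlation_matrix_rejected(self):
        bad = np.array([[1.0, 0.9], [0.9, 0.5]])
        with pytest.raises(ValueError):
            check_correlation_matrix(bad)


class TestVoltageSynthesis:
    def test_zero_units_pure_noise(self):
        truth = GroundTruth(unit_ids=np.array([]), spike_times_s=[],
                            positions_um=np.zeros((0, 2)))
        rec = synthesize_voltage(truth, [], noise_sd_uv=5.0, duration_s=2.0,
                                 seed=0)
        assert np.allclose(rec.samples.std(axis=1), 5.0, atol=0.2)

    def test_unit_at_channel_reproduces_template(self):
        from meapop.datatypes import grid_coordinates
        from meapop.synthetic import WINDOW_PRE_SAMPLES, WINDOW_SAMPLES
        coords = grid_coordinates((2, 2))
        tpl = default_template(80.0)
        truth = GroundTruth(unit_ids=np.array([0]),
                            spike_times_s=[np.array([0.5])],
                            positions_um=coords[[0]])
        rec = synthesize_voltage(truth, [tpl], channel_coords_um=coords,
                                 noise_sd_uv=0.0, duration_s=1.0, seed=0)
        t0 = int(round(0.5 * rec.sampling_rate_hz))
        window = rec.samples[0, t0 - WINDOW_PRE_SAMPLES:
                             t0 - WINDOW_PRE_SAMPLES + WINDOW_SAMPLES]
        assert np.allclose(window, tpl.samples)
        # decayed copy on a neighbor 300 µm away: gain 1/(1 + 300/150) = 1/3
        window1 = rec.samples[1, t0 - WINDOW_PRE_SAMPLES:
                              t0 - WINDOW_PRE_SAMPLES + WINDOW_SAMPLES]
        assert np.allclose(window1, tpl.samples / 3.0)

    def test_duplicate_spike_times_rejected(self):
        truth = GroundTruth(unit_ids=np.array([0]),
                            spike_times_s=[np.array([0.1, 0.2])],
                            positions_um=np.zeros((1, 2)))
        truth.spike_times_s = [np.array([0.1, 0.1])]  # bypass ctor sort check
        with pytest.raises(ValueError, match="duplicate"):
            synthesize_voltage(truth, [default_template()], duration_s=1.0)

    def test_reproducible(self):
        a, _ = planted_recording(n_units=2, duration_s=3.0, seed=8)
        b, _ = planted_recording(n_units=2, duration_s=3.0, seed=8)
        assert np.array_equal(a.samples, b.samples)


class TestTemplates:
    def test_default_template_single_negative_peak(self):
        tpl = default_template(100.0)
        assert tpl.peak_amplitude_uV == pytest.approx(100.0)
        assert tpl.samples.min() == -100.0

    def test_multi_peaked_template_rejected(self):
        from meapop.synthetic import WINDOW_SAMPLES
        w = np.zeros(WINDOW_SAMPLES)
        w[10] = -100.0
        w[25] = -90.0
        with pytest.raises(ValueError, match="multiple dominant"):
            WaveformTemplate(samples=w)


class TestTripletSynchrony:
    def test_sync_bins_have_exactly_three_active(self):
        r = generate_triplet_synchrony_raster(6, 5000, background_p=0.0,
                                              sync_p=0.05, seed=1)
        counts = r.matrix.sum(axis=0)
        assert set(np.unique(counts)) <= {0, 3}
        assert (counts == 3).sum() > 0
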