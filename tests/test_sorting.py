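"""Spike sorting chain: filter, detect, screen, cluster, merge, validate."""

import numpy as np
import pytest
from scipy import stats as sps

from meapop.datatypes import grid_coordinates
from meapop.sorting import (
    detect_events,
    extract_waveforms,
    filter_trace,
    is_compound_waveform,
    merge_similar_clusters,
    project_and_cluster,
    reject_symmetric_noise,
    sort_recording,
    validate_isi,
    WaveformSet,
)
from meapop.synthetic import (
    WINDOW_PRE_SAMPLES,
    WINDOW_SAMPLES,
    default_template,
    planted_recording,
)

FS = 12_500.0


def sinus(freq_hz, duration_s=20.0, fs=FS, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


class TestFilter:
    def test_passband_tone_preserved(self):
        x = sinus(1500.0)
        y = filter_trace(x, FS, pad_s=4.0)
        mid = slice(50_000, 200_000)
        gain = y[mid].std() / x[mid].std()
        assert abs(gain - 1.0) < 0.05

    def test_dc_removed(self):
        x = np.full(150_000, 42.0)
        y = filter_trace(x, FS, pad_s=4.0)
        assert np.max(np.abs(y)) < 1e-6

    def test_mains_notched(self):
        x = sinus(60.0)
        y = filter_trace(x, FS, pad_s=4.0)
        mid = slice(50_000, 200_000)
        assert y[mid].std() / x[mid].std() < 0.05

    def test_output_length_equals_input(self):
        x = np.random.default_rng(0).standard_normal(120_000)
        assert filter_trace(x, FS).size == x.size

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            filter_trace(np.zeros(1000), FS, pad_s=4.0)

    def test_double_filtering_near_idempotent_in_passband(self):
        x = sinus(1500.0)
        once = filter_trace(x, FS)
        twice = filter_trace(once, FS)
        mid = slice(50_000, 200_000)
        g1 = once[mid].std() / x[mid].std()
        g2 = twice[mid].std() / x[mid].std()
        assert abs(g2 - g1 ** 2) < 0.1


class TestDetect:
    def test_gaussian_noise_false_positive_rate(self, rng):
        """15 min of pure Gaussian noise: expected threshold crossings
        ≈ n · P(|Z| > 5); the observed count must be Poisson-consistent."""
        n = int(15 * 60 * FS)
        x = rng.standard_normal(n)
        events = detect_events(x, FS, k_sd=5.0)
        lam = n * 2 * sps.norm.sf(5.0)   # ≈ 6.4
        assert events.size <= sps.poisson.ppf(0.9999, lam)

    def test_injected_spike_found_at_its_time(self, rng):
        x = rng.standard_normal(100_000)
        tpl = default_template(8.0)   # 8 SD peak on unit-variance noise
        t0 = 50_000
        x[t0 - WINDOW_PRE_SAMPLES:t0 - WINDOW_PRE_SAMPLES + WINDOW_SAMPLES] += \
            tpl.samples
        events = detect_events(x, FS, k_sd=5.0)
        assert np.any(np.abs(events - t0) <= 1)

    def test_all_zero_trace_no_events(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            events = detect_events(np.zeros(10_000), FS)
        assert events.size == 0

    def test_count_monotone_in_threshold(self, rng):
        x = rng.standard_normal(200_000) * 3.0
        counts = [detect_events(x, FS, k_sd=k).size
                  for k in np.linspace(3.0, 5.5, 11)]
        assert np.all(np.diff(counts) <= 0)


def _make_waveset(snippets):
    snippets = np.asarray(snippets, dtype=float)[:, None, :]
    return WaveformSet(event_indices=np.arange(len(snippets)) * 1000 + 100,
                       snippets=snippets, channels=np.array([0]),
                       source_channel=0)


class TestSymmetricNoiseRejection:
    def test_sinusoid_snippet_rejected(self):
        t = np.arange(WINDOW_SAMPLES)
        snip = 3.0 * np.sin(2 * np.pi * t / 10 + np.pi / 3)
        ws = reject_symmetric_noise(_make_waveset([snip]))
        assert ws.n_events == 0

    def test_spike_template_retained(self):
        ws = reject_symmetric_noise(_make_waveset([default_template(80).samples]))
        assert ws.n_events == 1

    def test_planted_mixture_separated_exactly(self, rng):
        t = np.arange(WINDOW_SAMPLES)
        noise_snips = [3.0 * np.sin(2 * np.pi * t / 8 + ph)
                       for ph in rng.uniform(0, np.pi, 50)]
        spike_snips = [default_template(60 + a).samples
                       for a in rng.uniform(0, 40, 50)]
        ws = _make_waveset(noise_snips + spike_snips)
        kept = reject_symmetric_noise(ws)
        assert kept.n_events == 50
        # survivors are exactly the asymmetric spike templates
        assert np.all(kept.snippets.min(axis=2) < -50)


class TestClustering:
    def _two_cloud_waveset(self, rng, n=150, sep=10.0):
        tpl_a = default_template(40.0).samples
        tpl_b = np.roll(default_template(40.0).samples, 6) * -0.8
        snips, labels = [], []
        for i in range(n):
            if i % 2 == 0:
                snips.append(tpl_a + rng.standard_normal(WINDOW_SAMPLES)
                             * 40.0 / sep)
                labels.append(0)
            else:
                snips.append(tpl_b + rng.standard_normal(WINDOW_SAMPLES)
                             * 40.0 / sep)
                labels.append(1)
        order = np.argsort(rng.random(n))
        return _make_waveset([snips[i] for i in order]), \
            np.array(labels)[order]

    def test_two_separated_clouds_recovered(self, rng):
        ws, truth = self._two_cloud_waveset(rng)
        labels = project_and_cluster(ws, seed=0)
        assert np.unique(labels).size == 2
        # agreement up to permutation
        agree = max(np.mean(labels == truth), np.mean(labels != truth))
        assert agree >= 0.99

    def test_identical_events_single_cluster(self):
        snip = default_template(50.0).samples
        ws = _make_waveset([snip] * 30)
        labels = project_and_cluster(ws, seed=0)
        assert np.unique(labels).size == 1

    def test_identical_template_clouds_merge_downstream(self, rng):
        """Two clouds with the same underlying template are merged by the
        waveform-correlation rule even if EM split them."""
        tpl = default_template(50.0).samples
        means = [tpl + rng.standard_normal(WINDOW_SAMPLES) * 0.1,
                 tpl + rng.standard_normal(WINDOW_SAMPLES) * 0.1]
        groups = merge_similar_clusters(means, corr_threshold=0.8)
        assert np.unique(groups).size == 1


class TestMerge:
    def test_identical_waveforms_merged(self):
        w = default_template(50.0).samples
        assert np.unique(merge_similar_clusters([w, w.copy()])).size == 1

    def test_orthogonal_waveforms_kept_apart(self):
        t = np.arange(WINDOW_SAMPLES, dtype=float)
        a = np.sin(2 * np.pi * t / WINDOW_SAMPLES)
        b = np.cos(2 * np.pi * t / WINDOW_SAMPLES)
        assert np.unique(merge_similar_clusters([a, b])).size == 2

    def test_transitive_closure(self):
        """corr(A,B) ≈ corr(B,C) ≈ 0.9 but corr(A,C) ≈ 0.62: the closure
        still chains all three into one unit."""
        base = default_template(50.0).samples
        u = base - base.mean()
        u /= np.linalg.norm(u)
        t = np.linspace(0, 1, WINDOW_SAMPLES)
        v = np.sin(2 * np.pi * 3 * t)
        v -= v.mean()
        v -= (v @ u) * u
        v /= np.linalg.norm(v)
        ang = np.arccos(0.9)
        a = u
        b = np.cos(ang) * u + np.sin(ang) * v
        c = np.cos(2 * ang) * u + np.sin(2 * ang) * v
        cab = np.corrcoef(a, b)[0, 1]
        cbc = np.corrcoef(b, c)[0, 1]
        cac = np.corrcoef(a, c)[0, 1]
        assert cab > 0.8 and cbc > 0.8 and cac < 0.8
        assert np.unique(merge_similar_clusters([a, b, c], 0.8)).size == 1

    def test_merge_idempotent(self, rng):
        waves = [default_template(40 + 10 * i).samples
                 + rng.standard_normal(WINDOW_SAMPLES) * 5 for i in range(4)]
        g1 = merge_similar_clusters(waves, 0.8)
        merged_means = [np.mean([w for w, g in zip(waves, g1) if g == gg],
                                axis=0) for gg in np.unique(g1)]
        g2 = merge_similar_clusters(merged_means, 0.8)
        assert np.unique(g2).size == np.unique(g1).size


class TestISI:
    def test_regular_train_passes(self):
        ts = np.arange(0, 10, 0.1)
        ok, frac = validate_isi(ts)
        assert ok and frac == 0.0

    def test_all_refractory_violations_fail(self):
        ts = np.arange(100) * 0.001
        ok, frac = validate_isi(ts)
        assert not ok and frac == 1.0

    def test_fraction_counts_isis_not_spikes(self):
        """100 spikes with exactly 4 ISIs at 2 ms: fraction 4/99, passes."""
        isis = np.array([0.002] * 4 + [0.05] * 95)
        ts = np.concatenate([[0.0], np.cumsum(isis)])
        ok, frac = validate_isi(ts)
        assert ok
        assert frac == pytest.approx(4 / 99)

    def test_single_spike_passes_with_warning(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            ok, frac = validate_isi(np.array([1.0]))
        assert ok and frac == 0.0


class TestCompoundWaveform:
    def test_single_trough_not_compound(self):
        assert not is_compound_waveform(default_template(80.0).samples)

    def test_double_trough_compound(self):
        w = np.zeros(WINDOW_SAMPLES)
        w[10] = -100.0
        w[25] = -80.0
        assert is_compound_waveform(w)


class TestEndToEnd:
    def test_planted_units_recovered(self):
        """All planted units recovered with high spike recall and precision
        at high signal-to-noise ratio."""
        from conftest import match_planted_units
        rec, truth = planted_recording(n_units=3, duration_s=60.0, seed=0)
        catalog = sort_recording(rec, seed=0)
        assert len(catalog.valid_units()) == len(truth.spike_times_s)
        for recall, precision in match_planted_units(catalog, truth):
            assert recall >= 0.95
            assert precision >= 0.95
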