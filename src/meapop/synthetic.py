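"""Ground-truth generators for every pipeline stage.

Three generators cover the three levels the analysis operates on:

* :func:`sample_ising_exact` — i.i.d. binary words from a pairwise
  maximum-entropy (Ising) distribution by exact enumeration of the 2^K states;
  the forward oracle for the model-fitting stage.
* :func:`generate_correlated_trains` — spike trains with controllable per-unit
  rates and pairwise correlations via the dichotomized-Gaussian construction
  (threshold a correlated latent Gaussian at Φ⁻¹(1 − rate·bin)).
* :func:`synthesize_voltage` — raw multichannel voltage built from single-peaked
  waveform templates planted at known positions on the electrode grid, with
  distance-decayed amplitudes and additive Gaussian noise.

All generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datatypes import (
    BinarizedRaster,
    IsingParameters,
    VoltageRecording,
    check_correlation_matrix,
    grid_coordinates,
    SAMPLING_RATE_HZ,
)

# Waveform snippet window: 1 ms before the trough, 2 ms after, at 12.5 kHz.
WINDOW_PRE_SAMPLES = 13
WINDOW_POST_SAMPLES = 25
WINDOW_SAMPLES = WINDOW_PRE_SAMPLES + WINDOW_POST_SAMPLES

#: Length constant (µm) of the 1/(1 + d/λ) amplitude decay across the grid.
DECAY_LAMBDA_UM = 150.0


@dataclass
class WaveformTemplate:
    """Mean extracellular spike shape over a fixed 3 ms window.

    The shape must have a single dominant negative peak — multi-peaked
    (compound-spike) templates are excluded from analysis, so the generator
    refuses to plant them.
    """

    samples: np.ndarray  # µV, length WINDOW_SAMPLES, trough at WINDOW_PRE_SAMPLES

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("template samples must be finite")
        trough = self.samples.min()
        if trough >= 0:
            raise ValueError("template must have a negative peak")
        # single dominance: no second local minimum deeper than half the trough
        interior = self.samples[1:-1]
        minima = (interior < self.samples[:-2]) & (interior < self.samples[2:])
        deep = interior[minima] < 0.5 * trough
        if deep.sum() > 1:
            raise ValueError("template has multiple dominant negative peaks")

    @property
    def peak_amplitude_uV(self) -> float:
        return float(-self.samples.min())


def default_template(peak_amplitude_uv: float = 80.0,
                     sampling_rate_hz: float = SAMPLING_RATE_HZ) -> WaveformTemplate:
    """Canonical asymmetric extracellular spike: sharp trough, slow positive recovery."""
    t = (np.arange(WINDOW_SAMPLES) - WINDOW_PRE_SAMPLES) / sampling_rate_hz * 1e3  # ms
    trough = -np.exp(-0.5 * (t / 0.12) ** 2)
    recovery = 0.30 * np.exp(-0.5 * ((t - 0.55) / 0.45) ** 2)
    shape = trough + recovery
    shape *= peak_amplitude_uv / -shape.min()
    return WaveformTemplate(samples=shape)


@dataclass
class GroundTruth:
    """Planted truth against which every downstream stage is scored."""

    unit_ids: np.ndarray
    spike_times_s: list[np.ndarray]  # strictly increasing, non-negative, per unit
    positions_um: np.ndarray | None = None  # (n_units, 2)
    ising_params: IsingParameters | None = None
    latent_correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)
        for ts in self.spike_times_s:
            ts = np.asarray(ts)
            if ts.size and (np.any(np.diff(ts) <= 0) or ts[0] < 0):
                raise ValueError("spike times must be strictly increasing and >= 0")
        if self.latent_correlation is not None:
            self.latent_correlation = check_correlation_matrix(self.latent_correlation)


# ---------------------------------------------------------------------------
# Exact Ising sampler
# ---------------------------------------------------------------------------

def sample_ising_exact(params: IsingParameters, n_samples: int,
                       seed: int | np.random.Generator) -> BinarizedRaster:
    """Draw i.i.d. binary words from P(s) ∝ exp(Σ h_i s_i + Σ_{i<j} J_ij s_i s_j).

    Enumerates all 2^K states exactly, so K is capped at 16.
    """
    from .maxent import model_word_distribution, enumerate_states

    if params.k > 16:
        raise ValueError(
            f"exact enumeration requires K <= 16 (2^K states); got K={params.k}")
    dist = model_word_distribution(params)
    rng = np.random.default_rng(seed)
    words = rng.choice(2 ** params.k, size=n_samples, p=dist.dense())
    states = enumerate_states(params.k)  # (2^K, K)
    return BinarizedRaster(states[words].T)


# ---------------------------------------------------------------------------
# Dichotomized-Gaussian correlated spike trains
# ---------------------------------------------------------------------------

def dichotomized_gaussian_correlation(p_i: float, p_j: float,
                                      latent_corr: float) -> float:
    """Pearson correlation of two thresholded-Gaussian binary streams.

    Closed form via the bivariate-normal orthant probability: with thresholds
    t = Φ⁻¹(1 − p), P(both spike) = P(z_i > t_i, z_j > t_j) under latent
    correlation λ, and r = (P₁₁ − p_i p_j) / √(p_i(1−p_i) p_j(1−p_j)).
    """
    if not (0 < p_i < 1 and 0 < p_j < 1):
        raise ValueError("spike probabilities must be in (0, 1)")
    t_i = stats.norm.ppf(1 - p_i)
    t_j = stats.norm.ppf(1 - p_j)
    if latent_corr >= 1.0 - 1e-12:
        p11 = min(p_i, p_j)
    elif latent_corr <= -1.0 + 1e-12:
        p11 = max(0.0, p_i + p_j - 1.0)
    else:
        bvn = stats.multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, latent_corr], [latent_corr, 1.0]])
        # upper orthant by symmetry of the centered Gaussian
        p11 = float(bvn.cdf([-t_i, -t_j]))
    return (p11 - p_i * p_j) / np.sqrt(p_i * (1 - p_i) * p_j * (1 - p_j))


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Factor L with L Lᵀ = corr, tolerating rank deficiency (e.g. λ = 1)."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def generate_correlated_trains(rates_hz: np.ndarray, latent_corr: np.ndarray,
                               duration_s: float, bin_s: float = 0.010,
                               seed: int | np.random.Generator = 0,
                               ) -> tuple[list[np.ndarray], BinarizedRaster]:
    """Correlated spike trains from the dichotomized-Gaussian construction.

    Each 10 ms bin draws a latent Gaussian vector with the requested correlation;
    unit i spikes when its latent exceeds Φ⁻¹(1 − rate_i·bin). Spike times are
    placed within their bin with a uniform offset shared across units, so fully
    coupled units (latent correlation 1, equal rates) emit identical trains.

    Returns the continuous spike trains and the exact binarized raster they
    came from.
    """
    rates_hz = np.atleast_1d(np.asarray(rates_hz, dtype=float))
    latent_corr = check_correlation_matrix(latent_corr)
    k = rates_hz.size
    if latent_corr.shape != (k, k):
        raise ValueError("latent_corr shape must match number of rates")
    if np.any(rates_hz < 0):
        raise ValueError("rates must be non-negative")
    p = rates_hz * bin_s
    if np.any(p >= 1):
        raise ValueError(
            f"infeasible rate: rate*bin >= 1 for rates {rates_hz[p >= 1]}")
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")

    rng = np.random.default_rng(seed)
    n_bins = int(np.floor(duration_s / bin_s))
    thresholds = np.where(p > 0, stats.norm.ppf(1 - np.clip(p, 1e-300, 1)), np.inf)
    z = rng.standard_normal((n_bins, k)) @ _psd_factor(latent_corr).T
    spikes = (z > thresholds).T.astype(np.int8)  # (k, n_bins)

    offsets = rng.random(n_bins)
    trains = []
    for i in range(k):
        bins = np.flatnonzero(spikes[i])
        trains.append((bins + offsets[bins]) * bin_s)
    return trains, BinarizedRaster(spikes, bin_ms=bin_s * 1e3)


def generate_triplet_synchrony_raster(k: int, n_bins: int, background_p: float,
                                      sync_p: float,
                                      seed: int | np.random.Generator = 0,
                                      ) -> BinarizedRaster:
    """Raster with planted third-order structure a pairwise model cannot capture.

    Mixes independent background activity with exclusive triplet-synchrony
    events: in a sync bin, one randomly chosen unit triplet fires together and
    everyone else is silent. Word statistics then carry genuine third-order
    dependence beyond rates and pairwise co-activations.
    """
    if k < 3:
        raise ValueError("triplet synchrony needs at least 3 units")
    rng = np.random.default_rng(seed)
    raster = (rng.random((k, n_bins)) < background_p).astype(np.int8)
    sync_bins = np.flatnonzero(rng.random(n_bins) < sync_p)
    for b in sync_bins:
        raster[:, b] = 0
        raster[rng.choice(k, size=3, replace=False), b] = 1
    return BinarizedRaster(raster)


# ---------------------------------------------------------------------------
# Raw voltage synthesis
# ---------------------------------------------------------------------------

def synthesize_voltage(ground_truth: GroundTruth,
                       templates: list[WaveformTemplate],
                       channel_coords_um: np.ndarray | None = None,
                       noise_sd_uv: float = 5.0,
                       duration_s: float | None = None,
                       sampling_rate_hz: float = SAMPLING_RATE_HZ,
                       decay_lambda_um: float = DECAY_LAMBDA_UM,
                       seed: int | np.random.Generator = 0) -> VoltageRecording:
    """Build raw multichannel voltage from planted units.

    Each spike stamps its unit's template onto every channel, scaled by
    ``1 / (1 + d / λ)`` where d is the distance from the unit's true position
    to the electrode; i.i.d. Gaussian noise of ``noise_sd_uv`` is added.
    """
    if channel_coords_um is None:
        channel_coords_um = grid_coordinates()
    channel_coords_um = np.asarray(channel_coords_um, dtype=float)
    n_channels = channel_coords_um.shape[0]
    if len(templates) != len(ground_truth.spike_times_s):
        raise ValueError("one template per planted unit required")
    if duration_s is None:
        last = max((ts[-1] for ts in ground_truth.spike_times_s if ts.size),
                   default=0.0)
        duration_s = last + 0.01
    n_samples = int(round(duration_s * sampling_rate_hz))

    rng = np.random.default_rng(seed)
    traces = rng.standard_normal((n_channels, n_samples)) * noise_sd_uv
    positions = ground_truth.positions_um
    if positions is None:
        raise ValueError("ground truth must carry unit positions")

    for ts, tpl, pos in zip(ground_truth.spike_times_s, templates, positions):
        ts = np.asarray(ts)
        if ts.size != np.unique(ts).size:
            raise ValueError("duplicate spike times within one unit")
        d = np.linalg.norm(channel_coords_um - pos, axis=1)
        gains = 1.0 / (1.0 + d / decay_lambda_um)
        trough_idx = np.round(ts * sampling_rate_hz).astype(int)
        for t0 in trough_idx:
            lo = t0 - WINDOW_PRE_SAMPLES
            hi = t0 + WINDOW_POST_SAMPLES
            w_lo, w_hi = max(0, -lo), WINDOW_SAMPLES - max(0, hi - n_samples)
            lo, hi = max(lo, 0), min(hi, n_samples)
            if lo >= hi:
                continue
            traces[:, lo:hi] += gains[:, None] * tpl.samples[None, w_lo:w_hi]

    return VoltageRecording(samples=traces, sampling_rate_hz=sampling_rate_hz,
                            channel_coords_um=channel_coords_um)


def planted_recording(n_units: int = 3, duration_s: float = 60.0,
                      rates_hz: np.ndarray | None = None,
                      peak_uv: float = 100.0, noise_sd_uv: float = 5.0,
                      grid_side: int = 4,
                      seed: int | np.random.Generator = 0,
                      ) -> tuple[VoltageRecording, GroundTruth]:
    """Convenience: plant well-separated units on a grid corner and synthesize voltage.

    Units sit exactly on distinct electrodes, far apart, with Poisson spike
    trains (2.5 ms refractory period enforced by thinning).
    """
    rng = np.random.default_rng(seed)
    coords = grid_coordinates((grid_side, grid_side))
    if rates_hz is None:
        rates_hz = np.full(n_units, 2.0)
    rates_hz = np.asarray(rates_hz, dtype=float)
    # spread units over distinct, mutually distant electrodes
    idx = np.linspace(0, coords.shape[0] - 1, n_units).round().astype(int)
    positions = coords[idx]

    trains = []
    for rate in rates_hz:
        n_exp = rng.poisson(rate * duration_s)
        ts = np.sort(rng.uniform(0.005, duration_s - 0.005, size=n_exp))
        keep = np.concatenate([[True], np.diff(ts) > 0.0025]) if ts.size else \
            np.zeros(0, dtype=bool)
        trains.append(ts[keep])

    truth = GroundTruth(unit_ids=np.arange(n_units), spike_times_s=trains,
                        positions_um=positions)
    templates = [default_template(peak_uv * (1.0 + 0.25 * i))
                 for i in range(n_units)]
    rec = synthesize_voltage(truth, templates, channel_coords_um=coords,
                             noise_sd_uv=noise_sd_uv, duration_s=duration_s,
                             seed=rng)
    return rec, truth
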