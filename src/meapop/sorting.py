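"""Spike sorting: from raw multichannel voltage to validated single units.

The procedure follows the standard extracellular chain for planar MEA
recordings of cultured networks:

1. band-pass 500–3,500 Hz (3rd-order Butterworth, zero-phase) plus a 60 Hz
   notch, with 4 s reflection padding against edge effects;
2. putative spikes = excursions beyond 5 SD of the filtered trace;
3. rejection of time-symmetric high-frequency oscillations (noise) by
   waveform/time-reverse correlation and a peak-minus-trough amplitude
   criterion of 8 µV;
4. PCA projection of concatenated multi-channel waveforms and EM fitting of a
   Gaussian mixture (components chosen by BIC);
5. merging of clusters whose mean waveforms correlate above 0.8
   (anti-overclustering), transitively;
6. cross-channel deduplication of units detected on neighboring electrodes;
7. validation: < 5% of interspike intervals below the 2.5 ms refractory
   period, and exclusion of multi-peaked (compound-spike) mean waveforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .datatypes import Unit, UnitCatalog, VoltageRecording, SAMPLING_RATE_HZ
from .synthetic import WINDOW_PRE_SAMPLES, WINDOW_POST_SAMPLES, WINDOW_SAMPLES

# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_trace(trace: np.ndarray, sampling_rate_hz: float = SAMPLING_RATE_HZ,
                 low_hz: float = 500.0, high_hz: float = 3500.0,
                 pad_s: float = 4.0, notch_hz: float | None = 60.0,
                 notch_q: float = 30.0, order: int = 3) -> np.ndarray:
    """Zero-phase band-pass + notch filter; output has the input's length.

    The trace is padded by reflection (``pad_s`` on each side) before
    filtering and trimmed afterwards, so filter transients never reach the
    data. Zero-phase (forward-backward) filtering preserves waveform shape
    for the downstream clustering.
    """
    trace = np.asarray(trace, dtype=float)
    pad = int(round(pad_s * sampling_rate_hz))
    if trace.size <= 2 * pad:
        raise ValueError(
            f"trace ({trace.size} samples) too short for {pad_s} s padding")
    padded = np.pad(trace, pad, mode="reflect") if pad else trace
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=sampling_rate_hz, output="sos")
    out = signal.sosfiltfilt(sos, padded)
    if notch_hz:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=sampling_rate_hz)
        out = signal.filtfilt(b, a, out)
    return out[pad:trace.size + pad] if pad else out


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def detect_events(trace: np.ndarray, sampling_rate_hz: float = SAMPLING_RATE_HZ,
                  k_sd: float = 5.0, dead_time_ms: float = 1.0,
                  robust_sd: bool = False) -> np.ndarray:
    """Sample indices of threshold crossings (one per excursion).

    Candidate events are local peaks of |trace − mean| separated by at least
    the dead time; those exceeding ``k_sd`` standard deviations are kept.
    Because the candidate peaks do not depend on ``k_sd``, raising the
    threshold can only remove events (monotone detection).

    ``robust_sd`` switches the scale estimate from the literal standard
    deviation to 1.4826·MAD, which is less inflated by the spikes themselves.
    """
    trace = np.asarray(trace, dtype=float)
    dev = np.abs(trace - trace.mean())
    sd = (1.4826 * np.median(np.abs(trace - np.median(trace)))
          if robust_sd else trace.std())
    if sd == 0:
        warnings.warn("zero-variance trace: no events detectable")
        return np.zeros(0, dtype=int)
    dead = max(1, int(round(dead_time_ms * 1e-3 * sampling_rate_hz)))
    peaks, _ = signal.find_peaks(dev, distance=dead)
    return peaks[dev[peaks] > k_sd * sd]


# ---------------------------------------------------------------------------
# Waveform extraction
# ---------------------------------------------------------------------------

@dataclass
class WaveformSet:
    """Per-event waveform snippets on the source channel and its neighbors."""

    event_indices: np.ndarray        # sample index of each event (trough)
    snippets: np.ndarray             # (n_events, n_channels_used, window)
    channels: np.ndarray             # channel ids of the snippet rows
    source_channel: int
    sampling_rate_hz: float = SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        if self.snippets.ndim != 3 or self.snippets.shape[2] != WINDOW_SAMPLES:
            raise ValueError("snippets must be (n_events, n_channels, window)")
        if np.any(np.diff(self.event_indices) < 0):
            raise ValueError("event times must be sorted")

    @property
    def n_events(self) -> int:
        return self.snippets.shape[0]

    @property
    def event_times_s(self) -> np.ndarray:
        return self.event_indices / self.sampling_rate_hz

    def source_snippets(self) -> np.ndarray:
        row = int(np.flatnonzero(self.channels == self.source_channel)[0])
        return self.snippets[:, row, :]

    def concatenated(self) -> np.ndarray:
        """(n_events, n_channels_used * window) feature matrix for PCA."""
        return self.snippets.reshape(self.n_events, -1)

    def select(self, mask: np.ndarray) -> "WaveformSet":
        return WaveformSet(self.event_indices[mask], self.snippets[mask],
                           self.channels, self.source_channel,
                           self.sampling_rate_hz)

    def local_events(self) -> "WaveformSet":
        """Keep only events whose amplitude peaks on the source channel.

        An event whose signal is larger on a neighboring electrode belongs to
        a neuron centered there; that channel will claim it. Assigning each
        event to its peak channel prevents the same spike from seeding units
        on several channels and keeps bleed events out of the clustering.
        """
        src_row = int(np.flatnonzero(self.channels == self.source_channel)[0])
        peak_row = np.abs(self.snippets).max(axis=2).argmax(axis=1)
        return self.select(peak_row == src_row)


def neighbor_channels(coords_um: np.ndarray, channel: int,
                      radius_um: float = 450.0) -> np.ndarray:
    """The channel itself plus electrodes within ``radius_um`` (grid neighbors)."""
    d = np.linalg.norm(coords_um - coords_um[channel], axis=1)
    return np.flatnonzero(d <= radius_um)


def extract_waveforms(filtered: np.ndarray, coords_um: np.ndarray, channel: int,
                      event_indices: np.ndarray,
                      sampling_rate_hz: float = SAMPLING_RATE_HZ,
                      neighbor_radius_um: float = 450.0) -> WaveformSet:
    """Cut fixed windows (1 ms pre / 2 ms post trough) on a channel and its
    neighbors; events too close to the recording edges are dropped."""
    n_samples = filtered.shape[1]
    chans = neighbor_channels(coords_um, channel, neighbor_radius_um)
    ok = (event_indices >= WINDOW_PRE_SAMPLES) & \
         (event_indices < n_samples - WINDOW_POST_SAMPLES)
    idx = event_indices[ok]
    snippets = np.empty((idx.size, chans.size, WINDOW_SAMPLES))
    for e, t0 in enumerate(idx):
        snippets[e] = filtered[chans, t0 - WINDOW_PRE_SAMPLES:
                               t0 + WINDOW_POST_SAMPLES]
    return WaveformSet(idx, snippets, chans, channel, sampling_rate_hz)


# ---------------------------------------------------------------------------
# Noise rejection
# ---------------------------------------------------------------------------

def symmetry_correlation(w: np.ndarray, max_lag_fraction: float = 0.5) -> float:
    """Time-symmetry of a snippet: best correlation with its time-reverse.

    The maximum normalized correlation between the snippet and its
    time-reversed copy over all alignments (lags up to half the window).
    Reversing a periodic oscillation only shifts its phase, so noise scores
    near 1 at some lag; an action potential's sharp drop followed by a slow
    recovery matches its mirror at no alignment and scores low.
    """
    w = np.asarray(w, dtype=float) - np.mean(w)
    n = w.size
    if np.all(w == 0):
        return 1.0
    r = w[::-1]
    max_lag = int(n * max_lag_fraction)
    best = -1.0
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = w[lag:], r[:n - lag]
        else:
            a, b = w[:n + lag], r[-lag:]
        if a.size < 8 or a.std() == 0 or b.std() == 0:
            continue
        best = max(best, float(np.corrcoef(a, b)[0, 1]))
    return best


def reject_symmetric_noise(waveforms: WaveformSet,
                           symmetry_corr_threshold: float = 0.9,
                           peak_trough_diff_uv: float = 8.0) -> WaveformSet:
    """Drop events that look like periodic noise rather than spikes.

    An event is noise when its source-channel waveform is time-symmetric
    (correlation with its reverse above threshold) AND its peak and trough
    have nearly equal magnitude (absolute difference below 8 µV) — both
    hallmarks of oscillations, neither of an asymmetric action potential.
    """
    src = waveforms.source_snippets()
    sym = np.array([symmetry_correlation(w) for w in src])
    amp_diff = np.abs(np.abs(src.max(axis=1)) - np.abs(src.min(axis=1)))
    noise = (sym > symmetry_corr_threshold) & (amp_diff < peak_trough_diff_uv)
    return waveforms.select(~noise)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def project_and_cluster(waveforms: WaveformSet, n_components: int = 3,
                        max_clusters: int = 8, n_init: int = 10,
                        seed: int = 0) -> np.ndarray:
    """PCA to a low-dimensional space, then EM on a Gaussian mixture.

    The number of mixture components is chosen by BIC over 1..max_clusters
    (capped by the event count). Three components default: waveforms here
    concatenate several channels, and the spatial amplitude profile needs a
    dimension beyond the two that suffice for single-channel shape.
    Deterministic given the seed.
    """
    if waveforms.n_events < 2:
        return np.zeros(waveforms.n_events, dtype=int)
    X = waveforms.concatenated()
    n_comp = min(n_components, X.shape[0], X.shape[1])
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    best_labels, best_bic = None, np.inf
    for n in range(1, min(max_clusters, waveforms.n_events) + 1):
        gmm = GaussianMixture(n_components=n, n_init=n_init, random_state=seed,
                              reg_covar=1e-4)
        try:
            gmm.fit(proj)
        except ValueError:
            continue
        bic = gmm.bic(proj)
        if bic < best_bic:
            best_bic = bic
            best_labels = gmm.predict(proj)
    if best_labels is None:
        return np.zeros(waveforms.n_events, dtype=int)
    return best_labels


def merge_similar_clusters(mean_waveforms: list[np.ndarray],
                           corr_threshold: float = 0.8,
                           max_amp_ratio: float | None = None) -> np.ndarray:
    """Group labels merging clusters with waveform correlation > threshold.

    The merge is the transitive closure (union-find) over all pairs exceeding
    the threshold, so the result is order-independent and idempotent.
    ``max_amp_ratio`` optionally also requires the clusters' peak amplitudes
    to be within that factor: over-split clusters of one neuron share the
    amplitude, while a bleed cluster from a distant neuron has the right
    shape but a decayed amplitude and must not be merged in. Returns an
    array mapping cluster index -> merged group id (0-based, ordered by
    first member).
    """
    n = len(mean_waveforms)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        wi = np.ravel(mean_waveforms[i])
        for j in range(i + 1, n):
            wj = np.ravel(mean_waveforms[j])
            if wi.std() == 0 or wj.std() == 0:
                continue
            if max_amp_ratio is not None:
                ai, aj = np.abs(wi).max(), np.abs(wj).max()
                if max(ai, aj) > max_amp_ratio * min(ai, aj):
                    continue
            if np.corrcoef(wi, wj)[0, 1] > corr_threshold:
                parent[find(i)] = find(j)

    roots = [find(i) for i in range(n)]
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in remap:
            remap[r] = len(remap)
        out[i] = remap[r]
    return out


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_isi(spike_times_s: np.ndarray, max_violation_fraction: float = 0.05,
                 refractory_ms: float = 2.5) -> tuple[bool, float]:
    """Fraction of interspike intervals below the refractory period.

    Units with >= 5% of ISIs under 2.5 ms are contaminated (a real neuron
    cannot fire inside its absolute refractory period) and flagged fail.
    """
    ts = np.asarray(spike_times_s, dtype=float)
    if ts.size < 2:
        warnings.warn("fewer than 2 spikes: ISI check passes vacuously")
        return True, 0.0
    isi = np.diff(ts)
    frac = float(np.mean(isi < refractory_ms * 1e-3))
    return frac < max_violation_fraction, frac


def is_compound_waveform(mean_waveform: np.ndarray,
                         rel_threshold: float = 0.5) -> bool:
    """True when the waveform has multiple dominant peaks (compound spike)."""
    w = np.asarray(mean_waveform, dtype=float)
    mag = np.abs(w)
    peak = mag.max()
    if peak == 0:
        return False
    interior = mag[1:-1]
    is_ext = (interior >= mag[:-2]) & (interior >= mag[2:])
    # count separated dominant extrema (plateaus collapse to one)
    dom = np.flatnonzero(is_ext & (interior > rel_threshold * peak))
    n_dom = int(np.sum(np.diff(dom) > 1)) + (1 if dom.size else 0)
    return n_dom > 1


# ---------------------------------------------------------------------------
# Cross-channel deduplication and the full sorter
# ---------------------------------------------------------------------------

def _coincidence_fraction(a: np.ndarray, b: np.ndarray,
                          tol_s: float = 0.5e-3) -> float:
    """Fraction of the smaller train's spikes matched within ±tol in the other."""
    if a.size == 0 or b.size == 0:
        return 0.0
    small, big = (a, b) if a.size <= b.size else (b, a)
    pos = np.searchsorted(big, small)
    near = np.full(small.size, np.inf)
    left = np.clip(pos - 1, 0, big.size - 1)
    right = np.clip(pos, 0, big.size - 1)
    near = np.minimum(np.abs(small - big[left]), np.abs(small - big[right]))
    return float(np.mean(near <= tol_s))


def _directed_coincidence(a: np.ndarray, b: np.ndarray,
                          tol_s: float = 0.5e-3) -> float:
    """Fraction of a's spikes with a match within ±tol in b."""
    if a.size == 0 or b.size == 0:
        return 0.0
    pos = np.searchsorted(b, a)
    left = np.clip(pos - 1, 0, b.size - 1)
    right = np.clip(pos, 0, b.size - 1)
    near = np.minimum(np.abs(a - b[left]), np.abs(a - b[right]))
    return float(np.mean(near <= tol_s))


def _coincidence_fraction(a: np.ndarray, b: np.ndarray,
                          tol_s: float = 0.5e-3) -> float:
    """Fraction of the smaller train's spikes matched within ±tol in the other."""
    small, big = (a, b) if a.size <= b.size else (b, a)
    return _directed_coincidence(small, big, tol_s)


def dedupe_cross_channel(units: list[Unit], coords_um: np.ndarray,
                         coincidence_threshold: float = 0.5,
                         waveform_corr_threshold: float = 0.8,
                         tol_s: float = 0.5e-3,
                         neighbor_radius_um: float | None = None) -> list[Unit]:
    """Collapse the same neuron detected on multiple electrodes.

    A unit is absorbed when more than half of its spikes coincide within
    ±0.5 ms with spikes of larger-amplitude units whose mean waveforms
    correlate with its own above 0.8 — their electrodes see the underlying
    neuron(s) better. Coincidence is pooled over all such units, so a
    contaminated cluster collecting bleed from several neurons is absorbed
    too; absorption is directional, so a small cluster coinciding with two
    real units cannot chain them together the way a transitive merge would.
    Spike-time coincidence at sub-millisecond tolerance identifies the same
    neuron however far its signal carries, so no electrode-distance gate is
    applied unless ``neighbor_radius_um`` is given.
    """
    n = len(units)
    amp = [float(np.max(np.abs(u.mean_waveforms))) for u in units]
    # weakest units absorb first, into anything stronger still alive
    order = sorted(range(n), key=lambda i: amp[i])
    absorbed = [False] * n
    for j in order:
        uj = units[j]
        if uj.home_channel is None:
            continue
        pooled = []
        for i in range(n):
            if i == j or absorbed[i] or amp[i] <= amp[j]:
                continue
            ui = units[i]
            if ui.home_channel is None:
                continue
            if neighbor_radius_um is not None:
                d = np.linalg.norm(coords_um[ui.home_channel] -
                                   coords_um[uj.home_channel])
                if d > neighbor_radius_um:
                    continue
            wi = ui.mean_waveforms[ui.home_channel]
            wj = uj.mean_waveforms[uj.home_channel]
            if wi.std() > 0 and wj.std() > 0 and \
                    np.corrcoef(wi, wj)[0, 1] > waveform_corr_threshold:
                pooled.append(ui.spike_times_s)
        if pooled:
            ref = np.sort(np.concatenate(pooled))
            if _directed_coincidence(uj.spike_times_s, ref,
                                     tol_s) > coincidence_threshold:
                absorbed[j] = True

    kept = [u for i, u in enumerate(units) if not absorbed[i]]
    kept.sort(key=lambda u: u.unit_id)
    for new_id, u in enumerate(kept):
        u.unit_id = new_id
    return kept


def sort_recording(recording: VoltageRecording, k_sd: float = 5.0,
                   low_hz: float = 500.0, high_hz: float = 3500.0,
                   pad_s: float = 4.0, notch_hz: float | None = 60.0,
                   symmetry_corr_threshold: float = 0.9,
                   peak_trough_diff_uv: float = 8.0,
                   merge_corr_threshold: float = 0.8,
                   max_violation_fraction: float = 0.05,
                   refractory_ms: float = 2.5,
                   n_pca_components: int = 3, max_clusters: int = 8,
                   min_events: int = 10, robust_sd: bool = False,
                   seed: int = 0) -> UnitCatalog:
    """Run the full sorting chain on a recording and return validated units.

    Stages per channel: filter, detect, extract (channel + neighbors), reject
    symmetric noise, PCA + GMM cluster, merge correlated clusters. Then
    across channels: deduplicate coincident units, validate ISIs, exclude
    compound-spike waveforms. Units failing QC are retained in the catalog
    with their flags set but excluded from ``valid_units()``.
    """
    fs = recording.sampling_rate_hz
    coords = recording.channel_coords_um
    pad_s_eff = min(pad_s, 0.45 * recording.duration_s)
    filtered = np.vstack([
        filter_trace(recording.samples[c], fs, low_hz, high_hz, pad_s_eff,
                     notch_hz)
        for c in range(recording.n_channels)])

    units: list[Unit] = []
    uid = 0
    for c in range(recording.n_channels):
        events = detect_events(filtered[c], fs, k_sd, robust_sd=robust_sd)
        if events.size < min_events:
            continue
        ws = extract_waveforms(filtered, coords, c, events, fs)
        ws = reject_symmetric_noise(ws, symmetry_corr_threshold,
                                    peak_trough_diff_uv)
        ws = ws.local_events()
        if ws.n_events < min_events:
            continue
        labels = project_and_cluster(ws, n_pca_components, max_clusters,
                                     seed=seed)
        cluster_ids = np.unique(labels)
        cluster_means = [ws.snippets[labels == cid].mean(axis=0)
                         for cid in cluster_ids]
        # a cluster whose amplitude peaks on another electrode is bleed from a
        # neuron that channel will claim; drop it before merging so it cannot
        # contaminate this channel's units
        local = np.array([
            int(ws.channels[np.argmax(np.abs(m).max(axis=1))]) == c
            for m in cluster_means])
        cluster_ids = cluster_ids[local]
        cluster_means = [m for m, keep in zip(cluster_means, local) if keep]
        if not cluster_ids.size:
            continue
        groups = merge_similar_clusters([m.ravel() for m in cluster_means],
                                        merge_corr_threshold,
                                        max_amp_ratio=2.0)
        for g in np.unique(groups):
            mask = np.isin(labels, cluster_ids[groups == g])
            if mask.sum() < min_events:
                continue
            mean_multi = ws.snippets[mask].mean(axis=0)  # (n_chans_used, win)
            full = np.zeros((recording.n_channels, WINDOW_SAMPLES))
            full[ws.channels] = mean_multi
            home = int(ws.channels[np.argmax(np.abs(mean_multi).max(axis=1))])
            units.append(Unit(unit_id=uid,
                              spike_times_s=np.sort(ws.event_indices[mask] / fs),
                              mean_waveforms=full, home_channel=home,
                              waveform_channels=ws.channels))
            uid += 1

    units = dedupe_cross_channel(units, coords,
                                 waveform_corr_threshold=merge_corr_threshold)
    for u in units:
        u.isi_pass, u.isi_violation_fraction = validate_isi(
            u.spike_times_s, max_violation_fraction, refractory_ms)
        u.compound_pass = not is_compound_waveform(
            u.mean_waveforms[u.home_channel])
    return UnitCatalog(units=units, duration_s=recording.duration_s)
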