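"""Core data containers shared across the pipeline.

Conventions: time in seconds (float64), bins half-open ``[t, t + dt)`` aligned to
the recording start, unit indices 0-based internally, voltage in microvolts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Sampling rate of the recording hardware (Hz).
SAMPLING_RATE_HZ = 12_500.0
#: Electrode grid: 8 x 8 electrodes spaced 300 µm apart.
GRID_SHAPE = (8, 8)
GRID_PITCH_UM = 300.0
#: Total recording area covered by the array (µm); the electrodes sit inside it.
RECORDING_EXTENT_UM = 2100.0


def grid_coordinates(shape: tuple[int, int] = GRID_SHAPE,
                     pitch_um: float = GRID_PITCH_UM) -> np.ndarray:
    """(n_channels, 2) array of electrode (x, y) positions in µm, row-major."""
    rows, cols = shape
    xs, ys = np.meshgrid(np.arange(cols) * pitch_um, np.arange(rows) * pitch_um)
    return np.column_stack([xs.ravel(), ys.ravel()]).astype(float)


@dataclass
class VoltageRecording:
    """Raw multichannel extracellular voltage with grid geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in µV.
    sampling_rate_hz : float
        Samples per second (12.5 kHz for the Maestro-style hardware modelled here).
    channel_coords_um : ndarray, shape (n_channels, 2)
        Electrode (x, y) positions in µm.
    """

    samples: np.ndarray
    sampling_rate_hz: float = SAMPLING_RATE_HZ
    channel_coords_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (n_channels, n_samples) matrix")
        if self.samples.shape[0] > 64:
            raise ValueError("at most 64 channels supported (8x8 grid)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("voltage samples must be finite")
        if self.channel_coords_um is None:
            self.channel_coords_um = grid_coordinates()[: self.samples.shape[0]]
        self.channel_coords_um = np.asarray(self.channel_coords_um, dtype=float)
        if self.channel_coords_um.shape != (self.samples.shape[0], 2):
            raise ValueError("channel_coords_um must be (n_channels, 2)")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class Unit:
    """A putative single neuron isolated by spike sorting."""

    unit_id: int
    spike_times_s: np.ndarray
    mean_waveforms: np.ndarray | None = None  # (n_channels, n_window_samples) µV
    home_channel: int | None = None
    waveform_channels: np.ndarray | None = None  # channel ids of mean_waveforms rows
    isi_pass: bool = True
    isi_violation_fraction: float = 0.0
    compound_pass: bool = True

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) < 0):
            raise ValueError("spike times must be sorted")
        if self.spike_times_s.size and self.spike_times_s[0] < 0:
            raise ValueError("spike times must be non-negative")

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size

    @property
    def passes_qc(self) -> bool:
        return self.isi_pass and self.compound_pass


@dataclass
class UnitCatalog:
    """Collection of sorted units from one recording."""

    units: list[Unit]
    duration_s: float

    def __len__(self) -> int:
        return len(self.units)

    def valid_units(self) -> list[Unit]:
        """Units passing all quality flags; the substrate for downstream analysis."""
        return [u for u in self.units if u.passes_qc]

    def spike_trains(self, valid_only: bool = True) -> list[np.ndarray]:
        units = self.valid_units() if valid_only else self.units
        return [u.spike_times_s for u in units]

    def firing_rates_hz(self, valid_only: bool = True) -> np.ndarray:
        return np.array([u.n_spikes / self.duration_s
                         for u in (self.valid_units() if valid_only else self.units)])


@dataclass
class BinarizedRaster:
    """Binary population activity: units x 10 ms time bins.

    Bins are half-open ``[k*dt, (k+1)*dt)`` from t = 0; a bin is 1 when the unit
    fired at least once in it, irrespective of the number of spikes.
    """

    matrix: np.ndarray  # (n_units, n_bins) of {0, 1}
    bin_ms: float = 10.0
    unit_ids: np.ndarray | None = None
    multi_spike_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("raster must be 2-D (n_units, n_bins)")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)
        if self.unit_ids is None:
            self.unit_ids = np.arange(self.matrix.shape[0])
        self.unit_ids = np.asarray(self.unit_ids)

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def subset(self, unit_idx: np.ndarray) -> "BinarizedRaster":
        unit_idx = np.asarray(unit_idx)
        return BinarizedRaster(self.matrix[unit_idx], bin_ms=self.bin_ms,
                               unit_ids=self.unit_ids[unit_idx],
                               multi_spike_fraction=self.multi_spike_fraction)


@dataclass
class PatternDistribution:
    """Probability mass over binary population words of length K.

    Words are encoded as integers with unit i contributing bit i (unit order is
    the catalog order, so word ``0b101`` means units 0 and 2 active).
    """

    probs: np.ndarray  # indexed by word integer when dense; else aligned to words
    k: int
    words: np.ndarray | None = None  # explicit support (sparse empirical case)
    n_samples: int | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < -1e-12):
            raise ValueError("probabilities must be non-negative")
        if not np.isclose(self.probs.sum(), 1.0, atol=1e-8):
            raise ValueError("probabilities must sum to 1")
        if self.words is None and self.probs.size != 2 ** self.k:
            raise ValueError("dense distribution must have 2**k entries")
        if self.words is not None:
            self.words = np.asarray(self.words, dtype=np.int64)
            if self.words.size != self.probs.size:
                raise ValueError("words and probs must align")

    def dense(self) -> np.ndarray:
        """Probability vector over all 2**k words, indexed by word integer."""
        if self.words is None:
            return self.probs
        out = np.zeros(2 ** self.k)
        out[self.words] = self.probs
        return out

    def entropy_bits(self) -> float:
        p = self.probs[self.probs > 0]
        return float(-(p * np.log2(p)).sum())


@dataclass
class IsingParameters:
    """Parameters of the pairwise maximum-entropy (Ising) model.

    ``h[i]`` is the excitability of unit i and ``J[i, j]`` the symmetric pairwise
    interaction; the model is P(s) ∝ exp(Σ h_i s_i + Σ_{i<j} J_ij s_i s_j) over
    binary words s ∈ {0, 1}^K.
    """

    h: np.ndarray
    J: np.ndarray

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float).ravel()
        self.J = np.asarray(self.J, dtype=float)
        k = self.h.size
        if self.J.shape != (k, k):
            raise ValueError("J must be K x K matching h")
        if not np.allclose(self.J, self.J.T, atol=1e-10):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0.0, atol=1e-10):
            raise ValueError("J must have zero diagonal")
        if not (np.all(np.isfinite(self.h)) and np.all(np.isfinite(self.J))):
            raise ValueError("parameters must be finite")

    @property
    def k(self) -> int:
        return self.h.size


def check_correlation_matrix(corr: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Validate a correlation matrix (symmetric, unit diagonal, PSD)."""
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=atol):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(corr), 1.0, atol=atol):
        raise ValueError("correlation matrix must have unit diagonal")
    w = np.linalg.eigvalsh((corr + corr.T) / 2)
    if w.min() < -1e-8:
        raise ValueError(f"correlation matrix not PSD (min eigenvalue {w.min():.3g})")
    return corr


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
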