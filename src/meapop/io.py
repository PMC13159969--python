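"""File formats, configuration and provenance.

Formats:

* spike lists — tab-delimited text with columns ``unit_id`` and ``time_s``,
  sorted within unit; the interchange format for sorted data.
* voltage — HDF5 with dataset ``voltage`` [n_channels x n_samples] (µV),
  dataset ``channel_coords_um`` [n_channels x 2] and attributes
  ``sampling_rate_hz`` and ``grid_pitch_um``.
* configuration — YAML or JSON mirroring :class:`PipelineConfig`; every run
  echoes its config hash and package version into output provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .datatypes import GRID_PITCH_UM, SAMPLING_RATE_HZ, VoltageRecording


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, serializable and hashable.

    Defaults are the analysis-chain values: 500–3,500 Hz band, 5 SD
    threshold, 0.8 merge correlation, 5% ISI violations below 2.5 ms,
    100 ms / 5 ms stationarity window, 25 ms smoothing, 10 ms bins,
    K = 2–18 for entropy and 2–14 for the pairwise model, 100 subsamples
    and bootstraps, alpha 0.05.
    """

    # filtering / detection
    low_hz: float = 500.0
    high_hz: float = 3500.0
    notch_hz: float = 60.0
    pad_s: float = 4.0
    k_sd: float = 5.0
    robust_sd: bool = False
    # event screening / clustering
    symmetry_corr_threshold: float = 0.9
    peak_trough_diff_uv: float = 8.0
    n_pca_components: int = 3
    max_clusters: int = 8
    merge_corr_threshold: float = 0.8
    min_events: int = 10
    # unit validation
    max_isi_violation_fraction: float = 0.05
    refractory_ms: float = 2.5
    # stationarity
    stationarity_n_sigma: float = 3.0
    window_ms: float = 100.0
    step_ms: float = 5.0
    n_hist_bins: int = 30
    # binarization / correlation
    bin_ms: float = 10.0
    sigma_ms: float = 25.0
    # entropy / maxent
    entropy_k_min: int = 2
    entropy_k_max: int = 18
    maxent_k_min: int = 2
    maxent_k_max: int = 14
    n_subsamples: int = 100
    n_bootstrap: int = 100
    maxent_tol: float = 1e-6
    maxent_max_iter: int = 5000
    # statistics
    alpha: float = 0.05
    n_comparisons: int | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else \
            yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def provenance(config: PipelineConfig) -> dict:
    from . import __version__
    return {"config_hash": config.hash(), "version": __version__}


# ---------------------------------------------------------------------------
# Spike lists
# ---------------------------------------------------------------------------

def write_spike_list(path: str | Path, trains: list[np.ndarray],
                     unit_ids: list[int] | None = None) -> None:
    path = Path(path)
    if unit_ids is None:
        unit_ids = list(range(len(trains)))
    with path.open("w") as f:
        f.write("unit_id\ttime_s\n")
        for uid, ts in zip(unit_ids, trains):
            for t in np.asarray(ts, dtype=float):
                f.write(f"{uid}\t{t:.9g}\n")


def read_spike_list(path: str | Path) -> tuple[list[np.ndarray], list[int]]:
    """Read a spike list; rejects malformed rows naming the line number."""
    path = Path(path)
    per_unit: dict[int, list[float]] = {}
    with path.open() as f:
        header = f.readline().strip().split("\t")
        if header != ["unit_id", "time_s"]:
            raise ValueError(f"{path}: expected header 'unit_id\\ttime_s', "
                             f"got {header}")
        for lineno, line in enumerate(f, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            try:
                uid, t = int(parts[0]), float(parts[1])
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time {t}")
            bucket = per_unit.setdefault(uid, [])
            if bucket and t < bucket[-1]:
                raise ValueError(f"{path}:{lineno}: non-monotone spike time "
                                 f"for unit {uid}")
            bucket.append(t)
    unit_ids = sorted(per_unit)
    return [np.array(per_unit[u]) for u in unit_ids], unit_ids


# ---------------------------------------------------------------------------
# Voltage HDF5
# ---------------------------------------------------------------------------

def write_voltage_h5(path: str | Path, recording: VoltageRecording,
                     grid_pitch_um: float = GRID_PITCH_UM) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage", data=recording.samples)
        f.create_dataset("channel_coords_um", data=recording.channel_coords_um)
        f.attrs["sampling_rate_hz"] = recording.sampling_rate_hz
        f.attrs["grid_pitch_um"] = grid_pitch_um


def read_voltage_h5(path: str | Path) -> VoltageRecording:
    with h5py.File(path, "r") as f:
        if "voltage" not in f:
            raise ValueError(f"{path}: missing 'voltage' dataset")
        if "sampling_rate_hz" not in f.attrs:
            raise ValueError(f"{path}: missing 'sampling_rate_hz' attribute")
        samples = f["voltage"][:]
        coords = f["channel_coords_um"][:] if "channel_coords_um" in f else None
        fs = float(f.attrs["sampling_rate_hz"])
    return VoltageRecording(samples=samples, sampling_rate_hz=fs,
                            channel_coords_um=coords)


# ---------------------------------------------------------------------------
# Rasters, model parameters, pattern distributions
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, raster) -> None:
    """Binarized raster as sparse triplet text: header, then (unit, bin) of 1s."""
    from .datatypes import BinarizedRaster
    assert isinstance(raster, BinarizedRaster)
    units, bins = np.nonzero(raster.matrix)
    with Path(path).open("w") as f:
        f.write(f"# n_units={raster.n_units} n_bins={raster.n_bins} "
                f"bin_ms={raster.bin_ms:g}\n")
        f.write("unit\tbin\n")
        for u, b in zip(units, bins):
            f.write(f"{u}\t{b}\n")


def read_raster(path: str | Path):
    from .datatypes import BinarizedRaster
    path = Path(path)
    with path.open() as f:
        meta = f.readline()
        if not meta.startswith("#"):
            raise ValueError(f"{path}: missing raster header line")
        fields = dict(kv.split("=") for kv in meta[1:].split())
        header = f.readline().strip().split("\t")
        if header != ["unit", "bin"]:
            raise ValueError(f"{path}: expected 'unit\\tbin' header")
        mat = np.zeros((int(fields["n_units"]), int(fields["n_bins"])),
                       dtype=np.int8)
        for lineno, line in enumerate(f, start=3):
            if not line.strip():
                continue
            try:
                u, b = map(int, line.split("\t"))
                mat[u, b] = 1
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    return BinarizedRaster(mat, bin_ms=float(fields["bin_ms"]))


def write_ising_json(path: str | Path, params,
                     config: PipelineConfig | None = None) -> None:
    """Fitted (h, J) with provenance."""
    payload = {"h": np.asarray(params.h).tolist(),
               "J": np.asarray(params.J).tolist()}
    if config is not None:
        payload.update(provenance(config))
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ising_json(path: str | Path):
    from .datatypes import IsingParameters
    d = json.loads(Path(path).read_text())
    return IsingParameters(h=np.array(d["h"]), J=np.array(d["J"]))


def write_pattern_distribution(path: str | Path, dist) -> None:
    """(word-integer, probability) table over the distribution's support."""
    words = dist.words if dist.words is not None else np.arange(dist.probs.size)
    with Path(path).open("w") as f:
        f.write("word\tprobability\n")
        for w, p in zip(words, dist.probs):
            f.write(f"{int(w)}\t{p:.12g}\n")
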