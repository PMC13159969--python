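"""End-to-end pipeline: chain every stage and compare synthetic cohorts.

A recording enters as raw voltage (then it is spike sorted) or as a spike
list (sorting skipped). It passes the stationarity gate, is binarized, and
yields the four statistic families of the analysis: per-unit firing rates,
pairwise smoothed correlations, subsampled word/count entropies, and the
held-out KL divergence of the fitted pairwise maximum-entropy model.
Cohorts of recordings grouped by condition (e.g. plating density) are then
compared family-by-family with Brunner–Munzel tests under Bonferroni
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import entropy as ent
from . import maxent as me
from .correlation import pairwise_correlation
from .datatypes import BinarizedRaster, UnitCatalog, Unit, VoltageRecording
from .io import PipelineConfig
from .localization import localize_units, positional_entropy_sweep
from .sorting import sort_recording
from .stationarity import stationarity_report
from .stats import pairwise_group_tests
from .synthetic import generate_correlated_trains, generate_triplet_synchrony_raster

log = logging.getLogger("meapop")


@dataclass
class RecordingResult:
    catalog: UnitCatalog
    stationary: bool
    stationarity_p: float
    raster: BinarizedRaster | None
    firing_rates_hz: np.ndarray
    correlations: np.ndarray          # upper-triangle values
    entropy_table: pd.DataFrame | None
    maxent_klds: np.ndarray           # one per subsample fit
    positions: pd.DataFrame | None = None
    positional_entropy: pd.DataFrame | None = None


def maxent_klds(raster: BinarizedRaster, k: int, n_subsamples: int = 10,
                tol: float = 1e-6, max_iter: int = 5000,
                seed: int | np.random.Generator = 0) -> np.ndarray:
    """Held-out KL divergence of pairwise fits on random K-unit subsets.

    Each subsample: pick K units, split the raster into contiguous halves,
    fit the pairwise model on the first half, evaluate KL(test ‖ model).
    """
    rng = np.random.default_rng(seed)
    if k > raster.n_units:
        raise ValueError(f"K={k} exceeds population size {raster.n_units}")
    out = []
    for _ in range(n_subsamples):
        idx = rng.choice(raster.n_units, size=k, replace=False)
        sub = raster.subset(idx)
        train, test = me.split_train_test(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = me.PairwiseIsingModel(train).fit(tol=tol, max_iter=max_iter)
        out.append(res.evaluate(test))
    return np.array(out)


def run_recording(spike_trains: list[np.ndarray] | None = None,
                  duration_s: float | None = None,
                  voltage: VoltageRecording | None = None,
                  config: PipelineConfig | None = None,
                  maxent_k: int | None = None,
                  maxent_subsamples: int = 10,
                  entropy_subsamples: int | None = None) -> RecordingResult:
    """Run the full chain on one recording.

    Provide either ``voltage`` (spike sorting runs first) or pre-sorted
    ``spike_trains`` with ``duration_s`` (sorting is skipped). A recording
    failing the stationarity gate is returned with ``stationary=False`` and
    no downstream statistics, mirroring the exclusion rule of the analysis.
    """
    cfg = config or PipelineConfig()
    positions = pos_entropy = None
    if voltage is not None:
        catalog = sort_recording(
            voltage, k_sd=cfg.k_sd, low_hz=cfg.low_hz, high_hz=cfg.high_hz,
            pad_s=cfg.pad_s, notch_hz=cfg.notch_hz,
            symmetry_corr_threshold=cfg.symmetry_corr_threshold,
            peak_trough_diff_uv=cfg.peak_trough_diff_uv,
            merge_corr_threshold=cfg.merge_corr_threshold,
            max_violation_fraction=cfg.max_isi_violation_fraction,
            refractory_ms=cfg.refractory_ms,
            n_pca_components=cfg.n_pca_components,
            max_clusters=cfg.max_clusters, min_events=cfg.min_events,
            robust_sd=cfg.robust_sd, seed=cfg.seed)
        log.info("sorted %d units (%d valid)", len(catalog),
                 len(catalog.valid_units()))
        ups = localize_units(catalog.valid_units(), voltage.channel_coords_um)
        positions = pd.DataFrame([(p.unit_id, p.x_um, p.y_um) for p in ups],
                                 columns=["unit_id", "x_um", "y_um"])
        if ups:
            pos_entropy = positional_entropy_sweep(ups)
    else:
        if spike_trains is None or duration_s is None:
            raise ValueError("need either voltage or spike_trains + duration_s")
        catalog = UnitCatalog(
            units=[Unit(unit_id=i, spike_times_s=np.asarray(ts))
                   for i, ts in enumerate(spike_trains)],
            duration_s=duration_s)

    if len(catalog.valid_units()) < 2:
        log.warning("fewer than 2 valid units: empty report")
        return RecordingResult(catalog, False, 1.0, None,
                               catalog.firing_rates_hz(), np.array([]), None,
                               np.array([]), positions, pos_entropy)

    rep = stationarity_report(catalog, n_sigma=cfg.stationarity_n_sigma,
                              window_ms=cfg.window_ms, step_ms=cfg.step_ms,
                              n_hist_bins=cfg.n_hist_bins, alpha=cfg.alpha,
                              seed=cfg.seed)
    if not rep.stationary:
        log.warning("recording failed stationarity gate (p=%.3g)", rep.welch_p)
        return RecordingResult(catalog, False, rep.welch_p, None,
                               catalog.firing_rates_hz(), np.array([]), None,
                               np.array([]), positions, pos_entropy)

    raster = ent.binarize(catalog.spike_trains(), catalog.duration_s,
                          bin_ms=cfg.bin_ms)
    corr = pairwise_correlation(raster, sigma_ms=cfg.sigma_ms)
    n_units = raster.n_units
    k_ent = range(cfg.entropy_k_min, min(cfg.entropy_k_max, n_units) + 1)
    etable = ent.subsampled_entropy(
        raster, k_ent,
        n_subsamples=(entropy_subsamples or cfg.n_subsamples),
        n_bootstrap=cfg.n_bootstrap, seed=cfg.seed)
    k_me = maxent_k or min(cfg.maxent_k_max, n_units, 6)
    klds = maxent_klds(raster, k_me, n_subsamples=maxent_subsamples,
                       tol=cfg.maxent_tol, max_iter=cfg.maxent_max_iter,
                       seed=cfg.seed)
    return RecordingResult(catalog, True, rep.welch_p, raster,
                           catalog.firing_rates_hz(),
                           corr.upper_triangle()["r"].to_numpy(),
                           etable, klds, positions, pos_entropy)


# ---------------------------------------------------------------------------
# Synthetic cohorts and group comparison
# ---------------------------------------------------------------------------

@dataclass
class CohortResult:
    """Per-group statistic distributions and the pairwise group-test tables."""

    per_recording: pd.DataFrame
    distributions: dict[str, dict[str, np.ndarray]]  # family -> group -> values
    tests: dict[str, pd.DataFrame]                   # family -> test table


def simulate_cohort_rasters(group_params: dict[str, dict],
                            n_recordings: int = 4, k: int = 8,
                            n_bins: int = 20_000,
                            seed: int | np.random.Generator = 0,
                            ) -> dict[str, list[BinarizedRaster]]:
    """Synthetic cohorts emulating cultures of different plating density.

    Each group dict carries ``rate_hz``, ``latent_corr`` and optionally
    ``sync_p`` (rate of exclusive triplet-synchrony events, the planted
    higher-order structure that degrades a pairwise model's fit).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, list[BinarizedRaster]] = {}
    for name, p in group_params.items():
        recs = []
        for _ in range(n_recordings):
            rates = np.full(k, p["rate_hz"]) * rng.uniform(0.7, 1.3, size=k)
            corr = np.full((k, k), p.get("latent_corr", 0.0))
            np.fill_diagonal(corr, 1.0)
            _, raster = generate_correlated_trains(
                rates, corr, duration_s=n_bins * 0.01, bin_s=0.01, seed=rng)
            sync_p = p.get("sync_p", 0.0)
            if sync_p > 0:
                extra = generate_triplet_synchrony_raster(
                    k, n_bins, background_p=0.0, sync_p=sync_p, seed=rng)
                raster = BinarizedRaster(
                    np.maximum(raster.matrix, extra.matrix[:, :raster.n_bins]))
            recs.append(raster)
        out[name] = recs
    return out


def compare_cohorts(cohorts: dict[str, list[BinarizedRaster]],
                    config: PipelineConfig | None = None,
                    maxent_k: int = 6, maxent_subsamples: int = 5,
                    entropy_k: int = 6, entropy_subsamples: int = 20,
                    seed: int | np.random.Generator = 0) -> CohortResult:
    """Compute the four statistic families per recording and test all group pairs."""
    cfg = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    rows = []
    dists: dict[str, dict[str, list]] = {
        fam: {g: [] for g in cohorts}
        for fam in ("firing_rate_hz", "correlation", "word_entropy_bits",
                    "maxent_kld_bits")}
    for group, rasters in cohorts.items():
        for r_idx, raster in enumerate(rasters):
            rates = raster.matrix.mean(axis=1) / (raster.bin_ms * 1e-3)
            corr = pairwise_correlation(raster, sigma_ms=cfg.sigma_ms)
            rvals = corr.upper_triangle()["r"].dropna().to_numpy()
            et = ent.subsampled_entropy(raster, [min(entropy_k, raster.n_units)],
                                        n_subsamples=entropy_subsamples,
                                        n_bootstrap=0, seed=rng)
            we = et.query("kind == 'word'")["value_bits"].to_numpy()
            klds = maxent_klds(raster, min(maxent_k, raster.n_units),
                               n_subsamples=maxent_subsamples,
                               tol=cfg.maxent_tol, seed=rng)
            dists["firing_rate_hz"][group].extend(rates)
            dists["correlation"][group].extend(rvals)
            dists["word_entropy_bits"][group].extend(we)
            dists["maxent_kld_bits"][group].extend(klds)
            rows.append((group, r_idx, rates.mean(),
                         np.nanmean(rvals) if rvals.size else np.nan,
                         we.mean(), klds.mean()))
    per_rec = pd.DataFrame(rows, columns=["group", "recording",
                                          "mean_rate_hz", "mean_correlation",
                                          "mean_word_entropy_bits",
                                          "mean_maxent_kld_bits"])
    dist_arrays = {fam: {g: np.asarray(v) for g, v in by_g.items()}
                   for fam, by_g in dists.items()}
    tests = {fam: pairwise_group_tests(by_g, alpha=cfg.alpha,
                                       n_comparisons=cfg.n_comparisons)
             for fam, by_g in dist_arrays.items()}
    return CohortResult(per_recording=per_rec, distributions=dist_arrays,
                        tests=tests)
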