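"""Stationarity screening of recordings.

Only recordings whose spiking statistics are constant over the session feed
the downstream population analyses (correlation, entropy, maximum entropy —
all of which assume an equilibrium distribution). Two checks are applied:

1. *Half-split rates*: each unit's firing rate on the first and second half
   of the recording must agree within a Poisson-scale tolerance.
2. *Moving-rate KL divergence*: a sliding-window rate series (100 ms window,
   5 ms step) is computed per unit; the histogram of rates in the first half
   is compared with the second half by Kullback–Leibler divergence. For a
   stationary recording, same-unit KL divergences are stochastically smaller
   than those between moving-rate distributions of different (random) units,
   which is tested with a Welch test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import UnitCatalog


@dataclass
class MovingRateSeries:
    """Firing rate (Hz) on a sliding grid of overlapping windows."""

    rates_hz: np.ndarray
    window_ms: float = 100.0
    step_ms: float = 5.0


@dataclass
class KLDComparison:
    kld_bits: float
    kind: str  # "same-unit" | "random-pair"


def half_split_rates(spike_times_s: np.ndarray, duration_s: float,
                     ) -> tuple[float, float]:
    """Firing rate (Hz) on [0, T/2) and [T/2, T)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    ts = np.asarray(spike_times_s, dtype=float)
    half = duration_s / 2
    n1 = int(np.sum(ts < half))
    return n1 / half, (ts.size - n1) / half


def half_split_pass(spike_times_s: np.ndarray, duration_s: float,
                    n_sigma: float = 3.0) -> tuple[bool, float, float]:
    """Poisson-tolerance test that the rate did not change between halves.

    Passes when |r1 − r2| ≤ n_sigma·√(2·r̄/(T/2)), the standard error of a
    rate difference for a Poisson train of the pooled rate.
    """
    r1, r2 = half_split_rates(spike_times_s, duration_s)
    if r1 == 0 and r2 == 0:
        warnings.warn("empty spike train: half-split check passes vacuously")
        return True, r1, r2
    rbar = (r1 + r2) / 2
    se = np.sqrt(2 * rbar / (duration_s / 2))
    return abs(r1 - r2) <= n_sigma * se, r1, r2


def moving_rate(spike_times_s: np.ndarray, duration_s: float,
                window_ms: float = 100.0, step_ms: float = 5.0,
                ) -> MovingRateSeries:
    """Sliding-window firing rate; value = count in [t, t+window) / window."""
    if window_ms < step_ms:
        raise ValueError("window must be at least the step size")
    ts = np.sort(np.asarray(spike_times_s, dtype=float))
    win, step = window_ms * 1e-3, step_ms * 1e-3
    n_win = int(np.floor((duration_s - win) / step)) + 1
    starts = np.arange(n_win) * step
    counts = np.searchsorted(ts, starts + win, side="left") - \
        np.searchsorted(ts, starts, side="left")
    return MovingRateSeries(counts / win, window_ms, step_ms)


def rate_distribution_kld(series_a: np.ndarray, series_b: np.ndarray,
                          n_hist_bins: int = 30,
                          symmetric: bool = False) -> KLDComparison:
    """KL(P_a ‖ P_b) in bits between histogrammed rate distributions.

    Both series are histogrammed on shared equal-width bins spanning the
    pooled range; a pseudocount of 1/(n·bins) regularizes empty bins so the
    divergence stays finite.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("cannot compare an empty rate series")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_hist_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)

    def _p(x: np.ndarray) -> np.ndarray:
        counts = np.histogram(x, bins=edges)[0].astype(float)
        counts += 1.0 / (x.size * n_hist_bins)
        return counts / counts.sum()

    pa, pb = _p(a), _p(b)
    kld = float(np.sum(pa * np.log2(pa / pb)))
    if symmetric:
        kld = 0.5 * (kld + float(np.sum(pb * np.log2(pb / pa))))
    return KLDComparison(kld_bits=max(kld, 0.0), kind="")


def _half_series(spike_times_s: np.ndarray, duration_s: float,
                 window_ms: float, step_ms: float,
                 ) -> tuple[np.ndarray, np.ndarray]:
    half = duration_s / 2
    ts = np.asarray(spike_times_s, dtype=float)
    first = moving_rate(ts[ts < half], half, window_ms, step_ms).rates_hz
    second = moving_rate(ts[ts >= half] - half, half, window_ms,
                         step_ms).rates_hz
    return first, second


def same_unit_klds(trains: list[np.ndarray], duration_s: float,
                   window_ms: float = 100.0, step_ms: float = 5.0,
                   n_hist_bins: int = 30) -> np.ndarray:
    """KL divergence between each unit's first- and second-half rate histograms."""
    out = []
    for ts in trains:
        a, b = _half_series(ts, duration_s, window_ms, step_ms)
        out.append(rate_distribution_kld(a, b, n_hist_bins).kld_bits)
    return np.array(out)


def random_pair_klds(trains: list[np.ndarray], duration_s: float,
                     n_pairs: int | None = None,
                     window_ms: float = 100.0, step_ms: float = 5.0,
                     n_hist_bins: int = 30,
                     seed: int | np.random.Generator = 0) -> np.ndarray:
    """KL divergence between half-series of *different*, randomly paired units."""
    if len(trains) < 2:
        raise ValueError("need at least 2 units for random pairs")
    rng = np.random.default_rng(seed)
    halves = [_half_series(ts, duration_s, window_ms, step_ms)
              for ts in trains]
    if n_pairs is None:
        n_pairs = len(trains)
    out = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(trains), size=2, replace=False)
        out.append(rate_distribution_kld(halves[i][0], halves[j][1],
                                         n_hist_bins).kld_bits)
    return np.array(out)


@dataclass
class StationarityReport:
    per_unit: pd.DataFrame      # unit, rate_first, rate_second, half_pass, kld_same
    same_unit_kld: np.ndarray
    random_pair_kld: np.ndarray
    welch_statistic: float
    welch_p: float
    stationary: bool


def stationarity_report(catalog: UnitCatalog, n_sigma: float = 3.0,
                        window_ms: float = 100.0, step_ms: float = 5.0,
                        n_hist_bins: int = 30, alpha: float = 0.05,
                        seed: int | np.random.Generator = 0,
                        ) -> StationarityReport:
    """Full stationarity decision for one recording.

    Per unit: half-split rate check and same-unit moving-rate KL divergence.
    Population level: one-sided Welch test that same-unit divergences are
    smaller than random-pair divergences; the recording is stationary when
    the test is significant and every unit passes the half-split check.
    """
    units = catalog.valid_units()
    if len(units) < 2:
        raise ValueError("need at least 2 valid units")
    trains = [u.spike_times_s for u in units]
    T = catalog.duration_s

    same = same_unit_klds(trains, T, window_ms, step_ms, n_hist_bins)
    rand = random_pair_klds(trains, T, window_ms=window_ms, step_ms=step_ms,
                            n_hist_bins=n_hist_bins, seed=seed)

    rows = []
    for u, kld in zip(units, same):
        ok, r1, r2 = half_split_pass(u.spike_times_s, T, n_sigma)
        rows.append((u.unit_id, r1, r2, ok, kld))
    per_unit = pd.DataFrame(rows, columns=["unit_id", "rate_first_hz",
                                           "rate_second_hz", "half_split_pass",
                                           "kld_same_bits"])

    if np.allclose(same, same[0]) and np.allclose(rand, rand[0]) and \
            np.isclose(same[0], rand[0]):
        warnings.warn("degenerate KL-D distributions: no contrast measurable")
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.ttest_ind(same, rand, equal_var=False,
                                alternative="less")
    stationary = bool(p < alpha and per_unit["half_split_pass"].all())
    return StationarityReport(per_unit=per_unit, same_unit_kld=same,
                              random_pair_kld=rand,
                              welch_statistic=float(stat), welch_p=float(p),
                              stationary=stationary)
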