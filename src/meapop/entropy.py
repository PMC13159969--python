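"""Count and word entropy of binarized population activity.

Spike trains are discretized into 10 ms bins (a bin is 1 if the unit fired at
least once in it). Two summaries of each time bin are compared:

* the *count* — how many units fired, discarding identity (K+1 possible
  values for K units); a proxy for synchrony.
* the *word* — the full binary pattern of who fired (2^K possible patterns).

Counts are a function of words, so word entropy is never below count entropy;
the gap measures structure in population activity that synchrony alone misses.
Entropies are plug-in (maximum-likelihood) estimates in bits, with a
Miller–Madow bias correction available. Because the number of simultaneously
recorded units varies between recordings, entropies are compared across
recordings by subsampling fixed-size unit subsets (K = 2–18) with bootstrap
resampling of time bins for stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BinarizedRaster


def binarize(spike_trains: list[np.ndarray], duration_s: float,
             bin_ms: float = 10.0) -> BinarizedRaster:
    """Binarize spike trains on a half-open 10 ms grid aligned to t = 0.

    A bin with one or more spikes maps to 1; the fraction of occupied bins
    holding more than one spike is reported on the raster (the analysis
    assumes it is small).
    """
    bin_s = bin_ms * 1e-3
    n_bins = int(np.floor(duration_s / bin_s))
    mat = np.zeros((len(spike_trains), n_bins), dtype=np.int8)
    multi = 0
    occupied = 0
    for i, ts in enumerate(spike_trains):
        ts = np.asarray(ts, dtype=float)
        if ts.size and (ts.min() < 0 or ts.max() >= duration_s):
            raise ValueError("spike times must lie in [0, duration)")
        counts = np.bincount((ts / bin_s).astype(int), minlength=n_bins)
        mat[i] = counts > 0
        occupied += int((counts > 0).sum())
        multi += int((counts > 1).sum())
    frac_multi = multi / occupied if occupied else 0.0
    return BinarizedRaster(mat, bin_ms=bin_ms,
                           multi_spike_fraction=frac_multi)


def n_count_patterns(k: int) -> int:
    """Number of distinct count values for a K-unit population (0..K)."""
    return k + 1


def n_word_patterns(k: int) -> int:
    """Number of distinct binary words for a K-unit population."""
    return 2 ** k


def _plugin_entropy_bits(counts: np.ndarray, miller_madow: bool = False) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    h = float(-(p * np.log2(p)).sum())
    if miller_madow:
        h += (len(p) - 1) / (2 * n * np.log(2))
    return h


@dataclass
class EntropyEstimate:
    value_bits: float
    kind: str  # "count" | "word"
    k: int
    n_bootstrap: int = 0
    bootstrap_sd: float = 0.0


def count_entropy(raster: BinarizedRaster | np.ndarray,
                  miller_madow: bool = False) -> EntropyEstimate:
    """Plug-in entropy of the per-bin active-unit count distribution, bits."""
    m = raster.matrix if isinstance(raster, BinarizedRaster) else np.asarray(raster)
    k = m.shape[0]
    counts = np.bincount(m.sum(axis=0).astype(int), minlength=k + 1)
    return EntropyEstimate(_plugin_entropy_bits(counts, miller_madow), "count", k)


def word_entropy(raster: BinarizedRaster | np.ndarray,
                 miller_madow: bool = False) -> EntropyEstimate:
    """Plug-in entropy of the empirical binary-word distribution, bits."""
    m = raster.matrix if isinstance(raster, BinarizedRaster) else np.asarray(raster)
    k = m.shape[0]
    codes = m.astype(np.int64).T @ (1 << np.arange(k, dtype=np.int64))
    _, counts = np.unique(codes, return_counts=True)
    return EntropyEstimate(_plugin_entropy_bits(counts, miller_madow), "word", k)


def subsampled_entropy(raster: BinarizedRaster, k_range: range | list[int] = range(2, 19),
                       n_subsamples: int = 100, n_bootstrap: int = 100,
                       seed: int | np.random.Generator = 0,
                       miller_madow: bool = False) -> pd.DataFrame:
    """Count and word entropy over random K-unit subsets for each K.

    For each population size K in ``k_range`` draws ``n_subsamples`` random
    unit subsets; for the first subset of each K, ``n_bootstrap`` bootstrap
    resamples of time bins give the stability (SD) of the estimate.
    Deterministic given the seed. Returns a long-format table
    (K, subsample, kind, value_bits, bootstrap_sd).
    """
    rng = np.random.default_rng(seed)
    m = raster.matrix
    n_units, n_bins = m.shape
    rows = []
    for k in k_range:
        if k > n_units:
            warnings.warn(f"K={k} exceeds population size {n_units}; skipped")
            continue
        for s in range(n_subsamples):
            idx = rng.choice(n_units, size=k, replace=False)
            sub = m[idx]
            ce = count_entropy(sub, miller_madow).value_bits
            we = word_entropy(sub, miller_madow).value_bits
            sd_c = sd_w = np.nan
            if s == 0 and n_bootstrap > 0:
                boots_c, boots_w = [], []
                for _ in range(n_bootstrap):
                    bidx = rng.integers(0, n_bins, size=n_bins)
                    boots_c.append(count_entropy(sub[:, bidx],
                                                 miller_madow).value_bits)
                    boots_w.append(word_entropy(sub[:, bidx],
                                                miller_madow).value_bits)
                sd_c, sd_w = float(np.std(boots_c)), float(np.std(boots_w))
            rows.append((k, s, "count", ce, sd_c))
            rows.append((k, s, "word", we, sd_w))
    return pd.DataFrame(rows, columns=["K", "subsample", "kind", "value_bits",
                                       "bootstrap_sd"])
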