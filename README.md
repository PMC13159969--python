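# meapop

Population-activity analysis of multi-electrode-array (MEA) recordings from
neuronal cultures — from raw 64-channel extracellular voltage to the headline
population-complexity statistic: the held-out Kullback–Leibler divergence of a
pairwise maximum-entropy (Ising) model.

MEA plates (here an 8×8 electrode grid, 300 µm pitch, sampled at 12.5 kHz)
are the standard functional readout for iPSC-derived neural cultures, where
plating density and other culture parameters vary widely across studies. This
package implements the full analysis chain a careful study of such cultures
needs, with a synthetic ground-truth generator so every stage is verifiable
without any recording in hand:

1. **Spike sorting** — 500–3,500 Hz Butterworth band-pass + 60 Hz notch
   (zero-phase, 4 s padding), 5 SD event detection, rejection of
   time-symmetric oscillation noise, PCA + EM Gaussian-mixture clustering
   (BIC model selection), merging of clusters with waveform correlation
   > 0.8, cross-channel deduplication, and validation (< 5% of interspike
   intervals below the 2.5 ms refractory period; no compound-spike waveforms).
2. **Localization** — amplitude-weighted triangulation of each unit's soma
   from the integral of |waveform| per channel, and normalized positional
   entropy of the unit map over square regions spanning two decades of scale.
3. **Stationarity screening** — half-split firing-rate agreement and
   moving-rate (100 ms window, 5 ms step) distributions compared by KL
   divergence; recordings where same-unit divergences are not significantly
   below random-pair divergences (Welch test) are excluded downstream.
4. **Pairwise correlation** — spike trains binarized at 10 ms, convolved with
   a 25 ms Gaussian, Pearson correlation for all unit pairs.
5. **Count & word entropy** — the per-bin *count* (how many units fired;
   a synchrony measure with K+1 possible values) versus the *word* (which
   units fired; 2^K possible patterns), plug-in entropies in bits with
   population-size subsampling (K = 2–18) and bootstrap stability.
6. **Maximum entropy** — the pairwise Ising model

   P(s) = Z⁻¹ exp( Σᵢ hᵢ sᵢ + Σ_{i<j} J_{ij} sᵢ sⱼ ),  s ∈ {0,1}^K

   fitted by exact maximum likelihood (full 2^K enumeration, K ≤ 14) to one
   half of the binarized data, evaluated on the other half by
   KL(empirical ‖ model) in bits. Low divergence means rates and pairwise
   couplings explain the population's word statistics; high divergence means
   genuine higher-order structure.
7. **Statistics** — Brunner–Munzel rank tests with Bonferroni correction
   (the data are non-normal with unequal variances), KS/Levene diagnostics,
   Wilcoxon rank-sum, Welch tests.

## Worked example

Fit the pairwise model to a synthetic 5-unit culture with heterogeneous
firing rates (1–5 Hz) and latent correlation 0.3, and measure how well it
predicts held-out activity:

```python
import numpy as np
from meapop import PairwiseIsingModel, split_train_test, binarize
from meapop import word_entropy, count_entropy
from meapop.synthetic import generate_correlated_trains

rates = np.array([1.0, 2.0, 3.0, 4.0, 5.0])           # Hz
corr = np.full((5, 5), 0.3); np.fill_diagonal(corr, 1.0)
trains, _ = generate_correlated_trains(rates, corr, duration_s=900.0, seed=0)

raster = binarize(trains, duration_s=900.0)            # 10 ms bins
print("word entropy:  %.3f bits" % word_entropy(raster).value_bits)
print("count entropy: %.3f bits" % count_entropy(raster).value_bits)

train, test = split_train_test(raster)                 # contiguous halves
res = PairwiseIsingModel(train).fit()
print("held-out KL divergence: %.4f bits" % res.evaluate(test))
print(res.summary())
```

Output:

```
word entropy:  0.934 bits
count entropy: 0.647 bits
held-out KL divergence: 0.0015 bits
Pairwise maximum-entropy (Ising) model
======================================================
Units (K):            5
Training bins:        45000
Max moment residual:  1.06e-10
Model entropy (bits): 0.9240
Log-likelihood / bin: -0.6404
------------------------------------------------------
excitability h_i                 est       se
  h[ 0]                       -4.8871   0.0552
  h[ 1]                       -4.1725   0.0394
  ...
```

Reading the numbers: word entropy exceeds count entropy (identity of the
firing units carries information that synchrony alone misses); the held-out
KL divergence of 0.0015 bits says the pairwise model captures this
population's word statistics almost perfectly — as it must, since the
generator contains no higher-order structure. The fitted excitabilities h
increase with firing rate and the interactions J are positive, mirroring the
planted correlation.

A command-line interface mirrors the library stage by stage
(`meapop simulate | sort | stationarity | localize | correlate | entropy |
maxent | compare | all`); run `meapop --help`.

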