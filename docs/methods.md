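# Methods

## Scope and model

The package analyses population spiking in cultured neuronal networks
recorded on a planar MEA (8×8 electrodes, 300 µm pitch, 2.1 × 2.1 mm area,
12.5 kHz). Its central object is the second-order maximum-entropy (pairwise
Ising) model of binarized population activity: among all distributions over
binary words s ∈ {0,1}^K that match each unit's firing probability ⟨sᵢ⟩ and
each pair's co-activation probability ⟨sᵢsⱼ⟩, it is the one with maximal
entropy,

P(s) = Z⁻¹ exp( Σᵢ hᵢ sᵢ + Σ_{i<j} J_{ij} sᵢ sⱼ ).

The held-out KL divergence between the empirical word distribution and the
fitted model measures how much population structure is *not* explained by
rates and pairwise coupling — the package's headline complexity statistic.
The model assumes the recording is in statistical equilibrium, which is why
a stationarity screen gates every analysis.

## Fitting

The log-likelihood is concave in (h, J). We maximize it exactly: all 2^K
states are enumerated (K ≤ 14, i.e. ≤ 16,384 states), giving exact gradients
(model moments minus empirical moments) and Hessians (feature covariance
under the model). A trust-region Newton ascent (`scipy.optimize.minimize`,
`trust-exact`) is followed by a plain Newton polish; convergence is declared
only when every moment residual is below `tol` (default 10⁻⁶), otherwise the
fit raises rather than returning a silently bad model. Initialization is the
independent model (h = logit of empirical means, J = 0); by concavity it
affects only speed. Standard errors come from the inverse Fisher information
at the optimum divided by the number of training bins.

Degenerate moments (a unit never/always active, a perfectly coupled pair)
put the MLE at infinity. Empirical moments are therefore clipped into
[1/(2n), 1 − 1/(2n)] and pair moments additionally into the feasible
interval implied by the clipped means; this keeps parameters finite at a
documented O(1/n) bias. KL is evaluated as KL(empirical ‖ model), which is
always finite because the Boltzmann distribution is strictly positive; the
train/test split is contiguous halves, consistent with the stationarity
screen's half-split logic.

## Entropies

Activity is binarized in half-open 10 ms bins (≥ 1 spike → 1; the fraction
of multi-spike bins is reported and should stay small at culture firing
rates). Count entropy is the plug-in entropy of the per-bin active-unit
count (K+1 values); word entropy that of the full binary pattern (2^K
values, encoded as integers with unit i at bit i, catalog order). Counts are
a function of words, so H_word ≥ H_count on every raster — the suite tests
this exhaustively. Because recordings yield different population sizes,
entropies are compared via random K-unit subsets (K = 2–18, 100 subsamples
per K) with bootstrap resampling of time bins (100 draws) reported as an SD;
no automatic pass/fail is attached to the bootstrap. The plug-in estimator
is used by default; a Miller–Madow correction is available behind a flag.
Plug-in estimates are biased low by roughly (support − 1)/(2n ln 2), which
cancels in the within-K comparisons the pipeline makes.

## Spike sorting

Filtering: 3rd-order Butterworth band-pass 500–3,500 Hz applied
forward-backward (zero phase, preserving waveform shape), then a 60 Hz
notch (Q = 30); 4 s reflection padding absorbs filter transients and is
trimmed, so output length equals input length.

Detection: candidate events are local peaks of |trace − mean| separated by a
1 ms dead time; those exceeding k·SD (default k = 5; SD is the literal
standard deviation, with a 1.4826·MAD option) are kept. Selecting by height
from a threshold-independent peak set makes the detected count exactly
monotone in k, which a raw excursion-grouping rule does not guarantee
(an excursion can split in two as the threshold rises).

Waveforms are cut 1 ms before to 2 ms after the trough (13 + 25 samples) on
the detecting channel and its grid neighbors (≤ 450 µm). Oscillation noise
is rejected by time-symmetry — the maximal lagged correlation between a
snippet and its time-reverse (reversal only phase-shifts a periodic signal,
so noise scores near 1 at some lag; a spike's sharp drop and slow recovery
match their mirror at no lag) — combined with a |peak| − |trough| amplitude
difference below 8 µV. The symmetry threshold defaults to 0.9 and the
difference is interpreted in µV; both are configurable.

Events whose amplitude peaks on a neighboring electrode are dropped before
clustering (that electrode claims them), preventing one neuron from seeding
units on several channels. Clustering is PCA followed by an EM-fitted
Gaussian mixture with the component count chosen by BIC over 1–8 (10 EM
restarts, fixed seed). PCA keeps 3 components by default: two suffice for
single-channel shape, but the concatenated multi-channel snippet also
carries a spatial amplitude profile that needs a dimension of its own.
Clusters with mean-waveform correlation > 0.8 are merged transitively
(anti-overclustering); inside the full sorter this merge additionally
requires peak amplitudes within a factor 2, because shape correlation is
amplitude-blind and a distant neuron's decayed bleed has the right shape at
the wrong size. Across channels, a unit whose spikes mostly (> 50% within
±0.5 ms) coincide with larger-amplitude, waveform-matched units is absorbed
by them; absorption is directional and pooled, so a small contaminated
cluster cannot chain two real units together, and no electrode-distance gate
is applied (sub-millisecond coincidence identifies the same neuron at any
range).

Validation: units with ≥ 5% of interspike intervals under 2.5 ms fail the
refractory check (a 5 ms variant is exposed in config); units whose mean
waveform has more than one extremum exceeding half the global extremum are
flagged as compound spikes. Failed units stay in the catalog with flags set
but are excluded from every downstream analysis.

## Localization and positional entropy

A unit's position is the weighted mean of its electrodes' coordinates with
weights ∫|mean waveform| per channel — a visualization-grade estimate that
is exact when one channel dominates and always inside the contributing
electrodes' convex hull. Spatial homogeneity: units are assigned to square
regions (grid anchored at the array's lower-left corner, half-open regions)
and the entropy of the unit-count distribution is normalized by
log₂(min(n_units, n_regions)) — the most random arrangement cannot occupy
more regions than there are units. Region sizes sweep 100 µm–10 mm
(two decades). The distribution is over units, not spikes.

## Stationarity screen

Per unit: firing rates on the two halves must agree within
3·√(2r̄/(T/2)) (the Poisson standard error of a rate difference; the factor
is configurable). Per recording: each unit's moving-rate series (100 ms
window, 5 ms step) is histogrammed per half on 30 shared equal-width bins
with a 1/(n·bins) pseudocount, and compared by KL(first ‖ second) in bits
(a symmetric variant is available). The same-unit divergences are tested
against divergences between halves of randomly paired distinct units with a
one-sided Welch t-test; the recording passes only when same-unit divergences
are significantly smaller and every unit passes the half-split check. The
comparison is per-recording.

## Pairwise correlation

Binarized trains are convolved with a unit-area Gaussian kernel, σ = 25 ms
(σ, not FWHM; 2.5 bins on the 10 ms raster grid), truncated at ±4σ, and
Pearson correlation is computed per pair. Zero-variance units produce NaN
entries with a warning, never a silent zero.

## Group statistics

The distributional comparisons use the two-sided Brunner–Munzel test
(t approximation with Satterthwaite degrees of freedom), which is valid
under non-normality and unequal variances — both verified by per-group KS
normality and Levene absolute-deviation checks. The Bonferroni family size
is always an explicit argument (15 comparisons give the 0.0033 threshold
used for the five-density contrasts; it is never inferred). Completely
separated samples, where the rank variance degenerates, are reported at the
exact permutation bound 2/C(n_a+n_b, n_a) rather than as a failure. The
word-vs-count entropy comparison uses the Wilcoxon rank-sum test (exact for
small tie-free samples).

## Synthetic ground truth

Three generators, all bit-reproducible given (parameters, seed):

* **Exact Ising sampler** — i.i.d. words from the enumerated Boltzmann
  distribution (K ≤ 16); the forward oracle for fitting.
* **Dichotomized Gaussian** — correlated binary trains obtained by
  thresholding a latent Gaussian vector at Φ⁻¹(1 − rate·bin) per unit.
  Its observed binary correlation has a closed form via the bivariate-normal
  orthant probability, so generated correlations are analytically checkable;
  measured correlation is monotone in the latent one. Spike times get a
  uniform within-bin offset shared across units, so fully coupled units emit
  literally identical trains and binarization at 10 ms is exactly
  recoverable.
* **Voltage synthesis** — each planted spike stamps a single-peaked template
  (sharp Gaussian trough, 30% slow recovery bump) onto all channels scaled
  by 1/(1 + d/λ) with λ = 150 µm from the unit's true position, plus i.i.d.
  Gaussian noise. The 1/(1 + d/λ) law is a package choice — real
  extracellular decay and correlated noise are not modelled.

Default culture statistics (rates 0.1–5 Hz, latent correlations 0–0.6) are
plausible ranges for dissociated cultures, chosen once; real cultures also
exhibit bursting, rate drift, electrode artifacts and waveform
non-stationarity that the generators deliberately omit. Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical assumptions, not robustness to every pathology of real
recordings. The higher-order test cohort plants *exclusive triplet
synchrony* (a random triplet fires alone in designated bins) — third-order
structure that no pairwise model can capture — to verify that held-out KL
divergence separates pairwise-complete from higher-order populations.

## Problem sizes and numerical choices

The test and acceptance workloads use scaled-down but statistically adequate
sizes chosen as study conditions: 3 planted units on a 4×4 grid corner with
60 s of 12.5 kHz voltage at SNR 20 for sorting recovery; 50 recordings per
arm, K = 6, 20,000 bins for the KL discrimination; 10⁵ bins for parameter
recovery; 10,000 replicates for type-I calibration. Times are stored as
64-bit float seconds; bins are half-open [t, t+Δ); unit indices are 0-based
internally and 1-based only in human-facing tables. Ties in region
assignment, bin assignment and absorption ordering are broken
deterministically (lower index / larger amplitude first), and every
stochastic routine takes an explicit seed.

## Known limitations

* Exact enumeration caps the model at K = 14 (fit) / 16 (sampling); no
  pseudolikelihood or MCMC path for larger populations.
* Plug-in entropies are biased at small n; only Miller–Madow is offered.
* The sorter targets well-separated, stationary units; no drift correction,
  template matching, or overlapping-spike resolution.
* Burst-scale dynamics (hundreds of ms) are outside scope; all statistics
  live at the 10–25 ms scale.
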