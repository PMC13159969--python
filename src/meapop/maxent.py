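"""Second-order maximum-entropy (pairwise Ising) modelling of population words.

The model over binary words s ∈ {0,1}^K is

    P(s) = exp( Σ_i h_i s_i + Σ_{i<j} J_ij s_i s_j ) / Z,

the maximum-entropy distribution constrained to match each unit's firing
probability ⟨s_i⟩ and each pair's co-activation probability ⟨s_i s_j⟩.
Fitting maximizes the (concave) log-likelihood with exact gradients and
Hessians obtained by enumerating all 2^K states, which is feasible for the
population sizes analysed here (K ≤ 14). Goodness of fit is the
Kullback–Leibler divergence between the held-out empirical word distribution
and the model distribution, in bits.

Usage follows the Model/Results idiom::

    model = PairwiseIsingModel(train_raster)
    res = model.fit()
    res.params.h, res.params.J
    kld = evaluate_fit(res.distribution, test_raster)
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .datatypes import BinarizedRaster, IsingParameters, PatternDistribution

MAX_K_FIT = 14
MAX_K_ENUM = 16

_LN2 = np.log(2.0)


def enumerate_states(k: int) -> np.ndarray:
    """All 2^k binary words as a (2^k, k) matrix; word w has bit i = unit i."""
    if k > MAX_K_ENUM:
        raise ValueError(f"exact enumeration limited to K <= {MAX_K_ENUM}, got {k}")
    words = np.arange(2 ** k, dtype=np.int64)
    return ((words[:, None] >> np.arange(k)) & 1).astype(np.int8)


def _pair_index(k: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(k, k=1)


def _feature_matrix(k: int) -> np.ndarray:
    """Sufficient statistics per state: [s_1..s_K, s_i s_j for i<j]."""
    s = enumerate_states(k).astype(float)
    iu, ju = _pair_index(k)
    return np.hstack([s, s[:, iu] * s[:, ju]])


def _theta_to_params(theta: np.ndarray, k: int) -> IsingParameters:
    h = theta[:k]
    J = np.zeros((k, k))
    iu, ju = _pair_index(k)
    J[iu, ju] = theta[k:]
    return IsingParameters(h=h, J=J + J.T)


def _params_to_theta(params: IsingParameters) -> np.ndarray:
    iu, ju = _pair_index(params.k)
    return np.concatenate([params.h, params.J[iu, ju]])


def model_word_distribution(params: IsingParameters) -> PatternDistribution:
    """Exact Boltzmann distribution over all 2^K words; strictly positive."""
    F = _feature_matrix(params.k)
    logits = F @ _params_to_theta(params)
    logp = logits - logsumexp(logits)
    return PatternDistribution(probs=np.exp(logp), k=params.k)


def empirical_word_distribution(raster: BinarizedRaster | np.ndarray,
                                ) -> PatternDistribution:
    """Empirical probability of each observed word (sparse support)."""
    m = raster.matrix if isinstance(raster, BinarizedRaster) else np.asarray(raster)
    k, n = m.shape
    codes = (m.astype(np.int64).T @ (1 << np.arange(k, dtype=np.int64)))
    words, counts = np.unique(codes, return_counts=True)
    return PatternDistribution(probs=counts / n, k=k, words=words, n_samples=n)


def split_train_test(raster: BinarizedRaster) -> tuple[BinarizedRaster,
                                                       BinarizedRaster]:
    """Contiguous half split: first half trains the model, second evaluates it."""
    n = raster.n_bins
    if n < 2:
        raise ValueError("need at least 2 bins to split")
    half = n // 2
    return (BinarizedRaster(raster.matrix[:, :half], bin_ms=raster.bin_ms,
                            unit_ids=raster.unit_ids),
            BinarizedRaster(raster.matrix[:, half:], bin_ms=raster.bin_ms,
                            unit_ids=raster.unit_ids))


def evaluate_fit(model: PatternDistribution,
                 test_raster: BinarizedRaster | np.ndarray) -> float:
    """KL(empirical held-out ‖ model) in bits; finite because the model is
    strictly positive on every word. Higher values mean the pairwise model
    fails to capture structure in the data (more complex population)."""
    emp = empirical_word_distribution(test_raster)
    if emp.n_samples == 0:
        raise ValueError("test raster is empty")
    q = model.dense()[emp.words]
    return float(np.sum(emp.probs * (np.log2(emp.probs) - np.log2(q))))


def _clip_moments(mean_s: np.ndarray, mean_pair: np.ndarray, n: int,
                  iu: np.ndarray, ju: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Keep empirical moments strictly inside the feasible polytope.

    Boundary moments (a unit never/always active, a pair perfectly coupled)
    push the MLE to infinity; the 1/(2n) clip trades a documented O(1/n) bias
    for finite parameters.
    """
    eps = 1.0 / (2 * n)
    clipped = np.clip(mean_s, eps, 1 - eps)
    pair = np.clip(mean_pair, eps, 1 - eps)
    lo = np.maximum(eps, clipped[iu] + clipped[ju] - 1 + eps)
    hi = np.minimum(clipped[iu], clipped[ju]) - eps
    bad = lo > hi
    # degenerate interval: fall back to the independent prediction
    pair = np.where(bad, clipped[iu] * clipped[ju], np.clip(pair, lo, hi))
    return clipped, pair


class ConvergenceError(RuntimeError):
    """Raised when moment matching does not reach tolerance."""

    def __init__(self, msg: str, residuals: np.ndarray):
        super().__init__(msg)
        self.residuals = residuals


class PairwiseIsingModel:
    """Pairwise maximum-entropy model of a binarized population raster.

    Parameters
    ----------
    raster : BinarizedRaster or (K, n_bins) binary array
        Training data; K ≤ 14 (the fit enumerates all 2^K words exactly).

    Notes
    -----
    The log-likelihood is concave, so the quasi-Newton ascent converges to the
    unique maximum-entropy solution regardless of initialization; ``h`` starts
    at the logit of the empirical means and ``J`` at zero (the independent
    model), which only affects speed.
    """

    def __init__(self, raster: BinarizedRaster | np.ndarray):
        if not isinstance(raster, BinarizedRaster):
            raster = BinarizedRaster(np.asarray(raster))
        if raster.n_units > MAX_K_FIT:
            raise ValueError(
                f"exact fitting limited to K <= {MAX_K_FIT} units, "
                f"got {raster.n_units}")
        self.raster = raster
        self.k = raster.n_units
        self.n_obs = raster.n_bins
        m = raster.matrix.astype(float)
        iu, ju = _pair_index(self.k)
        mean_s = m.mean(axis=1)
        mean_pair = (m[iu] * m[ju]).mean(axis=1)
        if np.any(mean_s <= 0) or np.any(mean_s >= 1):
            warnings.warn("unit(s) never or always active in training data; "
                          "moments clipped to keep parameters finite")
        self._raw_moments = np.concatenate([mean_s, mean_pair])
        mean_s, mean_pair = _clip_moments(mean_s, mean_pair, self.n_obs, iu, ju)
        self.target_moments = np.concatenate([mean_s, mean_pair])
        self._F = _feature_matrix(self.k)

    @classmethod
    def from_spike_trains(cls, trains: list[np.ndarray], duration_s: float,
                          bin_ms: float = 10.0) -> "PairwiseIsingModel":
        from .entropy import binarize
        return cls(binarize(trains, duration_s, bin_ms=bin_ms))

    # -- likelihood machinery (per-observation scale) -----------------------

    def _model_moments(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits = self._F @ theta
        logp = logits - logsumexp(logits)
        p = np.exp(logp)
        return p, p @ self._F

    def _negloglik(self, theta: np.ndarray) -> float:
        logits = self._F @ theta
        return float(logsumexp(logits) - self.target_moments @ theta)

    def _grad(self, theta: np.ndarray) -> np.ndarray:
        _, mu = self._model_moments(theta)
        return mu - self.target_moments

    def _hess(self, theta: np.ndarray) -> np.ndarray:
        p, mu = self._model_moments(theta)
        return (self._F.T * p) @ self._F - np.outer(mu, mu)

    def fit(self, tol: float = 1e-6, max_iter: int = 5000,
            seed: int | None = None) -> "IsingFitResults":
        """Fit by exact quasi-Newton ascent on the concave log-likelihood.

        Converged when every model moment matches its (clipped) empirical
        target within ``tol``. ``seed`` is accepted for interface uniformity;
        the optimization is deterministic.

        Raises
        ------
        ConvergenceError
            If the maximum moment residual exceeds ``tol`` after polishing.
        """
        k = self.k
        mean_s = self.target_moments[:k]
        theta0 = np.concatenate([np.log(mean_s / (1 - mean_s)),
                                 np.zeros(k * (k - 1) // 2)])
        res = optimize.minimize(self._negloglik, theta0, jac=self._grad,
                                hess=self._hess, method="trust-exact",
                                options={"gtol": 0.1 * tol,
                                         "maxiter": max_iter})
        theta = res.x
        # Newton polish: the gradient IS the moment residual
        for _ in range(50):
            g = self._grad(theta)
            if np.max(np.abs(g)) <= 0.1 * tol:
                break
            H = self._hess(theta)
            try:
                step = np.linalg.solve(H + 1e-12 * np.eye(H.shape[0]), g)
            except np.linalg.LinAlgError:
                break
            theta = theta - step
        residuals = self._grad(theta)
        if np.max(np.abs(residuals)) > tol:
            raise ConvergenceError(
                f"moment matching failed: max residual "
                f"{np.max(np.abs(residuals)):.3g} > tol {tol:.3g}", residuals)
        params = _theta_to_params(theta, k)
        fisher = self._hess(theta)
        cov = np.linalg.pinv(fisher) / self.n_obs
        return IsingFitResults(model=self, params=params,
                               moment_residuals=residuals,
                               cov_params=cov, n_iter=int(res.nit))


@dataclass
class IsingFitResults:
    """Estimates, uncertainties and diagnostics of a pairwise Ising fit."""

    model: PairwiseIsingModel
    params: IsingParameters
    moment_residuals: np.ndarray
    cov_params: np.ndarray  # asymptotic covariance of (h, J_upper)
    n_iter: int
    _distribution: PatternDistribution | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return self.params.k

    @property
    def distribution(self) -> PatternDistribution:
        """Model word distribution (exact Boltzmann probabilities)."""
        if self._distribution is None:
            self._distribution = model_word_distribution(self.params)
        return self._distribution

    @property
    def bse(self) -> np.ndarray:
        """Asymptotic standard errors of the stacked (h, J_upper) parameters."""
        return np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    @property
    def h_se(self) -> np.ndarray:
        return self.bse[: self.k]

    @property
    def j_se(self) -> np.ndarray:
        return self.bse[self.k:]

    @property
    def max_moment_residual(self) -> float:
        return float(np.max(np.abs(self.moment_residuals)))

    def entropy_bits(self) -> float:
        return self.distribution.entropy_bits()

    def loglike_per_bin(self) -> float:
        return -self.model._negloglik(_params_to_theta(self.params))

    def sample(self, n_samples: int, seed: int | np.random.Generator = 0,
               ) -> BinarizedRaster:
        """Draw i.i.d. words from the fitted model (exact sampler)."""
        from .synthetic import sample_ising_exact
        return sample_ising_exact(self.params, n_samples, seed)

    def evaluate(self, test_raster: BinarizedRaster | np.ndarray) -> float:
        """KL(held-out empirical ‖ model) in bits."""
        return evaluate_fit(self.distribution, test_raster)

    def summary(self) -> str:
        """Plain-text summary in the spirit of statsmodels results."""
        buf = StringIO()
        iu, ju = _pair_index(self.k)
        buf.write("Pairwise maximum-entropy (Ising) model\n")
        buf.write("=" * 54 + "\n")
        buf.write(f"Units (K):            {self.k}\n")
        buf.write(f"Training bins:        {self.model.n_obs}\n")
        buf.write(f"Max moment residual:  {self.max_moment_residual:.2e}\n")
        buf.write(f"Model entropy (bits): {self.entropy_bits():.4f}\n")
        buf.write(f"Log-likelihood / bin: {self.loglike_per_bin():.4f}\n")
        buf.write("-" * 54 + "\n")
        buf.write("excitability h_i                 est       se\n")
        for i in range(self.k):
            buf.write(f"  h[{i:>2}]                    {self.params.h[i]:>10.4f} "
                      f"{self.h_se[i]:>8.4f}\n")
        buf.write("interaction J_ij                 est       se\n")
        for idx, (i, j) in enumerate(zip(iu, ju)):
            buf.write(f"  J[{i:>2},{j:>2}]                "
                      f"{self.params.J[i, j]:>10.4f} {self.j_se[idx]:>8.4f}\n")
        return buf.getvalue()


def params_vs_statistics(results: list[IsingFitResults],
                         bin_ms: float = 10.0) -> pd.DataFrame:
    """Pair fitted parameters with the empirical statistics they should track.

    For every fit: h_i against the unit's firing rate (Hz) in the training
    raster, and J_ij against the Pearson correlation of the binarized pair.
    Long format with columns (fit, kind, i, j, param, statistic).
    """
    if len(results) < 1:
        raise ValueError("need at least one fit")
    rows = []
    for f_idx, res in enumerate(results):
        m = res.model.raster.matrix.astype(float)
        rates = m.mean(axis=1) / (bin_ms * 1e-3)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(m)
        for i in range(res.k):
            rows.append((f_idx, "h", i, -1, res.params.h[i], rates[i]))
        iu, ju = _pair_index(res.k)
        for i, j in zip(iu, ju):
            rows.append((f_idx, "J", int(i), int(j), res.params.J[i, j],
                         corr[i, j]))
    return pd.DataFrame(rows, columns=["fit", "kind", "i", "j", "param",
                                       "statistic"])
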