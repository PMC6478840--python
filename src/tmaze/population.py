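"""Phenotype heterogeneity of a clonal population.

Tumble bias is Beta(α, β) distributed.  The pathway gain g = N·H compounds
three sources of expression noise: the receptor-cluster size N_tot
(Poisson, mean λ), the Tar/Tsr composition ratio r = N/(N_tot − N)
(Gamma, shape γ, scale δ), and the motor amplification H (Gaussian, mean µ,
s.d. σ, truncated at zero).  The gain density h_g is the resulting compound
distribution, evaluated by a truncated double sum over cluster size k and
integer Tar count N (1 ≤ N ≤ k−1; the composition weight diverges at N = k,
which is excluded), with a Gaussian kernel in g/N:

    h_g(g) ∝ Σ_k P(k; λ) Σ_N w(N | k; γ, δ) · φ((g/N − µ)/σ) / N .

Under the grouped-constant convention the chemotactic velocity of a
phenotype is v_c = g ε / T_B with ε a calibration constant, and its density
d_vc follows by the change of variables T_B = g ε / v_c.

Gain and tumble bias are treated as independent, so the joint phenotype
density factorizes: f(g, T_B) = h_g(g) · Beta(T_B; α, β).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .errors import DomainError, InvalidConfigurationError

__all__ = [
    "PopulationHyperparameters",
    "GainDistribution",
    "tumble_bias_pdf",
    "pathway_gain_pdf",
    "joint_pdf",
    "chemvel_pdf",
    "sample_phenotypes",
]


@dataclass(frozen=True)
class PopulationHyperparameters:
    """Hyperparameters of the phenotype-heterogeneity model.

    alpha, beta : Beta shape parameters of the tumble-bias distribution.
    gamma, delta : shape and scale of the Gamma-distributed Tar/Tsr ratio.
    lam : mean receptor-cluster size (Poisson).
    mu, sigma : mean and s.d. of the Gaussian motor amplification; sigma is
        the model's single free parameter (fitted value 7.8).
    epsilon : grouped constant of the chemotactic velocity, v_c = g ε / T_B
        (µm/s per unit gain); set by calibration against a fitted
        sensitivity coefficient.
    """

    alpha: float = 5.0
    beta: float = 17.0
    gamma: float = 2.2
    delta: float = 0.7
    lam: float = 9.0
    mu: float = 15.0
    sigma: float = 7.8
    epsilon: float | None = None

    def __post_init__(self):
        for name in ("alpha", "beta", "gamma", "delta", "lam", "mu", "sigma"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(f"{name} must be positive")
        if self.epsilon is not None and self.epsilon <= 0:
            raise InvalidConfigurationError("epsilon must be positive")

    @property
    def mean_tumble_bias(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def with_sigma(self, sigma: float) -> "PopulationHyperparameters":
        return replace(self, sigma=sigma)

    def with_epsilon(self, epsilon: float) -> "PopulationHyperparameters":
        return replace(self, epsilon=epsilon)


class GainDistribution:
    """Numerical representation of the compound pathway-gain density h_g.

    The double sum is truncated at cluster size ``k_max`` (default
    ``max(40, λ + 8√λ)``) and the density is tabulated on a uniform grid up
    to ``g_max`` (default ``3 µ λ``), then normalized; the raw (unnormalized)
    mass is retained as a truncation diagnostic.
    """

    def __init__(self, hyper: PopulationHyperparameters,
                 g_max: float | None = None, n_grid: int = 3001,
                 k_max: int | None = None):
        self.hyper = hyper
        lam = hyper.lam
        self.k_max = int(k_max if k_max is not None
                         else max(40, np.ceil(lam + 8 * np.sqrt(lam))))
        self.g_max = float(g_max if g_max is not None else 3 * hyper.mu * lam)
        self.g = np.linspace(0.0, self.g_max, n_grid)
        self._tabulate()

    def _cluster_weights(self):
        """P(k) for k >= 2 and, per k, the composition weight over N."""
        h = self.hyper
        ks = np.arange(2, self.k_max + 1)
        log_pk = ks * np.log(h.lam) - h.lam - gammaln(ks + 1)
        pk = np.exp(log_pk)
        weights = []
        for k in ks:
            N = np.arange(1, k)
            r = N / (k - N)
            # Gamma(γ, δ) density of the Tar/Tsr ratio times |dr/dN| = k/(k−N)²
            w = (r ** (h.gamma - 1.0) * np.exp(-r / h.delta)
                 / (h.delta ** h.gamma) * k / (k - N) ** 2)
            w = w / np.exp(gammaln(h.gamma))
            weights.append((k, N, w))
        return ks, pk, weights

    def _tabulate(self):
        h = self.hyper
        dens = np.zeros_like(self.g)
        ks, pk, weights = self._cluster_weights()
        for (k, N, w), p in zip(weights, pk):
            kern = np.exp(-((self.g[None, :] / N[:, None] - h.mu) ** 2)
                          / (2 * h.sigma ** 2))
            kern /= N[:, None] * np.sqrt(2 * np.pi * h.sigma ** 2)
            dens += p * (w[:, None] * kern).sum(axis=0)
        self.raw_mass = float(np.trapezoid(dens, self.g))
        self.pdf_grid = dens / self.raw_mass
        # conditional distribution of the integer Tar count N (marginalized
        # over k), used by the sampler cross-checks
        self._ks, self._pk, self._weights = ks, pk, weights

    # ---- queries ---------------------------------------------------------
    def pdf(self, g):
        g = np.asarray(g, dtype=float)
        out = np.interp(g, self.g, self.pdf_grid, left=0.0, right=0.0)
        return out if out.ndim else float(out)

    def expectation(self, values) -> float:
        """∫ values(g) h_g(g) dg over the tabulated support."""
        vals = values(self.g) if callable(values) else np.asarray(values)
        return float(np.trapezoid(vals * self.pdf_grid, self.g))

    def mean(self) -> float:
        return self.expectation(self.g)

    def var(self) -> float:
        m = self.mean()
        return self.expectation((self.g - m) ** 2)


@lru_cache(maxsize=16)
def _cached_gain(hyper: PopulationHyperparameters, g_max, n_grid, k_max):
    return GainDistribution(hyper, g_max=g_max, n_grid=n_grid, k_max=k_max)


def gain_distribution(hyper: PopulationHyperparameters, g_max=None,
                      n_grid: int = 3001, k_max=None) -> GainDistribution:
    """Cached accessor for :class:`GainDistribution`."""
    return _cached_gain(hyper, g_max, n_grid, k_max)


def tumble_bias_pdf(T_B, hyper: PopulationHyperparameters):
    """Beta(α, β) density of the tumble bias; zero outside (0, 1)."""
    out = stats.beta.pdf(np.asarray(T_B, dtype=float), hyper.alpha, hyper.beta)
    return out if out.ndim else float(out)


def pathway_gain_pdf(g, hyper: PopulationHyperparameters, **grid_opts):
    """Compound pathway-gain density h_g evaluated at ``g``."""
    dist = gain_distribution(hyper, **grid_opts)
    return dist.pdf(g)


def joint_pdf(g, T_B, hyper: PopulationHyperparameters):
    """Joint phenotype density f(g, T_B) = h_g(g) · Beta(T_B; α, β)."""
    return pathway_gain_pdf(g, hyper) * tumble_bias_pdf(T_B, hyper)


def chemvel_pdf(v_c, hyper: PopulationHyperparameters,
                epsilon: float | None = None):
    """Density of the chemotactic velocity v_c = g ε / T_B at the inlet.

    Obtained by the change of variables T_B = g ε / v_c under the joint
    density; the integrand vanishes wherever g ε / v_c lies outside (0, 1).
    """
    eps = hyper.epsilon if epsilon is None else epsilon
    if eps is None or eps <= 0:
        raise InvalidConfigurationError(
            "chemvel_pdf requires a positive epsilon (calibrate it first)")
    v = np.atleast_1d(np.asarray(v_c, dtype=float))
    if np.any(v <= 0):
        raise DomainError("chemotactic velocity support is v_c > 0")
    dist = gain_distribution(hyper)
    # integrate over the tumble bias at fixed v (g = v T / ε), which keeps
    # the quadrature well-conditioned at small velocities
    T = np.linspace(1e-6, 1 - 1e-6, 2001)
    bT = stats.beta.pdf(T, hyper.alpha, hyper.beta)
    h = np.interp(v[:, None] * T[None, :] / eps, dist.g, dist.pdf_grid,
                  left=0.0, right=0.0)
    out = np.trapezoid(h * (bT * T)[None, :], T, axis=1) / eps
    return out if np.asarray(v_c).ndim else float(out[0])


def sample_phenotypes(hyper: PopulationHyperparameters, count: int,
                      seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Monte-Carlo sample of phenotypes, the sampling oracle for the
    analytic densities.

    Per cell: N_tot ~ Poisson(λ) conditioned on N_tot ≥ 2, r ~ Gamma(γ, δ),
    N = round(r N_tot / (r + 1)) clipped to [1, N_tot − 1], H ~ N(µ, σ²)
    truncated at 0, T_B ~ Beta(α, β); g = N·H.

    Returns a DataFrame with columns g, N, H, T_B, N_tot, r.
    """
    if count <= 0:
        raise DomainError("count must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    k = rng.poisson(hyper.lam, size=count)
    while True:  # condition on k >= 2 (matching the density's support)
        bad = k < 2
        if not bad.any():
            break
        k[bad] = rng.poisson(hyper.lam, size=int(bad.sum()))
    r = rng.gamma(shape=hyper.gamma, scale=hyper.delta, size=count)
    N = np.clip(np.rint(r * k / (r + 1.0)), 1, k - 1).astype(int)
    a = (0.0 - hyper.mu) / hyper.sigma
    H = stats.truncnorm.rvs(a, np.inf, loc=hyper.mu, scale=hyper.sigma,
                            size=count, random_state=rng)
    T_B = rng.beta(hyper.alpha, hyper.beta, size=count)
    return pd.DataFrame({"g": N * H, "N": N, "H": H, "T_B": T_B,
                         "N_tot": k, "r": r})
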