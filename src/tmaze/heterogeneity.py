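"""Quantifying heterogeneity in chemotactic sensitivity from maze data.

The pipeline weighs every phenotype (g, T_B) of the population by its
navigation performance P_n to junction n and time t, and summarizes the
result in junction-resolved observables:

* ``N_B(n, t)``  — expected cell number of the heterogeneous population,
  the double quadrature of f(g, T_B) · P_n over the phenotype plane;
* ``H_n``        — the heterogeneous sorting index, N_B divided by the
  count of a homogeneous population carrying the mean phenotype
  (ḡ, T̄_B) and the population diffusivity;
* junction marginals of T_B (refit as a Beta(α(n,t), β(n,t))) and of g;
* the junction-resolved chemotactic-velocity distribution and its mean;
* the fits: χ from a junction-1 profile (transport model), σ (the width of
  the motor-gain distribution, the model's only free parameter) from
  observed H_n.

Phenotype conventions (see docs/methods.md for the full discussion):

* ``v_c = g ε / T_B`` with ε calibrated so the mean phenotype reproduces
  the fitted population sensitivity (χ_G ∇C, or χ_L ∇C/C_i per junction in
  the log regime, with C_i the concentration midway along the up-gradient
  semibranch).
* ``D(T_B) = D_ref · T̄_B / T_B``: all diffusivity variation is carried by
  the tumble bias, normalized so the mean phenotype has the measured
  population diffusivity.  Consequently the accumulation slope
  v_c/D ∝ g is independent of tumble bias and swimming speed.
* The sensitivity weight uses the damped ("transit") closed form of the
  sorting index; its population average over the right-skewed gain
  distribution exceeds the mean-phenotype value by Jensen's inequality,
  which is what H_n measures.
* ``H_n`` by default evaluates the diffusive arrival factor of both
  populations at the common reference diffusivity, isolating sensitivity
  heterogeneity from motility; ``arrival="phenotype"`` switches to the
  fully phenotype-resolved arrival factor (strongly time-dependent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import chemotaxis as ct
from .errors import (DomainError, InsufficientDataError,
                     InvalidConfigurationError, UnidentifiableError)
from .geometry import (ConcentrationField, MazeGeometry,
                       advective_concentration)
from .population import (GainDistribution, PopulationHyperparameters,
                         gain_distribution, tumble_bias_pdf)

__all__ = [
    "calibrate_epsilon",
    "MazeHeterogeneityModel",
    "performance_weighted_density",
    "population_count",
    "heterogeneous_sorting_index",
    "junction_marginals",
    "junction_chemvel_pdf",
    "fit_chi",
    "fit_sigma",
    "log_slope",
    "choice_factor",
    "empirical_sorting_index",
    "EXPERIMENTAL_TIMES_MIN",
]

#: times (minutes) at which junction observables are evaluated; the
#: observation window of the sorting experiments
EXPERIMENTAL_TIMES_MIN = (40.0, 80.0, 120.0, 160.0)


def calibrate_epsilon(chi: float, field: ConcentrationField,
                      hyper: PopulationHyperparameters,
                      geom: MazeGeometry | None = None) -> np.ndarray | float:
    """Calibrate the grouped constant ε so that the mean phenotype's
    chemotactic velocity ḡ ε / T̄_B equals the fitted population velocity.

    Linear regime: ε = χ ∇C · T̄_B / ḡ (scalar, junction-independent).
    Log regime (requires ``geom``): per-junction ε_i = χ (∇C / C_i) T̄_B / ḡ
    with C_i the concentration at the midpoint of junction i's up-gradient
    semibranch.
    """
    if chi <= 0:
        raise DomainError("chi must be positive")
    if field.gradient <= 0:
        raise DomainError("cannot calibrate against a zero gradient")
    gbar = gain_distribution(hyper).mean()
    tbar = hyper.mean_tumble_bias
    if field.regime == "log":
        if geom is None:
            raise InvalidConfigurationError(
                "log-regime calibration needs the maze geometry")
        C = np.array([advective_concentration(field, geom, n)
                      for n in range(1, geom.n_junctions + 1)])
        return chi * field.gradient / C * tbar / gbar
    return float(chi * field.gradient * tbar / gbar)


@dataclass
class BetaRefit:
    """Moment-matched Beta parameters of a junction tumble-bias marginal."""

    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def mean_inverse(self) -> float:
        if self.alpha <= 1:
            raise DomainError("E[1/T_B] undefined for refit alpha <= 1")
        return (self.alpha + self.beta - 1.0) / (self.alpha - 1.0)


class MazeHeterogeneityModel:
    """Junction-resolved heterogeneity observables for one maze + regime."""

    def __init__(self, hyper: PopulationHyperparameters, geom: MazeGeometry,
                 field: ConcentrationField,
                 params: ct.ChemotaxisParameters | None = None,
                 chi: float | None = None, D_ref: float | None = None,
                 sorting_form: str = "transit",
                 n_T: int = 4001):
        self.hyper = hyper
        self.geom = geom
        self.field = field
        self.params = params or ct.ChemotaxisParameters()
        self.D_ref = float(D_ref if D_ref is not None
                           else self.params.D_population)
        if chi is None:
            chi = (self.params.chi_log if field.regime == "log"
                   else self.params.chi_linear)
        self.chi = float(chi)
        if sorting_form not in ("transit", "growth"):
            raise InvalidConfigurationError(
                f"unknown sorting form {sorting_form!r}")
        self.sorting_form = sorting_form
        self.gain: GainDistribution = gain_distribution(hyper)
        self.gbar = self.gain.mean()
        self.tbar = hyper.mean_tumble_bias
        eps = calibrate_epsilon(self.chi, field, hyper, geom)
        self.eps_i = (np.full(geom.n_junctions, eps)
                      if np.isscalar(eps) else np.asarray(eps))
        # mean-phenotype drift speed per junction
        self.vbar_i = self.gbar * self.eps_i / self.tbar
        self._T = np.linspace(1e-5, 1 - 1e-5, n_T)
        self._bT = tumble_bias_pdf(self._T, hyper)

    # ---- elementary weights ---------------------------------------------
    def sorting_exponent(self, n: int) -> float:
        """|exponent| of the mean phenotype's sorting index up to junction n:
        Σ_{i<=n} i y_v v̄_c,i / (4 D_ref)."""
        i = np.arange(1, n + 1)
        return float(np.sum(i * self.geom.y_v * self.vbar_i[:n])
                     / (4.0 * self.D_ref))

    def sensitivity_weight(self, g, n: int) -> np.ndarray:
        """Sorting factor of a phenotype with gain g relative to unity at
        g = 0; damped ("transit") or growing ("growth") exponential in g."""
        s = self.sorting_exponent(n) / self.gbar
        sign = -1.0 if self.sorting_form == "transit" else 1.0
        return np.exp(sign * s * np.asarray(g, dtype=float))

    def arrival_exponent(self, n: int, t: float) -> float:
        """a_n = d_n² / (4 D_ref t) of the diffusive arrival Gaussian."""
        if t <= 0:
            raise DomainError("time must be positive")
        d = self.geom.d(n)
        return d * d / (4.0 * self.D_ref * t)

    def arrival_weight(self, T_B, n: int, t: float) -> np.ndarray:
        """Arrival factor of a phenotype with tumble bias T_B relative to
        the mean phenotype: B_n(D(T_B)) / B_n(D_ref) with
        D(T_B) = D_ref T̄_B / T_B."""
        a = self.arrival_exponent(n, t)
        x = np.asarray(T_B, dtype=float) / self.tbar
        return np.sqrt(x) * np.exp(-a * (x - 1.0))

    # ---- Eq.-style observables ------------------------------------------
    def _gain_factor(self, n: int) -> float:
        """E_g[sorting weight] / weight(ḡ): the gain-heterogeneity
        (Jensen) amplification of the sorting index."""
        w = self.sensitivity_weight(self.gain.g, n)
        return self.gain.expectation(w) / float(self.sensitivity_weight(self.gbar, n))

    def _arrival_factor(self, n: int, t: float) -> float:
        """E_T[arrival weight]: diffusivity-heterogeneity amplification of
        the arrival Gaussian."""
        w = self.arrival_weight(self._T, n, t) * self._bT
        return float(np.trapezoid(w, self._T))

    def homogeneous_count(self, n: int, t: float, B_0: float = 1.0) -> float:
        """Reference count B_n(D_ref) · S_n(ḡ, T̄_B) of the homogeneous
        mean-phenotype population."""
        from .navigation import diffusion_count
        s = self.sorting_exponent(n)
        sign = -1.0 if self.sorting_form == "transit" else 1.0
        return diffusion_count(B_0, self.D_ref, self.geom, n, t) * float(np.exp(sign * s))

    def population_count(self, n: int, t: float, B_0: float = 1.0,
                         arrival: str = "phenotype") -> float:
        """Expected heterogeneous cell number N_B(n, t): the phenotype
        density times navigation performance, integrated over (g, T_B)."""
        base = self.homogeneous_count(n, t, B_0)
        out = base * self._gain_factor(n)
        if arrival == "phenotype":
            out *= self._arrival_factor(n, t)
        elif arrival != "reference":
            raise InvalidConfigurationError(f"unknown arrival mode {arrival!r}")
        return float(out)

    def heterogeneous_sorting_index(self, n: int, t: float | None = None,
                                    arrival: str = "reference") -> float:
        """H_n = N_B / [B_n(T̄_B) S_n(ḡ, T̄_B)].

        Default ``arrival="reference"`` evaluates the arrival Gaussian of
        both populations at the common reference diffusivity, so H_n is
        time-independent and measures sensitivity heterogeneity alone;
        ``arrival="phenotype"`` (requires ``t``) keeps the per-phenotype
        arrival factor.
        """
        H = self._gain_factor(n)
        if arrival == "phenotype":
            if t is None:
                raise InvalidConfigurationError(
                    "phenotype-resolved arrival needs an evaluation time")
            H *= self._arrival_factor(n, t)
        elif arrival != "reference":
            raise InvalidConfigurationError(f"unknown arrival mode {arrival!r}")
        return float(H)

    # ---- junction marginals and velocity distributions -------------------
    def junction_tumble_marginal(self, n: int, t: float) -> BetaRefit:
        """Tumble-bias marginal at junction n, time t, refit as a Beta by
        moment matching.  The tilt comes from the arrival factor; the
        sorting factor carries no T_B dependence under the slope-invariance
        convention v_c/D ∝ g.  ``n = 0`` denotes the inlet (no selection)."""
        if n == 0:
            return BetaRefit(alpha=self.hyper.alpha, beta=self.hyper.beta)
        w = self.arrival_weight(self._T, n, t) * self._bT
        Z = np.trapezoid(w, self._T)
        m1 = np.trapezoid(self._T * w, self._T) / Z
        m2 = np.trapezoid(self._T ** 2 * w, self._T) / Z
        var = m2 - m1 * m1
        if var <= 0 or not 0 < m1 < 1:
            raise UnidentifiableError("degenerate tumble-bias marginal")
        nu = m1 * (1 - m1) / var - 1.0
        if nu <= 0:
            raise UnidentifiableError("marginal variance exceeds Beta bound")
        return BetaRefit(alpha=m1 * nu, beta=(1 - m1) * nu)

    def junction_gain_marginal(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """(g grid, density): gain marginal at junction n under the
        sensitivity weight, renormalized.  ``n = 0`` denotes the inlet."""
        if n == 0:
            return self.gain.g, self.gain.pdf_grid
        w = self.gain.pdf_grid * self.sensitivity_weight(self.gain.g, n)
        Z = np.trapezoid(w, self.gain.g)
        return self.gain.g, w / Z

    def junction_chemvel_pdf(self, n: int, t: float,
                             v_grid: np.ndarray | None = None,
                             gain: str = "inlet") -> tuple[np.ndarray, np.ndarray]:
        """Distribution of the chemotactic velocity v_c = g ε_n / T_B for
        cells at junction n at time t.

        The tumble-bias marginal is the junction-refit Beta; ``gain``
        selects the inlet gain distribution (default; the arrival-selection
        view, which reproduces the observed upward shift of the means) or
        the sensitivity-weighted ``"junction"`` marginal.
        """
        refit = self.junction_tumble_marginal(n, t)
        if gain == "inlet":
            g, hg = self.gain.g, self.gain.pdf_grid
        elif gain == "junction":
            g, hg = self.junction_gain_marginal(n)
        else:
            raise InvalidConfigurationError(f"unknown gain mode {gain!r}")
        eps = self.eps_i[max(n - 1, 0)]
        if v_grid is None:
            vmax = float(g[-1] * eps / 0.02)
            v_grid = np.linspace(1e-4, vmax, 4000)
        # integrate over T_B at fixed v (g = v T / ε): well-conditioned at
        # small velocities
        T = np.linspace(1e-6, 1 - 1e-6, 2001)
        bT = stats.beta.pdf(T, refit.alpha, refit.beta)
        hv = np.interp(v_grid[:, None] * T[None, :] / eps, g, hg,
                       left=0.0, right=0.0)
        pdf = np.trapezoid(hv * (bT * T)[None, :], T, axis=1) / eps
        return v_grid, pdf

    def junction_mean_velocity(self, n: int, t: float,
                               gain: str = "inlet") -> float:
        """Mean of the junction-n chemotactic-velocity distribution,
        E[g] ε_n E[1/T_B] under the junction marginals."""
        refit = self.junction_tumble_marginal(n, t)
        if gain == "inlet":
            mg = self.gbar
        elif gain == "junction":
            g, hg = self.junction_gain_marginal(n)
            mg = float(np.trapezoid(g * hg, g))
        else:
            raise InvalidConfigurationError(f"unknown gain mode {gain!r}")
        return float(mg * self.eps_i[max(n - 1, 0)] * refit.mean_inverse)

    def anchor_epsilon(self, v1_target: float, t: float,
                       gain: str = "inlet") -> "MazeHeterogeneityModel":
        """Return a copy of the model with ε rescaled so the junction-1 mean
        velocity equals ``v1_target`` at time ``t``.  Under the default
        (inlet-gain) convention the junction means are exactly linear in ε,
        so a single rescaling suffices; otherwise a short fixed-point
        iteration is applied."""
        out = self
        for _ in range(6):
            v1 = out.junction_mean_velocity(1, t, gain=gain)
            scale = v1_target / v1
            if abs(scale - 1) < 1e-12:
                break
            new = object.__new__(MazeHeterogeneityModel)
            new.__dict__ = dict(out.__dict__)
            new.eps_i = out.eps_i * scale
            new.vbar_i = out.vbar_i * scale
            out = new
            if gain == "inlet":
                break
        return out

    def summary(self, times_min=EXPERIMENTAL_TIMES_MIN) -> pd.DataFrame:
        """SortingResult table: per junction and time, the heterogeneous
        count, homogeneous reference, H_n, refit Beta parameters, and mean
        chemotactic velocity."""
        rows = []
        for tm in times_min:
            t = tm * 60.0
            for n in range(1, self.geom.n_junctions + 1):
                refit = self.junction_tumble_marginal(n, t)
                rows.append({
                    "time_min": tm, "junction": n,
                    "N_B": self.population_count(n, t),
                    "homogeneous_count": self.homogeneous_count(n, t),
                    "H_n": self.heterogeneous_sorting_index(n),
                    "H_n_arrival_resolved": self.heterogeneous_sorting_index(
                        n, t, arrival="phenotype"),
                    "alpha_nt": refit.alpha, "beta_nt": refit.beta,
                    "mean_tumble_bias": refit.mean,
                    "mean_chem_velocity": self.junction_mean_velocity(n, t),
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def _model(hyper, geom, field, params=None, **kw) -> MazeHeterogeneityModel:
    return MazeHeterogeneityModel(hyper, geom, field, params=params, **kw)


def performance_weighted_density(g, T_B, n: int, t: float,
                                 hyper: PopulationHyperparameters,
                                 geom: MazeGeometry, field: ConcentrationField,
                                 params=None, B_0: float = 1.0, **kw):
    """f(g, T_B) · P_n(g, T_B; t): the integrand of the heterogeneous count."""
    m = _model(hyper, geom, field, params, **kw)
    base = m.homogeneous_count(n, t, B_0)
    w = (m.gain.pdf(g) * tumble_bias_pdf(T_B, hyper)
         * m.sensitivity_weight(g, n) / m.sensitivity_weight(m.gbar, n)
         * m.arrival_weight(T_B, n, t))
    return base * w


def population_count(n: int, t: float, hyper, geom, field, params=None,
                     B_0: float = 1.0, **kw) -> float:
    return _model(hyper, geom, field, params, **kw).population_count(n, t, B_0)


def heterogeneous_sorting_index(n: int, t: float | None, hyper, geom, field,
                                params=None, arrival: str = "reference",
                                **kw) -> float:
    return _model(hyper, geom, field, params, **kw).heterogeneous_sorting_index(
        n, t, arrival=arrival)


def junction_marginals(n: int, t: float, hyper, geom, field, params=None, **kw):
    """(BetaRefit of T_B, (g grid, gain-marginal density)) at junction n."""
    m = _model(hyper, geom, field, params, **kw)
    return m.junction_tumble_marginal(n, t), m.junction_gain_marginal(n)


def junction_chemvel_pdf(n: int, t: float, hyper, geom, field, params=None,
                         gain: str = "inlet", **kw):
    m = _model(hyper, geom, field, params, **kw)
    return m.junction_chemvel_pdf(n, t, gain=gain)


# ---------------------------------------------------------------------------
# profile statistics
# ---------------------------------------------------------------------------

def log_slope(profile, window: tuple[float, float] | None = None,
              geom: MazeGeometry | None = None) -> tuple[float, float]:
    """Least-squares slope of ln(density) versus stem coordinate within the
    fitting window; returns (slope, standard error) in 1/µm.

    Non-positive counts inside the window are masked (with a warning); fewer
    than three usable points raises :class:`InsufficientDataError`.
    """
    if window is None:
        window = geom.slope_window if geom is not None else (750.0, 1100.0)
    y = np.asarray(profile.y, dtype=float)
    c = np.asarray(profile.density if hasattr(profile, "density")
                   else profile.counts, dtype=float)
    sel = (y >= window[0]) & (y <= window[1])
    y, c = y[sel], c[sel]
    pos = c > 0
    if pos.sum() < len(c):
        warnings.warn("non-positive counts in the slope window were masked",
                      stacklevel=2)
    y, c = y[pos], c[pos]
    if len(y) < 3:
        raise InsufficientDataError(
            "need at least three positive counts in the slope window")
    res = stats.linregress(y, np.log(c))
    return float(res.slope), float(res.stderr)


def choice_factor(n_up: float, n_down: float) -> float:
    """C_F = (N_up − N_down) / (N_up + N_down) ∈ [−1, 1]."""
    if n_up < 0 or n_down < 0:
        raise DomainError("counts must be non-negative")
    tot = n_up + n_down
    if tot == 0:
        raise DomainError("choice factor undefined for zero total count")
    return float((n_up - n_down) / tot)


def empirical_sorting_index(counts_a, counts_b) -> np.ndarray:
    """Per-junction ratio of strain A to strain B counts, normalized to 1 at
    junction 1: S_n = (A_n/B_n) / (A_1/B_1)."""
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidConfigurationError("count series must have equal length")
    if a[0] <= 0 or b[0] <= 0:
        raise DomainError("both strains need positive counts at junction 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (a / b) / (a[0] / b[0])
    return s


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    value: float
    cost: float
    detail: dict


def fit_chi(profile, geom: MazeGeometry, field: ConcentrationField,
            params: ct.ChemotaxisParameters | None = None,
            chi_bounds: tuple[float, float] | None = None,
            dx: float = 20.0, dt: float = 2.0) -> FitResult:
    """Fit the population chemotactic sensitivity χ to a junction-1 profile.

    Runs the 2-D transport model to the profile's time for candidate χ and
    minimizes the squared misfit of the peak-normalized junction-1 profiles.
    """
    from .transport import TransportSolver, extract_junction_profile, \
        initial_state

    params = params or ct.ChemotaxisParameters()
    if field.gradient <= 0:
        raise UnidentifiableError("zero-gradient field: chi unidentifiable")
    y_obs = np.asarray(profile.y, dtype=float)
    c_obs = np.asarray(profile.density if hasattr(profile, "density")
                       else profile.counts, dtype=float)
    if len(y_obs) < 10 or np.ptp(c_obs) == 0 or c_obs.max() <= 0:
        raise UnidentifiableError("profile flat or too short to constrain chi")
    c_obs = c_obs / c_obs.max()
    t_obs = profile.time
    if chi_bounds is None:
        ref = params.chi_log if field.regime == "log" else params.chi_linear
        chi_bounds = (ref / 20.0, ref * 20.0)
    cache: dict[float, float] = {}

    def cost(log_chi: float) -> float:
        chi = float(np.exp(log_chi))
        if chi in cache:
            return cache[chi]
        solver = TransportSolver(geom, field=field, params=params, chi=chi,
                                 dx=dx, dt=dt)
        state = solver.run(initial_state(geom, dx=dx), t_end=t_obs)[-1]
        prof = extract_junction_profile(state, geom, 1)
        model = np.interp(y_obs, prof.y, prof.density)
        if model.max() <= 0:
            return 1e6
        model = model / model.max()
        c = float(np.sum((model - c_obs) ** 2))
        cache[chi] = c
        return c

    res = optimize.minimize_scalar(cost, bounds=np.log(chi_bounds),
                                   method="bounded",
                                   options={"xatol": 0.01})
    return FitResult(value=float(np.exp(res.x)), cost=float(res.fun),
                     detail={"n_eval": len(cache), "bounds": chi_bounds})


def fit_sigma(H_obs, hyper: PopulationHyperparameters, geom: MazeGeometry,
              field: ConcentrationField,
              params: ct.ChemotaxisParameters | None = None,
              junctions=None, sigma_bounds: tuple[float, float] = (1e-3, 30.0),
              log_residuals: bool = True) -> FitResult:
    """Fit the motor-gain spread σ (the model's only free parameter) to
    observed heterogeneous sorting indices H_n.

    Least squares of log H (or H) between model and observation over the
    given junctions.  H ≡ 1 observations drive σ to its lower bound (the
    homogeneous limit).
    """
    H_obs = np.asarray(H_obs, dtype=float)
    if junctions is None:
        junctions = np.arange(1, len(H_obs) + 1)
    junctions = np.asarray(junctions, dtype=int)
    if len(H_obs) < 2:
        raise UnidentifiableError("need at least two junction observations")
    if np.any(H_obs <= 0):
        raise UnidentifiableError("sorting indices must be positive")

    def model_H(sigma: float) -> np.ndarray:
        m = MazeHeterogeneityModel(hyper.with_sigma(sigma), geom, field,
                                   params=params)
        return np.array([m.heterogeneous_sorting_index(int(n))
                         for n in junctions])

    def cost(sigma: float) -> float:
        H = model_H(sigma)
        if log_residuals:
            return float(np.sum((np.log(H) - np.log(H_obs)) ** 2))
        return float(np.sum((H - H_obs) ** 2))

    res = optimize.minimize_scalar(cost, bounds=sigma_bounds,
                                   method="bounded",
                                   options={"xatol": 1e-3})
    sigma = float(res.x)
    return FitResult(value=sigma, cost=float(res.fun),
                     detail={"residuals": model_H(sigma) - H_obs,
                             "junctions": junctions.tolist()})
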