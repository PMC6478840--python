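"""Run-and-tumble motility and the chemotactic response of single phenotypes.

A cell's chemotactic phenotype is summarized by two numbers: the pathway
gain g = N·H (receptor-cluster cooperativity N times motor amplification H),
which sets how strongly a sensed gradient is amplified into a swimming bias,
and the tumble bias T_B, the probability of being in the tumbling state,
which sets the run time τ_0 = τ_t/T_B and hence the random-motility
diffusivity.  The drift up a gradient (chemotactic velocity) is

    v_c = χ_0 · (K_A − K_I) ∇C / [(K_A + C)(K_I + C)],
    χ_0 = ½ v² (1 − a_0) g τ_t / T_B,

with the MWC-type receptor term reducing to linear sensing (v_c = χ_G ∇C)
for C ≪ K_I and to log sensing (v_c = χ_L ∇C/C) for K_I ≪ C ≪ K_A.

Because both χ_0 and the diffusivity D = v² τ_t / [3 T_B (1 − ⟨cos θ⟩)]
scale with the squared swimming speed, the steady-state accumulation slope
v_c/D is independent of speed — the property that lets a branching maze
sort on sensitivity rather than on motility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InvalidConfigurationError, \
    SingularPhenotypeError, UndefinedAccumulationError

__all__ = [
    "ChemotaxisParameters",
    "Phenotype",
    "receptor_response",
    "chemotactic_sensitivity",
    "swim_speed",
    "diffusivity",
    "chemotactic_velocity",
    "accumulation_length",
]


@dataclass(frozen=True)
class ChemotaxisParameters:
    """Population-level chemotaxis constants.

    Attributes
    ----------
    K_I, K_A
        Dissociation constants of the inactive and active Tar receptor for
        methylaspartate (µM).
    a_0
        Steady-state kinase activity (dimensionless).
    tau_t
        Tumble duration (s).
    v_run
        Run speed (µm/s).
    mean_cos_theta
        Mean cosine of the reorientation angle between runs.
    chi_linear
        Fitted chemotactic sensitivity in the linear-sensing regime
        (µm²/s/µM).
    chi_log
        Fitted chemotactic sensitivity in the log-sensing regime (µm²/s).
    D_population
        Population-average random-motility diffusivity (µm²/s).
    """

    K_I: float = 18.0
    K_A: float = 2900.0
    a_0: float = 1.0 / 3.0
    tau_t: float = 0.2
    v_run: float = 25.0
    mean_cos_theta: float = 1.0 / 3.0
    chi_linear: float = 6.4e2
    chi_log: float = 1.4e3
    D_population: float = 330.0

    def __post_init__(self):
        if not 0 < self.K_I < self.K_A:
            raise InvalidConfigurationError("require 0 < K_I < K_A")
        if not 0 < self.a_0 < 1:
            raise InvalidConfigurationError("require 0 < a_0 < 1")
        if self.tau_t <= 0 or self.v_run <= 0 or self.D_population <= 0:
            raise InvalidConfigurationError("time/speed/diffusivity scales must be positive")
        if not abs(self.mean_cos_theta) < 1:
            raise InvalidConfigurationError("require |<cos theta>| < 1")


@dataclass(frozen=True)
class Phenotype:
    """A single cell's chemotaxis phenotype: pathway gain and tumble bias.

    ``g = N * H`` where N is the number of Tar receptors per signalling
    cluster and H the motor amplification.  N and H are optional; when given
    they must be consistent with g.
    """

    g: float
    T_B: float
    N: float | None = None
    H: float | None = None

    def __post_init__(self):
        if not 0 < self.T_B < 1:
            raise SingularPhenotypeError(
                f"tumble bias must lie strictly in (0, 1), got {self.T_B}")
        if self.g <= 0:
            raise SingularPhenotypeError("pathway gain must be positive")
        if self.N is not None and self.H is not None:
            if self.N <= 0 or self.H <= 0:
                raise SingularPhenotypeError("N and H must be positive")
            if not np.isclose(self.g, self.N * self.H, rtol=1e-9):
                raise SingularPhenotypeError(
                    f"g = {self.g} inconsistent with N*H = {self.N * self.H}")

    @classmethod
    def from_receptors(cls, N: float, H: float, T_B: float) -> "Phenotype":
        return cls(g=N * H, T_B=T_B, N=N, H=H)


def receptor_response(C, gradC, p: ChemotaxisParameters = ChemotaxisParameters()):
    """MWC-type receptor response term K(C)·∇C (per µm).

    Equals ``(K_A − K_I) ∇C / [(K_A + C)(K_I + C)]``; approaches
    ``(1 − K_I/K_A) ∇C / C`` in the log-sensing window K_I ≪ C ≪ K_A and a
    concentration-independent ``(K_A − K_I)/(K_A K_I) ∇C`` for C ≪ K_I.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise DomainError("concentration must be non-negative")
    out = (p.K_A - p.K_I) * np.asarray(gradC, dtype=float) / ((p.K_A + C) * (p.K_I + C))
    return out if out.ndim else float(out)


def swim_speed(ph: Phenotype, p: ChemotaxisParameters = ChemotaxisParameters()) -> float:
    """Mean swimming speed v = v_r (1 − T_B): runs interrupted by tumbles."""
    return p.v_run * (1.0 - ph.T_B)


def chemotactic_sensitivity(ph: Phenotype,
                            p: ChemotaxisParameters = ChemotaxisParameters(),
                            v: float | None = None) -> float:
    """Chemotactic sensitivity coefficient χ_0 = ½ v² (1 − a_0) g τ_t / T_B.

    ``v`` defaults to the phenotype's own swim speed; pass a constant to use
    a population-level speed instead.
    """
    v = swim_speed(ph, p) if v is None else v
    return 0.5 * v * v * (1.0 - p.a_0) * ph.g * p.tau_t / ph.T_B


def diffusivity(ph: Phenotype,
                p: ChemotaxisParameters = ChemotaxisParameters(),
                v: float | None = None) -> float:
    """Run-and-tumble effective diffusivity D = v² τ_t / [3 T_B (1 − ⟨cos θ⟩)]."""
    v = swim_speed(ph, p) if v is None else v
    return v * v * p.tau_t / (3.0 * ph.T_B * (1.0 - p.mean_cos_theta))


def chemotactic_velocity(C, gradC, regime: str,
                         p: ChemotaxisParameters = ChemotaxisParameters(),
                         phenotype: Phenotype | None = None,
                         chi: float | None = None):
    """Chemotactic drift speed v_c (µm/s) under a given sensing law.

    regime "full" uses χ_0(phenotype) times the full receptor response;
    "linear" uses χ_G ∇C; "log" uses χ_L ∇C / C.  ``chi`` overrides the
    regime's default sensitivity coefficient.
    """
    if regime == "full":
        if phenotype is None and chi is None:
            raise InvalidConfigurationError(
                "full regime needs a phenotype or an explicit chi_0")
        chi0 = chi if chi is not None else chemotactic_sensitivity(phenotype, p)
        return chi0 * receptor_response(C, gradC, p)
    if regime == "linear":
        chi_g = p.chi_linear if chi is None else chi
        out = chi_g * np.asarray(gradC, dtype=float)
        return out if out.ndim else float(out)
    if regime == "log":
        C = np.asarray(C, dtype=float)
        if np.any(C <= 0):
            raise DomainError("log-sensing response undefined at C <= 0")
        chi_l = p.chi_log if chi is None else chi
        out = chi_l * np.asarray(gradC, dtype=float) / C
        return out if out.ndim else float(out)
    raise InvalidConfigurationError(f"unknown regime {regime!r}")


def accumulation_length(v_c: float, D: float) -> float:
    """Chemotactic accumulation length L_c = D / v_c, the inverse of the
    steady-state log-profile slope."""
    if v_c <= 0:
        raise UndefinedAccumulationError(
            "accumulation length undefined for v_c <= 0")
    return D / v_c
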