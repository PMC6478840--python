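"""Headline quantities of the reference analysis, recomputed from scratch.

Each function rebuilds its inputs from the package defaults (the
reconstructed device, the printed model constants and hyperparameters),
runs the corresponding part of the pipeline, and returns the measured
number together with the problem size used.  ``run_all`` bundles them for
the reproduction CLI command and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .chemotaxis import ChemotaxisParameters
from .geometry import MazeGeometry, linear_regime_field, log_regime_field
from .heterogeneity import (EXPERIMENTAL_TIMES_MIN, MazeHeterogeneityModel,
                            log_slope)
from .population import PopulationHyperparameters, gain_distribution

__all__ = ["run_all"]


def mean_pathway_gain() -> dict:
    """Mean of the compound pathway-gain distribution (quadrature)."""
    dist = gain_distribution(PopulationHyperparameters())
    return {"value": float(dist.mean()), "n": dist.g.size}


def sorting_index_ratio(regime: str) -> dict:
    """Junction-4 heterogeneous-to-homogeneous cell-number ratio H_4."""
    geom = MazeGeometry()
    field = (log_regime_field if regime == "log" else linear_regime_field)(geom)
    model = MazeHeterogeneityModel(PopulationHyperparameters(), geom, field)
    return {"value": float(model.heterogeneous_sorting_index(geom.n_junctions)),
            "n": model.gain.g.size}


def junction_mean_velocity(junction: int, anchor: float = 1.1,
                           t_min: float = EXPERIMENTAL_TIMES_MIN[0]) -> dict:
    """Mean chemotactic velocity (µm/s) of cells at a junction in the
    linear-sensing regime, with ε anchored to the junction-1 mean."""
    geom = MazeGeometry()
    field = linear_regime_field(geom)
    model = MazeHeterogeneityModel(PopulationHyperparameters(), geom, field)
    anchored = model.anchor_epsilon(anchor, t_min * 60.0)
    return {"value": float(anchored.junction_mean_velocity(junction,
                                                           t_min * 60.0)),
            "n": model.gain.g.size}


def homogeneous_slope_ratio(dx: float = 10.0, dt: float = 1.0,
                            times_min=EXPERIMENTAL_TIMES_MIN) -> dict:
    """Fold-decrease of the junction log-profile slope between junction 1
    and junction 4 for a chemotactically homogeneous population in the
    linear-sensing regime (2-D transport simulation, slopes averaged over
    the observation window)."""
    from .transport import TransportSolver, extract_junction_profile, \
        initial_state

    geom = MazeGeometry()
    field = linear_regime_field(geom)
    params = ChemotaxisParameters()
    solver = TransportSolver(geom, field=field, params=params, dx=dx, dt=dt)
    state = initial_state(geom, dx=dx)
    times = [tm * 60.0 for tm in times_min]
    slopes = {1: [], geom.n_junctions: []}
    n_cells = int(solver.mask.sum())
    for st in solver.run(state, record_times=times):
        for n in slopes:
            prof = extract_junction_profile(st, geom, n)
            s, _ = log_slope(prof, geom=geom)
            slopes[n].append(s)
    s1 = float(np.mean(slopes[1]))
    s4 = float(np.mean(slopes[geom.n_junctions]))
    return {"value": float(s1 / s4), "n": n_cells,
            "slope_junction1_per_um": s1, "slope_junction4_per_um": s4}


def run_all(seed: int = 0, fast: bool = False) -> dict:
    """All headline quantities.  ``seed`` controls any stochastic component
    (the computations here are deterministic quadratures and PDE runs, but
    the seed is threaded through for forward compatibility)."""
    del seed
    dx, dt = (20.0, 2.0) if fast else (10.0, 1.0)
    return {
        "mean_pathway_gain": mean_pathway_gain(),
        "sorting_ratio_junction4_linear": sorting_index_ratio("linear"),
        "sorting_ratio_junction4_log": sorting_index_ratio("log"),
        "mean_velocity_junction3_linear": junction_mean_velocity(3),
        "mean_velocity_junction4_linear": junction_mean_velocity(4),
        "slope_ratio_junction1_to_4": homogeneous_slope_ratio(dx=dx, dt=dt),
    }
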