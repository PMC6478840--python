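"""Synthetic observations: stochastic agents navigating the maze.

The generator and the PDE solver are independent implementations of the
same drift-diffusion process: each agent follows Euler–Maruyama dynamics
with its phenotype's diffusivity and a drift directed up the gradient that
acts only inside junction stems, with reflecting channel walls.  Rendered
observations are junction-resolved binned counts with optional Poisson
counting noise, the statistical structure the analysis pipeline assumes.

Junction decisions are tracked while stepping: the first semibranch end an
agent reaches after arriving at a junction feed defines its up/down choice;
agents whose first commitment is the down-gradient branch are recorded as
lost at that junction (they keep moving physically, and may re-enter).  For
a non-chemotactic population each decision is an unbiased coin flip, so the
number of agents passing junction n halves per junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from . import chemotaxis as ct
from .errors import DomainError, InvalidConfigurationError, StabilityError
from .geometry import (ConcentrationField, MazeGeometry, Segment,
                       build_concentration_field)
from .population import PopulationHyperparameters, gain_distribution, \
    sample_phenotypes

__all__ = [
    "AgentPopulation",
    "TrajectorySet",
    "SyntheticProfile",
    "simulate_agents",
    "render_observation",
    "generate_mixed_population",
    "generate_heterogeneous_experiment",
    "synthetic_sorting_indices",
    "phenotypes_to_agents",
]


@dataclass
class AgentPopulation:
    """Per-agent motility parameters.

    ``drift_mode``: "none" (v_c = 0), "linear" (constant drift ``vc`` per
    agent) or "log" (drift ``coeff / C(y)`` per agent).
    """

    D: np.ndarray
    drift_mode: str = "none"
    vc: np.ndarray | None = None      # linear mode (µm/s)
    coeff: np.ndarray | None = None   # log mode (µm/s · µM)
    labels: np.ndarray | None = None  # e.g. strain names
    phenotypes: pd.DataFrame | None = None

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D <= 0):
            raise InvalidConfigurationError("diffusivities must be positive")
        if self.drift_mode == "linear" and self.vc is None:
            raise InvalidConfigurationError("linear drift needs vc")
        if self.drift_mode == "log" and self.coeff is None:
            raise InvalidConfigurationError("log drift needs coeff")

    @property
    def n(self) -> int:
        return self.D.size

    @staticmethod
    def homogeneous(n: int, D: float = 330.0, vc: float = 0.0,
                    label: str | None = None) -> "AgentPopulation":
        labels = np.array([label] * n) if label is not None else None
        return AgentPopulation(D=np.full(n, D), drift_mode="linear",
                               vc=np.full(n, vc), labels=labels)

    @staticmethod
    def concatenate(pops: list["AgentPopulation"]) -> "AgentPopulation":
        mode = {p.drift_mode for p in pops}
        mode = "linear" if mode <= {"none", "linear"} else "log"
        D = np.concatenate([p.D for p in pops])
        vc = np.concatenate([
            p.vc if p.vc is not None else np.zeros(p.n) for p in pops])
        coeff = np.concatenate([
            p.coeff if p.coeff is not None else np.zeros(p.n) for p in pops])
        labels = np.concatenate([
            p.labels if p.labels is not None else np.array([""] * p.n)
            for p in pops])
        return AgentPopulation(D=D, drift_mode=mode,
                               vc=vc if mode == "linear" else None,
                               coeff=coeff if mode == "log" else None,
                               labels=labels)


@dataclass
class TrajectorySet:
    """Recorded agent trajectories plus junction-decision bookkeeping."""

    times: np.ndarray                 # recorded times (s)
    positions: np.ndarray             # (n_frames, n_agents, 2) float32, µm
    population: AgentPopulation
    geom: MazeGeometry
    seed: int
    dt: float
    #: per agent: highest junction passed via its first up-commitment chain
    passed: np.ndarray = dfield(default_factory=lambda: np.array([]))
    #: per agent: junction of first down-commitment (0 = never lost)
    lost_at: np.ndarray = dfield(default_factory=lambda: np.array([]))

    def passage_counts(self) -> np.ndarray:
        """Number of agents whose first-commitment chain passed junctions
        1..n_junctions."""
        return np.array([(self.passed >= n).sum()
                         for n in range(1, self.geom.n_junctions + 1)])

    def to_frame(self) -> pd.DataFrame:
        nf, na, _ = self.positions.shape
        return pd.DataFrame({
            "cell_id": np.tile(np.arange(na), nf),
            "t_s": np.repeat(self.times, na),
            "x_um": self.positions[:, :, 0].ravel(),
            "y_um": self.positions[:, :, 1].ravel(),
        })


@dataclass
class SyntheticProfile:
    """Binned junction counts emulating microscopy observation."""

    junction: int
    time: float                       # s
    y: np.ndarray                     # bin centers, stem-local µm
    counts: np.ndarray                # integer counts
    noise: str = "none"

    @property
    def time_min(self) -> float:
        return self.time / 60.0

    @property
    def density(self) -> np.ndarray:   # duck-types JunctionProfile
        return self.counts.astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.time_min,
                             "junction": self.junction,
                             "y_um": self.y, "count": self.counts})


def _region_grid(geom: MazeGeometry, dxm: float):
    """Integer region map: 0 outside, n for stem n, 100+n connector,
    200+n dead end, 300 inlet/port."""
    segs = geom.segments()
    x0 = min(s.x0 for s in segs) - dxm
    x1 = max(s.x1 for s in segs) + dxm
    y0 = min(s.y0 for s in segs) - dxm
    y1 = max(s.y1 for s in segs) + dxm
    nx = int(np.ceil((x1 - x0) / dxm))
    ny = int(np.ceil((y1 - y0) / dxm))
    xc = x0 + (np.arange(nx) + 0.5) * dxm
    yc = y0 + (np.arange(ny) + 0.5) * dxm
    X, Y = np.meshgrid(xc, yc)
    region = np.zeros((ny, nx), dtype=np.int16)
    code = {"stem": 0, "connector": 100, "dead_end": 200,
            "inlet": 300, "port": 300}
    # paint stems last so decision regions are unambiguous at overlaps
    order = {"inlet": 0, "port": 0, "connector": 1, "dead_end": 1, "stem": 2}
    for s in sorted(segs, key=lambda s: order[s.kind]):
        region[s.contains(X, Y)] = code[s.kind] + s.index
    return region, (x0, y0), dxm


def simulate_agents(geom: MazeGeometry, field: ConcentrationField | None,
                    population: AgentPopulation, t_end: float,
                    dt: float = 0.5, seed: int = 0,
                    record_interval: float = 60.0,
                    segments: list[Segment] | None = None,
                    mask_resolution: float = 5.0) -> TrajectorySet:
    """Euler–Maruyama simulation of the agent ensemble.

    ``segments`` overrides the maze layout with an arbitrary channel-segment
    union (no stems: no drift or decision tracking) — used for free-space
    checks.  All randomness comes from one generator seeded by ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = population.n
    if segments is None:
        region, origin, dxm = _region_grid(geom, mask_resolution)
    else:
        x0 = min(s.x0 for s in segments) - mask_resolution
        x1 = max(s.x1 for s in segments) + mask_resolution
        y0 = min(s.y0 for s in segments) - mask_resolution
        y1 = max(s.y1 for s in segments) + mask_resolution
        nx = int(np.ceil((x1 - x0) / mask_resolution))
        ny = int(np.ceil((y1 - y0) / mask_resolution))
        xc = x0 + (np.arange(nx) + 0.5) * mask_resolution
        yc = y0 + (np.arange(ny) + 0.5) * mask_resolution
        X, Y = np.meshgrid(xc, yc)
        region = np.zeros((ny, nx), dtype=np.int16)
        for s in segments:
            region[s.contains(X, Y)] = 300
        origin, dxm = (x0, y0), mask_resolution
    mask = region > 0
    step_rms = np.sqrt(2 * population.D.max() * dt)
    if step_rms > geom.channel_width / 2:
        raise StabilityError(
            "diffusive step exceeds half the channel width; reduce dt")

    def cell_of(x, y):
        i = np.clip(((x - origin[0]) / dxm).astype(np.int64), 0, mask.shape[1] - 1)
        j = np.clip(((y - origin[1]) / dxm).astype(np.int64), 0, mask.shape[0] - 1)
        return j, i

    # initial positions: uniform over the seeding port pad (clipped to mask)
    if segments is None:
        px, py = geom.inlet_port
        w = geom.channel_width
    else:
        px = 0.5 * (segments[0].x0 + segments[0].x1)
        py = 0.5 * (segments[0].y0 + segments[0].y1)
        w = min(segments[0].x1 - segments[0].x0,
                segments[0].y1 - segments[0].y0) / 2
    x = np.empty(n)
    y = np.empty(n)
    todo = np.ones(n, dtype=bool)
    while todo.any():
        m = int(todo.sum())
        xt = px + rng.uniform(-w, w, m)
        yt = py + rng.uniform(-w, w, m)
        j, i = cell_of(xt, yt)
        ok = mask[j, i]
        idx = np.flatnonzero(todo)[ok]
        x[idx], y[idx] = xt[ok], yt[ok]
        todo[idx] = False

    sig = np.sqrt(2 * population.D * dt)
    nj = geom.n_junctions
    feeds = np.array([geom.feed_y(k) for k in range(1, nj + 1)])
    stage = np.ones(n, dtype=np.int16)
    lost_at = np.zeros(n, dtype=np.int16)
    passed = np.zeros(n, dtype=np.int16)
    track = segments is None

    if field is not None:
        c0 = field.concentration(0.0)
        grad = field.gradient
    n_steps = int(np.round(t_end / dt))
    rec_every = max(1, int(np.round(record_interval / dt)))
    frames, times = [], []

    for step in range(n_steps):
        j, i = cell_of(x, y)
        reg = region[j, i]
        in_stem = (reg >= 1) & (reg <= nj)
        if population.drift_mode == "linear":
            drift = np.where(in_stem, population.vc, 0.0)
        elif population.drift_mode == "log":
            C = c0 + grad * y
            drift = np.where(in_stem, population.coeff / np.maximum(C, 1e-9), 0.0)
        else:
            drift = 0.0
        # x-move with wall rejection
        xn = x + sig * rng.standard_normal(n)
        j2, i2 = cell_of(xn, y)
        ok = mask[j2, i2]
        x = np.where(ok, xn, x)
        # y-move with wall rejection
        yn = y + drift * dt + sig * rng.standard_normal(n)
        j2, i2 = cell_of(x, yn)
        ok = mask[j2, i2]
        y = np.where(ok, yn, y)
        if track:
            j, i = cell_of(x, y)
            reg = region[j, i]
            active = lost_at == 0
            # up-commitment: entering the outgoing connector of the current
            # junction, or (for the last junction) reaching the stem top
            up = active & (reg == 100 + stage)
            top = active & (stage == nj) & (reg == nj) & \
                (y >= feeds[-1] + geom.y_v - geom.channel_width)
            adv = up | top
            passed[adv] = np.maximum(passed[adv], stage[adv])
            stage[adv] = np.minimum(stage[adv] + 1, nj + 1)
            # down-commitment: entering the dead end of the current junction
            down = active & (reg == 200 + stage)
            lost_at[down] = stage[down]
        if step % rec_every == 0 or step == n_steps - 1:
            frames.append(np.stack([x, y], axis=1).astype(np.float32))
            times.append((step + 1) * dt)

    return TrajectorySet(times=np.asarray(times), positions=np.asarray(frames),
                         population=population, geom=geom, seed=seed, dt=dt,
                         passed=passed, lost_at=lost_at)


def render_observation(traj: TrajectorySet, times, bin_width: float = 25.0,
                       noise: str | None = "poisson",
                       noise_seed: int = 0) -> list[SyntheticProfile]:
    """Binned junction counts at the requested times (s).

    With ``noise="poisson"`` each bin occupancy is resampled from a Poisson
    law with that mean (counting/imaging noise); ``noise=None`` returns the
    exact occupancies.
    """
    rng = np.random.default_rng(noise_seed)
    geom = traj.geom
    out = []
    edges = np.arange(0.0, 2 * geom.y_v + bin_width / 2, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for t in np.atleast_1d(times):
        k = int(np.argmin(np.abs(traj.times - t)))
        pos = traj.positions[k]
        for n in range(1, geom.n_junctions + 1):
            xc = geom.stem_x(n)
            lo, hi = geom.stem_interval(n)
            h = geom.channel_width / 2
            sel = ((np.abs(pos[:, 0] - xc) <= h)
                   & (pos[:, 1] >= lo) & (pos[:, 1] <= hi))
            counts, _ = np.histogram(pos[sel, 1] - lo, bins=edges)
            if noise == "poisson":
                counts = rng.poisson(counts)
            elif noise is not None:
                raise InvalidConfigurationError(f"unknown noise model {noise!r}")
            out.append(SyntheticProfile(junction=n, time=float(traj.times[k]),
                                        y=centers, counts=counts,
                                        noise=noise or "none"))
    return out


def junction_decision_counts(traj: TrajectorySet,
                             select: np.ndarray | None = None) -> pd.DataFrame:
    """Per-junction counts of resolved first commitments: agents whose first
    semibranch end reached was up-gradient versus down-gradient.  ``select``
    restricts to a subset of agents (e.g. one strain)."""
    passed = traj.passed if select is None else traj.passed[select]
    lost = traj.lost_at if select is None else traj.lost_at[select]
    rows = []
    for n in range(1, traj.geom.n_junctions + 1):
        up = int((passed >= n).sum())
        down = int((lost == n).sum())
        rows.append({"junction": n, "n_up": up, "n_down": down,
                     "dilution_factor": (up + down) / up if up else np.nan})
    return pd.DataFrame(rows)


def generate_mixed_population(n_chemotactic: int, n_null: int,
                              geom: MazeGeometry, field: ConcentrationField,
                              params: ct.ChemotaxisParameters | None = None,
                              seed: int = 0, t_end: float = 9600.0,
                              dt: float = 0.5,
                              record_interval: float = 120.0) -> TrajectorySet:
    """Two-strain demonstration: a chemotactic strain with the population
    drift law, and a non-chemotactic strain (v_c = 0) with the same
    motility, mixed at the inlet."""
    if n_chemotactic <= 0 or n_null <= 0:
        raise DomainError("both strain counts must be positive")
    params = params or ct.ChemotaxisParameters()
    D = params.D_population
    if field.regime == "log":
        wt = AgentPopulation(D=np.full(n_chemotactic, D), drift_mode="log",
                             coeff=np.full(n_chemotactic,
                                           params.chi_log * field.gradient),
                             labels=np.array(["WT"] * n_chemotactic))
    else:
        wt = AgentPopulation.homogeneous(
            n_chemotactic, D=D, vc=params.chi_linear * field.gradient,
            label="WT")
    null = AgentPopulation.homogeneous(n_null, D=D, vc=0.0, label="null")
    pop = AgentPopulation.concatenate([wt, null])
    return simulate_agents(geom, field, pop, t_end=t_end, dt=dt, seed=seed,
                           record_interval=record_interval)


def phenotypes_to_agents(phen: pd.DataFrame,
                         hyper: PopulationHyperparameters,
                         field: ConcentrationField, geom: MazeGeometry,
                         params: ct.ChemotaxisParameters | None = None,
                         ) -> AgentPopulation:
    """Map sampled phenotypes to agent motility parameters under the
    pipeline conventions: D = D_ref T̄_B/T_B and v_c = g ε / T_B, with the
    log-regime drift varying continuously as ∝ 1/C(y)."""
    params = params or ct.ChemotaxisParameters()
    tbar = hyper.mean_tumble_bias
    gbar = gain_distribution(hyper).mean()
    D = params.D_population * tbar / phen.T_B.to_numpy()
    rel = (phen.g.to_numpy() / gbar) * (tbar / phen.T_B.to_numpy())
    if field.regime == "log":
        coeff = rel * params.chi_log * field.gradient
        return AgentPopulation(D=D, drift_mode="log", coeff=coeff,
                               phenotypes=phen)
    vc = rel * params.chi_linear * field.gradient
    return AgentPopulation(D=D, drift_mode="linear", vc=vc, phenotypes=phen)


def single_junction_control_geometry(geom: MazeGeometry,
                                     field: ConcentrationField,
                                     ) -> tuple[MazeGeometry, ConcentrationField]:
    """A one-junction device whose stem spans the same concentration range
    as the last junction of the full maze (the 'unsorted' control)."""
    g1 = MazeGeometry(n_junctions=1, y_v=geom.y_v,
                      horizontal_len=geom.horizontal_len,
                      channel_width=geom.channel_width,
                      inlet_len=geom.inlet_len, inlet_y=geom.y_v,
                      slope_window=geom.slope_window)
    lo, hi = geom.stem_interval(geom.n_junctions)
    c_lo = float(field.concentration(lo))
    c_hi = float(field.concentration(hi))
    f1 = build_concentration_field(
        g1, field.source, field.sink, regime=field.regime,
        band=((c_lo - field.sink) / (field.source - field.sink),
              (c_hi - field.sink) / (field.source - field.sink)))
    return g1, f1


def generate_heterogeneous_experiment(hyper: PopulationHyperparameters,
                                      geom: MazeGeometry,
                                      field: ConcentrationField,
                                      n_cells: int, seed: int = 0,
                                      params: ct.ChemotaxisParameters | None = None,
                                      t_end: float = 9600.0, dt: float = 0.5,
                                      times=None,
                                      noise: str | None = "poisson") -> dict:
    """Full synthetic experiment for a heterogeneous clonal population.

    Returns a dict with the maze trajectory set and rendered profiles, the
    matching single-junction ('unsorted') control at the last junction's
    conditions, the ground-truth phenotypes, and a sorting-index observation
    table generated from the navigation model with counting noise (the
    input expected by :func:`tmaze.heterogeneity.fit_sigma`).
    """
    if n_cells < 1000:
        raise DomainError("need at least 1e3 cells for stable profiles")
    params = params or ct.ChemotaxisParameters()
    phen = sample_phenotypes(hyper, n_cells, seed=seed)
    pop = phenotypes_to_agents(phen, hyper, field, geom, params)
    # rare low-tumble-bias cells have large D; keep the step inside the bound
    dt = min(dt, 0.9 * (geom.channel_width / 2) ** 2 / (2 * pop.D.max()))
    traj = simulate_agents(geom, field, pop, t_end=t_end, dt=dt, seed=seed + 1)
    times = list(times) if times is not None else [t_end]
    profiles = render_observation(traj, times, noise=noise,
                                  noise_seed=seed + 2)
    # unsorted control: same population, single junction at last-junction
    # conditions
    g1, f1 = single_junction_control_geometry(geom, field)
    pop1 = phenotypes_to_agents(phen, hyper, f1, g1, params)
    traj1 = simulate_agents(g1, f1, pop1, t_end=t_end, dt=dt, seed=seed + 3)
    control = render_observation(traj1, times, noise=noise,
                                 noise_seed=seed + 4)
    table = synthetic_sorting_indices(hyper, geom, field, params=params,
                                      seed=seed + 5)
    return {"trajectories": traj, "profiles": profiles,
            "control_trajectories": traj1, "control_profiles": control,
            "phenotypes": phen, "sorting_observations": table,
            "control_geometry": g1, "control_field": f1}


def synthetic_sorting_indices(hyper: PopulationHyperparameters,
                              geom: MazeGeometry, field: ConcentrationField,
                              params: ct.ChemotaxisParameters | None = None,
                              noise: float = 0.1, n_replicates: int = 3,
                              seed: int = 0) -> pd.DataFrame:
    """Noisy heterogeneous-sorting-index observations from the navigation
    model: H_n multiplied by replicate-wise multiplicative Gaussian noise."""
    from .heterogeneity import MazeHeterogeneityModel

    rng = np.random.default_rng(seed)
    model = MazeHeterogeneityModel(hyper, geom, field, params=params)
    rows = []
    for rep in range(n_replicates):
        for n in range(1, geom.n_junctions + 1):
            H = model.heterogeneous_sorting_index(n)
            rows.append({"replicate": rep, "junction": n,
                         "H_n": H * max(1e-6, 1 + noise * rng.standard_normal())})
    return pd.DataFrame(rows)
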