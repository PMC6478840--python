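"""One-dimensional analytical model of maze navigation.

Working in the coordinate along the branching channels collapses the maze
to one dimension: the population spreads diffusively along the path, halves
at every junction (even split between the two semibranches), and is biased
up the gradient within the stems.  The expected density at the end of
junction n without chemotaxis is a branch-split Gaussian,

    B_n(t) = (B_0 / 2^n) · exp[−d_n² / (4 D t)] / sqrt(4 π D t),

with d_n the path distance from the inlet.  Chemotaxis multiplies B_n by a
sorting index S_n built from the per-junction drift speeds v_c,i over the
semibranch length y_v.  Two closed exponential forms of S_n are provided:

``"growth"``   S_n = exp[+Σ_{i<=n} i y_v v_c,i / (4D)] — the ratio of the
               advective to the diffusive arrival, > 1 for positive
               chemotaxis and exponentially increasing with n.
``"transit"``  the same magnitude with a damped (negative) exponent.  This
               is the compact closed form obtained when the ratio of the
               advected and diffusive Gaussians is evaluated at the
               chemotactic transit time t_n* = Σ i y_v / v_c,i, where the
               quadratic displacement cost (d − v t)² dominates; it is the
               form whose population average defines the heterogeneity
               quantification in :mod:`tmaze.heterogeneity`.
``"gaussian"`` the explicit two-Gaussian ratio at t_n* without further
               simplification.

Neither exponential form closes exactly against a brute-force 1-D
advection-diffusion solution for n ≥ 3 (the algebra does not commute with
the per-junction time bookkeeping); :func:`solve_path_1d` provides the
brute-force solver used to validate qualitative behavior and the 2-D code.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import diags
from scipy.sparse.linalg import splu

from .errors import DomainError, InvalidConfigurationError, StabilityError
from .geometry import MazeGeometry

__all__ = [
    "diffusion_count",
    "sorting_index",
    "navigation_performance",
    "solve_path_1d",
    "path_drift_profile",
    "validate_against_2d",
]


def diffusion_count(B_0: float, D: float, geom: MazeGeometry, n: int,
                    t: float) -> float:
    """Expected density at the end of junction ``n`` at time ``t`` (s) for a
    purely diffusive population, including the 2^n branch-split dilution."""
    if t <= 0:
        raise DomainError("time must be positive")
    if D <= 0:
        raise DomainError("diffusivity must be positive")
    d = geom.d(n)
    return float(B_0 / 2 ** n * np.exp(-d * d / (4 * D * t))
                 / np.sqrt(4 * np.pi * D * t))


def _vc_array(v_c, n: int) -> np.ndarray:
    v = np.atleast_1d(np.asarray(v_c, dtype=float))
    if v.size == 1:
        v = np.full(n, v[0])
    if v.size < n:
        raise InvalidConfigurationError(
            f"need a chemotactic velocity for each of {n} junctions")
    if np.any(v < 0):
        raise DomainError("chemotactic velocities must be >= 0")
    return v[:n]


def sorting_index(v_c, y_v: float, D: float, n: int,
                  form: str = "growth") -> float:
    """Sorting index S_n for per-junction drift speeds ``v_c`` (scalar or
    sequence), semibranch length ``y_v`` and diffusivity ``D``.

    S_n = 1 whenever all drift speeds vanish.  See the module docstring for
    the available ``form`` conventions.
    """
    if D <= 0:
        raise DomainError("diffusivity must be positive")
    v = _vc_array(v_c, n)
    if np.all(v == 0):
        return 1.0
    i = np.arange(1, n + 1)
    expo = float(np.sum(i * y_v * v) / (4.0 * D))
    if form == "growth":
        return float(np.exp(expo))
    if form == "transit":
        return float(np.exp(-expo))
    if form == "gaussian":
        if np.any(v == 0):
            raise DomainError(
                "gaussian form needs strictly positive drift at every junction")
        t_star = float(np.sum(i * y_v / v))
        L = n * y_v
        m = float(np.sum(i * y_v))  # advective displacement v_i * (i y_v / v_i) summed
        return float(np.exp((2 * L * m - m * m) / (4 * D * t_star)))
    raise InvalidConfigurationError(f"unknown sorting-index form {form!r}")


def navigation_performance(B_0: float, D: float, v_c, geom: MazeGeometry,
                           n: int, t: float, form: str = "growth") -> float:
    """Navigation performance P_n = B_n(t) · S_n: the expected density at
    junction ``n`` for a cell with diffusivity D and drift speeds v_c."""
    return diffusion_count(B_0, D, geom, n, t) * sorting_index(
        v_c, geom.y_v, D, n, form=form)


# ---------------------------------------------------------------------------
# brute-force 1-D solver on the unfolded path
# ---------------------------------------------------------------------------

def path_drift_profile(geom: MazeGeometry, v_c, s: np.ndarray) -> np.ndarray:
    """Drift speed along the unfolded path coordinate ``s``: v_c,i on the
    up-gradient semibranch of junction i, zero on inlet and connectors."""
    v = _vc_array(v_c, geom.n_junctions)
    out = np.zeros_like(s)
    jog = abs(geom.inlet_y - geom.feed_y(1))
    for i in range(1, geom.n_junctions + 1):
        feed_s = (geom.inlet_len + jog
                  + (i - 1) * (geom.stem_offset + geom.horizontal_len))
        on = (s >= feed_s) & (s < feed_s + geom.y_v)
        out[on] = v[i - 1]
    return out


def solve_path_1d(geom: MazeGeometry, D: float, v_c, t_end: float,
                  dt: float = 1.0, ds: float = 10.0,
                  record_times=None, s_max: float | None = None):
    """Finite-volume solution of the 1-D advection-diffusion equation on the
    unfolded maze path, with reflecting ends.

    Initial condition: a unit pulse at s = 0 (the inlet).  Branch splitting
    is *not* applied (this is a single line); divide by 2^n externally when
    comparing against :func:`diffusion_count`.

    Returns ``(s, records)`` where records is a list of (t, density array).
    """
    if s_max is None:
        # the path ends at the closed up-gradient end of the last junction
        s_max = geom.d(geom.n_junctions)
    ns = int(np.ceil(s_max / ds))
    s = (np.arange(ns) + 0.5) * ds
    v = path_drift_profile(geom, v_c, s)
    if np.max(np.abs(v)) * dt / ds > 1.0:
        raise StabilityError("advective CFL violated; reduce dt or increase ds")
    # implicit diffusion operator (zero-flux ends)
    lam = D * dt / ds ** 2
    main = np.full(ns, 1 + 2 * lam)
    main[0] = main[-1] = 1 + lam
    A = diags([np.full(ns - 1, -lam), main, np.full(ns - 1, -lam)],
              [-1, 0, 1], format="csc")
    lu = splu(A)
    b = np.zeros(ns)
    b[0] = 1.0 / ds  # unit mass pulse at the inlet
    record_times = sorted(record_times if record_times is not None else [t_end])
    records, t, k = [], 0.0, 0
    nsteps = int(np.ceil(record_times[-1] / dt))
    vf = 0.5 * (v[:-1] + v[1:])  # face velocities
    for _ in range(nsteps):
        # explicit upwind advection (drift >= 0 here)
        flux = np.where(vf >= 0, vf * b[:-1], vf * b[1:])
        b[:-1] -= dt / ds * flux
        b[1:] += dt / ds * flux
        b = lu.solve(b)
        t += dt
        while k < len(record_times) and t >= record_times[k] - dt / 2:
            records.append((t, b.copy()))
            k += 1
    return s, records


def validate_against_2d(v_c_values, geom: MazeGeometry, D: float,
                        t_end: float, n_times: int = 16,
                        dx: float = 15.0, dt: float = 1.5):
    """Compare junction-4 (last junction) occupancy time-courses between the
    1-D path model and the 2-D solver, for a set of drift speeds.

    Both curves are normalized to their maximum over the window; the table
    reports the maximum absolute deviation of the normalized curves per
    drift speed.  Returns a pandas DataFrame.
    """
    import pandas as pd

    from .transport import TransportSolver, initial_state, junction_region_mass

    times = np.linspace(t_end / n_times, t_end, n_times)
    n = geom.n_junctions
    rows = []
    for vc in np.atleast_1d(v_c_values):
        # --- 2-D ---
        solver = TransportSolver(geom, D=D, vc_const=float(vc), dx=dx, dt=dt)
        state = initial_state(geom, dx=dx)
        mass2d = []
        for st in solver.run(state, record_times=times):
            mass2d.append(junction_region_mass(st, geom, n))
        mass2d = np.asarray(mass2d)
        # --- 1-D ---
        s, rec = solve_path_1d(geom, D, float(vc), t_end,
                               dt=min(dt, 1.0), ds=10.0, record_times=times)
        lo = geom.d(n) - 2 * geom.y_v   # junction-n stem on the path
        hi = geom.d(n)
        sel = (s >= lo) & (s <= hi)
        mass1d = np.array([np.sum(b[sel]) * (s[1] - s[0]) for _, b in rec])
        c2 = mass2d / mass2d.max() if mass2d.max() > 0 else mass2d
        c1 = mass1d / mass1d.max() if mass1d.max() > 0 else mass1d
        rows.append({"v_c": float(vc),
                     "max_abs_deviation": float(np.max(np.abs(c1 - c2))),
                     "argmax_time_1d_s": float(times[np.argmax(mass1d)]),
                     "argmax_time_2d_s": float(times[np.argmax(mass2d)])})
    return pd.DataFrame(rows)
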