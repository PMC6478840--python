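"""T-maze geometry and the steady chemoattractant field.

The device is a sequence of T-junctions overlaid on a linear attractant
gradient.  Each junction is a vertical channel segment ("stem") of length
``2*y_v`` running parallel to the gradient; cells enter at its midpoint
("feed") from a horizontal connector, and must choose between the
up-gradient and down-gradient semibranch.  The up-gradient end of each stem
connects to the feed of the next junction; the down-gradient end opens into
a dead-end horizontal channel.  Consecutive stems are offset vertically so
that every junction presents the same gradient at a higher absolute
concentration.

Coordinates: x runs along the sequence of junctions, y along the gradient
(concentration increases with y).  Lengths in µm, concentrations in µM.

Device dimensions are reconstructed from printed constraints rather than
measured: the slope-fitting window [750, 1100] µm along a stem implies a
stem length of 1200 µm (y_v = 600 µm), and the test-channel concentration
extrema (47–469 µM under a 0–500 µM source/sink pair) imply a gradient of
(469−47)/3000 ≈ 0.1407 µM/µm across the four-junction span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import InvalidConfigurationError, InvalidGradientError

__all__ = [
    "MazeGeometry",
    "ConcentrationField",
    "Segment",
    "build_maze_geometry",
    "build_concentration_field",
    "linear_regime_field",
    "log_regime_field",
    "junction_concentrations",
    "advective_concentration",
]

#: fraction of the source-to-sink gap occupied by the maze band, implied by
#: the printed channel extrema (47/500 and 469/500 of the source level)
DEFAULT_BAND = (0.094, 0.938)

#: nominal inlet y-position: where the reconstructed 0-500 µM field equals
#: the printed inlet concentration of 140 µM (61 µm above the junction-1 feed)
DEFAULT_INLET_Y = 661.1


@dataclass(frozen=True)
class Segment:
    """An axis-aligned rectangular channel segment of the maze."""

    kind: str            # inlet | port | stem | connector | dead_end
    index: int           # junction index for stem/connector/dead_end, else 0
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x, y):
        return (self.x0 <= x) & (x <= self.x1) & (self.y0 <= y) & (y <= self.y1)


@dataclass(frozen=True)
class MazeGeometry:
    """Layout of the branching T-maze.

    Parameters
    ----------
    n_junctions
        Number of T-junctions in series.
    y_v
        Semibranch length of each junction stem (µm); the stem has length
        ``2*y_v``.
    stem_offset
        Vertical offset between consecutive junction feeds (µm).  ``None``
        (default) means equal to ``y_v``, which makes the up-gradient end of
        each stem coincide in height with the next feed so that connectors
        are horizontal.
    horizontal_len
        Length of the connector between consecutive junctions, and of the
        dead-end channel at each down-gradient stem end (µm).
    channel_width
        Width of every channel (µm).
    inlet_len
        Length of the inlet channel from the seeding port to junction 1 (µm).
    inlet_y
        Nominal y-position of the seeding port, used for the inlet
        concentration and the path distances.  Default reconstructed from the
        printed inlet concentration.
    slope_window
        Interval along the stem (local coordinate, 0 at the down-gradient
        end) in which log-profile slopes are fitted (µm).
    """

    n_junctions: int = 4
    y_v: float = 600.0
    stem_offset: float | None = None
    horizontal_len: float = 1000.0
    channel_width: float = 100.0
    inlet_len: float = 300.0
    inlet_y: float = DEFAULT_INLET_Y
    slope_window: tuple[float, float] = (750.0, 1100.0)
    port_radius: float | None = None   # seeding-port pad; default channel_width

    def __post_init__(self):
        if self.stem_offset is None:
            object.__setattr__(self, "stem_offset", self.y_v)
        if self.port_radius is None:
            object.__setattr__(self, "port_radius", self.channel_width)
        if self.n_junctions < 1:
            raise InvalidConfigurationError("need at least one junction")
        for name in ("y_v", "stem_offset", "horizontal_len", "channel_width",
                     "inlet_len"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(f"{name} must be positive")
        lo, hi = self.slope_window
        if not (0 <= lo < hi <= 2 * self.y_v):
            raise InvalidConfigurationError(
                "slope_window must lie within [0, 2*y_v]")

    # ---- vertical layout -------------------------------------------------
    @property
    def span(self) -> float:
        """Vertical extent of the maze (µm); y runs over [0, span]."""
        return 2 * self.y_v + (self.n_junctions - 1) * self.stem_offset

    def feed_y(self, n: int) -> float:
        """Height of the feed point (stem midpoint) of junction ``n``."""
        self._check_index(n)
        return self.y_v + (n - 1) * self.stem_offset

    def stem_x(self, n: int) -> float:
        """x-position of the centerline of junction ``n``'s stem."""
        self._check_index(n)
        return (n - 1) * self.horizontal_len

    def stem_interval(self, n: int) -> tuple[float, float]:
        """(y_low, y_high) of junction ``n``'s stem."""
        f = self.feed_y(n)
        return (f - self.y_v, f + self.y_v)

    # ---- path distances --------------------------------------------------
    def d(self, n: int) -> float:
        """Path distance from the inlet port to the up-gradient end of
        junction ``n``, measured along channel centerlines."""
        self._check_index(n)
        jog = abs(self.inlet_y - self.feed_y(1))
        return (self.inlet_len + jog
                + (n - 1) * (self.stem_offset + self.horizontal_len)
                + self.y_v)

    @property
    def d_n(self) -> np.ndarray:
        return np.array([self.d(n) for n in range(1, self.n_junctions + 1)])

    def _check_index(self, n: int) -> None:
        if not 1 <= n <= self.n_junctions:
            raise IndexError(
                f"junction index {n} outside 1..{self.n_junctions}")

    # ---- planar layout ---------------------------------------------------
    @property
    def inlet_port(self) -> tuple[float, float]:
        """(x, y) of the seeding port center in the 2-D mask."""
        return (self.stem_x(1) - self.inlet_len, self.feed_y(1))

    def segments(self) -> list[Segment]:
        """Axis-aligned rectangles whose union is the channel network."""
        w = self.channel_width
        h = w / 2.0
        segs: list[Segment] = []
        x1 = self.stem_x(1)
        f1 = self.feed_y(1)
        px, py = self.inlet_port
        r = self.port_radius
        segs.append(Segment("inlet", 0, px, f1 - h, x1, f1 + h))
        segs.append(Segment("port", 0, px - r, py - r, px + r, py + r))
        for n in range(1, self.n_junctions + 1):
            xc = self.stem_x(n)
            lo, hi = self.stem_interval(n)
            segs.append(Segment("stem", n, xc - h, lo, xc + h, hi))
            # dead-end channel at the down-gradient end, extending away from
            # the next junction is impossible for the last x, so all dead ends
            # extend in +x; they never overlap later stems, which start higher.
            segs.append(Segment("dead_end", n, xc + h, lo, xc + h + self.horizontal_len, lo + w))
            if n < self.n_junctions:
                xn = self.stem_x(n + 1)
                fy = self.feed_y(n + 1)
                segs.append(Segment("connector", n, xc, fy - h, xn, fy + h))
        return segs

    def local_coordinate(self, n: int, y) -> np.ndarray:
        """Stem-local coordinate: 0 at the down-gradient end, 2*y_v at the
        up-gradient end."""
        lo, _ = self.stem_interval(n)
        return np.asarray(y) - lo

    # ---- serialization ---------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        d["segments"] = [asdict(s) for s in self.segments()]
        return json.dumps(d, indent=2)


def build_maze_geometry(config: dict | None = None, **kwargs) -> MazeGeometry:
    """Construct a :class:`MazeGeometry` from a configuration mapping."""
    cfg = dict(config or {})
    cfg.update(kwargs)
    if "slope_window" in cfg:
        cfg["slope_window"] = tuple(cfg["slope_window"])
    return MazeGeometry(**cfg)


@dataclass(frozen=True)
class ConcentrationField:
    """Steady linear attractant field over the maze band.

    The attractant diffuses from a source channel to a buffer (sink) channel
    across a hydrogel gap of width ``W``; the maze occupies the fractional
    band ``band`` of that gap, so the field is affine in y with constant
    gradient ``(source - sink) / W``.

    ``regime`` tags which sensing law applies downstream: ``"linear"``
    (response to ∇C, valid for C ≪ K_I), ``"log"`` (response to ∇C/C, valid
    for K_I ≪ C ≪ K_A) or ``"full"`` (the full receptor response).
    """

    source: float
    sink: float
    span: float
    regime: str = "linear"
    band: tuple[float, float] = DEFAULT_BAND
    inlet_y: float = DEFAULT_INLET_Y

    def __post_init__(self):
        if self.source <= self.sink:
            raise InvalidGradientError(
                f"source ({self.source}) must exceed sink ({self.sink})")
        if self.sink < 0:
            raise InvalidGradientError("sink concentration must be >= 0")
        b0, b1 = self.band
        if not 0 <= b0 < b1 <= 1:
            raise InvalidConfigurationError("band fractions must satisfy 0 <= b0 < b1 <= 1")
        if self.regime not in ("linear", "log", "full"):
            raise InvalidConfigurationError(f"unknown regime {self.regime!r}")

    @property
    def W(self) -> float:
        """Source-to-sink gap width (µm) implied by the band fractions."""
        b0, b1 = self.band
        return self.span / (b1 - b0)

    @property
    def gradient(self) -> float:
        """∂C/∂y (µM/µm), constant across the maze."""
        return (self.source - self.sink) / self.W

    def concentration(self, y):
        """C(y) for y in maze coordinates [0, span]."""
        b0, _ = self.band
        return self.sink + (self.source - self.sink) * b0 + self.gradient * np.asarray(y)

    @property
    def C_min(self) -> float:
        return float(self.concentration(0.0))

    @property
    def C_max(self) -> float:
        return float(self.concentration(self.span))

    @property
    def C_0(self) -> float:
        """Concentration at the nominal inlet position."""
        return float(self.concentration(self.inlet_y))

    def to_json(self) -> str:
        return json.dumps({**asdict(self), "gradient": self.gradient,
                           "C_min": self.C_min, "C_max": self.C_max,
                           "C_0": self.C_0}, indent=2)


def build_concentration_field(geom: MazeGeometry, source: float, sink: float,
                              regime: str = "linear",
                              band: tuple[float, float] = DEFAULT_BAND,
                              ) -> ConcentrationField:
    """Build the steady linear field spanning ``sink`` → ``source`` across
    the hydrogel gap, restricted to the maze band."""
    return ConcentrationField(source=source, sink=sink, span=geom.span,
                              regime=regime, band=tuple(band),
                              inlet_y=geom.inlet_y)


def linear_regime_field(geom: MazeGeometry, source: float = 5.0,
                        sink: float = 0.0) -> ConcentrationField:
    """The low-concentration (0–5 µM) field, linear-sensing regime."""
    return build_concentration_field(geom, source, sink, regime="linear")


def log_regime_field(geom: MazeGeometry, source: float = 500.0,
                     sink: float = 0.0) -> ConcentrationField:
    """The high-concentration (0–500 µM) field, log-sensing regime."""
    return build_concentration_field(geom, source, sink, regime="log")


def junction_concentrations(field: ConcentrationField, geom: MazeGeometry,
                            n: int) -> tuple[float, float, float]:
    """Concentrations at the down-gradient end, feed point, and up-gradient
    end of junction ``n``'s stem."""
    lo, hi = geom.stem_interval(n)
    return (float(field.concentration(lo)),
            float(field.concentration(geom.feed_y(n))),
            float(field.concentration(hi)))


def advective_concentration(field: ConcentrationField, geom: MazeGeometry,
                            n: int) -> float:
    """Concentration at the midpoint of junction ``n``'s up-gradient
    semibranch — the mean concentration along the segment over which the
    chemotactic drift acts, used to evaluate the per-junction chemotactic
    velocity in the log-sensing regime."""
    return float(field.concentration(geom.feed_y(n) + geom.y_v / 2.0))
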