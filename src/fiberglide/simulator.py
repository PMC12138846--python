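"""Monte-Carlo simulation of microtubule tips gliding on a fiber-tip surface.

Only the leading tip of each filament is simulated: in a gliding assay the
tip finds the next surface-bound kinesin motor and the rest of the filament
follows its path.  The tip performs a worm-like-chain walk on the kinesin-
coated fiber tip (core disc plus cladding annulus).  A tip that runs over
the outer cladding edge detaches with a fixed probability; otherwise it is
steered along the boundary.  Detached tips diffuse in a 2-D projection of
the volume above the fiber and may re-land while over the motility zone, or
drift past an outer absorbing boundary and be lost for good.

Lengths are micrometres, times seconds, gliding speeds nanometres per
second (the unit gliding-assay speeds are conventionally reported in).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Zone",
    "FiberGeometry",
    "MotilityParams",
    "TipState",
    "PopulationSeries",
    "step_gliding",
    "apply_edge_rule",
    "step_diffusion",
    "simulate_population",
    "TipEnsemble",
]

_TWO_PI = 2.0 * math.pi


class Zone(enum.Enum):
    """Where a simulated tip currently is."""

    CORE = "core"  # on the light-guiding core; contributes to the signal
    CLADDING = "cladding"  # on the kinesin-coated cladding annulus; dark
    DIFFUSING = "diffusing"  # detached, diffusing above the fiber
    LOST = "lost"  # past the absorbing boundary; terminal


class InvalidParameterError(ValueError):
    """A physical parameter is out of its admissible range."""


def _wrap_angle(theta):
    """Wrap angle(s) to (-pi, pi]."""
    wrapped = np.mod(theta + math.pi, _TWO_PI) - math.pi
    # np.mod maps exact multiples of 2*pi-shifted -pi to -pi; fold onto +pi
    return np.where(wrapped == -math.pi, math.pi, wrapped)


@dataclass(frozen=True)
class FiberGeometry:
    """Circular fiber-tip geometry.

    Parameters
    ----------
    core_radius : float
        Radius of the light-guiding core in µm.  Default 100 µm
        (a 200 µm-diameter multimode fiber).
    cladding_width : float
        Width of the kinesin-coated cladding annulus in µm.  The
        motility-supporting zone is the disc of radius
        ``core_radius + cladding_width``.
    escape_factor : float
        The outer absorbing boundary of the diffusion zone sits at
        ``escape_factor * cladding_outer_radius``.  A diffusing tip that
        crosses it is lost permanently.
    """

    core_radius: float = 100.0
    cladding_width: float = 10.0
    escape_factor: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.core_radius):
            raise InvalidParameterError("core_radius must be positive")
        if not (self.cladding_width > 0.0):
            raise InvalidParameterError("cladding_width must be positive")
        if not (self.escape_factor > 1.0):
            raise InvalidParameterError("escape_factor must exceed 1")

    @property
    def cladding_outer_radius(self) -> float:
        return self.core_radius + self.cladding_width

    @property
    def escape_radius(self) -> float:
        return self.escape_factor * self.cladding_outer_radius


@dataclass(frozen=True)
class MotilityParams:
    """Kinetic parameters of one microtubule population.

    Parameters
    ----------
    gliding_speed : float
        Kinesin-driven gliding speed v_f in nm/s.
    persistence_length : float
        Trajectory persistence length L_p in µm.  Sets the variance of the
        per-step heading change, Var(dtheta) = v_f * dt / L_p.
    time_step : float
        Update interval dt in s (default 10 ms).
    detach_probability : float
        Probability that a tip reaching the outer cladding edge detaches
        instead of being steered along the boundary (default 0.8).
    landing_rate : float
        Rate in 1/s at which a diffusing tip hovering over the motility
        zone re-lands (default 0.01 /s); applied as a per-step Bernoulli
        trial with probability ``landing_rate * time_step``.
    diffusion_coefficient : float
        2-D diffusion coefficient of detached tips in µm²/s.
    bundled_fraction : float
        Fraction of tips cross-linked into bundles.  Bundles are held on
        the tip and keep contributing to the guided fluorescence, so
        bundled tips never detach: they are steered (probability 1) at the
        core edge and never leave the light-guiding core.
    """

    gliding_speed: float = 500.0
    persistence_length: float = 100.0
    time_step: float = 0.01
    detach_probability: float = 0.8
    landing_rate: float = 0.01
    diffusion_coefficient: float = 1.0
    bundled_fraction: float = 0.0

    def __post_init__(self) -> None:
        numeric = (
            self.gliding_speed,
            self.persistence_length,
            self.time_step,
            self.detach_probability,
            self.landing_rate,
            self.diffusion_coefficient,
            self.bundled_fraction,
        )
        if not all(np.isfinite(v) for v in numeric):
            raise InvalidParameterError("motility parameters must be finite")
        if self.gliding_speed < 0:
            raise InvalidParameterError("gliding_speed must be >= 0")
        if self.persistence_length <= 0:
            raise InvalidParameterError("persistence_length must be > 0")
        if self.time_step <= 0:
            raise InvalidParameterError("time_step must be > 0")
        for name in ("detach_probability", "bundled_fraction"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if self.landing_rate < 0 or self.diffusion_coefficient < 0:
            raise InvalidParameterError("rates must be nonnegative")

    @property
    def speed_um_per_s(self) -> float:
        return self.gliding_speed * 1e-3

    @property
    def step_length(self) -> float:
        """Distance glided per time step, µm."""
        return self.speed_um_per_s * self.time_step

    @property
    def heading_std(self) -> float:
        """Standard deviation of the per-step heading change, rad."""
        return math.sqrt(self.speed_um_per_s * self.time_step / self.persistence_length)

    @property
    def landing_probability_per_step(self) -> float:
        return min(self.landing_rate * self.time_step, 1.0)


@dataclass(frozen=True)
class TipState:
    """Position, heading and zone of one simulated microtubule tip."""

    position: np.ndarray
    heading: float
    zone: Zone = Zone.CORE
    bundled: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=float).reshape(2)
        )

    @property
    def radius(self) -> float:
        return float(np.hypot(self.position[0], self.position[1]))


def step_gliding(
    state: TipState, params: MotilityParams, rng: np.random.Generator
) -> TipState:
    """Advance a gliding tip by one worm-like-chain step.

    The heading is perturbed by a zero-mean normal draw with standard
    deviation sqrt(v_f * dt / L_p), then the tip advances v_f * dt along
    the new heading.  The heading is wrapped to (-pi, pi].
    """
    if state.zone not in (Zone.CORE, Zone.CLADDING):
        raise ValueError(f"cannot glide from zone {state.zone}")
    dtheta = rng.normal(0.0, params.heading_std) if params.heading_std > 0 else 0.0
    heading = float(_wrap_angle(state.heading + dtheta))
    step = params.step_length
    position = state.position + step * np.array([math.cos(heading), math.sin(heading)])
    return replace(state, position=position, heading=heading)


def _tangent_heading(position: np.ndarray, heading: float) -> float:
    """Heading along the boundary circle closest to the incoming direction.

    Of the two tangent directions at ``position``, pick the one with a
    positive component along the incoming heading; exact radial incidence
    resolves counter-clockwise.
    """
    ur = position / np.hypot(position[0], position[1])
    d = np.array([math.cos(heading), math.sin(heading)])
    cross = ur[0] * d[1] - ur[1] * d[0]
    if cross >= 0.0:  # counter-clockwise tangent (ties go CCW)
        tangent = np.array([-ur[1], ur[0]])
    else:
        tangent = np.array([ur[1], -ur[0]])
    return math.atan2(tangent[1], tangent[0])


def apply_edge_rule(
    state: TipState,
    geometry: FiberGeometry,
    params: MotilityParams,
    rng: np.random.Generator,
) -> TipState:
    """Resolve a tip whose proposed position lies beyond the cladding edge.

    With probability ``detach_probability`` the tip detaches (zone becomes
    DIFFUSING, position projected onto the boundary circle); otherwise it
    is steered along the boundary: position projected onto the circle and
    heading rotated to the nearer tangent direction.  Bundled tips are
    always steered, never detached, and their boundary is the core edge
    (bundles stay on the light-guiding core).
    """
    r_out = geometry.core_radius if state.bundled else geometry.cladding_outer_radius
    r = state.radius
    if r <= r_out:
        raise ValueError("edge rule applies only beyond the tip's boundary circle")
    boundary_pos = state.position * (r_out / r)
    detach = (not state.bundled) and (rng.random() < params.detach_probability)
    if detach:
        return replace(state, position=boundary_pos, zone=Zone.DIFFUSING)
    heading = _tangent_heading(boundary_pos, state.heading)
    return replace(state, position=boundary_pos, heading=heading)


def step_diffusion(
    state: TipState,
    geometry: FiberGeometry,
    params: MotilityParams,
    rng: np.random.Generator,
) -> TipState:
    """Advance a detached tip by one diffusion step.

    The tip takes an isotropic Gaussian step with per-axis variance
    ``2 * D * dt``.  Crossing the escape radius makes it LOST (terminal).
    While hovering over the motility zone it re-lands with per-step
    probability ``landing_rate * dt``; on landing the zone is CORE or
    CLADDING according to radius and the heading is redrawn uniformly.
    """
    if state.zone is not Zone.DIFFUSING:
        raise ValueError("step_diffusion applies only to diffusing tips")
    sigma = math.sqrt(2.0 * params.diffusion_coefficient * params.time_step)
    position = state.position + rng.normal(0.0, sigma, size=2) if sigma > 0 else state.position
    r = float(np.hypot(position[0], position[1]))
    if r > geometry.escape_radius:
        return replace(state, position=position, zone=Zone.LOST)
    if r <= geometry.cladding_outer_radius:
        if rng.random() < params.landing_probability_per_step:
            zone = Zone.CORE if r <= geometry.core_radius else Zone.CLADDING
            heading = rng.uniform(-math.pi, math.pi)
            return replace(state, position=position, heading=heading, zone=zone)
    return replace(state, position=position)


@dataclass
class PopulationSeries:
    """Zone-count time series of a simulated tip population."""

    times: np.ndarray
    count_core: np.ndarray
    count_cladding: np.ndarray
    count_diffusing: np.ndarray
    count_lost: np.ndarray
    n_total: int
    seed: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("count_core", "count_cladding", "count_diffusing", "count_lost"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64))

    def core_at(self, t) -> np.ndarray:
        """Core count at arbitrary times by previous-sample interpolation."""
        idx = np.clip(np.searchsorted(self.times, np.asarray(t), side="right") - 1, 0, None)
        return self.count_core[idx]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "count_core": self.count_core,
                "count_cladding": self.count_cladding,
                "count_diffusing": self.count_diffusing,
                "count_lost": self.count_lost,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, n_total: int | None = None, seed: int = -1) -> "PopulationSeries":
        df = pd.read_csv(path)
        counts = df[["count_core", "count_cladding", "count_diffusing", "count_lost"]]
        if n_total is None:
            n_total = int(counts.iloc[0].sum())
        return cls(
            times=df["time_s"].to_numpy(),
            count_core=df["count_core"].to_numpy(),
            count_cladding=df["count_cladding"].to_numpy(),
            count_diffusing=df["count_diffusing"].to_numpy(),
            count_lost=df["count_lost"].to_numpy(),
            n_total=n_total,
            seed=seed,
        )


_ZCORE, _ZCLAD, _ZDIFF, _ZLOST = 0, 1, 2, 3


@dataclass
class TipEnsemble:
    """Vectorised state of many tips, advanced one time step at a time.

    This is the engine behind :func:`simulate_population`; the per-tip
    operations :func:`step_gliding`, :func:`apply_edge_rule` and
    :func:`step_diffusion` implement the same rules one tip at a time and
    serve as the readable reference.
    """

    geometry: FiberGeometry
    params: MotilityParams
    rng: np.random.Generator
    x: np.ndarray = field(default=None)  # type: ignore[assignment]
    y: np.ndarray = field(default=None)  # type: ignore[assignment]
    heading: np.ndarray = field(default=None)  # type: ignore[assignment]
    zone: np.ndarray = field(default=None)  # type: ignore[assignment]
    bundled: np.ndarray = field(default=None)  # type: ignore[assignment]

    @classmethod
    def uniform_on_core(
        cls,
        n: int,
        geometry: FiberGeometry,
        params: MotilityParams,
        rng: np.random.Generator,
    ) -> "TipEnsemble":
        """Seed ``n`` tips uniformly over the core disc with random headings."""
        radius = geometry.core_radius * np.sqrt(rng.random(n))
        angle = rng.uniform(-math.pi, math.pi, n)
        n_bundled = int(round(params.bundled_fraction * n))
        bundled = np.zeros(n, dtype=bool)
        bundled[:n_bundled] = True
        return cls(
            geometry=geometry,
            params=params,
            rng=rng,
            x=radius * np.cos(angle),
            y=radius * np.sin(angle),
            heading=rng.uniform(-math.pi, math.pi, n),
            zone=np.full(n, _ZCORE, dtype=np.int8),
            bundled=bundled,
        )

    @property
    def n(self) -> int:
        return self.x.size

    def zone_counts(self) -> tuple[int, int, int, int]:
        counts = np.bincount(self.zone, minlength=4)
        return int(counts[0]), int(counts[1]), int(counts[2]), int(counts[3])

    def step(self) -> None:
        """Advance all tips by one time step of ``params.time_step``."""
        g, p, rng = self.geometry, self.params, self.rng
        r_out = g.cladding_outer_radius

        gliding = (self.zone == _ZCORE) | (self.zone == _ZCLAD)
        if gliding.any():
            idx = np.flatnonzero(gliding)
            dtheta = rng.normal(0.0, p.heading_std, idx.size) if p.heading_std > 0 else 0.0
            h = _wrap_angle(self.heading[idx] + dtheta)
            self.heading[idx] = h
            step = p.step_length
            x = self.x[idx] + step * np.cos(h)
            y = self.y[idx] + step * np.sin(h)
            r = np.hypot(x, y)

            # bundled tips are confined to the core disc, the rest to the
            # full motility zone (core + cladding annulus)
            limit = np.where(self.bundled[idx], g.core_radius, r_out)
            beyond = r > limit
            if beyond.any():
                bi = idx[beyond]
                blim = limit[beyond]
                scale = blim / r[beyond]
                bx, by = x[beyond] * scale, y[beyond] * scale
                detach = (~self.bundled[bi]) & (
                    rng.random(bi.size) < p.detach_probability
                )
                x[beyond], y[beyond] = bx, by
                r[beyond] = blim
                self.zone[bi[detach]] = _ZDIFF
                steer = ~detach
                if steer.any():
                    si = bi[steer]
                    urx, ury = bx[steer] / blim[steer], by[steer] / blim[steer]
                    hh = self.heading[si]
                    dx, dy = np.cos(hh), np.sin(hh)
                    ccw = (urx * dy - ury * dx) >= 0.0
                    tx = np.where(ccw, -ury, ury)
                    ty = np.where(ccw, urx, -urx)
                    self.heading[si] = np.arctan2(ty, tx)
            self.x[idx], self.y[idx] = x, y
            still = self.zone[idx] != _ZDIFF
            inner = r <= g.core_radius
            self.zone[idx[still & inner]] = _ZCORE
            self.zone[idx[still & ~inner]] = _ZCLAD

        diffusing = self.zone == _ZDIFF
        if diffusing.any():
            di = np.flatnonzero(diffusing)
            if p.diffusion_coefficient > 0:
                sigma = math.sqrt(2.0 * p.diffusion_coefficient * p.time_step)
                self.x[di] += rng.normal(0.0, sigma, di.size)
                self.y[di] += rng.normal(0.0, sigma, di.size)
            r = np.hypot(self.x[di], self.y[di])
            self.zone[di[r > g.escape_radius]] = _ZLOST
            over = r <= r_out
            if over.any() and p.landing_probability_per_step > 0:
                oi = di[over]
                land = rng.random(oi.size) < p.landing_probability_per_step
                li = oi[land]
                if li.size:
                    lr = r[over][land]
                    self.zone[li] = np.where(lr <= g.core_radius, _ZCORE, _ZCLAD)
                    self.heading[li] = rng.uniform(-math.pi, math.pi, li.size)


def simulate_population(
    n_total: int,
    geometry: FiberGeometry,
    params: MotilityParams,
    duration: float,
    seed: int,
    record_interval: float | None = None,
    trajectory_recorder=None,
) -> PopulationSeries:
    """Simulate ``n_total`` tips for ``duration`` seconds.

    Tips start uniformly distributed over the core disc with uniform random
    headings; a ``bundled_fraction`` of them is marked bundled.  Zone counts
    are recorded every ``record_interval`` seconds (default: every step).

    ``trajectory_recorder``, if given, is called at every recording time as
    ``recorder(t, x, y, heading, zone)`` with the raw state arrays (zone
    codes 0=core, 1=cladding, 2=diffusing, 3=lost).

    Identical ``(seed, configuration)`` give bit-identical output.
    """
    if n_total < 1:
        raise InvalidParameterError("n_total must be >= 1")
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    dt = params.time_step
    n_steps = int(round(duration / dt))
    if record_interval is None:
        record_every = 1
    else:
        record_every = max(1, int(round(record_interval / dt)))

    rng = np.random.default_rng(seed)
    ens = TipEnsemble.uniform_on_core(n_total, geometry, params, rng)

    times, cc, cl, cd, cx = [], [], [], [], []

    def record(t: float) -> None:
        a, b, c, d = ens.zone_counts()
        times.append(t)
        cc.append(a)
        cl.append(b)
        cd.append(c)
        cx.append(d)
        if trajectory_recorder is not None:
            trajectory_recorder(t, ens.x, ens.y, ens.heading, ens.zone)

    record(0.0)
    for k in range(1, n_steps + 1):
        ens.step()
        if k % record_every == 0 or k == n_steps:
            record(k * dt)

    return PopulationSeries(
        times=np.array(times),
        count_core=np.array(cc),
        count_cladding=np.array(cl),
        count_diffusing=np.array(cd),
        count_lost=np.array(cx),
        n_total=n_total,
        seed=seed,
    )
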