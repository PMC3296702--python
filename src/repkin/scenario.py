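"""Replication scenarios: initiation-rate and fork-velocity profiles.

A *scenario* is the full specification of a replication program on a genomic
region: the initiation rate ``I(x, t)`` (expected initiations per kb of
unreplicated DNA per second), the fork velocity ``v±(x, t)`` (kb/sec), the
boundary condition (periodic / isolated / fork injection from flanking DNA),
and an optional fork-stalling defect model.  Scenarios are declarative and
serializable; the numerics live in :mod:`repkin.solver` and
:mod:`repkin.simulate`.

Units are fixed package-wide: kb for position, seconds for time,
initiations/kb/sec for initiation rates, kb/sec for velocities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "Grid",
    "Zone",
    "InitiationProfile",
    "VelocityProfile",
    "BoundaryCondition",
    "DefectModel",
    "Scenario",
    "ScenarioError",
    "SchemaError",
    "evaluate_initiation",
    "evaluate_velocity",
    "load_scenario",
    "save_scenario",
    "two_zone_scenario",
]


class ScenarioError(ValueError):
    """Invalid scenario parameter or out-of-domain evaluation."""


class SchemaError(ScenarioError):
    """Scenario config text does not conform to the documented schema."""


@dataclass(frozen=True)
class Grid:
    """Discretization of the space-time domain.

    Parameters
    ----------
    length : float
        Genome / fragment length ``L`` in kb.
    dx : float
        Spatial step in kb.  ``length / dx`` must be a whole number of cells.
    dt : float
        Time step in seconds.
    t_max : float
        Integration horizon in seconds; ``t_max / dt`` must be whole.
    x0 : float
        Position of the left edge of the domain (kb), default 0.
    """

    length: float
    dx: float = 0.5
    dt: float = 10.0
    t_max: float = 20000.0
    x0: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.dx <= 0 or self.dt <= 0 or self.t_max <= 0:
            raise ScenarioError("grid lengths and steps must be positive")
        if abs(self.length / self.dx - round(self.length / self.dx)) > 1e-9:
            raise ScenarioError(
                f"length/dx = {self.length}/{self.dx} is not a whole number of cells"
            )
        if abs(self.t_max / self.dt - round(self.t_max / self.dt)) > 1e-9:
            raise ScenarioError(
                f"t_max/dt = {self.t_max}/{self.dt} is not a whole number of steps"
            )

    @property
    def nx(self) -> int:
        return int(round(self.length / self.dx))

    @property
    def nt(self) -> int:
        return int(round(self.t_max / self.dt))

    @property
    def x(self) -> np.ndarray:
        """Cell centers (kb); cells are half-open bins ``[x, x+dx)``."""
        return self.x0 + (np.arange(self.nx) + 0.5) * self.dx

    @property
    def x_edges(self) -> np.ndarray:
        return self.x0 + np.arange(self.nx + 1) * self.dx

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.nt + 1) * self.dt

    def contains(self, x: float) -> bool:
        return self.x0 - 1e-9 <= x <= self.x0 + self.length + 1e-9


@dataclass(frozen=True)
class Zone:
    """A single initiation zone.

    ``shape`` is ``"gaussian"`` (``width`` is the Gaussian sigma) or
    ``"rounded_box"`` (``width`` is the full width; logistic edges of scale
    ``edge_scale``).  ``amplitude`` is the peak initiation rate.  An optional
    activation window ``[t_on, t_off)`` gates the zone in time: outside the
    window the zone contributes exactly zero.
    """

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"
    edge_scale: float = 2.0
    t_on: float = 0.0
    t_off: float = math.inf

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "rounded_box"):
            raise ScenarioError(f"unknown zone shape {self.shape!r}")
        if self.amplitude < 0:
            raise ScenarioError("zone amplitude must be >= 0")
        if self.width <= 0:
            raise ScenarioError("zone width must be > 0")
        if self.edge_scale <= 0:
            raise ScenarioError("zone edge_scale must be > 0")
        if self.t_off < self.t_on:
            raise ScenarioError("zone gate must satisfy t_off >= t_on")

    def spatial(self, x: np.ndarray) -> np.ndarray:
        """Spatial factor of the zone (peak value = amplitude), no gate."""
        x = np.asarray(x, dtype=float)
        if self.shape == "gaussian":
            return self.amplitude * np.exp(-((x - self.center) ** 2) / (2.0 * self.width**2))
        lo = self.center - self.width / 2.0
        hi = self.center + self.width / 2.0
        s_lo = 1.0 / (1.0 + np.exp(-(x - lo) / self.edge_scale))
        s_hi = 1.0 / (1.0 + np.exp(-(hi - x) / self.edge_scale))
        return self.amplitude * s_lo * s_hi

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_off


@dataclass(frozen=True)
class InitiationProfile:
    """Initiation rate ``I(x, t)``: a constant background plus gated zones."""

    zones: tuple[Zone, ...] = ()
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ScenarioError("background initiation rate must be >= 0")
        object.__setattr__(self, "zones", tuple(self.zones))

    def __call__(self, x, t: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.full_like(x, self.background, dtype=float)
        for z in self.zones:
            if z.active(t):
                out += z.spatial(x)
        return out

    @property
    def time_dependent(self) -> bool:
        return any(z.t_on > 0.0 or math.isfinite(z.t_off) for z in self.zones)


@dataclass(frozen=True)
class VelocityProfile:
    """Fork speeds ``v+(x)`` and ``v-(x)``, constant or piecewise in space.

    ``segments`` is a sequence of ``(x_lo, x_hi, speed)`` overrides applied to
    both directions (later segments win), or ``(x_lo, x_hi, speed, direction)``
    with direction ``"+"`` / ``"-"``.
    """

    v_plus: float = 0.04
    v_minus: Optional[float] = None
    segments: tuple = ()

    def __post_init__(self) -> None:
        if self.v_minus is None:
            object.__setattr__(self, "v_minus", self.v_plus)
        if self.v_plus <= 0 or self.v_minus <= 0:
            raise ScenarioError("fork velocities must be > 0")
        segs = []
        for seg in self.segments:
            if len(seg) == 3:
                x_lo, x_hi, v = seg
                d = "both"
            else:
                x_lo, x_hi, v, d = seg
            if v <= 0:
                raise ScenarioError("segment fork velocity must be > 0")
            if d not in ("+", "-", "both"):
                raise ScenarioError(f"segment direction must be '+', '-' or 'both', got {d!r}")
            segs.append((float(x_lo), float(x_hi), float(v), d))
        object.__setattr__(self, "segments", tuple(segs))

    def evaluate(self, x, t: float = 0.0, direction: str = "+") -> np.ndarray:
        if direction not in ("+", "-"):
            raise ScenarioError("direction must be '+' or '-'")
        x = np.asarray(x, dtype=float)
        base = self.v_plus if direction == "+" else self.v_minus
        out = np.full_like(x, base, dtype=float)
        for x_lo, x_hi, v, d in self.segments:
            if d in (direction, "both"):
                out[(x >= x_lo) & (x < x_hi)] = v
        return out

    @property
    def v_max(self) -> float:
        speeds = [self.v_plus, self.v_minus] + [s[2] for s in self.segments]
        return max(speeds)


_BOUNDARY_MODES = ("periodic", "isolated", "injection")


@dataclass(frozen=True)
class BoundaryCondition:
    """How the domain ends are treated.

    - ``periodic``: the molecule is a circle (forks wrap).
    - ``isolated``: linear molecule, zero fork inflow, forks exit freely.
    - ``injection``: linear fragment embedded in a longer genome; forks enter
      from semi-infinite homogeneous flanks with constant outside initiation
      rates ``I_left`` / ``I_right`` and outside fork speed ``v_out``.
    """

    mode: str = "periodic"
    I_left: float = 0.0
    I_right: float = 0.0
    v_out: float = 0.04

    def __post_init__(self) -> None:
        if self.mode not in _BOUNDARY_MODES:
            raise ScenarioError(f"boundary mode must be one of {_BOUNDARY_MODES}, got {self.mode!r}")
        if self.I_left < 0 or self.I_right < 0:
            raise ScenarioError("injection rates must be >= 0")
        if self.mode == "periodic" and (self.I_left > 0 or self.I_right > 0):
            raise ScenarioError("periodic boundaries forbid injection rates")
        if self.v_out <= 0:
            raise ScenarioError("outside fork speed must be > 0")


@dataclass(frozen=True)
class DefectModel:
    """Stochastic fork stalling at DNA defects.

    ``spacing`` is the mean distance between defects (kb); ``repair_time`` is
    the mean stall duration in seconds (``inf`` = never repaired this S phase).
    """

    spacing: float
    repair_time: float = math.inf

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ScenarioError("defect spacing must be > 0")
        if self.repair_time <= 0:
            raise ScenarioError("repair time must be > 0 (may be inf)")


@dataclass(frozen=True)
class Scenario:
    """A full replication scenario ``(I(x,t), v±(x,t), boundary, defects)``."""

    initiation: InitiationProfile
    velocity: VelocityProfile = field(default_factory=VelocityProfile)
    boundary: BoundaryCondition = field(default_factory=BoundaryCondition)
    defects: Optional[DefectModel] = None

    def without_defects(self) -> "Scenario":
        return replace(self, defects=None)


# ---------------------------------------------------------------------------
# evaluation helpers (operation surface)

def evaluate_initiation(profile: InitiationProfile, x, t: float, grid: Optional[Grid] = None):
    """Evaluate ``I(x, t)`` (initiations/kb/sec); domain-checked if a grid is given."""
    if t < 0:
        raise ScenarioError("t must be >= 0")
    if grid is not None:
        for xi in np.atleast_1d(np.asarray(x, dtype=float)):
            if not grid.contains(float(xi)):
                raise ScenarioError(f"x = {xi} outside domain [{grid.x0}, {grid.x0 + grid.length}]")
    out = profile(x, t)
    return float(out) if np.isscalar(x) else out


def evaluate_velocity(profile: VelocityProfile, x, t: float, direction: str):
    """Evaluate ``v±(x, t)`` (kb/sec); strictly positive by construction."""
    out = profile.evaluate(x, t, direction)
    return float(out) if np.isscalar(x) else out


# ---------------------------------------------------------------------------
# serialization

_ZONE_KEYS = {"shape", "center", "width", "amplitude", "edge_scale", "t_on", "t_off"}
_INIT_KEYS = {"background", "zones"}
_VEL_KEYS = {"v_plus", "v_minus", "segments"}
_BND_KEYS = {"mode", "I_left", "I_right", "v_out"}
_DEF_KEYS = {"spacing", "repair_time"}
_TOP_KEYS = {"initiation", "velocity", "boundary", "defects"}


def _check_keys(d: dict, allowed: set, path: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise SchemaError(f"unknown key(s) {sorted(unknown)} at {path!r}")


def load_scenario(text: str) -> Scenario:
    """Parse a YAML scenario config into a :class:`Scenario`.

    Schema (all rates in /kb/sec, positions in kb, times in sec)::

        initiation:
          background: 0.0
          zones:
            - {shape: gaussian, center: 200, width: 25, amplitude: 1.0e-5}
            - {shape: gaussian, center: 800, width: 25, amplitude: 1.0e-4, t_on: 5000}
        velocity: {v_plus: 0.04}
        boundary: {mode: periodic}
        defects:  {spacing: 100, repair_time: 1000}   # optional

    Raises :class:`SchemaError` naming the offending path on unknown keys,
    missing required fields, or invariant violations.
    """
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:  # pragma: no cover - yaml details vary
        raise SchemaError(f"config is not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "<root>")
    if "initiation" not in raw:
        raise SchemaError("missing required section 'initiation'")

    init_raw = raw["initiation"] or {}
    _check_keys(init_raw, _INIT_KEYS, "initiation")
    zones = []
    for i, zr in enumerate(init_raw.get("zones", []) or []):
        _check_keys(zr, _ZONE_KEYS, f"initiation.zones[{i}]")
        for req in ("center", "width", "amplitude"):
            if req not in zr:
                raise SchemaError(f"missing required field {req!r} at initiation.zones[{i}]")
        kw = dict(zr)
        if kw.get("t_off") in ("inf", ".inf", None):
            kw.pop("t_off", None)
        try:
            zones.append(Zone(**kw))
        except ScenarioError as exc:
            raise SchemaError(f"initiation.zones[{i}]: {exc}") from exc
    try:
        initiation = InitiationProfile(zones=tuple(zones), background=float(init_raw.get("background", 0.0)))
    except ScenarioError as exc:
        raise SchemaError(f"initiation: {exc}") from exc

    vel_raw = raw.get("velocity") or {}
    _check_keys(vel_raw, _VEL_KEYS, "velocity")
    try:
        velocity = VelocityProfile(
            v_plus=float(vel_raw.get("v_plus", 0.04)),
            v_minus=(None if vel_raw.get("v_minus") is None else float(vel_raw["v_minus"])),
            segments=tuple(tuple(s) for s in (vel_raw.get("segments") or [])),
        )
    except ScenarioError as exc:
        raise SchemaError(f"velocity: {exc}") from exc

    bnd_raw = raw.get("boundary") or {}
    _check_keys(bnd_raw, _BND_KEYS, "boundary")
    try:
        boundary = BoundaryCondition(
            mode=bnd_raw.get("mode", "periodic"),
            I_left=float(bnd_raw.get("I_left", 0.0)),
            I_right=float(bnd_raw.get("I_right", 0.0)),
            v_out=float(bnd_raw.get("v_out", 0.04)),
        )
    except ScenarioError as exc:
        raise SchemaError(f"boundary: {exc}") from exc

    defects = None
    if raw.get("defects") is not None:
        def_raw = raw["defects"]
        _check_keys(def_raw, _DEF_KEYS, "defects")
        if "spacing" not in def_raw:
            raise SchemaError("missing required field 'spacing' at defects")
        rt = def_raw.get("repair_time", math.inf)
        if rt in ("inf", ".inf"):
            rt = math.inf
        try:
            defects = DefectModel(spacing=float(def_raw["spacing"]), repair_time=float(rt))
        except ScenarioError as exc:
            raise SchemaError(f"defects: {exc}") from exc

    return Scenario(initiation=initiation, velocity=velocity, boundary=boundary, defects=defects)


def save_scenario(scenario: Scenario) -> str:
    """Serialize a scenario to canonical YAML (sorted keys, stable floats)."""
    zones = []
    for z in scenario.initiation.zones:
        zr = {
            "shape": z.shape,
            "center": float(z.center),
            "width": float(z.width),
            "amplitude": float(z.amplitude),
        }
        if z.shape == "rounded_box":
            zr["edge_scale"] = float(z.edge_scale)
        if z.t_on > 0.0:
            zr["t_on"] = float(z.t_on)
        if math.isfinite(z.t_off):
            zr["t_off"] = float(z.t_off)
        zones.append(zr)
    doc: dict = {
        "initiation": {"background": float(scenario.initiation.background), "zones": zones},
        "velocity": {
            "v_plus": float(scenario.velocity.v_plus),
            "v_minus": float(scenario.velocity.v_minus),
        },
        "boundary": {"mode": scenario.boundary.mode},
    }
    if scenario.velocity.segments:
        doc["velocity"]["segments"] = [list(s) for s in scenario.velocity.segments]
    if scenario.boundary.mode == "injection":
        doc["boundary"].update(
            I_left=float(scenario.boundary.I_left),
            I_right=float(scenario.boundary.I_right),
            v_out=float(scenario.boundary.v_out),
        )
    if scenario.defects is not None:
        doc["defects"] = {
            "spacing": float(scenario.defects.spacing),
            "repair_time": ("inf" if math.isinf(scenario.defects.repair_time) else float(scenario.defects.repair_time)),
        }
    return yaml.safe_dump(doc, sort_keys=True, default_flow_style=False)


# ---------------------------------------------------------------------------
# packaged test system

def two_zone_scenario(
    early_amplitude: float = 1.0e-5,
    late_ratio: float = 10.0,
    sigma: float = 25.0,
    t_on_late: float = 5000.0,
    v: float = 0.04,
) -> Scenario:
    """The packaged two-zone test system on a 1000 kb periodic genome.

    An "early" Gaussian initiation zone centered at 200 kb is active at all
    times; a "late" zone at 800 kb, ten times more efficient at its peak,
    switches on at 5000 sec.  Fork velocity is a constant 0.04 kb/sec.  The
    early-zone peak amplitude (1e-5 initiations/kb/sec) and the Gaussian sigma
    (25 kb, i.e. a zone of roughly 50 kb extent) are package defaults.
    """
    return Scenario(
        initiation=InitiationProfile(
            zones=(
                Zone(center=200.0, width=sigma, amplitude=early_amplitude),
                Zone(center=800.0, width=sigma, amplitude=early_amplitude * late_ratio, t_on=t_on_late),
            )
        ),
        velocity=VelocityProfile(v_plus=v),
        boundary=BoundaryCondition(mode="periodic"),
    )


def two_zone_config_path() -> str:
    """Path to the packaged two-zone scenario YAML fixture."""
    from importlib.resources import files

    return str(files("repkin").joinpath("data/two_zone.yaml"))


def two_zone_grid(dx: float = 0.5, dt: float = 10.0, t_max: float = 20000.0) -> Grid:
    """Default solver grid for :func:`two_zone_scenario` (CFL-safe at v=0.04)."""
    return Grid(length=1000.0, dx=dx, dt=dt, t_max=t_max)
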