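"""Mean-field rate equations for inhomogeneous DNA replication.

Solves the coupled system for the replication fraction ``f(x,t)`` and the
right-/left-moving fork densities ``rho±(x,t)``::

    df/dt              = v+ rho+ + v- rho-
    drho±/dt ± d(v± rho±)/dx = I(x,t)(1-f) - (v+ + v-) rho+ rho- / (1-f)

New forks are created at the initiation rate ``I`` rescaled by the probability
``1-f`` that the position is not already replicated; converging fork
populations annihilate in proportion to both local densities and their
relative speed.  With a defect model the moving-fork equations gain stall,
repair and stalled-collision terms, and two stationary stalled-density fields
are integrated alongside (see :func:`solve`).

The scheme is explicit first-order: direction-aware upwind fluxes for the
advection term and forward-Euler source/sink updates, under the CFL condition
``max(v) * dt <= dx``.  The advection flux telescopes exactly under periodic
boundaries, so the discrete initiation and coalescence budgets balance to
round-off once replication completes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .scenario import BoundaryCondition, Grid, Scenario, ScenarioError

__all__ = [
    "FieldSolution",
    "EventDensities",
    "SolverError",
    "solve",
    "solve_with_stalls",
    "event_densities",
    "boundary_fork_density",
]

_EPS_F = 1e-12  # clamp on the (1-f) denominator


class SolverError(RuntimeError):
    """Configuration or numerical-stability failure of the field solver."""


def boundary_fork_density(I_out: float, v_out: float, t) -> np.ndarray:
    """Fork density arriving from a semi-infinite homogeneous flank.

    For constant outside initiation rate ``I_out`` and fork speed ``v_out``,
    the density of (inward-moving) forks at the boundary of the modeled region
    is the homogeneous-theory per-direction fork density::

        rho_b(t) = I_out * t * exp(-I_out * v_out * t**2)

    It peaks at ``t* = 1/sqrt(2 I_out v_out)`` and decays as the flank itself
    finishes replicating.
    """
    if I_out < 0:
        raise ScenarioError("I_out must be >= 0")
    if v_out <= 0:
        raise ScenarioError("v_out must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ScenarioError("t must be >= 0")
    return I_out * t * np.exp(-I_out * v_out * t * t)


@dataclass
class FieldSolution:
    """Fields on the space-time lattice.

    Arrays are shaped ``(nt+1, nx)`` with rows indexed by ``t`` (the stored
    horizon may be shorter than ``grid.t_max`` if replication completed early).
    ``f_plus``/``f_minus`` are the directional replication fractions
    ``f± = ∫ v± rho± dt``; they sum to ``f`` up to the clamp at 1.
    """

    grid: Grid
    scenario: Scenario
    t: np.ndarray
    f: np.ndarray
    rho_plus: np.ndarray
    rho_minus: np.ndarray
    f_plus: np.ndarray
    f_minus: np.ndarray
    rho_stall_plus: Optional[np.ndarray] = None
    rho_stall_minus: Optional[np.ndarray] = None
    residual_unreplicated: float = 0.0
    N_init: float = 0.0  # expected initiations per cycle (exact discrete quadrature)
    N_coal: float = 0.0  # expected coalescences per cycle

    @property
    def x(self) -> np.ndarray:
        return self.grid.x

    @property
    def has_stalls(self) -> bool:
        return self.rho_stall_plus is not None

    def source_term(self) -> np.ndarray:
        """Initiation source ``I(x,t)(1-f)`` on the lattice (1/kb/sec)."""
        I_xt = _initiation_table(self.scenario, self.grid, self.t)
        return I_xt * (1.0 - self.f)

    def sink_term(self) -> np.ndarray:
        """Coalescence sink, including moving-stalled collisions (1/kb/sec).

        Recomputed from the stored rows with the integrator's availability
        limiter; the exact per-cycle coalescence budget is carried separately
        in ``N_coal``.
        """
        vp = self.scenario.velocity.evaluate(self.x, 0.0, "+")
        vm = self.scenario.velocity.evaluate(self.x, 0.0, "-")
        coal, hit_p, hit_m = _limited_sinks(
            self.f, self.rho_plus, self.rho_minus,
            self.rho_stall_plus, self.rho_stall_minus, vp, vm, self.grid.dt,
        )
        sink = coal
        if self.has_stalls:
            sink = sink + hit_p + hit_m
        return sink


@dataclass
class EventDensities:
    """Normalized space-time event densities and expected per-cycle counts."""

    grid: Grid
    t: np.ndarray
    D_init: np.ndarray
    D_coal: np.ndarray
    N_init: float
    N_coal: float


def _limited_sinks(f, rp, rm, sp, sm, vp, vm, dt):
    """Coalescence/collision sink terms with a fork-availability limiter.

    The raw sinks divide by ``1-f`` and diverge as replication completes; a
    forward-Euler step must not annihilate more forks than a cell holds, so
    all pairwise sinks in a cell are scaled by a common factor keeping every
    removal within its population.  The limiter only engages in essentially
    finished cells, where it suppresses round-off blowup.
    """
    one_mf = np.maximum(1.0 - f, _EPS_F)
    coal = (vp + vm) * rp * rm / one_mf
    if sp is not None:
        hit_p = vp * rp * sm / one_mf  # moving + annihilates a stalled -
        hit_m = vm * rm * sp / one_mf
    else:
        hit_p = hit_m = np.zeros_like(coal)
    tiny = 1e-300
    lam = np.minimum(1.0, rp / (dt * (coal + hit_p) + tiny))
    lam = np.minimum(lam, rm / (dt * (coal + hit_m) + tiny))
    if sp is not None:
        lam = np.minimum(lam, np.where(hit_m > 0, sp / (dt * hit_m + tiny), 1.0))
        lam = np.minimum(lam, np.where(hit_p > 0, sm / (dt * hit_p + tiny), 1.0))
    return coal * lam, hit_p * lam, hit_m * lam


def _initiation_components(scenario: Scenario, x: np.ndarray):
    """Split I(x,t) into a static spatial row plus gated zone rows."""
    prof = scenario.initiation
    static = np.full(len(x), prof.background, dtype=float)
    gated = []
    for z in prof.zones:
        row = z.spatial(x)
        if z.t_on > 0.0 or math.isfinite(z.t_off):
            gated.append((z.t_on, z.t_off, row))
        else:
            static = static + row
    return static, gated


def _initiation_table(scenario: Scenario, grid: Grid, t: np.ndarray) -> np.ndarray:
    """I(x,t) on the lattice, evaluated at step start times."""
    x = grid.x
    static, gated = _initiation_components(scenario, x)
    table = np.empty((len(t), grid.nx))
    table[:] = static
    for t_on, t_off, row in gated:
        active = (t >= t_on) & (t < t_off)
        table[active] += row
    return table


def solve(
    scenario: Scenario,
    grid: Grid,
    stop_when_complete: bool = True,
    complete_threshold: float = 0.999,
    store_stride: int = 1,
) -> FieldSolution:
    """Integrate the rate equations from ``f = 0``, ``rho± = 0``.

    Each step first advects the moving-fork densities (conservative upwind;
    exact translation when ``v*dt = dx``) and then applies the initiation
    source and the coalescence/stall sinks to the advected fields.  Splitting
    this way keeps the discrete initiation and coalescence budgets exactly
    balanced under periodic boundaries (up to residual fork mass), since the
    advection flux telescopes and the limited sink can never overdraw a cell.

    If the scenario carries a :class:`~repkin.scenario.DefectModel`, stalled
    fork densities are integrated as well (see :func:`solve_with_stalls`).

    When ``stop_when_complete`` is true, integration stops once the Poisson
    whole-domain ending probability exceeds ``complete_threshold``; otherwise
    it runs to ``grid.t_max``.  If the horizon is exhausted first, the
    residual unreplicated mass is recorded and a warning emitted.

    ``store_stride`` keeps every k-th time row (plus the final row) in the
    returned solution; the integration itself always uses ``grid.dt``.
    """
    vel = scenario.velocity
    if vel.v_max * grid.dt > grid.dx * (1.0 + 1e-12):
        raise SolverError(
            f"CFL violation: max(v)*dt = {vel.v_max * grid.dt:.4g} kb exceeds dx = {grid.dx} kb"
        )
    if store_stride < 1:
        raise SolverError("store_stride must be >= 1")
    nx, nt, dx, dt = grid.nx, grid.nt, grid.dx, grid.dt
    x = grid.x
    t_lattice = grid.t
    bnd = scenario.boundary
    periodic = bnd.mode == "periodic"
    stalls = scenario.defects is not None
    d_spacing = scenario.defects.spacing if stalls else math.inf
    tau = scenario.defects.repair_time if stalls else math.inf

    vp = vel.evaluate(x, 0.0, "+")
    vm = vel.evaluate(x, 0.0, "-")
    I_static, I_gated = _initiation_components(scenario, x)

    # state vectors
    fn = np.zeros(nx)
    rpn = np.zeros(nx)
    rmn = np.zeros(nx)
    fpn = np.zeros(nx)
    fmn = np.zeros(nx)
    spn = np.zeros(nx) if stalls else None
    smn = np.zeros(nx) if stalls else None

    rows_t: list = [0.0]
    rows: list = [[fn.copy(), rpn.copy(), rmn.copy(), fpn.copy(), fmn.copy(),
                   spn.copy() if stalls else None, smn.copy() if stalls else None]]
    N_init_acc = 0.0
    N_coal_acc = 0.0
    stopped_early = False

    for n in range(nt):
        tn = t_lattice[n]

        # --- advection step (conservative upwind)
        flux_p = vp * rpn
        flux_m = vm * rmn
        if periodic:
            rp_a = rpn - (dt / dx) * (flux_p - np.roll(flux_p, 1))
            rm_a = rmn - (dt / dx) * (flux_m - np.roll(flux_m, -1))
        else:
            # Inflow ghost fluxes; outward-moving forks exit freely.  The
            # boundary fork density is the semi-infinite-flank edge density
            # I_out * t thinned by the probability that the boundary point is
            # still unreplicated; evaluating that factor with the *local* f
            # (rather than the flank-only closed form of
            # boundary_fork_density) keeps the inflow exact when the interior
            # replication program differs from the flank's.
            ghost_left = 0.0
            ghost_right = 0.0
            if bnd.mode == "injection":
                ghost_left = bnd.v_out * bnd.I_left * tn * max(1.0 - fn[0], 0.0)
                ghost_right = bnd.v_out * bnd.I_right * tn * max(1.0 - fn[-1], 0.0)
            rp_a = rpn.copy()
            rp_a[1:] -= (dt / dx) * (flux_p[1:] - flux_p[:-1])
            rp_a[0] -= (dt / dx) * (flux_p[0] - ghost_left)
            rm_a = rmn.copy()
            rm_a[:-1] -= (dt / dx) * (flux_m[:-1] - flux_m[1:])
            rm_a[-1] -= (dt / dx) * (flux_m[-1] - ghost_right)

        # --- reaction step on advected fields
        I_row = I_static
        for t_on, t_off, row in I_gated:
            if t_on <= tn < t_off:
                I_row = I_row + row
        source = I_row * (1.0 - fn)
        coal, hit_p, hit_m = _limited_sinks(fn, rp_a, rm_a, spn, smn, vp, vm, dt)
        N_init_acc += float(source.sum())
        N_coal_acc += float((coal + hit_p + hit_m).sum())

        drp = source - coal
        drm = source - coal
        if stalls:
            stall_p = vp * rp_a / d_spacing
            stall_m = vm * rm_a / d_spacing
            # exponential-decay repair flux: exact for pure decay, stable for tau << dt
            if math.isfinite(tau):
                k_rep = -math.expm1(-dt / tau) / dt
                repair_p = spn * k_rep
                repair_m = smn * k_rep
            else:
                repair_p = repair_m = 0.0
            drp += -stall_p + repair_p - hit_p
            drm += -stall_m + repair_m - hit_m
            spn = np.maximum(spn + dt * (stall_p - repair_p - hit_m), 0.0)
            smn = np.maximum(smn + dt * (stall_m - repair_m - hit_p), 0.0)
        rp_next = np.maximum(rp_a + dt * drp, 0.0)
        rm_next = np.maximum(rm_a + dt * drm, 0.0)

        df_p = dt * vp * rp_a
        df_m = dt * vm * rm_a
        fpn = fpn + df_p
        fmn = fmn + df_m
        f_new = fn + df_p + df_m
        if np.any(f_new > 1.0 + 1e-2):  # small Euler overshoot is clamped; larger means instability
            i_bad = int(np.argmax(f_new))
            raise SolverError(
                f"numerical instability: f = {f_new[i_bad]:.6f} > 1 at x = {x[i_bad]:.3f} kb, "
                f"t = {t_lattice[n + 1]:.1f} s"
            )
        fn = np.minimum(f_new, 1.0)
        rpn, rmn = rp_next, rm_next

        store_now = ((n + 1) % store_stride == 0) or (n + 1 == nt)

        if stop_when_complete and (n % 16 == 0 or store_now):
            q = np.where(fn > _EPS_F, rpn / np.maximum(fn, _EPS_F), 0.0)
            if stalls:
                q = q + np.where(fn > _EPS_F, spn / np.maximum(fn, _EPS_F), 0.0)
            p_end = math.exp(-float(np.sum(q) * dx)) if np.any(fn > _EPS_F) else 0.0
            if p_end > complete_threshold:
                stopped_early = True
                store_now = True

        if store_now:
            rows_t.append(t_lattice[n + 1])
            rows.append([fn.copy(), rpn.copy(), rmn.copy(), fpn.copy(), fmn.copy(),
                         spn.copy() if stalls else None, smn.copy() if stalls else None])
        if stopped_early:
            break

    stack = lambda i: np.stack([r[i] for r in rows])
    sol = FieldSolution(
        grid=grid,
        scenario=scenario,
        t=np.array(rows_t),
        f=stack(0),
        rho_plus=stack(1),
        rho_minus=stack(2),
        f_plus=stack(3),
        f_minus=stack(4),
        rho_stall_plus=stack(5) if stalls else None,
        rho_stall_minus=stack(6) if stalls else None,
        N_init=N_init_acc * dx * dt,
        N_coal=N_coal_acc * dx * dt,
    )
    sol.residual_unreplicated = float(np.max(1.0 - sol.f[-1]))
    if not stopped_early and sol.residual_unreplicated > 1.0 - complete_threshold:
        warnings.warn(
            f"integration horizon t_max = {grid.t_max} s reached with residual "
            f"unreplicated mass {sol.residual_unreplicated:.3g}; quantities that "
            "integrate over the full S phase may be biased",
            stacklevel=2,
        )
    return sol


def solve_with_stalls(scenario: Scenario, grid: Grid, **kwargs) -> FieldSolution:
    """Integrate the rate equations including fork stalling at defects.

    Moving forks stall at rate ``v± rho± / d`` (mean defect spacing ``d``),
    stalled forks are repaired at rate ``1/tau`` (dropped for ``tau = inf``)
    and are annihilated by opposing moving forks; stalled densities do not
    advect.  Requires ``scenario.defects``.
    """
    if scenario.defects is None:
        raise SolverError("scenario has no DefectModel; use solve()")
    return solve(scenario, grid, **kwargs)


def event_densities(sol: FieldSolution, residual_tolerance: float = 1e-2) -> EventDensities:
    """Initiation/coalescence space-time densities and expected counts.

    ``D_init ∝ I(1-f)`` and ``D_coal ∝ (v+ + v-) rho+ rho- / (1-f)`` (plus the
    moving-stalled collision terms when a defect model is present), each
    normalized to unit space-time integral over the stored rows.  ``N_init``
    and ``N_coal`` are the expected numbers of initiations and coalescences
    per replication cycle, accumulated exactly during the integration (so
    under periodic boundaries they agree to the residual fork mass).
    """
    grid = sol.grid
    S = sol.source_term()
    C = sol.sink_term()
    if sol.residual_unreplicated > residual_tolerance:
        warnings.warn(
            f"event densities computed on an incomplete S phase (residual "
            f"unreplicated mass {sol.residual_unreplicated:.3g})",
            stacklevel=2,
        )
    # normalize the stored-row tables by their own trapezoid quadrature
    from scipy.integrate import trapezoid

    Zi = float(trapezoid(S.sum(axis=1) * grid.dx, sol.t))
    Zc = float(trapezoid(C.sum(axis=1) * grid.dx, sol.t))
    D_init = S / Zi if Zi > 0 else S
    D_coal = C / Zc if Zc > 0 else C
    return EventDensities(grid=grid, t=sol.t, D_init=D_init, D_coal=D_coal,
                          N_init=sol.N_init, N_coal=sol.N_coal)
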