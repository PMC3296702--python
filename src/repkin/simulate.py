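"""Stochastic simulation of single replication cycles and ensembles.

The Monte Carlo simulator is the ground-truth counterpart of the mean-field
solver: it realizes individual replication cycles (stochastic initiations,
deterministic fork motion, coalescences, optional stalling at randomly placed
defects) and aggregates them into ensemble statistics that converge to the
rate-equation fields as the number of cycles grows.

Fork-injection boundaries are realized *exactly* here by simulating explicit
homogeneous flanking DNA of length ``v_out * t_max`` on both sides of the
fragment, so that forks entering the fragment "were previously initiated
elsewhere"; agreement with the solver's closed-form boundary density is
itself a test of that closed form.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _mc
from .scenario import Grid, Scenario, ScenarioError

__all__ = ["EventLog", "EnsembleStats", "ForkPath", "simulate_cycle", "run_ensemble", "empirical_timing"]

DEFAULT_MC_DX = 0.1  # kb; the simulation lattice is finer than the analysis one


@dataclass
class ForkPath:
    """Piecewise-linear space-time path of a single fork."""

    fork_id: int
    direction: int  # +1 right-moving, -1 left-moving
    vertices: np.ndarray  # (n, 2) columns (t, x); stall intervals repeat x
    fate: str  # 'coalescence', 'exit', or 'alive'


@dataclass
class EventLog:
    """Full record of one simulated replication cycle.

    Positions are in kb relative to the analysis domain origin ``grid.x0``;
    the lattice covers the analysis region only (flank events under injection
    boundaries are excluded, but forks entering from the flanks are visible in
    the site-level record and trajectories).
    """

    grid: Grid
    scenario: Scenario
    seed: int
    mc_dx: float
    x: np.ndarray                    # site centers, kb
    rep_time: np.ndarray             # per-site replication time, inf if never
    rep_dir: np.ndarray              # +1 / -1 fork direction, 0 = origin site
    initiations: np.ndarray          # (n, 2) columns (x, t)
    coalescences: np.ndarray
    boundary_exits: np.ndarray
    fork_trajectories: List[ForkPath] = field(default_factory=list)

    @property
    def t_first_init(self) -> float:
        return float(self.initiations[:, 1].min()) if len(self.initiations) else math.inf

    @property
    def t_last_coal(self) -> float:
        return float(self.coalescences[:, 1].max()) if len(self.coalescences) else math.inf

    @property
    def t_first_rep(self) -> float:
        """Time the first site of the analysis region replicates."""
        return float(self.rep_time.min())

    @property
    def t_complete(self) -> float:
        """Time the analysis region finishes replicating (inf if it never did)."""
        m = self.rep_time.max()
        return float(m) if m < _mc.INF else math.inf


@dataclass
class EnsembleStats:
    """Binned ensemble averages over many simulated cycles."""

    n_cycles: int
    t_out: np.ndarray                # sample times, sec
    x_edges: np.ndarray              # spatial bin edges, kb
    mean_f: np.ndarray               # (n_tout, n_xbin)
    se_f: np.ndarray
    mean_rho_plus: np.ndarray        # moving forks only, forks/kb
    se_rho_plus: np.ndarray
    mean_rho_minus: np.ndarray
    se_rho_minus: np.ndarray
    mean_rho_stall_plus: Optional[np.ndarray]
    mean_rho_stall_minus: Optional[np.ndarray]
    initiations: np.ndarray          # (n, 3) columns (cycle, x, t)
    coalescences: np.ndarray
    N_init_per_cycle: np.ndarray
    t_first_init: np.ndarray         # per cycle, inf if no event
    t_last_coal: np.ndarray
    t_complete: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])


# ---------------------------------------------------------------------------

def _lattice_for(scenario: Scenario, grid: Grid, mc_dx: float, flank_time: Optional[float] = None):
    """Build the simulation lattice, extending with explicit flanks for injection.

    ``flank_time`` bounds how long inflow must stay exact (default: the full
    horizon); flank length is the distance a fork can travel in that time.
    """
    n_core = int(round(grid.length / mc_dx))
    if abs(n_core * mc_dx - grid.length) > 1e-6:
        raise ScenarioError(f"mc_dx = {mc_dx} does not evenly divide the domain length {grid.length}")
    bnd = scenario.boundary
    if bnd.mode == "injection":
        flank = math.ceil(bnd.v_out * (flank_time if flank_time is not None else grid.t_max) / mc_dx)
    else:
        flank = 0
    n_sites = n_core + 2 * flank
    # site centers in *local* coordinates [0, n_sites*mc_dx)
    x_local = (np.arange(n_sites) + 0.5) * mc_dx
    offset = grid.x0 - flank * mc_dx  # absolute = local + offset
    return n_sites, n_core, flank, x_local, offset


def _rate_components(scenario: Scenario, grid: Grid, mc_dx: float, n_sites, flank, x_local, offset):
    """Per-component spatial rate tables (component 0 = ungated)."""
    x_abs = x_local + offset
    core = slice(flank, n_sites - flank) if flank else slice(0, n_sites)
    prof = scenario.initiation
    base = np.zeros(n_sites)
    base[core] = prof.background
    if flank:
        base[:flank] = scenario.boundary.I_left
        base[n_sites - flank:] = scenario.boundary.I_right
    comps = [base]
    gates = [(0.0, _mc.INF)]
    for z in prof.zones:
        s = np.zeros(n_sites)
        s[core] = z.spatial(x_abs[core])
        if z.t_on > 0.0 or math.isfinite(z.t_off):
            comps.append(s)
            gates.append((z.t_on, z.t_off if math.isfinite(z.t_off) else _mc.INF))
        else:
            comps[0] = comps[0] + s
    cum = np.zeros((len(comps), n_sites + 1))
    for c, s in enumerate(comps):
        cum[c, 1:] = np.cumsum(s) * mc_dx
    gate_on = np.array([g[0] for g in gates])
    gate_off = np.array([g[1] for g in gates])
    return cum, gate_on, gate_off


def _velocity_tables(scenario: Scenario, n_sites, flank, x_local, offset):
    x_abs = x_local + offset
    vp = scenario.velocity.evaluate(x_abs, 0.0, "+")
    vm = scenario.velocity.evaluate(x_abs, 0.0, "-")
    if flank:
        vp[:flank] = scenario.boundary.v_out
        vp[n_sites - flank:] = scenario.boundary.v_out
        vm[:flank] = scenario.boundary.v_out
        vm[n_sites - flank:] = scenario.boundary.v_out
    return vp, vm


def _check_resolution(cum, mc_dx, dt_mc):
    # max per-site event probability; thinning needs I*dx*dt small
    site_rates = np.diff(cum, axis=1) / mc_dx
    p = site_rates.sum(axis=0).max() * mc_dx * dt_mc
    if p > 0.1:
        raise ScenarioError(
            f"MC resolution too coarse: max I*dx*dt = {p:.3g} > 0.1; reduce mc_dx or the rates"
        )


def _prepare_context(scenario: Scenario, grid: Grid, mc_dx: float, flank_time: Optional[float] = None):
    """Precompute the lattice tables shared by every cycle of a scenario."""
    n_sites, n_core, flank, x_local, offset = _lattice_for(scenario, grid, mc_dx, flank_time)
    cum, gate_on, gate_off = _rate_components(scenario, grid, mc_dx, n_sites, flank, x_local, offset)
    vp, vm = _velocity_tables(scenario, n_sites, flank, x_local, offset)
    dt_mc = mc_dx / max(vp.max(), vm.max())
    _check_resolution(cum, mc_dx, dt_mc)
    d_spacing = scenario.defects.spacing if scenario.defects else math.inf
    tau = scenario.defects.repair_time if scenario.defects else math.inf
    return {
        "n_sites": n_sites, "n_core": n_core, "flank": flank, "offset": offset,
        "cum": cum, "gate_on": gate_on, "gate_off": gate_off, "vp": vp, "vm": vm,
        "dt_mc": dt_mc,
        "d_spacing": _mc.INF if math.isinf(d_spacing) else d_spacing,
        "tau": _mc.INF if math.isinf(tau) else tau,
        "periodic": scenario.boundary.mode == "periodic",
    }


def _cycle_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-cycle substreams from one master seed."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint64) % np.uint64(2**31 - 1)).astype(np.int64) + 1


def _run_raw(
    scenario: Scenario,
    grid: Grid,
    cycle_seed: int,
    mc_dx: float,
    out_times: np.ndarray,
    record_traj: bool,
    forced: Optional[Sequence[Tuple[float, float]]] = None,
    flank_time: Optional[float] = None,
):
    n_sites, n_core, flank, x_local, offset = _lattice_for(scenario, grid, mc_dx, flank_time)
    cum, gate_on, gate_off = _rate_components(scenario, grid, mc_dx, n_sites, flank, x_local, offset)
    vp, vm = _velocity_tables(scenario, n_sites, flank, x_local, offset)
    dt_mc = mc_dx / max(vp.max(), vm.max())
    _check_resolution(cum, mc_dx, dt_mc)
    d_spacing = scenario.defects.spacing if scenario.defects else math.inf
    d_spacing = _mc.INF if math.isinf(d_spacing) else d_spacing
    tau = scenario.defects.repair_time if scenario.defects else math.inf
    tau = _mc.INF if math.isinf(tau) else tau
    if forced:
        forced = sorted(forced, key=lambda p: p[1])
        forced_x = np.array([p[0] - offset for p in forced])
        forced_t = np.array([p[1] for p in forced])
    else:
        forced_x = np.zeros(0)
        forced_t = np.zeros(0)
    periodic = scenario.boundary.mode == "periodic"
    out = _mc.run_cycle(
        int(cycle_seed) % (2**31 - 1),
        n_sites,
        mc_dx,
        periodic,
        cum,
        gate_on,
        gate_off,
        vp,
        vm,
        dt_mc,
        float(grid.t_max),
        d_spacing,
        tau,
        forced_x,
        forced_t,
        np.asarray(out_times, dtype=float),
        record_traj,
    )
    (rep_time, rep_dir, init_xt, coal_xt, exit_xt, exit_side, snap, traj, fork_dir, t_end, overflow) = out
    if overflow:
        raise RuntimeError("MC gap table overflow; scenario initiates far more domains than expected")
    return {
        "n_sites": n_sites,
        "n_core": n_core,
        "flank": flank,
        "offset": offset,
        "x_local": x_local,
        "rep_time": rep_time,
        "rep_dir": rep_dir,
        "init_xt": init_xt,
        "coal_xt": coal_xt,
        "exit_xt": exit_xt,
        "exit_side": exit_side,
        "snap": snap,
        "traj": traj,
        "fork_dir": fork_dir,
        "t_end": t_end,
    }


def _build_paths(raw, v_lookup) -> List[ForkPath]:
    paths: dict[int, list] = {}
    fates: dict[int, str] = {}
    for row in raw["traj"]:
        fid, code, x, t = int(row[0]), int(row[1]), row[2] + raw["offset"], row[3]
        paths.setdefault(fid, []).append((t, x, code))
    out = []
    for fid, rows in sorted(paths.items()):
        rows.sort(key=lambda r: r[0])
        verts = np.array([(t, x) for t, x, _ in rows])
        fate = "alive"
        for t, x, code in rows:
            if code == _mc.TRAJ_COAL:
                fate = "coalescence"
            elif code == _mc.TRAJ_EXIT:
                fate = "exit"
        out.append(ForkPath(fork_id=fid, direction=int(raw["fork_dir"][fid]), vertices=verts, fate=fate))
    return out


def simulate_cycle(
    scenario: Scenario,
    grid: Grid,
    seed: int,
    mc_dx: float = DEFAULT_MC_DX,
    record_trajectories: bool = True,
    forced_initiations: Optional[Sequence[Tuple[float, float]]] = None,
) -> EventLog:
    """Simulate one replication cycle and return its full event log.

    ``forced_initiations`` is a list of ``(x, t)`` events injected
    deterministically (useful for constructing reference geometries); a forced
    event landing on already replicated DNA is dropped.
    """
    raw = _run_raw(scenario, grid, int(seed), mc_dx, np.zeros(0), record_trajectories, forced_initiations)
    flank, n_core, offset = raw["flank"], raw["n_core"], raw["offset"]
    core = slice(flank, flank + n_core)
    x_core = raw["x_local"][core] + offset
    rep_time = raw["rep_time"][core].copy()
    rep_dir = raw["rep_dir"][core].copy()

    def _shift(ev):
        if len(ev) == 0:
            return ev.reshape(0, 2)
        ev = ev.copy()
        ev[:, 0] += offset
        return ev

    init_xt = _shift(raw["init_xt"])
    coal_xt = _shift(raw["coal_xt"])
    exit_xt = _shift(raw["exit_xt"])
    if flank:  # keep only events inside the analysis region
        x_lo, x_hi = grid.x0, grid.x0 + grid.length
        init_xt = init_xt[(init_xt[:, 0] >= x_lo) & (init_xt[:, 0] <= x_hi)]
        coal_xt = coal_xt[(coal_xt[:, 0] >= x_lo) & (coal_xt[:, 0] <= x_hi)]
        exit_xt = exit_xt[(exit_xt[:, 0] >= x_lo) & (exit_xt[:, 0] <= x_hi)]
    paths = _build_paths(raw, scenario.velocity) if record_trajectories else []
    return EventLog(
        grid=grid,
        scenario=scenario,
        seed=int(seed),
        mc_dx=mc_dx,
        x=x_core,
        rep_time=rep_time,
        rep_dir=rep_dir,
        initiations=init_xt,
        coalescences=coal_xt,
        boundary_exits=exit_xt,
        fork_trajectories=paths,
    )


def run_ensemble(
    scenario: Scenario,
    grid: Grid,
    n_cycles: int,
    seed: int,
    mc_dx: float = DEFAULT_MC_DX,
    t_out: Optional[np.ndarray] = None,
    x_bin: float = 10.0,
) -> EnsembleStats:
    """Simulate ``n_cycles`` independent cycles and aggregate binned statistics.

    ``t_out`` are the sample times for the field snapshots (default: 81 evenly
    spaced times over ``[0, t_max]``); ``x_bin`` is the spatial bin width (kb)
    for the mean fields.  Per-bin standard errors are empirical (across-cycle
    sample standard deviation / sqrt(n)).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if t_out is None:
        t_out = np.linspace(0.0, grid.t_max, 81)
    t_out = np.asarray(t_out, dtype=float)
    n_xb = int(round(grid.length / x_bin))
    if abs(n_xb * x_bin - grid.length) > 1e-6:
        raise ValueError("x_bin must evenly divide the domain length")
    x_edges = grid.x0 + np.arange(n_xb + 1) * x_bin
    per_bin = int(round(x_bin / mc_dx))
    stalls = scenario.defects is not None

    seeds = _cycle_seeds(seed, n_cycles)
    n_t = len(t_out)
    sum_f = np.zeros((n_t, n_xb))
    sq_f = np.zeros((n_t, n_xb))
    sum_rp = np.zeros((n_t, n_xb))
    sq_rp = np.zeros((n_t, n_xb))
    sum_rm = np.zeros((n_t, n_xb))
    sq_rm = np.zeros((n_t, n_xb))
    sum_sp = np.zeros((n_t, n_xb)) if stalls else None
    sum_sm = np.zeros((n_t, n_xb)) if stalls else None
    inits = []
    coals = []
    N_init = np.zeros(n_cycles)
    t_first = np.full(n_cycles, math.inf)
    t_last = np.full(n_cycles, math.inf)
    t_comp = np.full(n_cycles, math.inf)

    for c in range(n_cycles):
        raw = _run_raw(scenario, grid, int(seeds[c]), mc_dx, t_out, False)
        flank, n_core = raw["flank"], raw["n_core"]
        core = slice(flank, flank + n_core)
        rt = raw["rep_time"][core]
        # binned replication indicator per sample time
        ind = (rt[None, :] <= t_out[:, None]).astype(np.float64)
        fb = ind.reshape(n_t, n_xb, per_bin).mean(axis=2)
        sum_f += fb
        sq_f += fb * fb
        # fork snapshots -> binned densities (forks/kb)
        snap = raw["snap"]
        rp_b = np.zeros((n_t, n_xb))
        rm_b = np.zeros((n_t, n_xb))
        if len(snap):
            pos_abs = snap[:, 1] + raw["offset"]
            inside = (pos_abs >= grid.x0) & (pos_abs < grid.x0 + grid.length)
            s = snap[inside]
            pos_abs = pos_abs[inside]
            it = s[:, 0].astype(int)
            ix = np.minimum(((pos_abs - grid.x0) / x_bin).astype(int), n_xb - 1)
            moving = s[:, 3] == 0.0
            plus = s[:, 2] > 0
            np.add.at(rp_b, (it[plus & moving], ix[plus & moving]), 1.0 / x_bin)
            np.add.at(rm_b, (it[~plus & moving], ix[~plus & moving]), 1.0 / x_bin)
            if stalls:
                sp_b = np.zeros((n_t, n_xb))
                sm_b = np.zeros((n_t, n_xb))
                np.add.at(sp_b, (it[plus & ~moving], ix[plus & ~moving]), 1.0 / x_bin)
                np.add.at(sm_b, (it[~plus & ~moving], ix[~plus & ~moving]), 1.0 / x_bin)
                sum_sp += sp_b
                sum_sm += sm_b
        sum_rp += rp_b
        sq_rp += rp_b * rp_b
        sum_rm += rm_b
        sq_rm += rm_b * rm_b

        init_xt = raw["init_xt"]
        coal_xt = raw["coal_xt"]
        if flank:
            off = raw["offset"]
            init_xt = init_xt.copy()
            coal_xt = coal_xt.copy()
            if len(init_xt):
                init_xt[:, 0] += off
                init_xt = init_xt[(init_xt[:, 0] >= grid.x0) & (init_xt[:, 0] <= grid.x0 + grid.length)]
            if len(coal_xt):
                coal_xt[:, 0] += off
                coal_xt = coal_xt[(coal_xt[:, 0] >= grid.x0) & (coal_xt[:, 0] <= grid.x0 + grid.length)]
        else:
            init_xt = init_xt.copy()
            coal_xt = coal_xt.copy()
            if len(init_xt):
                init_xt[:, 0] += raw["offset"]
            if len(coal_xt):
                coal_xt[:, 0] += raw["offset"]
        N_init[c] = len(init_xt)
        if len(init_xt):
            inits.append(np.column_stack([np.full(len(init_xt), c), init_xt]))
            t_first[c] = init_xt[:, 1].min()
        if len(coal_xt):
            coals.append(np.column_stack([np.full(len(coal_xt), c), coal_xt]))
            t_last[c] = coal_xt[:, 1].max()
        if rt.max() < _mc.INF:
            t_comp[c] = rt.max()

    n = float(n_cycles)

    def _mean_se(s, q):
        mean = s / n
        var = np.maximum(q / n - mean * mean, 0.0)
        se = np.sqrt(var / max(n - 1.0, 1.0))
        return mean, se

    mean_f, se_f = _mean_se(sum_f, sq_f)
    mean_rp, se_rp = _mean_se(sum_rp, sq_rp)
    mean_rm, se_rm = _mean_se(sum_rm, sq_rm)
    return EnsembleStats(
        n_cycles=n_cycles,
        t_out=t_out,
        x_edges=x_edges,
        mean_f=mean_f,
        se_f=se_f,
        mean_rho_plus=mean_rp,
        se_rho_plus=se_rp,
        mean_rho_minus=mean_rm,
        se_rho_minus=se_rm,
        mean_rho_stall_plus=(sum_sp / n if stalls else None),
        mean_rho_stall_minus=(sum_sm / n if stalls else None),
        initiations=(np.vstack(inits) if inits else np.zeros((0, 3))),
        coalescences=(np.vstack(coals) if coals else np.zeros((0, 3))),
        N_init_per_cycle=N_init,
        t_first_init=t_first,
        t_last_coal=t_last,
        t_complete=t_comp,
    )


def empirical_timing(times: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of a sample of event times.

    Returns ``(sorted_times, cdf)`` with the exact step structure; cycles with
    no event (``inf`` entries) are excluded with a warning and the CDF is
    normalized by the total sample size (so it saturates below 1 when events
    are missing).
    """
    times = np.asarray(times, dtype=float)
    finite = times[np.isfinite(times)]
    n_missing = len(times) - len(finite)
    if n_missing:
        warnings.warn(f"{n_missing} of {len(times)} cycles had no event; excluded from CDF", stacklevel=2)
    if len(finite) == 0:
        return np.zeros(0), np.zeros(0)
    ts = np.sort(finite)
    cdf = np.arange(1, len(ts) + 1) / len(times)
    return ts, cdf
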