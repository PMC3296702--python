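"""SMARD observables: simulated dual-label molecules and their predictions.

SMARD (single-molecule analysis of replicated DNA) pulse-labels an
asynchronous cell population with a first ("red") and second ("green")
nucleotide label.  On a stretched molecule, DNA replicated before the label
switch is red, DNA replicated after is green, and every red/green transition
marks the position of a replication fork at the switch time, moving from the
red side into the green side.  Only molecules carrying *both* labels — those
whose replication spanned the switch — are analyzed.

This module simulates that protocol on top of :mod:`repkin.simulate`
(`sample_smard`), computes the experiment's summary profiles (red-green
content per 5 kb bin, directional fork densities per 50 kb bin, and the
red-green autocorrelation), and predicts the same profiles directly from the
mean-field solution:

    r̃(x)   = ∫ [f(x,t) − P_e(t)] dt / ∫ [P_s(t) − P_e(t)] dt
    ρ̃±(x) = ∫ ρ±(x,t) dt          / ∫ [P_s(t) − P_e(t)] dt

The ``P_e`` subtraction removes fully replicated molecules from the content
average (they are collected but are uniformly red); no correction is needed
for the fork densities since finished molecules carry no forks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .scenario import Grid, Scenario, ScenarioError
from .simulate import DEFAULT_MC_DX, _cycle_seeds
from .solver import FieldSolution
from .timing import TimingCurves, end_probability, start_probability

__all__ = [
    "Molecule",
    "MoleculeSet",
    "SmardProfiles",
    "label_cycle",
    "sample_smard",
    "profiles",
    "predict_red_green",
    "predict_fork_density",
]


@dataclass
class Molecule:
    """A single fully labeled molecule on the analysis lattice.

    ``label`` holds 1 for red (replicated before the switch) and 0 for green
    per lattice site; ``fork_marks`` are ``(x, direction)`` pairs read off the
    label transitions (direction +1 where red lies left of green).
    ``t_switch`` is known for synthetic molecules and absent for real data.
    """

    id: str
    x0: float
    dx: float
    label: np.ndarray
    t_switch: Optional[float] = None

    @property
    def x(self) -> np.ndarray:
        return self.x0 + (np.arange(len(self.label)) + 0.5) * self.dx

    @property
    def fork_marks(self) -> List[Tuple[float, int]]:
        lab = self.label
        marks = []
        for i in np.nonzero(np.diff(lab.astype(np.int8)) != 0)[0]:
            xb = self.x0 + (i + 1) * self.dx  # boundary between sites i, i+1
            direction = 1 if lab[i] == 1 else -1  # fork moves red -> green
            marks.append((xb, direction))
        return marks

    @property
    def is_two_color(self) -> bool:
        return 0 < int(self.label.sum()) < len(self.label)


@dataclass
class MoleculeSet:
    """A collection of labeled molecules sharing one lattice.

    ``n_red_full`` / ``n_green_full`` count the fully labeled one-color
    molecules that were collected but excluded from two-color analysis (the
    experimental fork-velocity estimator needs them); ``n_attempted`` counts
    simulated cycles.
    """

    molecules: List[Molecule]
    x0: float
    dx: float
    length: float
    periodic: bool = False
    n_red_full: int = 0
    n_green_full: int = 0
    n_attempted: int = 0
    t_window: Optional[float] = None
    seed: Optional[int] = None
    fragment: Optional[Tuple[float, float]] = None

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def n_sites(self) -> int:
        return int(round(self.length / self.dx))

    @property
    def x(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_sites) + 0.5) * self.dx

    def label_matrix(self) -> np.ndarray:
        return np.stack([m.label for m in self.molecules])

    @property
    def acceptance_fraction(self) -> float:
        return len(self.molecules) / self.n_attempted if self.n_attempted else math.nan


@dataclass
class SmardProfiles:
    """Binned SMARD summary profiles."""

    x_content: np.ndarray        # content bin centers (kb)
    r: np.ndarray                # red-green content per bin, in [0, 1]
    se_r: np.ndarray
    x_fork: np.ndarray           # fork bin centers (kb)
    rho_bar_plus: np.ndarray     # forks/kb
    se_rho_plus: np.ndarray
    rho_bar_minus: np.ndarray
    se_rho_minus: np.ndarray
    bin_content: float
    bin_fork: float
    n_molecules: int
    lags: np.ndarray             # autocorrelation lags (kb)
    autocorr: np.ndarray


def label_cycle(log, t_switch: float, mol_id: str = "mol") -> Molecule:
    """Label one simulated cycle: red where replicated before ``t_switch``."""
    if t_switch < 0:
        raise ScenarioError("t_switch must be >= 0")
    label = (log.rep_time < t_switch).astype(np.uint8)
    return Molecule(id=mol_id, x0=log.x[0] - log.mc_dx / 2, dx=log.mc_dx, label=label, t_switch=t_switch)


def sample_smard(
    scenario: Scenario,
    grid: Grid,
    n_keep: int,
    seed: int,
    t_window: Optional[float] = None,
    keep: str = "two_color_only",
    fragment: Optional[Tuple[float, float]] = None,
    mc_dx: float = DEFAULT_MC_DX,
    sol: Optional[FieldSolution] = None,
    max_attempts_factor: int = 1000,
) -> MoleculeSet:
    """Simulate the SMARD collection protocol.

    Replication cycles are simulated one by one; for each, a label-switch time
    is drawn uniformly on ``[0, t_window]`` (the perfectly asynchronous
    population assumption), the molecule — the whole domain, or the
    ``fragment=(x_lo, x_hi)`` restriction fragment cut out of it — is labeled,
    and it is kept according to ``keep``:

    - ``"two_color_only"``: only molecules whose replication spans the switch
      (first replicated position before it, completion after it);
    - ``"all_fully_labeled"``: also fully red and fully green molecules.

    ``t_window`` defaults to the smallest time at which the ending probability
    exceeds 0.999, found from ``sol`` (or a fresh mean-field pre-solve).
    One-color counts are recorded on the returned set either way.
    """
    if n_keep < 1:
        raise ScenarioError("n_keep must be >= 1")
    if keep not in ("two_color_only", "all_fully_labeled"):
        raise ScenarioError("keep must be 'two_color_only' or 'all_fully_labeled'")
    if t_window is None:
        if sol is None:
            from .solver import solve

            sol = solve(scenario, grid, complete_threshold=0.999)
        region = "whole_pbc" if scenario.boundary.mode == "periodic" else "fragment"
        frag_bounds = fragment if (fragment and region == "fragment") else (grid.x0, grid.x0 + grid.length)
        pe = end_probability(sol, region=region, fragment=None if region == "whole_pbc" else frag_bounds)
        above = np.nonzero(pe.P_end > 0.999)[0]
        t_window = float(pe.t[above[0]]) if len(above) else float(grid.t_max)

    if fragment is not None:
        x_lo, x_hi = fragment
        if not (grid.contains(x_lo) and grid.contains(x_hi) and x_hi > x_lo):
            raise ScenarioError("fragment bounds invalid or outside domain")
    periodic = scenario.boundary.mode == "periodic" and fragment is None

    rng_master = np.random.default_rng(seed)
    max_attempts = max_attempts_factor * n_keep
    seeds = _cycle_seeds(seed, max_attempts)
    switch_times = rng_master.uniform(0.0, t_window, size=max_attempts)

    from . import _mc
    from .simulate import _prepare_context

    # flanks only need to feed forks while molecules can still be replicating
    ctx = _prepare_context(scenario, grid, mc_dx, flank_time=1.25 * t_window)
    if fragment is not None:
        i_lo = ctx["flank"] + int(round((x_lo - grid.x0) / mc_dx))
        i_hi = ctx["flank"] + int(round((x_hi - grid.x0) / mc_dx))
        x0_abs = x_lo
    else:
        i_lo = ctx["flank"]
        i_hi = ctx["flank"] + ctx["n_core"]
        x0_abs = grid.x0
    labels, tsw, kept, attempts, n_red, n_green = _mc.run_fragment_batch(
        seeds, switch_times, n_keep, keep == "all_fully_labeled",
        ctx["n_sites"], mc_dx, ctx["periodic"], ctx["cum"], ctx["gate_on"], ctx["gate_off"],
        ctx["vp"], ctx["vm"], ctx["dt_mc"], float(grid.t_max), ctx["d_spacing"], ctx["tau"],
        i_lo, i_hi,
    )
    if kept < n_keep:
        raise RuntimeError(
            f"collected only {kept} of {n_keep} molecules in {attempts} attempts "
            f"(acceptance {kept/max(attempts,1):.2g}; widen max_attempts_factor or "
            "narrow the switch-time window)"
        )
    mols = [
        Molecule(id=f"mol{i:05d}", x0=x0_abs, dx=mc_dx, label=labels[i], t_switch=float(tsw[i]))
        for i in range(kept)
    ]
    length = (x_hi - x_lo) if fragment is not None else grid.length
    return MoleculeSet(
        molecules=mols,
        x0=x0_abs if fragment is not None else grid.x0,
        dx=mc_dx,
        length=length,
        periodic=periodic,
        n_red_full=n_red,
        n_green_full=n_green,
        n_attempted=attempts,
        t_window=t_window,
        seed=int(seed),
        fragment=fragment,
    )


def profiles(
    ms: MoleculeSet,
    bin_content: float = 5.0,
    bin_fork: float = 50.0,
    max_lag: Optional[float] = None,
) -> SmardProfiles:
    """Red-green content, fork densities and content autocorrelation.

    ``r(x)`` is the across-molecule mean label, averaged into ``bin_content``
    bins; fork densities are per-molecule transition counts per ``bin_fork``
    bin divided by the bin width.  The autocorrelation of the centered label
    ``l_i(x) − r(x)`` is the biased estimator averaged over molecules and
    positions, with wraparound for periodic molecule sets (maximum lag L/2).
    Standard errors are across-molecule.
    """
    if len(ms) == 0:
        raise ScenarioError("empty molecule set")
    lab = ms.label_matrix().astype(float)
    n_mol, n_sites = lab.shape

    def _binned(mat, width):
        per = int(round(width / ms.dx))
        if per * ms.dx != width and abs(per * ms.dx - width) > 1e-9:
            raise ScenarioError(f"bin width {width} is not a multiple of the lattice step {ms.dx}")
        nb = n_sites // per
        return mat[:, : nb * per].reshape(n_mol, nb, per), nb, per

    content, nb_c, _ = _binned(lab, bin_content)
    per_mol_r = content.mean(axis=2)
    r = per_mol_r.mean(axis=0)
    se_r = per_mol_r.std(axis=0, ddof=1) / math.sqrt(n_mol) if n_mol > 1 else np.zeros(nb_c)

    # fork transitions per molecule, binned
    per_f = int(round(bin_fork / ms.dx))
    nb_f = n_sites // per_f
    counts_p = np.zeros((n_mol, nb_f))
    counts_m = np.zeros((n_mol, nb_f))
    for i, m in enumerate(ms.molecules):
        for xb, d in m.fork_marks:
            j = int((xb - ms.x0) / bin_fork)
            j = min(max(j, 0), nb_f - 1)
            if d > 0:
                counts_p[i, j] += 1
            else:
                counts_m[i, j] += 1
    rho_p = counts_p / bin_fork
    rho_m = counts_m / bin_fork
    se_p = rho_p.std(axis=0, ddof=1) / math.sqrt(n_mol) if n_mol > 1 else np.zeros(nb_f)
    se_m = rho_m.std(axis=0, ddof=1) / math.sqrt(n_mol) if n_mol > 1 else np.zeros(nb_f)

    # autocorrelation of centered labels on the content-bin lattice
    resid = per_mol_r - r[None, :]
    if max_lag is None:
        max_lag = ms.length / 2 if ms.periodic else ms.length / 2
    n_lag = int(max_lag / bin_content)
    lags = np.arange(n_lag) * bin_content
    ac = np.zeros(n_lag)
    var0 = float(np.mean(resid * resid))
    for k in range(n_lag):
        if ms.periodic:
            shifted = np.roll(resid, -k, axis=1)
            ac[k] = float(np.mean(resid * shifted))
        else:
            if k >= resid.shape[1]:
                break
            ac[k] = float(np.mean(resid[:, : resid.shape[1] - k] * resid[:, k:]))
    if var0 > 0:
        ac = ac / var0

    bc = ms.x0 + (np.arange(nb_c) + 0.5) * bin_content
    bf = ms.x0 + (np.arange(nb_f) + 0.5) * bin_fork
    return SmardProfiles(
        x_content=bc, r=r, se_r=se_r,
        x_fork=bf, rho_bar_plus=rho_p.mean(axis=0), se_rho_plus=se_p,
        rho_bar_minus=rho_m.mean(axis=0), se_rho_minus=se_m,
        bin_content=bin_content, bin_fork=bin_fork, n_molecules=n_mol,
        lags=lags, autocorr=ac,
    )


def _s_phase_weight(curves: TimingCurves) -> float:
    from scipy.integrate import trapezoid

    w = float(trapezoid(curves.P_start - curves.P_end, curves.t))
    if w <= 0:
        raise ScenarioError("degenerate scenario: molecule spends no time replicating")
    return w


def predict_red_green(
    sol: FieldSolution,
    curves: TimingCurves,
    fragment: Optional[Tuple[float, float]] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Mean-field prediction of the red-green content profile.

    Returns ``(x, r̃(x))`` on the solver lattice (restricted to ``fragment``
    if given).  ``curves`` must be the start/end curves of the same region the
    molecules come from.
    """
    from scipy.integrate import trapezoid

    if curves.P_end[-1] < 0.99:
        warnings.warn(
            f"ending probability reaches only {curves.P_end[-1]:.3f} at the end of the "
            "integration horizon; the content prediction may be biased",
            stacklevel=2,
        )
    grid = sol.grid
    if fragment is not None:
        from .timing import _fragment_slice

        sl, _, _ = _fragment_slice(grid, *fragment)
    else:
        sl = slice(0, grid.nx)
    x = grid.x[sl]
    w = _s_phase_weight(curves)
    num = trapezoid(sol.f[:, sl] - curves.P_end[:, None], curves.t, axis=0)
    r = np.clip(num / w, 0.0, 1.0)
    return x, r


def predict_fork_density(
    sol: FieldSolution,
    curves: TimingCurves,
    fragment: Optional[Tuple[float, float]] = None,
    include_stalled: bool = True,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean-field prediction ``(x, ρ̃+(x), ρ̃-(x))`` of the SMARD fork densities."""
    from scipy.integrate import trapezoid

    grid = sol.grid
    if fragment is not None:
        from .timing import _fragment_slice

        sl, _, _ = _fragment_slice(grid, *fragment)
    else:
        sl = slice(0, grid.nx)
    x = grid.x[sl]
    w = _s_phase_weight(curves)
    rp = sol.rho_plus[:, sl]
    rm = sol.rho_minus[:, sl]
    if include_stalled and sol.has_stalls:
        rp = rp + sol.rho_stall_plus[:, sl]
        rm = rm + sol.rho_stall_minus[:, sl]
    rho_p = trapezoid(rp, curves.t, axis=0) / w
    rho_m = trapezoid(rm, curves.t, axis=0) / w
    return x, rho_p, rho_m
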