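"""Replication start- and end-time probabilities.

The start probability is exact within the model: the number of initiations
expected in ``[0, t]`` on a molecule (ignoring suppression by earlier events,
since we ask about the *first* event) is ``N_e(t) = ∫∫ I dx dt'``, and
``P_s(t) = 1 - exp(-N_e(t))``.  For a sub-fragment of a longer molecule the
no-start probability also requires that no fork crossed either boundary, which
is the product ``(1 - f+(x-, t)) (1 - f-(x+, t))`` of directional replication
fractions at the fragment ends.

The end probability is estimated by treating the number of surviving forks as
Poisson: for a periodic molecule ``P̃_e(t) = exp(-∫ q+ dx)`` where ``q+`` is
the right-moving fork density normalized by the probability of being
replicated, ``q+ = rho+ / f`` (an equivalent estimate uses ``rho-``).  For a
fragment, ``P_e(t) = f(x-, t) exp(-∫ q+ dx)`` over the fragment (mirrored for
the left-moving variant).  The Poisson approximation is accurate early and
late in S phase and degrades mid-S where fork numbers are larger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .scenario import Grid, Scenario, ScenarioError
from .solver import FieldSolution, _initiation_table

__all__ = ["TimingCurves", "start_probability", "end_probability", "timing_densities"]

_EPS = 1e-12


@dataclass
class TimingCurves:
    """Start/end probability curves on a common time lattice."""

    t: np.ndarray
    P_start: np.ndarray
    P_end: np.ndarray
    x_minus: Optional[float] = None
    x_plus: Optional[float] = None

    @property
    def dP_start(self) -> np.ndarray:
        return timing_densities(self.t, self.P_start)

    @property
    def dP_end(self) -> np.ndarray:
        return timing_densities(self.t, self.P_end)


def _fragment_slice(grid: Grid, x_minus: float, x_plus: float) -> Tuple[slice, int, int]:
    if x_plus <= x_minus:
        raise ScenarioError("fragment requires x_plus > x_minus")
    if not (grid.contains(x_minus) and grid.contains(x_plus)):
        raise ScenarioError(
            f"fragment [{x_minus}, {x_plus}] outside solved domain "
            f"[{grid.x0}, {grid.x0 + grid.length}]"
        )
    i_lo = int(np.clip(np.floor((x_minus - grid.x0) / grid.dx), 0, grid.nx - 1))
    i_hi = int(np.clip(np.ceil((x_plus - grid.x0) / grid.dx), 1, grid.nx))
    return slice(i_lo, i_hi), i_lo, i_hi


def start_probability(
    sol: FieldSolution,
    region: str = "whole",
    fragment: Optional[Tuple[float, float]] = None,
) -> TimingCurves:
    """Probability that replication of the region has started by time t.

    ``region`` is ``"whole"`` (the full molecule; valid with or without
    periodic boundaries) or ``"fragment"`` with ``fragment=(x_minus, x_plus)``
    bounds in kb, in which case fork inflow across the fragment boundaries is
    accounted for through the directional replication fractions.
    """
    grid, t = sol.grid, sol.t
    I_xt = _initiation_table(sol.scenario, grid, t)
    if region == "whole":
        rate = I_xt.sum(axis=1) * grid.dx  # initiations/sec over the molecule
        N_e = _cumtrapz0(rate, t)
        P_s = 1.0 - np.exp(-N_e)
        P_e = end_probability(sol, region="whole_pbc" if sol.scenario.boundary.mode == "periodic" else "fragment",
                              fragment=(grid.x0, grid.x0 + grid.length)).P_end
        return TimingCurves(t=t, P_start=P_s, P_end=np.minimum(P_e, P_s))
    if region != "fragment":
        raise ScenarioError("region must be 'whole' or 'fragment'")
    if fragment is None:
        raise ScenarioError("fragment bounds required")
    x_minus, x_plus = fragment
    sl, i_lo, i_hi = _fragment_slice(grid, x_minus, x_plus)
    rate = I_xt[:, sl].sum(axis=1) * grid.dx
    N_e = _cumtrapz0(rate, t)
    no_cross = (1.0 - sol.f_plus[:, i_lo]) * (1.0 - sol.f_minus[:, i_hi - 1])
    P_s = 1.0 - np.exp(-N_e) * np.clip(no_cross, 0.0, 1.0)
    P_e = end_probability(sol, region="fragment", fragment=fragment).P_end
    return TimingCurves(t=t, P_start=P_s, P_end=np.minimum(P_e, P_s), x_minus=x_minus, x_plus=x_plus)


def end_probability(
    sol: FieldSolution,
    region: str = "whole_pbc",
    fragment: Optional[Tuple[float, float]] = None,
    side: str = "plus",
    normalized: bool = True,
) -> TimingCurves:
    """Poisson estimate of the probability that replication has ended by t.

    ``region="whole_pbc"`` requires a periodic solution; ``region="fragment"``
    takes ``fragment=(x_minus, x_plus)``.  ``side`` selects the right-moving
    (``"plus"``) or left-moving (``"minus"``) fork-density variant; under
    periodic boundaries the two agree.  ``normalized=False`` uses the raw fork
    density instead of the replication-probability-normalized one (shipped for
    comparison; the normalized form is the default because the raw form does
    not vanish at early times).
    """
    if side not in ("plus", "minus"):
        raise ScenarioError("side must be 'plus' or 'minus'")
    grid, t = sol.grid, sol.t
    rho = sol.rho_plus if side == "plus" else sol.rho_minus
    if sol.has_stalls:
        rho = rho + (sol.rho_stall_plus if side == "plus" else sol.rho_stall_minus)
    if region == "whole_pbc":
        if sol.scenario.boundary.mode != "periodic":
            raise ScenarioError("whole_pbc end probability requires a periodic solution")
        sl = slice(0, grid.nx)
        prefactor = 1.0
        started = sol.f.max(axis=1) > _EPS
    elif region == "fragment":
        if fragment is None:
            raise ScenarioError("fragment bounds required")
        sl, i_lo, i_hi = _fragment_slice(grid, *fragment)
        prefactor = sol.f[:, i_lo] if side == "plus" else sol.f[:, i_hi - 1]
        started = sol.f[:, sl].max(axis=1) > _EPS
    else:
        raise ScenarioError("region must be 'whole_pbc' or 'fragment'")
    if normalized:
        q = np.where(sol.f[:, sl] > _EPS, rho[:, sl] / np.maximum(sol.f[:, sl], _EPS), 0.0)
    else:
        q = rho[:, sl]
    P_e = prefactor * np.exp(-q.sum(axis=1) * grid.dx)
    P_e = np.where(started, P_e, 0.0)
    P_e = np.clip(np.maximum.accumulate(P_e), 0.0, 1.0)  # enforce monotone CDF
    frag = fragment if region == "fragment" else (grid.x0, grid.x0 + grid.length)
    return TimingCurves(t=t, P_start=np.ones_like(P_e), P_end=P_e, x_minus=frag[0], x_plus=frag[1])


def timing_densities(t: np.ndarray, P: np.ndarray, tolerance: float = 1e-9) -> np.ndarray:
    """Differentiate a probability curve to a density (1/sec).

    Central differences with one-sided endpoint stencils; negative round-off
    is clipped at zero.  A curve that decreases by more than ``tolerance``
    anywhere is rejected.
    """
    P = np.asarray(P, dtype=float)
    if np.any(np.diff(P) < -tolerance):
        raise ValueError("probability curve is not non-decreasing")
    dP = np.gradient(P, t)
    return np.clip(dP, 0.0, None)


def _cumtrapz0(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid

    return cumulative_trapezoid(y, t, initial=0.0)
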