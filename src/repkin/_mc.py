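"""Compiled single-cycle replication kernel.

One replication cycle is simulated as a set of shrinking *unreplicated gaps*.
Every gap is eaten from its left by a right-moving fork and from its right by
a left-moving fork (or bounded by a static molecule end).  Initiations split a
gap in two and create a divergent fork pair; a gap that closes produces a
coalescence (fork-fork) or a boundary exit (fork-end).  Positions are
continuous; the lattice only receives per-site replication times/directions.

Initiations are sampled by thinning: per step a Poisson number of candidate
events is drawn from the full-domain rate and candidates landing on already
replicated DNA are rejected, which realizes the inhomogeneous "unreplicated
site fires with probability I(x,t) dx dt" process to first order.
"""

import numpy as np
from numba import njit

INF = 1.0e30

# trajectory event codes
TRAJ_BIRTH = 0
TRAJ_STALL = 1
TRAJ_RESUME = 2
TRAJ_COAL = 3
TRAJ_EXIT = 4

MAX_GAPS = 2048
MAX_EVENTS = 8192
MAX_TRAJ = 65536
MAX_SNAP = 262144


@njit(cache=True)
def _site(pos, dx, n_sites, periodic):
    idx = int(pos / dx)
    if periodic:
        idx = idx % n_sites
        if idx < 0:
            idx += n_sites
    else:
        if idx < 0:
            idx = 0
        elif idx >= n_sites:
            idx = n_sites - 1
    return idx


@njit(cache=True)
def _mark_plus(a, a1, va, t, dx, n_sites, periodic, rep_time, rep_dir):
    # sites whose centers lie in (a, a1], replicated by the right-moving fork
    j = int(np.floor(a / dx - 0.5)) + 1
    while (j + 0.5) * dx <= a1 + 1e-12:
        c = (j + 0.5) * dx
        if c > a:
            idx = j % n_sites if periodic else j
            if 0 <= idx < n_sites and rep_time[idx] >= INF:
                rep_time[idx] = t + (c - a) / va if va > 0 else t
                rep_dir[idx] = 1
        j += 1


@njit(cache=True)
def _mark_minus(b1, b, vb, t, dx, n_sites, periodic, rep_time, rep_dir):
    # sites whose centers lie in [b1, b), replicated by the left-moving fork
    j = int(np.ceil(b / dx - 0.5)) - 1
    while (j + 0.5) * dx >= b1 - 1e-12:
        c = (j + 0.5) * dx
        if c < b:
            idx = j % n_sites if periodic else j
            if 0 <= idx < n_sites and rep_time[idx] >= INF:
                rep_time[idx] = t + (b - c) / vb if vb > 0 else t
                rep_dir[idx] = -1
        j -= 1


@njit(cache=True)
def _first_defect_in(def_pos, def_alive, lo, hi, L, periodic):
    """Index of the first live defect with position in (lo, hi], else -1.

    Positions are lattice coordinates in [0, L); (lo, hi] is an unwrapped
    interval of length << L which may straddle the periodic seam.
    """
    if hi <= lo or len(def_pos) == 0:
        return -1
    if periodic:
        lo_m = lo % L
        hi_m = lo_m + (hi - lo)
        # segment 1: (lo_m, min(hi_m, L)]
        i = np.searchsorted(def_pos, lo_m)
        while i < len(def_pos) and def_pos[i] <= min(hi_m, L) + 1e-12:
            if def_alive[i] and def_pos[i] > lo_m:
                return i
            i += 1
        if hi_m > L:
            i = 0
            while i < len(def_pos) and def_pos[i] <= hi_m - L + 1e-12:
                if def_alive[i]:
                    return i
                i += 1
        return -1
    i = np.searchsorted(def_pos, lo)
    while i < len(def_pos) and def_pos[i] <= hi + 1e-12:
        if def_alive[i] and def_pos[i] > lo:
            return i
        i += 1
    return -1


@njit(cache=True)
def _last_defect_in(def_pos, def_alive, lo, hi, L, periodic):
    """Index of the live defect in [lo, hi) closest to hi, else -1."""
    if hi <= lo or len(def_pos) == 0:
        return -1
    if periodic:
        hi_m = hi % L
        lo_m = hi_m - (hi - lo)
        i = np.searchsorted(def_pos, hi_m) - 1
        while i >= 0 and def_pos[i] >= max(lo_m, 0.0) - 1e-12:
            if def_alive[i] and def_pos[i] < hi_m:
                return i
            i -= 1
        if lo_m < 0.0:
            i = len(def_pos) - 1
            while i >= 0 and def_pos[i] >= lo_m + L - 1e-12:
                if def_alive[i]:
                    return i
                i -= 1
        return -1
    i = np.searchsorted(def_pos, hi) - 1
    while i >= 0 and def_pos[i] >= lo - 1e-12:
        if def_alive[i] and def_pos[i] < hi:
            return i
        i -= 1
    return -1


@njit(cache=True)
def _place_initiation(
    y, t, L, dx, n_sites, periodic, virgin,
    gl, gr, glf, grf, gli, gri, gls, grs, n_gaps,
    rep_time, rep_dir, init_xt, n_init, traj, n_traj, fork_dir, n_forks,
    record_traj,
):
    """Attempt an initiation at position y, time t.

    Returns (virgin, n_gaps, n_init, n_traj, n_forks, overflow).
    """
    overflow = 0
    placed = False
    y_un = y
    if virgin:
        id_p = n_forks
        fork_dir[id_p] = 1
        id_m = n_forks + 1
        fork_dir[id_m] = -1
        n_forks += 2
        gl[0] = y
        gr[0] = y + L
        glf[0] = 1
        grf[0] = 1
        gli[0] = id_p
        gri[0] = id_m
        gls[0] = -1.0
        grs[0] = -1.0
        n_gaps = 1
        virgin = False
        placed = True
    else:
        for k in range(n_gaps):
            a = gl[k]
            b = gr[k]
            if periodic:
                rel = (y - a) % L
                inside = 1e-12 < rel < (b - a) - 1e-12
                y_un = a + rel
            else:
                inside = a + 1e-12 < y < b - 1e-12
                y_un = y
            if inside:
                if n_gaps >= MAX_GAPS:
                    return virgin, n_gaps, n_init, n_traj, n_forks, 1
                id_p = n_forks
                fork_dir[id_p] = 1
                id_m = n_forks + 1
                fork_dir[id_m] = -1
                n_forks += 2
                m = n_gaps
                gl[m] = y_un
                gr[m] = b
                glf[m] = 1
                grf[m] = grf[k]
                gli[m] = id_p
                gri[m] = gri[k]
                gls[m] = -1.0
                grs[m] = grs[k]
                n_gaps += 1
                gr[k] = y_un
                grf[k] = 1
                gri[k] = id_m
                grs[k] = -1.0
                placed = True
                break
    if placed:
        js = _site(y_un, dx, n_sites, periodic)
        if rep_time[js] >= INF:
            rep_time[js] = t
            rep_dir[js] = 0
        x_rec = y_un % L if periodic else y_un
        if n_init < MAX_EVENTS:
            init_xt[n_init, 0] = x_rec
            init_xt[n_init, 1] = t
            n_init += 1
        if record_traj and n_traj + 1 < MAX_TRAJ:
            traj[n_traj, 0] = n_forks - 2
            traj[n_traj, 1] = TRAJ_BIRTH
            traj[n_traj, 2] = x_rec
            traj[n_traj, 3] = t
            traj[n_traj + 1, 0] = n_forks - 1
            traj[n_traj + 1, 1] = TRAJ_BIRTH
            traj[n_traj + 1, 2] = x_rec
            traj[n_traj + 1, 3] = t
            n_traj += 2
    return virgin, n_gaps, n_init, n_traj, n_forks, overflow


@njit(cache=True)
def run_cycle(
    seed,
    n_sites,
    dx,
    periodic,
    cum_rate,      # (n_comp, n_sites+1) cumulative sum of I_c(x)*dx over sites
    gate_on,       # (n_comp,)
    gate_off,      # (n_comp,)
    v_plus,        # (n_sites,)
    v_minus,       # (n_sites,)
    dt,
    t_cap,
    d_spacing,     # mean defect spacing (kb); INF = no defects
    tau,           # mean repair time (INF = never repaired)
    forced_x,      # forced initiation positions (kb)
    forced_t,      # forced initiation times (sorted)
    out_times,     # snapshot times for fork-position sampling (sorted)
    record_traj,
):
    np.random.seed(seed)
    L = n_sites * dx

    # independent Poisson defect sets per fork direction (strand-specific lesions)
    if d_spacing < INF:
        n_dp = np.random.poisson(L / d_spacing)
        def_pos_p = np.sort(np.random.uniform(0.0, L, n_dp))
        n_dm = np.random.poisson(L / d_spacing)
        def_pos_m = np.sort(np.random.uniform(0.0, L, n_dm))
    else:
        def_pos_p = np.zeros(0)
        def_pos_m = np.zeros(0)

    rep_time = np.full(n_sites, INF)
    rep_dir = np.zeros(n_sites, dtype=np.int8)

    gl = np.zeros(MAX_GAPS)
    gr = np.zeros(MAX_GAPS)
    glf = np.zeros(MAX_GAPS, dtype=np.uint8)
    grf = np.zeros(MAX_GAPS, dtype=np.uint8)
    gli = np.full(MAX_GAPS, -1, dtype=np.int64)
    gri = np.full(MAX_GAPS, -1, dtype=np.int64)
    gls = np.full(MAX_GAPS, -1.0)  # stall release time; -1 = not stalled
    grs = np.full(MAX_GAPS, -1.0)
    n_gaps = 0

    virgin = periodic
    if not periodic:
        gl[0] = 0.0
        gr[0] = L
        n_gaps = 1

    def_alive_p = np.ones(len(def_pos_p), dtype=np.uint8)
    def_alive_m = np.ones(len(def_pos_m), dtype=np.uint8)

    init_xt = np.zeros((MAX_EVENTS, 2))
    coal_xt = np.zeros((MAX_EVENTS, 2))
    exit_xt = np.zeros((MAX_EVENTS, 2))
    exit_side = np.zeros(MAX_EVENTS, dtype=np.int8)
    n_init = 0
    n_coal = 0
    n_exit = 0

    snap = np.zeros((MAX_SNAP, 4))  # i_out, pos, dir, stalled
    n_snap = 0
    traj = np.zeros((MAX_TRAJ, 4))  # fork_id, code, x, t
    n_traj = 0
    fork_dir = np.zeros(MAX_EVENTS * 2, dtype=np.int8)
    n_forks = 0

    n_comp = cum_rate.shape[0]
    comp_tot = np.zeros(n_comp)
    for c in range(n_comp):
        comp_tot[c] = cum_rate[c, n_sites]

    t = 0.0
    i_out = 0
    i_forced = 0
    overflow = 0

    while True:
        if (not virgin) and n_gaps == 0:
            break
        if t >= t_cap:
            break

        # --- snapshots at step-start state
        while i_out < len(out_times) and t - 1e-9 <= out_times[i_out] < t + dt - 1e-9:
            for k in range(n_gaps):
                if glf[k] and n_snap < MAX_SNAP:
                    stalled = 1.0 if (gls[k] >= 0.0 and t < gls[k]) else 0.0
                    snap[n_snap, 0] = i_out
                    snap[n_snap, 1] = gl[k] % L if periodic else gl[k]
                    snap[n_snap, 2] = 1.0
                    snap[n_snap, 3] = stalled
                    n_snap += 1
                if grf[k] and n_snap < MAX_SNAP:
                    stalled = 1.0 if (grs[k] >= 0.0 and t < grs[k]) else 0.0
                    snap[n_snap, 0] = i_out
                    snap[n_snap, 1] = gr[k] % L if periodic else gr[k]
                    snap[n_snap, 2] = -1.0
                    snap[n_snap, 3] = stalled
                    n_snap += 1
            i_out += 1

        # --- initiation candidates (thinning)
        R = 0.0
        for c in range(n_comp):
            if gate_on[c] <= t < gate_off[c]:
                R += comp_tot[c]
        n_cand = 0
        if R > 0.0:
            n_cand = np.random.poisson(R * dt)
        for _cand in range(n_cand):
            u = np.random.random() * R
            acc = 0.0
            c_sel = -1
            for c in range(n_comp):
                if gate_on[c] <= t < gate_off[c]:
                    if u < acc + comp_tot[c]:
                        c_sel = c
                        break
                    acc += comp_tot[c]
            if c_sel < 0:
                continue
            r = u - acc
            j = np.searchsorted(cum_rate[c_sel], r) - 1
            if j < 0:
                j = 0
            elif j >= n_sites:
                j = n_sites - 1
            y = (j + np.random.random()) * dx
            virgin, n_gaps, n_init, n_traj, n_forks, ovf = _place_initiation(
                y, t, L, dx, n_sites, periodic, virgin,
                gl, gr, glf, grf, gli, gri, gls, grs, n_gaps,
                rep_time, rep_dir, init_xt, n_init, traj, n_traj, fork_dir,
                n_forks, record_traj,
            )
            overflow |= ovf
        # forced initiations scheduled within this step (dropped if the DNA
        # there is already replicated)
        while i_forced < len(forced_t) and forced_t[i_forced] < t + dt:
            y = forced_x[i_forced]
            i_forced += 1
            virgin, n_gaps, n_init, n_traj, n_forks, ovf = _place_initiation(
                y, forced_t[i_forced - 1], L, dx, n_sites, periodic, virgin,
                gl, gr, glf, grf, gli, gri, gls, grs, n_gaps,
                rep_time, rep_dir, init_xt, n_init, traj, n_traj, fork_dir,
                n_forks, record_traj,
            )
            overflow |= ovf

        # --- advance gap edges
        k = 0
        while k < n_gaps:
            a = gl[k]
            b = gr[k]
            va = 0.0
            vb = 0.0
            if glf[k]:
                if gls[k] >= 0.0 and t < gls[k]:
                    va = 0.0
                else:
                    if gls[k] >= 0.0:
                        gls[k] = -1.0
                        if record_traj and n_traj < MAX_TRAJ:
                            traj[n_traj, 0] = gli[k]
                            traj[n_traj, 1] = TRAJ_RESUME
                            traj[n_traj, 2] = a % L if periodic else a
                            traj[n_traj, 3] = t
                            n_traj += 1
                    va = v_plus[_site(a, dx, n_sites, periodic)]
            if grf[k]:
                if grs[k] >= 0.0 and t < grs[k]:
                    vb = 0.0
                else:
                    if grs[k] >= 0.0:
                        grs[k] = -1.0
                        if record_traj and n_traj < MAX_TRAJ:
                            traj[n_traj, 0] = gri[k]
                            traj[n_traj, 1] = TRAJ_RESUME
                            traj[n_traj, 2] = b % L if periodic else b
                            traj[n_traj, 3] = t
                            n_traj += 1
                    vb = v_minus[_site(b - 1e-9, dx, n_sites, periodic)]

            a1 = a + va * dt
            b1 = b - vb * dt

            # defect crossing: the edge halts at the first defect it reaches
            if len(def_pos_p) > 0 and va > 0.0:
                idef = _first_defect_in(def_pos_p, def_alive_p, a, a1, L, periodic)
                if idef >= 0:
                    p = def_pos_p[idef]
                    p_un = a + ((p - a) % L) if periodic else p
                    t_hit = t + (p_un - a) / va
                    stall_len = tau if tau >= INF else np.random.exponential(tau)
                    gls[k] = t_hit + stall_len
                    def_alive_p[idef] = 0
                    if record_traj and n_traj < MAX_TRAJ:
                        traj[n_traj, 0] = gli[k]
                        traj[n_traj, 1] = TRAJ_STALL
                        traj[n_traj, 2] = p_un % L if periodic else p_un
                        traj[n_traj, 3] = t_hit
                        n_traj += 1
                    a1 = p_un
            if len(def_pos_m) > 0 and vb > 0.0:
                idef = _last_defect_in(def_pos_m, def_alive_m, b1, b, L, periodic)
                if idef >= 0:
                    p = def_pos_m[idef]
                    p_un = b - ((b - p) % L) if periodic else p
                    t_hit = t + (b - p_un) / vb
                    stall_len = tau if tau >= INF else np.random.exponential(tau)
                    grs[k] = t_hit + stall_len
                    def_alive_m[idef] = 0
                    if record_traj and n_traj < MAX_TRAJ:
                        traj[n_traj, 0] = gri[k]
                        traj[n_traj, 1] = TRAJ_STALL
                        traj[n_traj, 2] = p_un % L if periodic else p_un
                        traj[n_traj, 3] = t_hit
                        n_traj += 1
                    b1 = p_un

            if a1 >= b1 - 1e-12:
                # gap closes within this step
                denom = va + vb
                if denom > 0.0:
                    tau_m = (b - a) / denom
                    if tau_m < 0.0:
                        tau_m = 0.0
                    x_m = a + va * tau_m
                    t_m = t + tau_m
                else:
                    x_m = 0.5 * (a + b)
                    t_m = t
                if va > 0.0:
                    _mark_plus(a, x_m, va, t, dx, n_sites, periodic, rep_time, rep_dir)
                if vb > 0.0:
                    _mark_minus(x_m, b, vb, t, dx, n_sites, periodic, rep_time, rep_dir)
                x_rec = x_m % L if periodic else x_m
                if glf[k] and grf[k]:
                    if n_coal < MAX_EVENTS:
                        coal_xt[n_coal, 0] = x_rec
                        coal_xt[n_coal, 1] = t_m
                        n_coal += 1
                    if record_traj and n_traj + 1 < MAX_TRAJ:
                        traj[n_traj, 0] = gli[k]
                        traj[n_traj, 1] = TRAJ_COAL
                        traj[n_traj, 2] = x_rec
                        traj[n_traj, 3] = t_m
                        n_traj += 1
                        traj[n_traj, 0] = gri[k]
                        traj[n_traj, 1] = TRAJ_COAL
                        traj[n_traj, 2] = x_rec
                        traj[n_traj, 3] = t_m
                        n_traj += 1
                elif glf[k] or grf[k]:
                    fid = gli[k] if glf[k] else gri[k]
                    if n_exit < MAX_EVENTS:
                        exit_xt[n_exit, 0] = x_rec
                        exit_xt[n_exit, 1] = t_m
                        exit_side[n_exit] = 1 if glf[k] else -1
                        n_exit += 1
                    if record_traj and n_traj < MAX_TRAJ:
                        traj[n_traj, 0] = fid
                        traj[n_traj, 1] = TRAJ_EXIT
                        traj[n_traj, 2] = x_rec
                        traj[n_traj, 3] = t_m
                        n_traj += 1
                # compact: move last gap into slot k
                n_gaps -= 1
                if k != n_gaps:
                    gl[k] = gl[n_gaps]
                    gr[k] = gr[n_gaps]
                    glf[k] = glf[n_gaps]
                    grf[k] = grf[n_gaps]
                    gli[k] = gli[n_gaps]
                    gri[k] = gri[n_gaps]
                    gls[k] = gls[n_gaps]
                    grs[k] = grs[n_gaps]
                continue  # re-process slot k (now holds a different gap)
            else:
                if va > 0.0:
                    _mark_plus(a, a1, va, t, dx, n_sites, periodic, rep_time, rep_dir)
                if vb > 0.0:
                    _mark_minus(b1, b, vb, t, dx, n_sites, periodic, rep_time, rep_dir)
                gl[k] = a1
                gr[k] = b1
            k += 1

        t += dt

    return (
        rep_time,
        rep_dir,
        init_xt[:n_init].copy(),
        coal_xt[:n_coal].copy(),
        exit_xt[:n_exit].copy(),
        exit_side[:n_exit].copy(),
        snap[:n_snap].copy(),
        traj[:n_traj].copy(),
        fork_dir[:n_forks].copy(),
        t,
        overflow,
    )

@njit(cache=True)
def run_fragment_batch(
    seeds,          # per-cycle RNG seeds
    switch_times,   # per-cycle label-switch times
    n_keep,
    keep_all,       # also keep fully red / fully green molecules
    n_sites,
    dx,
    periodic,
    cum_rate,
    gate_on,
    gate_off,
    v_plus,
    v_minus,
    dt,
    t_cap,
    d_spacing,
    tau,
    i_lo,           # fragment slice on the lattice
    i_hi,
):
    """Simulate cycles until n_keep molecules of the fragment are collected.

    Returns (labels, t_switch, n_kept, attempts, n_red_full, n_green_full).
    A molecule is two-color iff its fragment starts replicating before the
    switch and finishes at or after it.
    """
    width = i_hi - i_lo
    labels = np.zeros((n_keep, width), dtype=np.uint8)
    tsw = np.zeros(n_keep)
    empty = np.zeros(0)
    kept = 0
    attempts = 0
    n_red = 0
    n_green = 0
    for k in range(len(seeds)):
        if kept >= n_keep:
            break
        attempts += 1
        out = run_cycle(
            seeds[k], n_sites, dx, periodic, cum_rate, gate_on, gate_off,
            v_plus, v_minus, dt, t_cap, d_spacing, tau, empty, empty, empty, False,
        )
        rep_time = out[0]
        rt = rep_time[i_lo:i_hi]
        ts = switch_times[k]
        t_start = rt.min()
        t_end = rt.max()
        two = (t_start < ts) and (ts <= t_end)
        if two or keep_all:
            for j in range(width):
                labels[kept, j] = 1 if rt[j] < ts else 0
            tsw[kept] = ts
            kept += 1
        if not two:
            if t_end < ts:
                n_red += 1
            else:
                n_green += 1
    return labels, tsw, kept, attempts, n_red, n_green
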