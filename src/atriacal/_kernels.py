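"""Numba time-stepping kernels with voltage lookup tables.

Production integrators for single cells, 1D strands and 2D sheets.  All
voltage-dependent gate coefficients (Rush-Larsen steady state and decay
factor at the run's fixed dt) and voltage-dependent current factors are
tabulated on a fine Vm grid and linearly interpolated, which is what makes
monodomain runs tractable on one CPU.  The equations are the same as in
``_model``; agreement is enforced by tests against the adaptive-solver
reference.

State layout per node follows ``_model`` (21 variables); the effective
parameter vector per node is the 12-entry vector of ``CellParams``.
"""

from __future__ import annotations

import math

import numba
import numpy as np

from ._model import (CA_O, CA_UP_MAX, CM, CMDN_MAX, CSQN_MAX, E_CA_L, F,
                     GAMMA, I_UP_MAX, K_MCA, K_MNA, K_O, K_Q10, K_REL, K_SAT,
                     K_UP, KM_CMDN, KM_CSQN, KM_K_O, KM_NA_I, KM_TRPN, NA_O,
                     NACA_DENOM0, RT_F, SIGMA_NAK, TAU_HCA, TAU_TR, TAU_U,
                     TRPN_MAX, V_I, V_REL, V_UP, gate_rates, step_rl)

VMIN = -150.0
VMAX = 200.0   # beyond the table, nodes fall back to the exact scalar step
DV = 0.02
NB = int(round((VMAX - VMIN) / DV)) + 1
INV_DV = 1.0 / DV

N_ROWS = 30  # 12 gates x (inf, rl) + 6 current factors


@numba.njit(cache=True)
def _build_tables(dt):
    tb = np.empty((NB, N_ROWS))
    inf = np.empty(12)
    tau = np.empty(12)
    for i in range(NB):
        V = VMIN + i * DV
        gate_rates(V, inf, tau)
        for k in range(12):
            tb[i, 2 * k] = inf[k]
            tb[i, 2 * k + 1] = math.exp(-dt / tau[k])
        tb[i, 24] = 1.0 / (1.0 + math.exp(0.07 * (V + 80.0)))
        tb[i, 25] = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
        tb[i, 26] = 1.0 / (1.0 + math.exp((V + 15.0) / 22.4))
        tb[i, 27] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / RT_F)
                           + 0.0365 * SIGMA_NAK * math.exp(-V / RT_F))
        ex1 = math.exp(GAMMA * V / RT_F)
        ex2 = math.exp((GAMMA - 1.0) * V / RT_F)
        denom = NACA_DENOM0 * (1.0 + K_SAT * ex2)
        tb[i, 28] = ex1 * CA_O / denom
        tb[i, 29] = ex2 * NA_O ** 3 / denom
    return tb


# auxiliary tables: logistic function over a clipped argument, and the
# Rush-Larsen decay factor of the SR-release v gate as a function of u_inf
SIG_X0 = -42.0
SIG_DX = 0.02
SIG_N = int(round(84.0 / SIG_DX)) + 1
SIG_INV_DX = 1.0 / SIG_DX


def _build_aux(dt):
    x = SIG_X0 + SIG_DX * np.arange(SIG_N)
    sig = 1.0 / (1.0 + np.exp(x))
    u = np.linspace(0.0, 1.0, 513)
    rlv = np.exp(-dt / (1.91 + 2.09 * u))
    return sig, rlv


_TABLE_CACHE: dict = {}


def tables_for(dt: float):
    """(main table, logistic table, v-gate decay table) for a fixed dt."""
    key = round(float(dt), 9)
    tb = _TABLE_CACHE.get(key)
    if tb is None:
        tb = (_build_tables(float(dt)),) + _build_aux(float(dt))
        _TABLE_CACHE[key] = tb
    return tb


@numba.njit(cache=True, fastmath=True, inline="always")
def _logistic(sig, x):
    # 1/(1+exp(x)) from the clipped lookup table
    if x <= SIG_X0:
        return 1.0
    if x >= -SIG_X0:
        return 0.0
    p = (x - SIG_X0) * SIG_INV_DX
    k = int(p)
    w = p - k
    return sig[k] + w * (sig[k + 1] - sig[k])


@numba.njit(cache=True, fastmath=True, inline="always")
def _node_step(Y, i, tb, sig, rlv, eff, dt, rl_hca, rl_u, ena, ek, eca,
               stim, dvm_diff):
    """Advance node ``i`` one step; returns new Vm (written by caller)."""
    V = Y[i, 0]
    x = (V - VMIN) * INV_DV
    k = int(x)
    if k < 0 or k >= NB - 1:
        return 1.0e30
    w = x - k

    # interpolated current factors
    ik1f = tb[k, 24] + w * (tb[k + 1, 24] - tb[k, 24])
    gkur = tb[k, 25] + w * (tb[k + 1, 25] - tb[k, 25])
    ikrf = tb[k, 26] + w * (tb[k + 1, 26] - tb[k, 26])
    fnak = tb[k, 27] + w * (tb[k + 1, 27] - tb[k, 27])
    ncaa = tb[k, 28] + w * (tb[k + 1, 28] - tb[k, 28])
    ncab = tb[k, 29] + w * (tb[k + 1, 29] - tb[k, 29])

    na_i = Y[i, 16]
    k_i = Y[i, 17]
    ca_i = Y[i, 18]
    ca_up = Y[i, 19]
    ca_rel = Y[i, 20]

    i_na = eff[i, 0] * Y[i, 1] ** 3 * Y[i, 2] * Y[i, 3] * (V - ena[i])
    i_k1 = eff[i, 1] * ik1f * (V - ek[i])
    i_to = eff[i, 2] * Y[i, 4] * Y[i, 5] * (V - ek[i])
    i_kur = eff[i, 3] * gkur * Y[i, 6] ** 3 * Y[i, 7] * (V - ek[i])
    i_kr = eff[i, 4] * Y[i, 8] * ikrf * (V - ek[i])
    i_ks = eff[i, 5] * Y[i, 9] ** 2 * (V - ek[i])
    i_cal = eff[i, 6] * Y[i, 10] * Y[i, 11] * Y[i, 12] * (V - E_CA_L)
    rat = KM_NA_I / na_i
    i_nak = eff[i, 9] * fnak * (K_O / (K_O + KM_K_O)) / (1.0 + rat * math.sqrt(rat))
    i_naca = eff[i, 10] * (ncaa * na_i ** 3 - ncab * ca_i)
    i_bna = eff[i, 8] * (V - ena[i])
    i_bca = eff[i, 7] * (V - eca[i])
    i_pca = eff[i, 11] * ca_i / (0.0005 + ca_i)

    i_ion = (i_cal + i_na + i_k1 + i_to + i_kur + i_kr + i_ks + i_naca
             + i_nak + i_bna + i_bca + i_pca)

    i_rel = K_REL * Y[i, 13] ** 2 * Y[i, 14] * Y[i, 15] * (ca_rel - ca_i)
    i_tr = (ca_up - ca_rel) / TAU_TR
    i_up = I_UP_MAX / (1.0 + K_UP / ca_i)
    i_upleak = I_UP_MAX * ca_up / CA_UP_MAX
    fn = 1e-12 * V_REL * i_rel - (5e-13 / F) * (0.5 * i_cal - 0.2 * i_naca) * CM

    # Rush-Larsen gate updates (V-dependent gates from the table)
    for g in range(12):
        gi = g + 1  # state index of gate g (m..f occupy 1..11, w is 15)
        if g == 11:
            gi = 15
        ginf = tb[k, 2 * g] + w * (tb[k + 1, 2 * g] - tb[k, 2 * g])
        grl = tb[k, 2 * g + 1] + w * (tb[k + 1, 2 * g + 1] - tb[k, 2 * g + 1])
        Y[i, gi] = ginf + (Y[i, gi] - ginf) * grl

    hca_inf = 1.0 / (1.0 + ca_i / 0.00035)
    Y[i, 12] = hca_inf + (Y[i, 12] - hca_inf) * rl_hca

    u_inf = _logistic(sig, -(fn - 3.4175e-13) / 13.67e-16)
    v_inf = 1.0 - _logistic(sig, -(fn - 6.835e-14) / 13.67e-16)
    p = u_inf * 512.0
    kk = int(p)
    if kk >= 512:
        kk = 511
    rl_v = rlv[kk] + (p - kk) * (rlv[kk + 1] - rlv[kk])
    Y[i, 13] = u_inf + (Y[i, 13] - u_inf) * rl_u
    Y[i, 14] = v_inf + (Y[i, 14] - v_inf) * rl_v

    Y[i, 16] = na_i + dt * (-3.0 * i_nak - 3.0 * i_naca - i_bna - i_na) * CM / (F * V_I)
    Y[i, 17] = k_i + dt * (2.0 * i_nak - i_k1 - i_to - i_kur - i_kr - i_ks) * CM / (F * V_I)
    b1 = ((2.0 * i_naca - i_pca - i_cal - i_bca) * CM / (2.0 * F * V_I)
          + (V_UP * (i_upleak - i_up) + i_rel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (ca_i + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (ca_i + KM_CMDN) ** 2)
    Y[i, 18] = ca_i + dt * b1 / b2
    Y[i, 19] = ca_up + dt * (i_up - i_upleak - i_tr * V_REL / V_UP)
    Y[i, 20] = ca_rel + dt * (i_tr - i_rel) / (
        1.0 + CSQN_MAX * KM_CSQN / (ca_rel + KM_CSQN) ** 2)

    return V + dt * (-(i_ion - stim) + dvm_diff)


@numba.njit(cache=True, fastmath=True)
def simulate_1d(Y, eff, tb, sig, rlv, dt, nsteps, t0, dcoef, inv_dx2,
                ev_t, ev_dur, ev_amp, ev_lo, ev_hi,
                rec_every, Vrec, act_times, act_counts):
    """Monodomain 1D strand (or single cell when n == 1, dcoef == 0).

    Zero-flux (mirrored) ends.  Stimulus events are (start time, duration,
    positive depolarising amplitude, node range lo..hi inclusive).  Records
    Vm every ``rec_every`` steps into ``Vrec`` (if its size allows) and logs
    -40 mV upstroke crossing times per node into ``act_times``.

    Returns (status, node, nrec): status 0 ok, 1 blow-up at ``node``.
    """
    n = Y.shape[0]
    nev = ev_t.shape[0]
    ena = np.empty(n)
    ek = np.empty(n)
    eca = np.empty(n)
    lap = np.empty(n)
    _act_amp = np.empty(4)
    _act_lo = np.empty(4, dtype=np.int64)
    _act_hi = np.empty(4, dtype=np.int64)
    rl_hca = math.exp(-dt / TAU_HCA)
    rl_u = math.exp(-dt / TAU_U)
    nrec_max = Vrec.shape[0]
    maxact = act_times.shape[1]
    irec = 0
    for step in range(nsteps):
        t = t0 + step * dt
        if rec_every > 0 and step % rec_every == 0 and irec < nrec_max:
            for i in range(n):
                Vrec[irec, i] = Y[i, 0]
            irec += 1
        if step % 10 == 0:
            for i in range(n):
                ena[i] = RT_F * math.log(NA_O / Y[i, 16])
                ek[i] = RT_F * math.log(K_O / Y[i, 17])
                eca[i] = 0.5 * RT_F * math.log(CA_O / Y[i, 18])
        if n > 1:
            lap[0] = dcoef * inv_dx2 * 2.0 * (Y[1, 0] - Y[0, 0])
            lap[n - 1] = dcoef * inv_dx2 * 2.0 * (Y[n - 2, 0] - Y[n - 1, 0])
            for i in range(1, n - 1):
                lap[i] = dcoef * inv_dx2 * (Y[i - 1, 0] - 2.0 * Y[i, 0] + Y[i + 1, 0])
        else:
            lap[0] = 0.0
        # collect events active at this step (usually none or one)
        na = 0
        for e in range(nev):
            if ev_t[e] <= t < ev_t[e] + ev_dur[e]:
                _act_amp[na] = ev_amp[e]
                _act_lo[na] = ev_lo[e]
                _act_hi[na] = ev_hi[e]
                na += 1
                if na == 4:
                    break
        for i in range(n):
            stim = 0.0
            for e in range(na):
                if _act_lo[e] <= i <= _act_hi[e]:
                    stim += _act_amp[e]
            vold = Y[i, 0]
            vnew = _node_step(Y, i, tb, sig, rlv, eff, dt, rl_hca, rl_u, ena, ek, eca,
                              stim, lap[i])
            if vnew > 1.0e29:
                # Vm outside the tabulated range (strong stimuli): exact update
                step_rl(Y[i], eff[i], stim + lap[i], dt)
                vnew = Y[i, 0]
                if not (-1.0e6 < vnew < 1.0e6):
                    return 1, i, irec
            if vold < -40.0 <= vnew and act_counts[i] < maxact:
                frac = (-40.0 - vold) / (vnew - vold)
                act_times[i, act_counts[i]] = t + dt * frac
                act_counts[i] += 1
            Y[i, 0] = vnew
    return 0, -1, irec


@numba.njit(cache=True, fastmath=True)
def simulate_2d(Y, eff, tb, sig, rlv, dt, nsteps, t0, ny, nx, dcoef, inv_dx2,
                ev_t, ev_dur, ev_amp, ev_x0, ev_x1, ev_y0, ev_y1,
                frame_every, frames, ivm, act_first):
    """Monodomain 2D sheet on an ny x nx grid (nodes flattened row-major).

    Zero-flux edges via mirrored neighbours.  Stimulus events are rectangles
    in grid coordinates (x0..x1, y0..y1 inclusive).  Stores float32 frames
    and the spatial-mean Vm every ``frame_every`` steps, and the first
    -40 mV upstroke crossing time per node in ``act_first`` (-1 if none).

    Returns (status, node, nframes).
    """
    n = ny * nx
    nev = ev_t.shape[0]
    ena = np.empty(n)
    ek = np.empty(n)
    eca = np.empty(n)
    lap = np.empty(n)
    vbuf = np.empty(n)
    for i in range(n):
        vbuf[i] = Y[i, 0]
    _a_amp = np.empty(4)
    _a_x0 = np.empty(4, dtype=np.int64)
    _a_x1 = np.empty(4, dtype=np.int64)
    _a_y0 = np.empty(4, dtype=np.int64)
    _a_y1 = np.empty(4, dtype=np.int64)
    rl_hca = math.exp(-dt / TAU_HCA)
    rl_u = math.exp(-dt / TAU_U)
    nfr_max = frames.shape[0]
    ifr = 0
    for step in range(nsteps):
        t = t0 + step * dt
        if frame_every > 0 and step % frame_every == 0 and ifr < nfr_max:
            acc = 0.0
            for i in range(n):
                v = Y[i, 0]
                frames[ifr, i] = v
                acc += v
            ivm[ifr] = acc / n
            ifr += 1
        if step % 10 == 0:
            for i in range(n):
                ena[i] = RT_F * math.log(NA_O / Y[i, 16])
                ek[i] = RT_F * math.log(K_O / Y[i, 17])
                eca[i] = 0.5 * RT_F * math.log(CA_O / Y[i, 18])
        for iy in range(ny):
            ym = iy - 1 if iy > 0 else 1
            yp = iy + 1 if iy < ny - 1 else ny - 2
            base = iy * nx
            basem = ym * nx
            basep = yp * nx
            for ix in range(nx):
                xm = ix - 1 if ix > 0 else 1
                xp = ix + 1 if ix < nx - 1 else nx - 2
                i = base + ix
                lap[i] = dcoef * inv_dx2 * (
                    vbuf[basem + ix] + vbuf[basep + ix]
                    + vbuf[base + xm] + vbuf[base + xp] - 4.0 * vbuf[i])
        # collect events active at this step (rectangles may overlap, sum them)
        na = 0
        for e in range(nev):
            if ev_t[e] <= t < ev_t[e] + ev_dur[e]:
                _a_amp[na] = ev_amp[e]
                _a_x0[na] = ev_x0[e]
                _a_x1[na] = ev_x1[e]
                _a_y0[na] = ev_y0[e]
                _a_y1[na] = ev_y1[e]
                na += 1
                if na == 4:
                    break
        for iy in range(ny):
            base = iy * nx
            for ix in range(nx):
                i = base + ix
                stim = 0.0
                for e in range(na):
                    if (_a_x0[e] <= ix <= _a_x1[e]
                            and _a_y0[e] <= iy <= _a_y1[e]):
                        stim += _a_amp[e]
                vold = Y[i, 0]
                vnew = _node_step(Y, i, tb, sig, rlv, eff, dt, rl_hca, rl_u,
                                  ena, ek, eca, stim, lap[i])
                if vnew > 1.0e29:
                    step_rl(Y[i], eff[i], stim + lap[i], dt)
                    vnew = Y[i, 0]
                    if not (-1.0e6 < vnew < 1.0e6):
                        return 1, i, ifr
                if vold < -40.0 <= vnew and act_first[i] < 0.0:
                    act_first[i] = t + dt * (-40.0 - vold) / (vnew - vold)
                Y[i, 0] = vnew
                vbuf[i] = vnew
    return 0, -1, ifr


@numba.njit(cache=True, fastmath=True)
def simulate_clamp(Y, eff, tb, sig, rlv, dt, nsteps, v_schedule_t, v_schedule_v,
                   rec_every, ical_rec, t_rec, pin_hca):
    """Voltage clamp of a single cell: Vm follows the piecewise-constant
    schedule; gates and concentrations evolve freely.  Records I_CaL.

    Returns the number of recorded samples.
    """
    rl_hca = math.exp(-dt / TAU_HCA)
    rl_u = math.exp(-dt / TAU_U)
    ena = np.empty(1)
    ek = np.empty(1)
    eca = np.empty(1)
    nrec_max = ical_rec.shape[0]
    nseg = v_schedule_t.shape[0]
    irec = 0
    seg = 0
    hca0 = Y[0, 12]
    for step in range(nsteps):
        t = step * dt
        while seg + 1 < nseg and t >= v_schedule_t[seg + 1]:
            seg += 1
        Y[0, 0] = v_schedule_v[seg]
        if step % 10 == 0:
            ena[0] = RT_F * math.log(NA_O / Y[0, 16])
            ek[0] = RT_F * math.log(K_O / Y[0, 17])
            eca[0] = 0.5 * RT_F * math.log(CA_O / Y[0, 18])
        if rec_every > 0 and step % rec_every == 0 and irec < nrec_max:
            ical_rec[irec] = (eff[0, 6] * Y[0, 10] * Y[0, 11] * Y[0, 12]
                              * (Y[0, 0] - E_CA_L))
            t_rec[irec] = t
            irec += 1
        _node_step(Y, 0, tb, sig, rlv, eff, dt, rl_hca, rl_u, ena, ek, eca, 0.0, 0.0)
        # the clamp owns Vm (reset at the top of the loop); optionally the
        # Ca-dependent gate is pinned at its holding-state value so that
        # mutant sweeps are exact conductance scalings of wild type
        if pin_hca == 1:
            Y[0, 12] = hca0
    return irec
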