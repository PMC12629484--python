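"""Single-cell pacing protocols: steady-state APs, biomarkers, ERP, restitution.

Conventions (fixed, recorded in the methods note):

* stimulus: 2-ms rectangular pulse, 20 pA/pF, depolarising;
* steady state: 50 pre-beats at each cycle length (100 when BCL < 400 ms);
* AP onset at the maximum-upstroke-velocity instant; APD90 ends when Vm first
  falls below RMP + 0.1 * APA;
* ERP: the shortest S1-S2 interval whose S2 response reaches at least 80 % of
  the S1 action-potential amplitude, bisected to 1 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sim import DT, StimEvent, node_states, pacing_events, run
from .cell_model import CellParams

STIM_AMP = 20.0    # pA/pF
STIM_DUR = 2.0     # ms
ERP_FRACTION = 0.8
ALTERNANS_MS = 2.0


def n_prebeats(bcl: float) -> int:
    return 100 if bcl < 400.0 else 50


#: conditioned single-cell states keyed by (region, f, s_mut, BCL, dt,
#: stimulus amplitude, pre-beats); purely a recomputation cache
_ERP_CONDITIONING: dict = {}


@dataclass
class Trace:
    """Uniformly sampled membrane-potential trace of one node."""
    dt: float                      # sampling step, ms
    vm: np.ndarray                 # mV
    t0: float = 0.0
    stim_times: tuple = ()         # ms, absolute

    def __post_init__(self):
        if len(self.vm) == 0:
            raise ValueError("empty trace")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.vm))


@dataclass
class Biomarkers:
    APD90: float   # ms
    APA: float     # mV
    MUV: float     # V/s
    RMP: float     # mV


@dataclass
class RestitutionCurve:
    """(abscissa, value) pairs; bifurcated points carry a second branch."""
    abscissa_name: str
    points: list = field(default_factory=list)  # (x, value, second_branch|None)

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def y(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def max_slope(self) -> float:
        """Maximum centred-finite-difference slope d(value)/d(abscissa)."""
        order = np.argsort(self.x)
        x, y = self.x[order], self.y[order]
        if len(x) < 3:
            raise ValueError("need at least 3 points for a slope")
        return float(np.max((y[2:] - y[:-2]) / (x[2:] - x[:-2])))


def pace_to_steady(p: CellParams, bcl: float, n_beats: int | None = None, *,
                   dt: float = DT, stim_amp: float = STIM_AMP,
                   record_ms: float | None = None):
    """Pace a single cell at fixed BCL; return (last-beat Trace, state, captured).

    The trace covers the final beat (or the final ``record_ms``).  Capture is
    judged on the final beat: an upstroke crossing of -40 mV must follow the
    last stimulus.  Loss of capture is flagged, not raised.
    """
    if n_beats is None:
        n_beats = n_prebeats(bcl)
    if bcl <= STIM_DUR:
        raise ValueError("BCL must exceed the stimulus duration")
    Y, eff = node_states(p, 1)
    events = pacing_events(n_beats, bcl, stim_amp)
    t_last = (n_beats - 1) * bcl
    run(Y, eff, events, t_last, dt=dt)
    rec_ms = bcl if record_ms is None else record_ms
    res = run(Y, eff, events, rec_ms, t0=t_last, dt=dt, rec_every=1)
    captured = res.activations_after(0, t_last - 1e-9).size > 0
    trace = Trace(dt, res.vrec[:, 0], t0=t_last,
                  stim_times=tuple(e.time for e in events))
    return trace, Y[0].copy(), captured


def ap_biomarkers(trace: Trace, stim_time: float | None = None) -> Biomarkers:
    """Biomarkers of the AP elicited by the stimulus at ``stim_time``.

    RMP is read just before the stimulus, APA from RMP to the peak, MUV is
    the maximum upstroke dVm/dt, and APD90 runs from the MUV instant to 90 %
    repolarisation.  Raises if no AP was captured.
    """
    if stim_time is None:
        if not trace.stim_times:
            raise ValueError("trace carries no stimulus events")
        t_end = trace.t0 + trace.dt * len(trace.vm)
        in_window = [s for s in trace.stim_times if s < t_end]
        if not in_window:
            raise ValueError("no stimulus event within the trace window")
        stim_time = max(in_window)
    i_st = min(len(trace.vm) - 1,
               max(0, int(round((stim_time - trace.t0) / trace.dt))))
    v = trace.vm
    rmp = v[i_st]
    dvdt = np.gradient(v, trace.dt)
    i_up = i_st + int(np.argmax(dvdt[i_st:]))
    peak = float(np.max(v[i_st:]))
    apa = peak - rmp
    if apa < 40.0 or v[i_up] > 20.0 + peak:
        raise ValueError("no action potential captured after the stimulus")
    v90 = rmp + 0.1 * apa
    i_pk = i_st + int(np.argmax(v[i_st:]))
    below = np.flatnonzero(v[i_pk:] < v90)
    if below.size == 0:
        raise ValueError("action potential does not repolarise within the trace")
    apd90 = (i_pk - i_up + below[0]) * trace.dt
    return Biomarkers(APD90=float(apd90), APA=float(apa),
                      MUV=float(np.max(dvdt[i_st:])), RMP=float(rmp))


def _s2_amplitude_ratio(Y, eff, bcl, si, dt, stim_amp):
    """Run S1 (t=0) + S2 (t=si) from a conditioned state copy; return
    S2/S1 response-amplitude ratio."""
    Yc = Y.copy()
    ev = [StimEvent(0.0, stim_amp), StimEvent(si, stim_amp)]
    res = run(Yc, eff, ev, si + 400.0, dt=dt, rec_every=10)
    v = res.vrec[:, 0]
    rec_dt = res.rec_dt
    i1 = 0
    i2 = int(round(si / rec_dt))
    a1 = np.max(v[i1:i2]) - v[i1]
    a2 = np.max(v[i2:]) - v[i2]
    return a2 / a1


def measure_erp_cell(p: CellParams, bcl: float, *, dt: float = DT,
                     stim_amp: float = STIM_AMP, resolution: float = 1.0,
                     si_grid: bool = False) -> float:
    """Effective refractory period (ms) after steady pacing at ``bcl``.

    S1-S2 protocol from the conditioned state; S2 capture requires >= 80 % of
    the S1 amplitude.  Bisection (or, with ``si_grid``, a 1-ms linear scan)
    to ``resolution``.  Returns NaN if even S2 = BCL fails (flagged ERP).
    """
    n_pre = n_prebeats(bcl)
    # the conditioning train is deterministic in these parameters, so cache it
    key = (p.region, p.ical.f, p.ical.s_mut, bcl, dt, stim_amp, n_pre)
    cached = _ERP_CONDITIONING.get(key)
    if cached is None:
        Y, eff = node_states(p, 1)
        run(Y, eff, pacing_events(n_pre - 1, bcl, stim_amp), (n_pre - 1) * bcl,
            dt=dt)
        _ERP_CONDITIONING[key] = (Y.copy(), eff)
    else:
        Y, eff = cached[0].copy(), cached[1]
    # the conditioning train's last beat acts as the S1 at t=0
    hi = bcl
    if _s2_amplitude_ratio(Y, eff, bcl, hi, dt, stim_amp) < ERP_FRACTION:
        return float("nan")
    lo = 20.0
    if si_grid:
        si = lo
        while si < hi and _s2_amplitude_ratio(Y, eff, bcl, si, dt, stim_amp) < ERP_FRACTION:
            si += resolution
        return si
    while hi - lo > resolution:
        mid = 0.5 * (hi + lo)
        if _s2_amplitude_ratio(Y, eff, bcl, mid, dt, stim_amp) >= ERP_FRACTION:
            hi = mid
        else:
            lo = mid
    return hi


def _apd_of_beat(vseg, rec_dt):
    rmp = vseg[0]
    dvdt = np.gradient(vseg, rec_dt)
    i_up = int(np.argmax(dvdt))
    apa = np.max(vseg) - rmp
    if apa < 40.0:
        return None
    i_pk = int(np.argmax(vseg))
    below = np.flatnonzero(vseg[i_pk:] < rmp + 0.1 * apa)
    return float((i_pk - i_up + below[0]) * rec_dt) if below.size else None


def restitution(p: CellParams, protocol: str = "dynamic", quantity: str = "APD90", *,
                bcls: np.ndarray | None = None, dt: float = DT,
                stim_amp: float = STIM_AMP, beats_per_bcl: int = 20):
    """APD90 (or ERP) restitution over a decremental BCL sweep.

    ``dynamic``: the state is carried from one BCL to the next (the standard
    decremental protocol); the curve is reported against the diastolic
    interval DI = BCL - APD of the preceding beat.  ``S1S2``: ERP/APD of a
    single premature beat after steady S1 pacing, against the S1-S2 interval.
    Alternans (> 2 ms even/odd APD difference) is recorded as a second branch.

    Returns (RestitutionCurve, max_slope).
    """
    if quantity not in ("APD90", "ERP"):
        raise ValueError("quantity must be APD90 or ERP")
    if bcls is None:
        bcls = np.array([1000., 900., 800., 700., 600., 500., 450., 400., 350.,
                         325., 300., 280., 260., 240., 220., 200., 180., 160.,
                         140., 120., 100.])
    curve = RestitutionCurve("DI_ms" if quantity == "APD90" else "BCL_ms")
    if quantity == "ERP":
        for bcl in bcls:
            erp = measure_erp_cell(p, float(bcl), dt=dt, stim_amp=stim_amp)
            if np.isfinite(erp):
                curve.points.append((float(bcl), erp, None))
        return curve, _slope_or_nan(curve)

    if protocol not in ("dynamic", "S1S2"):
        raise ValueError("protocol must be dynamic or S1S2")
    if protocol == "S1S2":
        return _restitution_s1s2(p, bcls, dt, stim_amp)
    Y, eff = node_states(p, 1)
    run(Y, eff, pacing_events(n_prebeats(bcls[0]), bcls[0], stim_amp),
        n_prebeats(bcls[0]) * bcls[0], dt=dt)
    for bcl in bcls:
        bcl = float(bcl)
        events = pacing_events(beats_per_bcl, bcl, stim_amp)
        res = run(Y, eff, events, beats_per_bcl * bcl, dt=dt, rec_every=10)
        rec_dt = res.rec_dt
        spb = int(round(bcl / rec_dt))
        apds = []
        for b in range(beats_per_bcl):
            seg = res.vrec[b * spb:(b + 1) * spb, 0]
            apds.append(_apd_of_beat(seg, rec_dt))
        last, prev = apds[-1], apds[-2]
        if last is None or prev is None:
            continue  # capture lost: curve ends here
        di = bcl - prev
        if abs(last - prev) > ALTERNANS_MS:
            curve.points.append((di, last, prev))
        else:
            curve.points.append((di, last, None))
    return curve, _slope_or_nan(curve)


def _restitution_s1s2(p, sis, dt, stim_amp, bcl=1000.0):
    """Premature-beat APD against DI after steady S1 pacing at 1000 ms."""
    n_pre = n_prebeats(bcl)
    Y, eff = node_states(p, 1)
    run(Y, eff, pacing_events(n_pre - 1, bcl, stim_amp), (n_pre - 1) * bcl, dt=dt)
    curve = RestitutionCurve("DI_ms")
    res0 = run(Y.copy(), eff, [StimEvent(0.0, stim_amp)], bcl, dt=dt, rec_every=10)
    apd_s1 = _apd_of_beat(res0.vrec[:, 0], res0.rec_dt)
    if apd_s1 is None:
        return curve, float("nan")
    for si in sorted(float(s) for s in sis):
        Yc = Y.copy()
        ev = [StimEvent(0.0, stim_amp), StimEvent(si, stim_amp)]
        res = run(Yc, eff, ev, si + 500.0, dt=dt, rec_every=10)
        v = res.vrec[:, 0]
        i2 = int(round(si / res.rec_dt))
        apd_s2 = _apd_of_beat(v[i2:], res.rec_dt)
        if apd_s2 is not None:
            curve.points.append((si - apd_s1, apd_s2, None))
    return curve, _slope_or_nan(curve)


def _slope_or_nan(curve: RestitutionCurve) -> float:
    try:
        return curve.max_slope()
    except ValueError:
        return float("nan")
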