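"""Monodomain 1D strand: conduction, refractoriness, excitability, vulnerability.

The strand is the study's standard cable: 100 isotropic nodes at 0.25 mm
spacing, diffusion coefficient 0.21 mm^2/ms, zero-flux ends, paced at one
end (first three nodes).  Conduction velocity is read between the 25th and
75th nodes from -40 mV upstroke crossings; wavelength is CV x ERP; the
excitation threshold (EXT) is the minimal 2-ms S2 amplitude that evokes a
propagating wave; the vulnerable window (VW) is the S2 coupling-interval
range producing unidirectional conduction block at a regional junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sim import DT, SimResult, StimEvent, node_states, pacing_events, run
from .cell_model import ConfigurationError, make_regional_params
from .cell_protocols import RestitutionCurve

S1_AMP = 80.0        # pA/pF, strand pacing amplitude (>2x diastolic threshold)
S1_DUR = 2.0         # ms
EXT_CAP = 600.0      # pA/pF, search ceiling for the excitation threshold
ACT_THRESHOLD = -40.0


@dataclass
class StrandConfig:
    """Geometry, diffusion and per-node cell types of a 1D strand."""
    n_nodes: int = 100
    dx: float = 0.25          # mm
    D: float = 0.21           # mm^2/ms
    regions: tuple = ("RA",)  # one label (uniform) or one per node
    variant: str = "WT"
    f: float = 0.0
    stim_lo: int = 0          # stimulus electrode (node range, inclusive):
    stim_hi: int = 1          # a 0.5-mm two-node segment at the strand end
    s2_lo: int | None = None  # S2 site; defaults to the S1 site
    s2_hi: int | None = None

    def __post_init__(self):
        if self.n_nodes < 3:
            raise ConfigurationError("strand needs at least 3 nodes")
        if self.dx <= 0:
            raise ConfigurationError("dx must be positive")
        if self.D < 0:
            raise ConfigurationError("D must be non-negative")
        if len(self.regions) not in (1, self.n_nodes):
            raise ConfigurationError("regions: give one label or one per node")

    def node_regions(self) -> list:
        return (list(self.regions) * self.n_nodes if len(self.regions) == 1
                else list(self.regions))

    def cell_params(self) -> list:
        return [make_regional_params(r, self.variant, self.f)
                for r in self.node_regions()]

    def check_cfl(self, dt: float) -> None:
        if self.D > 0 and dt > self.dx ** 2 / (2.0 * self.D):
            raise ConfigurationError(
                f"dt={dt} violates the explicit-FDM stability bound "
                f"dx^2/(2D)={self.dx ** 2 / (2 * self.D):.4f} ms")

    def s2_site(self) -> tuple:
        lo = self.stim_lo if self.s2_lo is None else self.s2_lo
        hi = self.stim_hi if self.s2_hi is None else self.s2_hi
        return lo, hi


def strand_states(cfg: StrandConfig):
    return node_states(cfg.cell_params(), cfg.n_nodes)


def run_strand(cfg: StrandConfig, stimuli, duration: float, *,
               state=None, t0: float = 0.0, dt: float = DT,
               rec_every: int = 0) -> SimResult:
    """Forward-Euler monodomain run; ``stimuli`` is a list of StimEvent.

    The CFL bound is checked before the run.  ``state`` is an optional
    (Y, eff) pair to continue from; it is advanced in place.
    """
    cfg.check_cfl(dt)
    Y, eff = strand_states(cfg) if state is None else state
    return run(Y, eff, stimuli, duration, t0=t0, dt=dt, D=cfg.D, dx=cfg.dx,
               rec_every=rec_every)


def condition_strand(cfg: StrandConfig, bcl: float = 1000.0, n_beats: int = 5,
                     *, dt: float = DT, rec_every: int = 0, stim_sites=None):
    """S1 conditioning train; returns (SimResult of last beat, (Y, eff)).

    The returned state is a snapshot taken at t = 0, the instant of the final
    S1 stimulus (which has not yet been applied): S1-S2 trials continue from
    it by delivering their own S1 at t = 0 and the S2 at the coupling
    interval.  The returned SimResult records the final conditioning beat.
    """
    cfg.check_cfl(dt)
    if stim_sites is None:
        stim_sites = [(cfg.stim_lo, cfg.stim_hi)]
    Y, eff = strand_states(cfg)
    ev = []
    for lo, hi in stim_sites:
        ev += pacing_events(n_beats - 1, bcl, S1_AMP, S1_DUR, lo, hi,
                            t_first=-(n_beats - 1) * bcl)
    run(Y, eff, ev, (n_beats - 1) * bcl, t0=-(n_beats - 1) * bcl, dt=dt,
        D=cfg.D, dx=cfg.dx)
    snapshot = Y.copy()
    s1 = [StimEvent(0.0, S1_AMP, S1_DUR, lo, hi) for lo, hi in stim_sites]
    res = run(Y, eff, s1, bcl, t0=0.0, dt=dt, D=cfg.D, dx=cfg.dx,
              rec_every=rec_every)
    return res, (snapshot, eff)


def cv_from_vm(vm: np.ndarray, rec_dt: float, cfg: StrandConfig,
               node_a: int = 24, node_b: int = 74) -> float:
    """CV (cm/s) from a space-time Vm array via -40 mV upstroke crossings.

    Nodes are 0-based (defaults are the 25th and 75th nodes).  Returns 0.0
    (the conduction-failure convention) if either node never activates.
    """
    times = []
    for node in (node_a, node_b):
        v = vm[:, node]
        up = np.flatnonzero((v[:-1] < ACT_THRESHOLD) & (v[1:] >= ACT_THRESHOLD))
        if up.size == 0:
            return 0.0
        i = up[0]
        frac = (ACT_THRESHOLD - v[i]) / (v[i + 1] - v[i])
        times.append((i + frac) * rec_dt)
    dt_act = times[1] - times[0]
    if dt_act <= 0:
        return 0.0
    return float((node_b - node_a) * cfg.dx / dt_act * 100.0)


def measure_cv(res: SimResult, cfg: StrandConfig, after: float = -np.inf,
               node_a: int = 24, node_b: int = 74) -> float:
    """CV (cm/s) from kernel-recorded activation times of the first upstroke
    after ``after`` at the two measurement nodes; 0.0 on conduction failure."""
    ta = res.activations_after(node_a, after)
    tb = res.activations_after(node_b, after)
    if ta.size == 0 or tb.size == 0 or tb[0] <= ta[0]:
        return 0.0
    return float((node_b - node_a) * cfg.dx / (tb[0] - ta[0]) * 100.0)


def _propagates(res: SimResult, after: float, probe: int = 74) -> bool:
    return res.activations_after(probe, after).size > 0


def measure_erp_strand(cfg: StrandConfig, bcl: float = 1000.0, *,
                       state=None, dt: float = DT, resolution: float = 1.0,
                       n_beats: int = 5) -> float:
    """Strand ERP (ms): minimal S1-S2 interval whose S2 (at the pacing site,
    S1 amplitude) evokes a wave that reaches the 75th node.  Bisection to
    ``resolution``; NaN if S2 at the full BCL fails."""
    if state is None:
        _, state = condition_strand(cfg, bcl, n_beats, dt=dt)
    Y, eff = state

    def trial(si):
        Yc = Y.copy()
        ev = [StimEvent(0.0, S1_AMP, S1_DUR, cfg.stim_lo, cfg.stim_hi),
              StimEvent(si, S1_AMP, S1_DUR, cfg.stim_lo, cfg.stim_hi)]
        res = run(Yc, eff, ev, si + 150.0, dt=dt, D=cfg.D, dx=cfg.dx)
        return _propagates(res, si + 2.0)

    lo, hi = 60.0, float(bcl)
    if not trial(hi):
        return float("nan")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if trial(mid):
            hi = mid
        else:
            lo = mid
    return hi


def wavelength(cfg: StrandConfig, bcl: float = 1000.0, *, dt: float = DT) -> dict:
    """CV (cm/s), ERP (ms) and wavelength WL = CV x ERP (mm) at one BCL."""
    res, state = condition_strand(cfg, bcl, dt=dt)
    cv = measure_cv(res, cfg, after=0.0)
    erp = measure_erp_strand(cfg, bcl, state=state, dt=dt)
    wl = cv / 100.0 * erp  # (mm/ms) * ms
    return {"CV_cm_per_s": cv, "ERP_ms": erp, "WL_mm": wl}


def strand_restitution(cfg: StrandConfig, quantity: str = "CV", *,
                       bcls=None, beats_per_bcl: int = 8, dt: float = DT):
    """Restitution of CV, ERP or WL over a decremental BCL sweep.

    The state is carried across BCLs (dynamic protocol).  The cut-off BCL is
    the smallest BCL in the sweep with 1:1 conduction to the 75th node; the
    curve stops there.  CV alternans (>1 cm/s beat-to-beat difference)
    records both branch values.

    Returns (RestitutionCurve, cutoff_bcl).
    """
    if quantity not in ("CV", "ERP", "WL"):
        raise ConfigurationError("quantity must be CV, ERP or WL")
    if bcls is None:
        bcls = [1000., 600., 500., 450., 400., 380., 360., 340., 320.,
                300., 290., 280., 270., 260., 250., 240., 230., 220., 210., 200.]
    cfg.check_cfl(dt)
    Y, eff = strand_states(cfg)
    curve = RestitutionCurve("BCL_ms")
    cutoff = float("nan")
    t = 0.0
    for bcl in bcls:
        bcl = float(bcl)
        ev = pacing_events(beats_per_bcl, bcl, S1_AMP, S1_DUR,
                           cfg.stim_lo, cfg.stim_hi, t_first=t)
        res = run(Y, eff, ev, beats_per_bcl * bcl, t0=t, dt=dt,
                  D=cfg.D, dx=cfg.dx)
        n_waves = res.activations_after(74, t - 1e-9).size
        one_to_one = n_waves >= beats_per_bcl
        if one_to_one:
            cutoff = bcl
            if quantity == "CV":
                cv_last = measure_cv(res, cfg, after=t + (beats_per_bcl - 1) * bcl)
                cv_prev = measure_cv(res, cfg, after=t + (beats_per_bcl - 2) * bcl,
                                     ) if beats_per_bcl > 1 else cv_last
                # guard: measure_cv(after=...) picks the first activation after
                # the given time, so cv_prev is the preceding beat's wave
                if abs(cv_last - cv_prev) > 1.0:
                    curve.points.append((bcl, cv_last, cv_prev))
                else:
                    curve.points.append((bcl, cv_last, None))
            elif quantity in ("ERP", "WL"):
                cv = measure_cv(res, cfg, after=t + (beats_per_bcl - 1) * bcl)
                erp = measure_erp_strand(cfg, bcl, state=(Y.copy(), eff), dt=dt)
                val = erp if quantity == "ERP" else cv / 100.0 * erp
                curve.points.append((bcl, val, None))
        t += beats_per_bcl * bcl
        if not one_to_one:
            break
    return curve, cutoff


def excitation_threshold(cfg: StrandConfig, si: float, *, state=None,
                         dt: float = DT, resolution: float = 1.0,
                         mode: str = "bisect", probe_amp: float = 0.0) -> float:
    """EXT (pA/pF): minimal 2-ms S2 amplitude at the pacing site whose wave
    reaches the 75th node, delivered ``si`` ms after the last conditioning S1.

    Bisection (or a linear scan with ``mode='scan'``) to ``resolution``,
    capped at 600 pA/pF (the cap is returned when nothing captures).
    ``mode='probe'`` runs a single trial at ``probe_amp`` and returns
    ``probe_amp`` on capture (EXT <= probe_amp) or the cap otherwise: a cheap
    one-sided bound used by the critical-SI walk.
    """
    if state is None:
        _, state = condition_strand(cfg, 1000.0, 5, dt=dt)
    Y, eff = state

    def trial(amp):
        Yc = Y.copy()
        ev = [StimEvent(0.0, S1_AMP, S1_DUR, cfg.stim_lo, cfg.stim_hi),
              StimEvent(si, amp, S1_DUR, cfg.stim_lo, cfg.stim_hi)]
        res = run(Yc, eff, ev, si + 150.0, dt=dt, D=cfg.D, dx=cfg.dx)
        return _propagates(res, si + 2.0)

    if mode == "probe":
        return float(probe_amp) if trial(probe_amp) else EXT_CAP
    if mode == "scan":
        amp = resolution
        while amp <= EXT_CAP:
            if trial(amp):
                return float(amp)
            amp += resolution
        return EXT_CAP
    lo, hi = 0.0, EXT_CAP
    if not trial(hi):
        return EXT_CAP
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if trial(mid):
            hi = mid
        else:
            lo = mid
    return float(np.ceil(hi / resolution) * resolution)


def critical_si(cfg: StrandConfig, *, si_start: float = 400.0,
                si_min: float = 40.0, dt: float = DT) -> tuple:
    """(critical SI, EXT there): descending the SI axis at 1-ms resolution,
    the first SI at which EXT exceeds 400 pA/pF after being below 250 pA/pF.

    A coarse descent (16-ms steps) brackets the sharp transition first; a
    1-ms walk then runs only inside the bracket.  Each grid point is
    classified with two single-amplitude probes (does 250 capture? does 400?)
    rather than a full bisection; only the returned point's EXT is bisected
    out.  Returns (nan, nan) if no transition is found in the scanned range.
    """
    _, state = condition_strand(cfg, 1000.0, 5, dt=dt)

    def below_250(si):
        return excitation_threshold(cfg, si, state=state, dt=dt,
                                    mode="probe", probe_amp=250.0) <= 250.0

    def above_400(si):
        return excitation_threshold(cfg, si, state=state, dt=dt,
                                    mode="probe", probe_amp=400.0) > 400.0

    si_lo_side = None  # largest coarse SI with EXT > 400 (previous one < 250)
    si = si_start
    prev_low = None
    while si >= si_min:
        if above_400(si) and prev_low:
            si_lo_side = si
            break
        prev_low = below_250(si)
        si -= 16.0
    if si_lo_side is None:
        return float("nan"), float("nan")
    for s in np.arange(si_lo_side + 16.0 - 1.0, si_lo_side - 1.0, -1.0):
        s = float(s)
        if above_400(s):
            return s, float(excitation_threshold(cfg, s, state=state, dt=dt))
    return si_lo_side, float(excitation_threshold(cfg, si_lo_side, state=state,
                                                  dt=dt))


# ---------------------------------------------------------------------------
# vulnerable window

@dataclass
class VulnerableWindow:
    junction: str
    lower: float      # ms, S2 coupling interval
    upper: float      # ms
    outcomes: dict = field(default_factory=dict)  # SI -> classification

    @property
    def width(self) -> float:
        return max(0.0, self.upper - self.lower)


def classify_s2(cfg: StrandConfig, state, si: float, *, amp: float = S1_AMP,
                dt: float = DT, stim_sites=None) -> str:
    """Outcome of one premature S2 at the junction site, ``si`` ms after S1.

    'bidirectional_block' | 'unidirectional_block' | 'bidirectional_conduction',
    judged by whether the S2 wave reaches probe nodes near both strand ends.
    """
    Y, eff = state
    Yc = Y.copy()
    lo, hi = cfg.s2_site()
    if stim_sites is None:
        stim_sites = [(cfg.stim_lo, cfg.stim_hi)]
    ev = [StimEvent(0.0, S1_AMP, S1_DUR, a, b) for a, b in stim_sites]
    ev.append(StimEvent(si, amp, S1_DUR, lo, hi))
    res = run(Yc, eff, ev, si + 110.0, dt=dt, D=cfg.D, dx=cfg.dx)
    left = res.activations_after(5, si + 2.0).size > 0
    right = res.activations_after(cfg.n_nodes - 6, si + 2.0).size > 0
    if left and right:
        return "bidirectional_conduction"
    if left or right:
        return "unidirectional_block"
    return "bidirectional_block"


def vulnerable_window(cfg: StrandConfig, *, bcl: float = 1000.0,
                      coarse: float = 4.0, resolution: float = 0.1,
                      dt: float = DT, junction_name: str | None = None,
                      si_range: tuple | None = None) -> VulnerableWindow:
    """Vulnerable window of a junction strand: the S2 coupling-interval range
    producing unidirectional conduction block.

    After S1 conditioning, the coupling interval is scanned coarsely across
    the junction's repolarisation span, then each edge of the (largest)
    unidirectional interval is bisected to ``resolution``.
    """
    rec_every = max(1, int(round(1.0 / dt)))
    res, state = condition_strand(cfg, bcl, 5, dt=dt, rec_every=rec_every)
    lo, hi = cfg.s2_site()
    jc = (lo + hi) // 2
    if si_range is None:
        # repolarisation times (V < -60 mV) within +-8 nodes of the junction
        vm = res.vrec
        t_rep = []
        for node in range(max(0, jc - 8), min(cfg.n_nodes, jc + 9)):
            v = vm[:, node]
            dn = np.flatnonzero((v[:-1] >= -60.0) & (v[1:] < -60.0))
            if dn.size:
                t_rep.append(dn[-1] * res.rec_dt)
        if not t_rep:
            t_rep = [300.0]
        si_range = (max(20.0, min(t_rep) - 60.0), max(t_rep) + 80.0)

    outcomes = {}

    def cls(si):
        si = round(float(si), 6)
        if si not in outcomes:
            outcomes[si] = classify_s2(cfg, state, si, dt=dt)
        return outcomes[si]

    grid = np.arange(si_range[0], si_range[1] + 1e-9, coarse)
    labels = [cls(s) for s in grid]
    uni = [k for k, l in enumerate(labels) if l == "unidirectional_block"]
    name = junction_name or "-".join(dict.fromkeys(cfg.node_regions()))
    if not uni:
        return VulnerableWindow(name, 0.0, 0.0, outcomes)
    # largest contiguous unidirectional run
    runs, start = [], uni[0]
    for a, b in zip(uni, uni[1:] + [None]):
        if b is None or b != a + 1:
            runs.append((start, a))
            start = b
    k0, k1 = max(runs, key=lambda r: r[1] - r[0])

    def bisect_edge(s_in, s_out):
        while abs(s_out - s_in) > resolution:
            mid = 0.5 * (s_in + s_out)
            if cls(mid) == "unidirectional_block":
                s_in = mid
            else:
                s_out = mid
        return s_in

    lower = grid[k0] if k0 == 0 else bisect_edge(grid[k0], grid[k0 - 1])
    upper = (grid[k1] if k1 == len(grid) - 1
             else bisect_edge(grid[k1], grid[k1 + 1]))
    return VulnerableWindow(name, float(lower), float(upper), outcomes)
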