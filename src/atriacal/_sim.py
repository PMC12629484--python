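"""Thin driver over the time-stepping kernels: events, recording, activation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k
from .cell_model import CellParams, IntegrationBlowupError, default_state

#: default integration step (ms)
DT = 0.01


@dataclass
class StimEvent:
    """One rectangular-pulse stimulus: positive amplitude = depolarising."""
    time: float            # ms
    amplitude: float       # pA/pF
    duration: float = 2.0  # ms
    lo: int = 0            # first node (inclusive)
    hi: int = 0            # last node (inclusive)


@dataclass
class SimResult:
    vrec: np.ndarray          # (n_samples, n_nodes) recorded Vm
    rec_dt: float             # sampling step of vrec (ms)
    t0: float                 # time of vrec[0]
    act_times: np.ndarray     # (n_nodes, max_act) -40 mV upstroke crossings
    act_counts: np.ndarray    # (n_nodes,) crossings recorded per node
    state: np.ndarray         # (n_nodes, 21) final state

    def activations_after(self, node: int, t: float) -> np.ndarray:
        a = self.act_times[node, : self.act_counts[node]]
        return a[a >= t]


def node_states(params: CellParams | list, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(state, eff) arrays for ``n`` nodes; ``params`` one CellParams or one per node."""
    Y = np.repeat(default_state()[None, :], n, axis=0)
    if isinstance(params, CellParams):
        eff = np.repeat(params.effective_vector()[None, :], n, axis=0)
    else:
        if len(params) != n:
            raise ValueError("need one CellParams per node")
        eff = np.stack([p.effective_vector() for p in params])
    return Y, eff


def _event_arrays(events):
    if not events:
        z = np.zeros(0)
        return z, z.copy(), z.copy(), np.zeros(0, np.int64), np.zeros(0, np.int64)
    ev = sorted(events, key=lambda e: e.time)
    return (np.array([e.time for e in ev]),
            np.array([e.duration for e in ev]),
            np.array([e.amplitude for e in ev]),
            np.array([e.lo for e in ev], dtype=np.int64),
            np.array([e.hi for e in ev], dtype=np.int64))


def run(Y: np.ndarray, eff: np.ndarray, events, duration: float, *,
        t0: float = 0.0, dt: float = DT, D: float = 0.0, dx: float = 1.0,
        rec_every: int = 0, max_act: int = 64) -> SimResult:
    """Advance ``Y`` in place for ``duration`` ms; see ``StimEvent`` for stimuli.

    ``rec_every`` > 0 records Vm every that many steps.  Raises
    ``IntegrationBlowupError`` if any node leaves the tabulated Vm range.
    """
    n = Y.shape[0]
    tb, sig, rlv = _k.tables_for(dt)
    nsteps = int(round(duration / dt))
    nrec = (nsteps + rec_every - 1) // rec_every if rec_every > 0 else 0
    vrec = np.empty((nrec, n))
    act_times = np.full((n, max_act), -1.0)
    act_counts = np.zeros(n, dtype=np.int64)
    evs = _event_arrays(events)
    status, node, nrec_done = _k.simulate_1d(
        Y, eff, tb, sig, rlv, dt, nsteps, t0, D, 1.0 / (dx * dx),
        *evs, rec_every, vrec, act_times, act_counts)
    if status != 0:
        raise IntegrationBlowupError(f"membrane potential diverged at node {node}")
    return SimResult(vrec[:nrec_done], dt * rec_every, t0, act_times, act_counts, Y)


def pacing_events(n_beats: int, bcl: float, amplitude: float, duration: float = 2.0,
                  lo: int = 0, hi: int = 0, t_first: float = 0.0) -> list[StimEvent]:
    return [StimEvent(t_first + k * bcl, amplitude, duration, lo, hi)
            for k in range(n_beats)]
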