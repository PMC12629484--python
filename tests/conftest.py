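import numpy as np
import pytest

from atriacal import cell_model as cm
from atriacal import cell_protocols as cp


@pytest.fixture(scope="session")
def wt_params():
    return cm.make_regional_params("RA", "WT")


@pytest.fixture(scope="session")
def relaxed_wt_state(wt_params):
    """WT state after 20 s of unpaced relaxation (near the resting fixed point)."""
    from atriacal._sim import node_states, run
    Y, eff = node_states(wt_params, 1)
    run(Y, eff, [], 20000.0)
    return Y[0].copy()


@pytest.fixture(scope="session")
def wt_steady_beat(wt_params):
    """(Trace, final state, captured) of the 50th paced WT beat at BCL 1000 ms."""
    return cp.pace_to_steady(wt_params, 1000.0)


# ---------------------------------------------------------------------------
# expensive strand/sheet computations shared by unit and acceptance tests

@pytest.fixture(scope="session")
def strand_bundle():
    """CV / ERP / WL and a conditioned snapshot for f in {0, 0.5, 1}."""
    from atriacal import tissue1d as t1
    from atriacal.fixtures import make_uniform_strand
    out = {}
    for f in (0.0, 0.5, 1.0):
        cfg = make_uniform_strand(variant="G490R", f=f)
        res, state = t1.condition_strand(cfg)
        cv = t1.measure_cv(res, cfg, after=0.0)
        erp = t1.measure_erp_strand(cfg, 1000.0, state=state)
        out[f] = {"cfg": cfg, "state": state, "CV_cm_per_s": cv,
                  "ERP_ms": erp, "WL_mm": cv / 100.0 * erp}
    return out


@pytest.fixture(scope="session")
def wt_cutoff_bcl(strand_bundle):
    from atriacal import tissue1d as t1
    _, cutoff = t1.strand_restitution(strand_bundle[0.0]["cfg"], "CV")
    return cutoff


@pytest.fixture(scope="session")
def ext_bundle(strand_bundle):
    """EXT at SI 700 ms for WT and f=1, plus the WT critical SI."""
    from atriacal import tissue1d as t1
    out = {}
    for f in (0.0, 1.0):
        b = strand_bundle[f]
        out[f] = t1.excitation_threshold(b["cfg"], 700.0, state=b["state"])
    out["critical_si_wt"] = t1.critical_si(strand_bundle[0.0]["cfg"])
    return out


@pytest.fixture(scope="session")
def vw_bundle():
    """Vulnerable-window widths at both junctions for f in {0, 0.5, 1}."""
    from atriacal import tissue1d as t1
    from atriacal.fixtures import make_junction_strand
    out = {}
    for junction in ("CT_PM", "LA_PV"):
        for f in (0.0, 0.5, 1.0):
            vw = t1.vulnerable_window(make_junction_strand(junction, f=f),
                                      junction_name=junction)
            out[(junction, f)] = vw
    return out


@pytest.fixture(scope="session")
def sheet_bundle():
    """Desk-scale re-entry runs: the study's 100 x 100 mm sheet at a reduced
    150 x 150 grid, 3 s, for wild type and the homozygous condition."""
    from atriacal.tissue2d import SheetConfig, reentry_metrics, run_sheet_s1s2
    out = {}
    for f in (1.0, 0.0):
        cfg = SheetConfig(nx=150, ny=150, dx=100.0 / 150.0, duration=3000.0,
                          dt=0.025, variant="G490R", f=f)
        res = run_sheet_s1s2(cfg)
        out[f] = {"result": res, "metrics": reentry_metrics(res)}
    return out


def trapezoid_trace(dt=0.05, rmp=-80.0, peak=20.0, upstroke_ms=1.0,
                    plateau_ms=100.0, repol_ms=120.0, total_ms=500.0,
                    stim_at=10.0):
    """Synthetic AP with known geometry for biomarker closed-form checks."""
    t = np.arange(0.0, total_ms, dt)
    v = np.full_like(t, rmp)
    t0 = stim_at
    up = (t >= t0) & (t < t0 + upstroke_ms)
    v[up] = rmp + (peak - rmp) * (t[up] - t0) / upstroke_ms
    plat = (t >= t0 + upstroke_ms) & (t < t0 + upstroke_ms + plateau_ms)
    v[plat] = peak
    rep = ((t >= t0 + upstroke_ms + plateau_ms)
           & (t < t0 + upstroke_ms + plateau_ms + repol_ms))
    v[rep] = peak + (rmp - peak) * (t[rep] - (t0 + upstroke_ms + plateau_ms)) / repol_ms
    return cp.Trace(dt, v, t0=0.0, stim_times=(stim_at,))
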