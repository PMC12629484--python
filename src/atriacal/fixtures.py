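"""Synthetic inputs: region-labelled meshes, analytic test fields, canned configs.

These stand in for inputs that are not distributed with the study this
pipeline reproduces (anatomical geometry, experimental clamp recordings):
uniform and junction strands, analytic rigid rotors for validating the
phase-singularity tracker, and one canned configuration per headline
experiment.  Everything here is deterministic given its arguments.
"""

from __future__ import annotations

import numpy as np

from .cell_model import ConfigurationError, REGIONS
from .tissue1d import StrandConfig

JUNCTIONS = {"CT_PM": ("CT", "PM"), "LA_PV": ("LA", "PV")}


def make_uniform_strand(region: str = "RA", n: int = 100, dx: float = 0.25,
                        D: float = 0.21, variant: str = "WT",
                        f: float = 0.0) -> StrandConfig:
    """All-nodes-one-region strand with the default end electrode."""
    if region not in REGIONS:
        raise ConfigurationError(f"unknown atrial region {region!r}")
    return StrandConfig(n_nodes=n, dx=dx, D=D, regions=(region,),
                        variant=variant, f=f)


def make_junction_strand(junction: str, variant: str = "G490R",
                         f: float = 0.0, n: int = 100) -> StrandConfig:
    """Two-region strand (half/half) with the S2 electrode spanning the junction.

    ``junction`` is ``CT_PM`` (crista terminalis / pectinate muscle) or
    ``LA_PV`` (left atrium / pulmonary vein).  S1 paces the first-region end;
    S2 covers the six nodes straddling the mid-strand junction.
    """
    if junction not in JUNCTIONS:
        raise ConfigurationError(f"unknown junction {junction!r}; "
                                 f"expected one of {tuple(JUNCTIONS)}")
    a, b = JUNCTIONS[junction]
    half = n // 2
    regions = tuple([a] * half + [b] * (n - half))
    return StrandConfig(n_nodes=n, regions=regions, variant=variant, f=f,
                        s2_lo=half - 3, s2_hi=half + 2)


def make_analytic_rotor(ny: int = 60, nx: int = 60, dx: float = 0.25,
                        omega: float = 2.0 * np.pi * 5e-3,
                        core: tuple | None = None, n_frames: int = 200,
                        frame_dt: float = 1.0, v0: float = -30.0,
                        amp: float = 50.0, chirality: int = 1) -> dict:
    """Rigid-rotor test movie: Vm(x, y, t) = v0 + amp*cos(theta - chirality*omega*t).

    ``omega`` is in rad/ms.  The default amplitude spans -80..+20 mV so that
    threshold-based operators are exercised.  Returns a dict with ``frames``
    (n_frames, ny, nx), ``frame_dt``, ``dx`` and the core position (mm).
    """
    if omega <= 0:
        raise ValueError("omega must be positive")
    if core is None:
        core = ((nx - 1) * dx / 2.0, (ny - 1) * dx / 2.0)
    xc, yc = core
    if not (0 <= xc <= (nx - 1) * dx and 0 <= yc <= (ny - 1) * dx):
        raise ValueError("rotor core outside the grid")
    x = dx * np.arange(nx)
    y = dx * np.arange(ny)
    th = np.arctan2(y[:, None] - yc, x[None, :] - xc)
    t = frame_dt * np.arange(n_frames)
    frames = v0 + amp * np.cos(th[None, :, :] - chirality * omega * t[:, None, None])
    return {"frames": frames.astype(np.float32), "frame_dt": frame_dt,
            "dx": dx, "core": (xc, yc), "omega": omega}


def make_protocol_suite() -> dict:
    """Canned configuration per headline experiment (see ``cli_io.run_experiment``)."""
    suite = {}
    for name, f in [("wt", 0.0), ("f02", 0.2), ("f04", 0.4), ("f05", 0.5),
                    ("f06", 0.6), ("f08", 0.8), ("f1", 1.0)]:
        suite[f"biomarkers_{name}"] = {
            "id": f"biomarkers_{name}", "kind": "cell_biomarkers",
            "params": {"variant": "G490R", "f": f, "bcl": 1000.0}}
    suite["clamp_iv_all"] = {"id": "clamp_iv_all", "kind": "clamp_iv", "params": {}}
    suite["strand_cv_wt"] = {"id": "strand_cv_wt", "kind": "strand_cv",
                             "params": {"f": 0.0, "bcl": 1000.0}}
    for name, f in [("wt", 0.0), ("f05", 0.5), ("f1", 1.0)]:
        suite[f"wavelength_{name}"] = {
            "id": f"wavelength_{name}", "kind": "strand_wavelength",
            "params": {"variant": "G490R", "f": f, "bcl": 1000.0}}
        for j in ("CT_PM", "LA_PV"):
            suite[f"vw_{j.lower()}_{name}"] = {
                "id": f"vw_{j.lower()}_{name}", "kind": "strand_vw",
                "params": {"junction": j, "variant": "G490R", "f": f}}
    suite["strand_cutoff_wt"] = {"id": "strand_cutoff_wt",
                                 "kind": "strand_cutoff", "params": {"f": 0.0}}
    suite["ext_si700_wt"] = {"id": "ext_si700_wt", "kind": "strand_ext",
                             "params": {"f": 0.0, "si": 700.0}}
    suite["critical_si_wt"] = {"id": "critical_si_wt", "kind": "strand_critical_si",
                               "params": {"f": 0.0}}
    for name, f in [("wt", 0.0), ("f1", 1.0)]:
        suite[f"sheet_reentry_{name}"] = {
            "id": f"sheet_reentry_{name}", "kind": "sheet_reentry",
            "params": {"variant": "G490R", "f": f, "nx": 150, "ny": 150,
                       "dx": 100.0 / 150.0, "duration": 3000.0, "dt": 0.025}}
    return suite
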