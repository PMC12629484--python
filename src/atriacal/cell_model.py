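"""Human atrial ionic model: parameters, state, currents, single-cell stepping.

The base model is CRN (Courtemanche-Ramirez-Nattel) with Maleckar Ito
kinetics and a fixed 2-ms Ca-dependent inactivation time constant for I_CaL.
Loss-of-function L-type channel variants are represented as a conductance
mixture: a fraction ``f`` of channels carries the mutant relative conductance
``s_mut`` and the remainder is wild type, with all gating shared::

    ICaL' = (1 - f) * ICaL_WT + f * s_mut * ICaL_WT
          = [(1 - f) + f * s_mut] * gCaL * d * h * hCa * (Vm - ECa)

``f = 0`` is wild type, ``f = 0.5`` the conventional heterozygous assumption
and ``f = 1`` homozygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _model
from ._model import (MANIFEST, N_EFF, N_STATE, initial_state,
                     manifest_checksum)

REGIONS = tuple(MANIFEST["regional_scalings"].keys())
VARIANTS = tuple(MANIFEST["variants"].keys())

_SCALING_KEYS = ("g_Na", "g_K1", "g_to", "g_Kur", "g_Kr", "g_Ks", "g_CaL")

CURRENT_NAMES = ("ICaL", "INa", "IK1", "Ito", "IKur", "IKr", "IKs",
                 "INaCa", "INaK", "IbNa", "IbCa", "IpCa")


class ConfigurationError(ValueError):
    """Unknown region/variant or otherwise invalid model configuration."""


class IntegrationBlowupError(RuntimeError):
    """Non-finite state encountered during time stepping."""


@dataclass(frozen=True)
class IcalParams:
    """Parameters of the mixed wild-type/mutant L-type Ca current."""

    gCaL_WT: float = _model.G_CAL   # nS/pF
    s_mut: float = 1.0              # mutant conductance relative to WT, [0, 1]
    f: float = 0.0                  # mutant mixing fraction, [0, 1]
    ECa: float = _model.E_CA_L      # mV (fixed base-model reversal)
    tau_hCa: float = _model.TAU_HCA # ms

    def __post_init__(self):
        if not 0.0 <= self.f <= 1.0:
            raise ConfigurationError(f"mixing fraction f={self.f} outside [0, 1]")
        if not 0.0 <= self.s_mut <= 1.0:
            raise ConfigurationError(f"s_mut={self.s_mut} outside [0, 1]")

    @property
    def conductance_factor(self) -> float:
        """Single scale equivalent of the mixture: (1-f) + f*s_mut."""
        return (1.0 - self.f) + self.f * self.s_mut


@dataclass(frozen=True)
class CellParams:
    """Fully resolved cell parameters: region scalings plus the I_CaL mixture."""

    region: str = "RA"
    ical: IcalParams = field(default_factory=IcalParams)
    Cm: float = _model.CM
    regional_scalings: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ConfigurationError(f"unknown atrial region {self.region!r}; "
                                     f"expected one of {REGIONS}")
        if not self.regional_scalings:
            object.__setattr__(self, "regional_scalings",
                               dict(MANIFEST["regional_scalings"][self.region]))

    def effective_vector(self) -> np.ndarray:
        """Length-12 effective parameter vector consumed by the kernels."""
        s = self.regional_scalings
        eff = np.empty(N_EFF)
        eff[0] = _model.G_NA * s["g_Na"]
        eff[1] = _model.G_K1 * s["g_K1"]
        eff[2] = _model.G_TO * s["g_to"]
        eff[3] = s["g_Kur"]            # scale on the V-dependent gKur(V)
        eff[4] = _model.G_KR * s["g_Kr"]
        eff[5] = _model.G_KS * s["g_Ks"]
        eff[6] = self.ical.gCaL_WT * s["g_CaL"] * self.ical.conductance_factor
        eff[7] = _model.G_BCA
        eff[8] = _model.G_BNA
        eff[9] = _model.I_NAK_MAX
        eff[10] = _model.I_NACA_MAX
        eff[11] = _model.I_PCA_MAX
        return eff


#: names of the 21 state variables, in vector order
STATE_NAMES = ("Vm", "m", "h", "j", "r", "s", "ua", "ui", "xr", "xs", "d", "f",
               "hCa", "u", "v", "w", "Na_i", "K_i", "Ca_i", "Ca_up", "Ca_rel")

_GATE_SLICE = slice(1, 16)


def default_state() -> np.ndarray:
    """Published base-model initial state (pace to steady state before use)."""
    return initial_state()


def validate_state(y: np.ndarray) -> None:
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},)")
    gates = y[_GATE_SLICE]
    if np.any(gates < -1e-9) or np.any(gates > 1.0 + 1e-9):
        raise ValueError("gating variables outside [0, 1]")
    if np.any(y[16:] <= 0):
        raise ValueError("non-positive intracellular concentration")


def compute_ical(state: np.ndarray, p: IcalParams) -> float:
    """Mixed WT/mutant L-type Ca current density (pA/pF) at the given state.

    Gating variables are shared by the WT and mutant populations; the
    mutation only rescales the maximal conductance.
    """
    validate_state(state)
    Vm, d, f_gate, hCa = state[0], state[10], state[11], state[12]
    wt = p.gCaL_WT * d * f_gate * hCa * (Vm - p.ECa)
    return (1.0 - p.f) * wt + p.f * p.s_mut * wt


def compute_currents(state: np.ndarray, p: CellParams) -> dict:
    """All current densities (pA/pF) with regional scalings applied.

    Returns a dict of the 12 component currents plus ``Iion_tot``.
    """
    validate_state(state)
    out = np.empty(18)
    _model.compute_currents_arr(state, p.effective_vector(), out)
    cur = {name: float(out[k]) for k, name in enumerate(CURRENT_NAMES)}
    cur["Iion_tot"] = float(out[12])
    return cur


def step_cell(state: np.ndarray, Ist: float, dt: float, p: CellParams) -> np.ndarray:
    """Advance one node by one forward-Euler/Rush-Larsen step.

    ``Ist`` is a positive depolarising stimulus magnitude (pA/pF); zero when
    unstimulated.  Returns a new state array.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = state.copy()
    try:
        _model.step_rl(y, p.effective_vector(), Ist, dt)
    except (ZeroDivisionError, OverflowError, FloatingPointError) as exc:
        raise IntegrationBlowupError(f"state diverged during the step: {exc}")
    if not np.all(np.isfinite(y)):
        bad = int(np.flatnonzero(~np.isfinite(y))[0])
        raise IntegrationBlowupError(
            f"non-finite state variable {STATE_NAMES[bad]!r} after step")
    return y


def make_regional_params(region: str, variant: str = "WT", f: float = 0.0,
                         s_mut: float | None = None) -> CellParams:
    """Cell parameters for an atrial region and an L-type channel variant.

    ``variant`` sets the mutant relative conductance (G490R 0.07, A39V exon 8A
    0.13, A39V exon 8 0.20); ``"custom"`` uses the supplied ``s_mut``.  The WT
    variant forces ``f = 0``.
    """
    if region not in REGIONS:
        raise ConfigurationError(f"unknown atrial region {region!r}")
    if variant == "custom":
        if s_mut is None:
            raise ConfigurationError("variant 'custom' requires s_mut")
        smut = float(s_mut)
    elif variant in VARIANTS:
        vinfo = MANIFEST["variants"][variant]
        smut = float(vinfo["s_mut"])
        if vinfo["forces_f_zero"]:
            f = 0.0
    else:
        raise ConfigurationError(f"unknown variant {variant!r}")
    return CellParams(region=region, ical=IcalParams(s_mut=smut, f=float(f)))


def with_mixture(p: CellParams, f: float, s_mut: float | None = None) -> CellParams:
    """Copy of ``p`` with a different I_CaL mixing fraction (and optionally s_mut)."""
    ical = replace(p.ical, f=float(f),
                   **({} if s_mut is None else {"s_mut": float(s_mut)}))
    return replace(p, ical=ical)
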