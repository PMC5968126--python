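"""Membrane kinetics of atrial myocytes and fibroblasts.

The myocyte is the Courtemanche-Ramirez-Nattel (CRN) human atrial model with
regional multiplicative factors on the maximum conductances of I_to, I_CaL
and I_Kr (eleven labelled atrial regions); the fibroblast is the active
MacCannell model with four membrane currents (I_Kv, I_K1, I_NaK, I_b,Na).

Single-cell pacing uses a rectangular 2 ms stimulus at twice the diastolic
threshold (found by bisection); gates are integrated with Rush-Larsen,
concentrations with forward Euler, dt = 0.02 ms by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .constants import (CRN_STATE_NAMES, MACCANNELL, N_STATE, REGION_TABLE,
                        crn_initial_state, region_factors)

CURRENT_NAMES = ("I_Na", "I_K1", "I_to", "I_Kur", "I_Kr", "I_Ks", "I_CaL",
                 "I_pCa", "I_NaK", "I_NaCa", "I_bNa", "I_bCa")
FIB_CURRENT_NAMES = ("I_Kv", "I_K1", "I_NaK", "I_bNa")

DEFAULT_DT = 0.02          # ms
STIM_DURATION = 2.0        # ms
GATE_SLOTS = slice(1, 16)  # gating variables within the state vector


class NoCaptureError(RuntimeError):
    """Raised when a stimulus fails to elicit an action potential."""


class NoActionPotentialError(ValueError):
    """Raised when a voltage trace contains no upstroke."""


@dataclass(frozen=True)
class MyocyteParams:
    """Regional CRN variant: conductance factors for I_to, I_CaL, I_Kr."""

    region_id: str = "LA"
    f_gto: float = 1.0
    f_gCaL: float = 1.0
    f_gKr: float = 1.0
    Cm: float = 100.0  # pF

    @classmethod
    def from_region(cls, region: str) -> "MyocyteParams":
        if region not in REGION_TABLE:
            raise KeyError(f"unknown atrial region {region!r}")
        fto, fcal, fkr = region_factors(region)
        return cls(region_id=region, f_gto=fto, f_gCaL=fcal, f_gKr=fkr)

    def __post_init__(self):
        if min(self.f_gto, self.f_gCaL, self.f_gKr) <= 0:
            raise ValueError("conductance factors must be positive")


@dataclass(frozen=True)
class FibroblastParams:
    """MacCannell active fibroblast: four currents, fixed concentrations."""

    g_Kv: float = MACCANNELL["g_Kv"]
    g_K1: float = MACCANNELL["g_K1"]
    I_NaK_max: float = MACCANNELL["I_NaK_max"]
    g_bNa: float = MACCANNELL["g_bNa"]
    Cm_fb: float = MACCANNELL["Cm_fb"]
    E_K: float = _kernels.FIB_EK
    E_Na: float = _kernels.FIB_ENA

    @property
    def n_currents(self) -> int:
        return 4


@dataclass
class CellState:
    """Instantaneous membrane state (voltage, gates, concentrations)."""

    vector: np.ndarray = field(default_factory=crn_initial_state)
    t: float = 0.0

    @property
    def V(self) -> float:
        return float(self.vector[0])

    @property
    def gates(self) -> np.ndarray:
        return self.vector[GATE_SLOTS]

    @property
    def concentrations(self) -> np.ndarray:
        return self.vector[16:]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(CRN_STATE_NAMES, map(float, self.vector)))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise FloatingPointError("non-finite cell state (numerical divergence)")


@dataclass(frozen=True)
class APMetrics:
    """Action-potential summary: RMP, peak, amplitude, APD90/APD50."""

    RMP: float
    peak: float
    amplitude: float
    APD90: float
    APD50: float


def fibroblast_initial_state() -> np.ndarray:
    """Fibroblast state column: V plus its two I_Kv gates (r, s slots)."""
    s = np.zeros(N_STATE)
    s[0] = -49.6
    s[1] = 0.0  # r
    s[2] = 1.0  # s
    return s


# ----------------------------------------------------------------- currents
def myocyte_ionic_current(state: CellState, params: MyocyteParams):
    """Total ionic current density (pA/pF) and the 12 individual currents."""
    state.validate()
    S = np.ascontiguousarray(state.vector.reshape(N_STATE, 1))
    cur = _kernels.crn_currents(S, 0, params.f_gto, params.f_gCaL, params.f_gKr)
    currents = dict(zip(CURRENT_NAMES, map(float, cur)))
    return sum(currents.values()), currents


def fibroblast_ionic_current(state: CellState, params: FibroblastParams = FibroblastParams()):
    """Total fibroblast current density (pA/pF) and the 4 individual currents."""
    state.validate()
    v = state.vector
    cur = _kernels.fib_currents(float(v[0]), float(v[1]), float(v[2]))
    currents = dict(zip(FIB_CURRENT_NAMES, map(float, cur)))
    return sum(currents.values()), currents


def fibroblast_resting_potential(tol: float = 1e-10) -> float:
    """Steady-state fibroblast RMP by root-finding on the total current.

    The gates are set to their voltage steady state, so the root of
    I_Kv + I_K1 + I_NaK + I_b,Na is the true equilibrium of the model.
    """
    def total(V):
        rinf = 1.0 / (1.0 + np.exp(-(V + 20.0) / 11.0))
        sinf = 1.0 / (1.0 + np.exp((V + 23.0) / 2.7))
        return sum(_kernels.fib_currents(V, rinf, sinf))

    # bracket below the N-shaped region of the I-V curve: the stable
    # equilibrium sits near -50 mV, additional crossings exist above -45 mV
    return brentq(total, -90.0, -40.0, xtol=tol)


# ------------------------------------------------------------------- pacing
def pace_single_cell(params: MyocyteParams, bcl: float = 500.0,
                     n_beats: int = 20, dt: float = DEFAULT_DT,
                     stim_amp: float | None = None,
                     state: np.ndarray | None = None):
    """Pace a myocyte for ``n_beats`` and return (t, V) of the final beat.

    The stimulus is rectangular, 2 ms, at ``stim_amp`` pA/pF (default: twice
    the diastolic threshold found by bisection).  Raises
    :class:`NoCaptureError` if the final beat fails to reach 0 mV.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if bcl <= 0 or dt <= 0:
        raise ValueError("bcl and dt must be positive")
    if stim_amp is None:
        stim_amp = 2.0 * diastolic_threshold(params, dt=dt)
    S = np.ascontiguousarray(
        (state if state is not None else crn_initial_state()).reshape(N_STATE, 1)
    ).astype(np.float64)
    steps_per_beat = int(round(bcl / dt))
    if n_beats > 1:
        _kernels.integrate_myocyte(S, dt, steps_per_beat * (n_beats - 1), bcl,
                                   stim_amp, STIM_DURATION,
                                   params.f_gto, params.f_gCaL, params.f_gKr,
                                   np.empty(0), 1, 0.0)
    Vout = np.empty(steps_per_beat)
    _kernels.integrate_myocyte(S, dt, steps_per_beat, bcl, stim_amp,
                               STIM_DURATION,
                               params.f_gto, params.f_gCaL, params.f_gKr,
                               Vout, 1, 0.0)
    t = np.arange(steps_per_beat) * dt
    if Vout.max() < 0.0:
        raise NoCaptureError(
            f"no capture: peak {Vout.max():.1f} mV < 0 mV "
            f"(stim {stim_amp:.2f} pA/pF)")
    return t, Vout, S


def diastolic_threshold(params: MyocyteParams, dt: float = DEFAULT_DT,
                        tol: float = 0.25) -> float:
    """Minimum 2 ms rectangular stimulus density eliciting an AP (bisection)."""
    base = np.ascontiguousarray(crn_initial_state().reshape(N_STATE, 1))

    def captures(amp: float) -> bool:
        S = base.copy()
        n = int(round(100.0 / dt))  # 100 ms observation window
        Vout = np.empty(n)
        _kernels.integrate_myocyte(S, dt, n, 1e9, amp, STIM_DURATION,
                                   params.f_gto, params.f_gCaL, params.f_gKr,
                                   Vout, 1, 0.0)
        return Vout.max() > 0.0

    lo, hi = 0.0, 8.0
    while not captures(hi):
        hi *= 2.0
        if hi > 512.0:
            raise NoCaptureError("cell inexcitable: no threshold below 512 pA/pF")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ------------------------------------------------------------------ metrics
def compute_ap_metrics(t: np.ndarray, V: np.ndarray) -> APMetrics:
    """AP metrics from a single-upstroke voltage trace.

    RMP is the pre-stimulus (pre-upstroke) plateau; APDx runs from the time
    of maximum dV/dt to recovery to RMP + (1 - x/100) * amplitude.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.shape != V.shape or t.size < 5:
        raise ValueError("t and V must be equal-length vectors")
    dV = np.gradient(V, t)
    i_up = int(np.argmax(dV))
    if dV[i_up] <= 1.0 or V.max() - V.min() < 10.0:
        raise NoActionPotentialError("trace contains no upstroke")
    # pre-stimulus plateau: median of the samples before the upstroke foot,
    # falling back to the initial sample for traces that start at the stimulus
    pre = V[: max(i_up - int(0.05 * V.size), 1)]
    RMP = float(np.median(pre)) if pre.size else float(V[0])
    peak = float(V.max())
    amplitude = peak - RMP
    apd = {}
    for frac in (0.90, 0.50):
        level = RMP + (1.0 - frac) * amplitude
        i_peak = int(np.argmax(V))
        below = np.nonzero(V[i_peak:] <= level)[0]
        if below.size == 0:
            apd[frac] = float(t[-1] - t[i_up])  # never repolarized in window
        else:
            k = i_peak + below[0]
            # linear interpolation of the crossing
            if k > 0 and V[k - 1] != V[k]:
                tc = t[k - 1] + (level - V[k - 1]) * (t[k] - t[k - 1]) / (V[k] - V[k - 1])
            else:
                tc = t[k]
            apd[frac] = float(tc - t[i_up])
    return APMetrics(RMP=RMP, peak=peak, amplitude=amplitude,
                     APD90=apd[0.90], APD50=apd[0.50])


def save_trace(path, t, V) -> None:
    np.savetxt(path, np.column_stack([t, V]), fmt="%.6g",
               delimiter=",", header="t_ms,V_mV", comments="")


def load_trace(path):
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return arr[:, 0], arr[:, 1]
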