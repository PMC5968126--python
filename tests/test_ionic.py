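"""Membrane-model tests: regional scaling, equilibria, AP metrics, gates."""

import math

import numpy as np
import pytest

from fibrofocal import _kernels, ionic
from fibrofocal.constants import (CRN, N_STATE, REGION_TABLE,
                                  crn_initial_state, region_factors)

# --------------------------------------------------------------------------
# Independent transcription of the CRN current equations (oracle).  Written
# directly from the published formulation, structured differently from the
# implementation on purpose: plain dict of closures over a state dict.
# --------------------------------------------------------------------------
RTF = CRN["R"] * CRN["T"] / CRN["F"]


def oracle_crn_currents(s: dict) -> dict:
    V, Nai, Ki, Cai = s["V"], s["Na_i"], s["K_i"], s["Ca_i"]
    ENa = RTF * math.log(CRN["Na_o"] / Nai)
    EK = RTF * math.log(CRN["K_o"] / Ki)
    ECa = RTF / 2 * math.log(CRN["Ca_o"] / Cai)
    out = {}
    out["I_Na"] = CRN["g_Na"] * s["m"] ** 3 * s["h"] * s["j"] * (V - ENa)
    out["I_K1"] = CRN["g_K1"] * (V - EK) / (1 + math.exp(0.07 * (V + 80)))
    out["I_to"] = CRN["g_to"] * s["oa"] ** 3 * s["oi"] * (V - EK)
    out["I_Kur"] = ((0.005 + 0.05 / (1 + math.exp((15 - V) / 13)))
                    * s["ua"] ** 3 * s["ui"] * (V - EK))
    out["I_Kr"] = (CRN["g_Kr"] * s["xr"] * (V - EK)
                   / (1 + math.exp((V + 15) / 22.4)))
    out["I_Ks"] = CRN["g_Ks"] * s["xs"] ** 2 * (V - EK)
    out["I_CaL"] = CRN["g_CaL"] * s["d"] * s["f"] * s["fCa"] * (V - 65)
    out["I_pCa"] = CRN["I_pCa_max"] * Cai / (0.0005 + Cai)
    sig = (math.exp(CRN["Na_o"] / 67.3) - 1) / 7
    f_nak = 1 / (1 + 0.1245 * math.exp(-0.1 * V / RTF)
                 + 0.0365 * sig * math.exp(-V / RTF))
    out["I_NaK"] = (CRN["I_NaK_max"] * f_nak
                    * (1 / (1 + (CRN["K_mNai"] / Nai) ** 1.5))
                    * CRN["K_o"] / (CRN["K_o"] + CRN["K_mKo"]))
    g, ks = CRN["gamma"], CRN["k_sat"]
    num = (math.exp(g * V / RTF) * Nai ** 3 * CRN["Ca_o"]
           - math.exp((g - 1) * V / RTF) * CRN["Na_o"] ** 3 * Cai)
    den = ((CRN["K_mNa"] ** 3 + CRN["Na_o"] ** 3) * (CRN["K_mCa"] + CRN["Ca_o"])
           * (1 + ks * math.exp((g - 1) * V / RTF)))
    out["I_NaCa"] = CRN["I_NaCa_max"] * num / den
    out["I_bNa"] = CRN["g_bNa"] * (V - ENa)
    out["I_bCa"] = CRN["g_bCa"] * (V - ECa)
    return out


CLAMP_VOLTAGES = (-80.0, -60.0, -40.0, 0.0, 30.0)


@pytest.mark.parametrize("vm", CLAMP_VOLTAGES)
def test_crn_currents_match_independent_oracle(vm):
    """With unit factors the model equals the base formulation, current by
    current, at clamped voltages."""
    state = ionic.CellState()
    state.vector[0] = vm
    _, ours = ionic.myocyte_ionic_current(
        state, ionic.MyocyteParams(region_id="RA"))
    ref = oracle_crn_currents(state.as_dict())
    for name in ours:
        assert ours[name] == pytest.approx(ref[name], rel=1e-9, abs=1e-12), name


def test_resting_equilibrium_holds():
    """Zero net current at rest: V drifts < 0.1 mV over 1000 ms unpaced."""
    S = np.ascontiguousarray(crn_initial_state().reshape(N_STATE, 1))
    v0 = S[0, 0]
    _kernels.integrate_myocyte(S, 0.02, 50000, 1e9, 0.0, 0.0,
                               1.0, 1.0, 1.0, np.empty(0), 1, 0.0)
    assert abs(S[0, 0] - v0) < 0.1


def test_regional_factor_scales_named_current_only():
    """RAA (f_gto 0.68) scales I_to by exactly 0.68 relative to RA; MVR
    (f_gKr 2.44) scales I_Kr by 2.44; other currents are untouched."""
    state = ionic.CellState()
    state.vector[0] = -20.0  # active range
    _, base = ionic.myocyte_ionic_current(state, ionic.MyocyteParams.from_region("RA"))
    _, raa = ionic.myocyte_ionic_current(state, ionic.MyocyteParams.from_region("RAA"))
    assert raa["I_to"] == pytest.approx(0.68 * base["I_to"], rel=1e-12)
    _, mvr = ionic.myocyte_ionic_current(state, ionic.MyocyteParams.from_region("MVR"))
    assert mvr["I_Kr"] == pytest.approx(2.44 * base["I_Kr"], rel=1e-12)
    assert mvr["I_Na"] == pytest.approx(base["I_Na"], rel=1e-12)
    assert raa["I_Ks"] == pytest.approx(base["I_Ks"], rel=1e-12)


def test_region_table_has_eleven_labelled_columns():
    assert len(REGION_TABLE) == 11
    for name, row in REGION_TABLE.items():
        fto, fcal, fkr = region_factors(name)
        assert min(fto, fcal, fkr) > 0


def test_gates_stay_in_unit_interval_during_pacing(la_params):
    """Rush-Larsen keeps every gating variable in [0,1] while pacing."""
    S = np.ascontiguousarray(crn_initial_state().reshape(N_STATE, 1))
    for _ in range(40):  # 40 x 250 ms = 10 s in chunks, checking each chunk
        _kernels.integrate_myocyte(S, 0.05, 5000, 500.0, 22.0, 2.0,
                                   la_params.f_gto, la_params.f_gCaL,
                                   la_params.f_gKr, np.empty(0), 1, 0.0)
        gates = S[1:16, 0]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)


def test_doubling_gkr_shortens_apd(la_params):
    """I_Kr is repolarizing: doubling its conductance strictly decreases
    APD90 at BCL 500 ms."""
    t, v, _ = ionic.pace_single_cell(la_params, bcl=500.0, n_beats=5,
                                     stim_amp=22.0)
    base = ionic.compute_ap_metrics(t, v).APD90
    fast = ionic.MyocyteParams(region_id="LAx", f_gto=la_params.f_gto,
                               f_gCaL=la_params.f_gCaL,
                               f_gKr=2 * la_params.f_gKr)
    t, v, _ = ionic.pace_single_cell(fast, bcl=500.0, n_beats=5, stim_amp=22.0)
    assert ionic.compute_ap_metrics(t, v).APD90 < base


def test_accommodation_between_first_and_twentieth_beat(la_params):
    t, v1, _ = ionic.pace_single_cell(la_params, bcl=500.0, n_beats=1,
                                      stim_amp=22.0)
    t, v20, _ = ionic.pace_single_cell(la_params, bcl=500.0, n_beats=20,
                                       stim_amp=22.0)
    a1 = ionic.compute_ap_metrics(t, v1).APD90
    a20 = ionic.compute_ap_metrics(t, v20).APD90
    assert np.isfinite(a1) and np.isfinite(a20) and a1 != a20


# ------------------------------------------------------------- fibroblast
def test_fibroblast_has_exactly_four_currents():
    state = ionic.CellState(vector=ionic.fibroblast_initial_state())
    total, cur = ionic.fibroblast_ionic_current(state)
    assert set(cur) == {"I_Kv", "I_K1", "I_NaK", "I_bNa"}
    assert total == pytest.approx(sum(cur.values()))


def test_fibroblast_ikv_vanishes_at_k_reversal():
    params = ionic.FibroblastParams()
    state = ionic.CellState(vector=ionic.fibroblast_initial_state())
    state.vector[0] = params.E_K
    state.vector[1] = 0.5
    state.vector[2] = 0.5
    _, cur = ionic.fibroblast_ionic_current(state)
    assert cur["I_Kv"] == pytest.approx(0.0, abs=1e-12)


def test_fibroblast_rests_above_myocyte():
    """Fibroblasts have a much higher (less negative) RMP than myocytes."""
    fib_rmp = ionic.fibroblast_resting_potential()
    myo_rmp = crn_initial_state()[0]
    assert fib_rmp > myo_rmp + 20.0
    assert -55.0 < fib_rmp < -40.0  # regression: root of the 4-current system


def test_fibroblast_rmp_is_a_stable_equilibrium():
    """Integrating the fibroblast from its root-found RMP stays put."""
    rmp = ionic.fibroblast_resting_potential()
    S = np.zeros((N_STATE, 1))
    S[0, 0] = rmp
    S[1, 0] = 1.0 / (1.0 + math.exp(-(rmp + 20.0) / 11.0))
    S[2, 0] = 1.0 / (1.0 + math.exp((rmp + 23.0) / 2.7))
    _kernels.integrate_fibroblast(S, 0.02, 50000, 0.0, 1.0)
    assert S[0, 0] == pytest.approx(rmp, abs=0.5)


# ---------------------------------------------------------------- metrics
def test_square_pulse_metrics_are_exact():
    t = np.arange(0.0, 200.0, 0.1)
    v = np.where((t >= 50.0) & (t < 150.0), 0.0, -80.0)
    m = ionic.compute_ap_metrics(t, v)
    assert m.amplitude == pytest.approx(80.0, abs=1e-6)
    assert m.APD90 == pytest.approx(100.0, abs=0.2)
    assert m.APD50 == pytest.approx(100.0, abs=0.2)
    assert m.amplitude == pytest.approx(m.peak - m.RMP)


def test_flat_trace_raises_no_ap():
    t = np.arange(0.0, 100.0, 0.1)
    with pytest.raises(ionic.NoActionPotentialError):
        ionic.compute_ap_metrics(t, np.full_like(t, -80.0))


def test_apd50_never_exceeds_apd90(la_params):
    t, v, _ = ionic.pace_single_cell(la_params, bcl=500.0, n_beats=2,
                                     stim_amp=22.0)
    m = ionic.compute_ap_metrics(t, v)
    assert m.APD50 <= m.APD90


def test_subthreshold_stimulus_raises_no_capture(la_params):
    with pytest.raises(ionic.NoCaptureError):
        ionic.pace_single_cell(la_params, bcl=500.0, n_beats=1, stim_amp=0.5)


def test_nonfinite_state_is_rejected(la_params):
    state = ionic.CellState()
    state.vector[0] = np.nan
    with pytest.raises(FloatingPointError):
        ionic.myocyte_ionic_current(state, la_params)


def test_trace_roundtrip(tmp_path, la_params):
    t, v, _ = ionic.pace_single_cell(la_params, bcl=500.0, n_beats=1,
                                     stim_amp=22.0)
    path = tmp_path / "trace.csv"
    ionic.save_trace(path, t, v)
    t2, v2 = ionic.load_trace(path)
    assert np.allclose(t2, t, atol=1e-4) and np.allclose(v2, v, atol=1e-3)
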