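"""Numba kernels for the myocyte/fibroblast membrane models and tissue stepping.

State layout (one column per cell, see :mod:`fibrofocal.constants`):
``V, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fCa, u, v, w, Na_i, K_i, Ca_i,
Ca_up, Ca_rel``.  Fibroblast cells store their two I_Kv gates (r, s) in the
``m`` and ``h`` slots and leave the rest untouched.

All currents are densities in pA/pF (numerically mV/ms), gates integrated
with the Rush-Larsen exponential scheme, concentrations with forward Euler.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .constants import CRN, MACCANNELL, LABEL_FIBROBLAST, LABEL_NONCONDUCTING

# ---------------------------------------------------------------- constants
_R = CRN["R"]
_T = CRN["T"]
_F = CRN["F"]
_RTF = _R * _T / _F
_Nao = CRN["Na_o"]
_Ko = CRN["K_o"]
_Cao = CRN["Ca_o"]
_gNa = CRN["g_Na"]
_gK1 = CRN["g_K1"]
_gto = CRN["g_to"]
_gKr = CRN["g_Kr"]
_gKs = CRN["g_Ks"]
_gCaL = CRN["g_CaL"]
_gbCa = CRN["g_bCa"]
_gbNa = CRN["g_bNa"]
_INaKmax = CRN["I_NaK_max"]
_KmNai = CRN["K_mNai"]
_KmKo = CRN["K_mKo"]
_INaCamax = CRN["I_NaCa_max"]
_KmNa = CRN["K_mNa"]
_KmCa = CRN["K_mCa"]
_ksat = CRN["k_sat"]
_gamma = CRN["gamma"]
_IpCamax = CRN["I_pCa_max"]
_KQ10 = CRN["K_Q10"]
_krel = CRN["k_rel"]
_Iupmax = CRN["I_up_max"]
_Kup = CRN["K_up"]
_Caupmax = CRN["Ca_up_max"]
_CMDNmax = CRN["CMDN_max"]
_TRPNmax = CRN["TRPN_max"]
_CSQNmax = CRN["CSQN_max"]
_KmCMDN = CRN["Km_CMDN"]
_KmTRPN = CRN["Km_TRPN"]
_KmCSQN = CRN["Km_CSQN"]
_tautr = CRN["tau_tr"]
_tauu = CRN["tau_u"]
_taufCa = CRN["tau_fCa"]
_Vi = CRN["V_i"]
_Vup = CRN["V_up"]
_Vrel = CRN["V_rel"]
_sigma_nak = (math.exp(_Nao / 67.3) - 1.0) / 7.0

_f_gKv = MACCANNELL["g_Kv"]
_f_gK1 = MACCANNELL["g_K1"]
_f_INaKmax = MACCANNELL["I_NaK_max"]
_f_KmK = MACCANNELL["K_mK"]
_f_KmNa = MACCANNELL["K_mNa"]
_f_Vrev = MACCANNELL["V_rev_NaK"]
_f_B = MACCANNELL["B_NaK"]
_f_gbNa = MACCANNELL["g_bNa"]
_f_Nai = MACCANNELL["Na_i"]
_f_Ki = MACCANNELL["K_i"]
_f_Nao = MACCANNELL["Na_o"]
_f_Ko = MACCANNELL["K_o"]
_f_EK = _RTF * math.log(_f_Ko / _f_Ki)
_f_ENa = _RTF * math.log(_f_Nao / _f_Nai)

FIB_EK = _f_EK
FIB_ENA = _f_ENa


# ------------------------------------------------------------- CRN currents
@njit(cache=True, fastmath=True)
def crn_currents(S, i, fto, fcal, fkr):
    """Twelve membrane currents of the myocyte model for cell ``i``.

    Returns (INa, IK1, Ito, IKur, IKr, IKs, ICaL, IpCa, INaK, INaCa,
    IbNa, IbCa) in pA/pF with the three regional factors applied to
    I_to, I_CaL and I_Kr.
    """
    V = S[0, i]
    m = S[1, i]
    h = S[2, i]
    j = S[3, i]
    oa = S[4, i]
    oi = S[5, i]
    ua = S[6, i]
    ui = S[7, i]
    xr = S[8, i]
    xs = S[9, i]
    d = S[10, i]
    f = S[11, i]
    fca = S[12, i]
    Nai = S[16, i]
    Ki = S[17, i]
    Cai = S[18, i]

    ENa = _RTF * math.log(_Nao / Nai)
    EK = _RTF * math.log(_Ko / Ki)
    ECa = 0.5 * _RTF * math.log(_Cao / Cai)

    INa = _gNa * m * m * m * h * j * (V - ENa)
    IK1 = _gK1 * (V - EK) / (1.0 + math.exp(0.07 * (V + 80.0)))
    Ito = fto * _gto * oa * oa * oa * oi * (V - EK)
    gkur = 0.005 + 0.05 / (1.0 + math.exp(-(V - 15.0) / 13.0))
    IKur = gkur * ua * ua * ua * ui * (V - EK)
    IKr = fkr * _gKr * xr * (V - EK) / (1.0 + math.exp((V + 15.0) / 22.4))
    IKs = _gKs * xs * xs * (V - EK)
    ICaL = fcal * _gCaL * d * f * fca * (V - 65.0)
    IpCa = _IpCamax * Cai / (0.0005 + Cai)
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V / _RTF)
                  + 0.0365 * _sigma_nak * math.exp(-V / _RTF))
    INaK = (_INaKmax * fnak * _Ko / (_Ko + _KmKo)
            / (1.0 + (_KmNai / Nai) ** 1.5))
    ega = math.exp(_gamma * V / _RTF)
    egm = math.exp((_gamma - 1.0) * V / _RTF)
    INaCa = (_INaCamax * (ega * Nai ** 3 * _Cao - egm * _Nao ** 3 * Cai)
             / ((_KmNa ** 3 + _Nao ** 3) * (_KmCa + _Cao) * (1.0 + _ksat * egm)))
    IbNa = _gbNa * (V - ENa)
    IbCa = _gbCa * (V - ECa)
    return INa, IK1, Ito, IKur, IKr, IKs, ICaL, IpCa, INaK, INaCa, IbNa, IbCa


@njit(cache=True, fastmath=True)
def crn_step_cell(S, i, dt, fto, fcal, fkr, istim):
    """Advance myocyte cell ``i`` by ``dt`` (membrane reaction only).

    ``istim`` is an inward stimulus density in pA/pF (positive depolarizes).
    Returns the total outward ionic current density (pA/pF).
    """
    V = S[0, i]

    (INa, IK1, Ito, IKur, IKr, IKs, ICaL, IpCa, INaK, INaCa,
     IbNa, IbCa) = crn_currents(S, i, fto, fcal, fkr)
    Iion = (INa + IK1 + Ito + IKur + IKr + IKs + ICaL + IpCa + INaK
            + INaCa + IbNa + IbCa)

    # --- gates (Rush-Larsen) ---
    # fast Na
    dv = V + 47.13
    if abs(dv) < 1e-10:
        am = 3.2
    else:
        am = 0.32 * dv / (1.0 - math.exp(-0.1 * dv))
    bm = 0.08 * math.exp(-V / 11.0)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = (0.3 * math.exp(-2.535e-7 * V)
              / (1.0 + math.exp(-0.1 * (V + 32.0))))
    else:
        ah = 0.135 * math.exp(-(V + 80.0) / 6.8)
        bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        aj = ((-1.2714e5 * math.exp(0.2444 * V)
               - 3.474e-5 * math.exp(-0.04391 * V)) * (V + 37.78)
              / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = (0.1212 * math.exp(-0.01052 * V)
              / (1.0 + math.exp(-0.1378 * (V + 40.14))))

    # transient outward / ultrarapid
    aoa = 0.65 / (math.exp(-(V + 10.0) / 8.5) + math.exp(-(V - 30.0) / 59.0))
    boa = 0.65 / (2.5 + math.exp((V + 82.0) / 17.0))
    oainf = 1.0 / (1.0 + math.exp(-(V + 20.47) / 17.54))
    tauoa = 1.0 / ((aoa + boa) * _KQ10)
    aoi = 1.0 / (18.53 + math.exp((V + 113.7) / 10.95))
    boi = 1.0 / (35.56 + math.exp(-(V + 1.26) / 7.44))
    oiinf = 1.0 / (1.0 + math.exp((V + 43.1) / 5.3))
    tauoi = 1.0 / ((aoi + boi) * _KQ10)

    uainf = 1.0 / (1.0 + math.exp(-(V + 30.3) / 9.6))
    tauua = tauoa  # identical alpha/beta forms
    aui = 1.0 / (21.0 + math.exp(-(V - 185.0) / 28.0))
    bui = math.exp((V - 158.0) / 16.0)
    uiinf = 1.0 / (1.0 + math.exp((V - 99.45) / 27.48))
    tauui = 1.0 / ((aui + bui) * _KQ10)

    # delayed rectifiers
    dv = V + 14.1
    if abs(dv) < 1e-10:
        axr = 0.0015
    else:
        axr = 0.0003 * dv / (1.0 - math.exp(-dv / 5.0))
    dv = V - 3.3328
    if abs(dv) < 1e-10:
        bxr = 3.7836118e-4
    else:
        bxr = 7.3898e-5 * dv / (math.exp(dv / 5.1237) - 1.0)
    xrinf = 1.0 / (1.0 + math.exp(-(V + 14.1) / 6.5))
    tauxr = 1.0 / (axr + bxr)

    dv = V - 19.9
    if abs(dv) < 1e-10:
        axs = 6.8e-4
        bxs = 3.15e-4
    else:
        axs = 4e-5 * dv / (1.0 - math.exp(-dv / 17.0))
        bxs = 3.5e-5 * dv / (math.exp(dv / 9.0) - 1.0)
    xsinf = 1.0 / math.sqrt(1.0 + math.exp(-(V - 19.9) / 12.7))
    tauxs = 0.5 / (axs + bxs)

    # L-type Ca
    dv = V + 10.0
    dinf = 1.0 / (1.0 + math.exp(-dv / 8.0))
    if abs(dv) < 1e-10:
        taud = 2.28938
    else:
        e = math.exp(-dv / 6.24)
        taud = (1.0 - e) / (0.035 * dv * (1.0 + e))
    finf = 1.0 / (1.0 + math.exp((V + 28.0) / 6.9))
    tauf = 9.0 / (0.0197 * math.exp(-0.0337 * 0.0337 * dv * dv) + 0.02)
    Cai = S[18, i]
    fcainf = 1.0 / (1.0 + Cai / 0.00035)

    # SR release gates
    Carel = S[20, i]
    u = S[13, i]
    v = S[14, i]
    w = S[15, i]
    Irel = _krel * u * u * v * w * (Carel - Cai)
    # Fn uses whole-cell currents in pA (densities are per Cm = 100 pF)
    Fn = 1e-12 * _Vrel * Irel - (5e-13 / _F) * (0.5 * ICaL - 0.2 * INaCa) * 100.0
    uinf = 1.0 / (1.0 + math.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    vinf = 1.0 - 1.0 / (1.0 + math.exp(-(Fn - 6.835e-14) / 13.67e-16))
    tauv = 1.91 + 2.09 / (1.0 + math.exp(-(Fn - 3.4175e-13) / 13.67e-16))
    dv = V - 7.9
    if abs(dv) < 1e-10:
        tauw = 0.923077
    else:
        e = math.exp(-dv / 5.0)
        tauw = 6.0 * (1.0 - e) / ((1.0 + 0.3 * e) * dv)
    winf = 1.0 - 1.0 / (1.0 + math.exp(-(V - 40.0) / 17.0))

    # Rush-Larsen updates
    minf = am / (am + bm)
    taum = 1.0 / (am + bm)
    S[1, i] = minf + (S[1, i] - minf) * math.exp(-dt / taum)
    hinf = ah / (ah + bh)
    tauh = 1.0 / (ah + bh)
    S[2, i] = hinf + (S[2, i] - hinf) * math.exp(-dt / tauh)
    jinf = aj / (aj + bj)
    tauj = 1.0 / (aj + bj)
    S[3, i] = jinf + (S[3, i] - jinf) * math.exp(-dt / tauj)
    S[4, i] = oainf + (S[4, i] - oainf) * math.exp(-dt / tauoa)
    S[5, i] = oiinf + (S[5, i] - oiinf) * math.exp(-dt / tauoi)
    S[6, i] = uainf + (S[6, i] - uainf) * math.exp(-dt / tauua)
    S[7, i] = uiinf + (S[7, i] - uiinf) * math.exp(-dt / tauui)
    S[8, i] = xrinf + (S[8, i] - xrinf) * math.exp(-dt / tauxr)
    S[9, i] = xsinf + (S[9, i] - xsinf) * math.exp(-dt / tauxs)
    S[10, i] = dinf + (S[10, i] - dinf) * math.exp(-dt / taud)
    S[11, i] = finf + (S[11, i] - finf) * math.exp(-dt / tauf)
    S[12, i] = fcainf + (S[12, i] - fcainf) * math.exp(-dt / _taufCa)
    S[13, i] = uinf + (S[13, i] - uinf) * math.exp(-dt / _tauu)
    S[14, i] = vinf + (S[14, i] - vinf) * math.exp(-dt / tauv)
    S[15, i] = winf + (S[15, i] - winf) * math.exp(-dt / tauw)

    # --- concentrations (forward Euler) ---
    Nai = S[16, i]
    Ki = S[17, i]
    Caup = S[19, i]
    Iup = _Iupmax / (1.0 + _Kup / Cai)
    Iupleak = _Iupmax * Caup / _Caupmax
    Itr = (Caup - Carel) / _tautr

    # currents in pA for the flux balance (Cm = 100 pF)
    cm = 100.0
    S[16, i] = Nai + dt * (-3.0 * INaK - 3.0 * INaCa - IbNa - INa) * cm / (_F * _Vi)
    S[17, i] = Ki + dt * (2.0 * INaK - IK1 - Ito - IKur - IKr - IKs) * cm / (_F * _Vi)
    b1 = ((2.0 * INaCa - IpCa - ICaL - IbCa) * cm / (2.0 * _F * _Vi)
          + (_Vup * (Iupleak - Iup) + Irel * _Vrel) / _Vi)
    b2 = (1.0 + _TRPNmax * _KmTRPN / ((Cai + _KmTRPN) ** 2)
          + _CMDNmax * _KmCMDN / ((Cai + _KmCMDN) ** 2))
    S[18, i] = Cai + dt * b1 / b2
    S[19, i] = Caup + dt * (Iup - Iupleak - Itr * _Vrel / _Vup)
    S[20, i] = Carel + dt * (Itr - Irel) / (
        1.0 + _CSQNmax * _KmCSQN / ((Carel + _KmCSQN) ** 2))

    S[0, i] = V + dt * (-(Iion) + istim)
    return Iion


# ------------------------------------------------------ fibroblast currents
@njit(cache=True, fastmath=True)
def fib_currents(V, r, s):
    """Four fibroblast membrane currents (I_Kv, I_K1, I_NaK, I_bNa), pA/pF."""
    IKv = _f_gKv * r * s * (V - _f_EK)
    vk = V - _f_EK
    ak1 = 0.1 / (1.0 + math.exp(0.06 * (vk - 200.0)))
    bk1 = ((3.0 * math.exp(0.0002 * (vk + 100.0)) + math.exp(0.1 * (vk - 10.0)))
           / (1.0 + math.exp(-0.5 * vk)))
    IK1 = _f_gK1 * (ak1 / (ak1 + bk1)) * vk
    INaK = (_f_INaKmax * (_f_Ko / (_f_Ko + _f_KmK))
            * (_f_Nai ** 1.5 / (_f_Nai ** 1.5 + _f_KmNa ** 1.5))
            * (V - _f_Vrev) / (V - _f_B))
    IbNa = _f_gbNa * (V - _f_ENa)
    return IKv, IK1, INaK, IbNa


@njit(cache=True, fastmath=True)
def fib_step_cell(S, i, dt, scale, istim):
    """Advance fibroblast cell ``i`` by ``dt``; gates r,s live in slots 1,2."""
    V = S[0, i]
    r = S[1, i]
    s = S[2, i]
    IKv, IK1, INaK, IbNa = fib_currents(V, r, s)
    Iion = (IKv + IK1 + INaK + IbNa) * scale

    rinf = 1.0 / (1.0 + math.exp(-(V + 20.0) / 11.0))
    taur = 20.3 + 138.0 * math.exp(-((V + 20.0) / 25.9) ** 2)
    sinf = 1.0 / (1.0 + math.exp((V + 23.0) / 2.7))
    taus = 1574.0 + 5268.0 * math.exp(-((V + 23.0) / 22.7) ** 2)
    S[1, i] = rinf + (r - rinf) * math.exp(-dt / taur)
    S[2, i] = sinf + (s - sinf) * math.exp(-dt / taus)
    S[0, i] = V + dt * (-Iion + istim)
    return Iion


# ------------------------------------------------------------ cell drivers
@njit(cache=True)
def integrate_myocyte(S, dt, n_steps, bcl, stim_amp, stim_dur,
                      fto, fcal, fkr, Vout, sample_every, t_offset):
    """Pace one myocyte with a rectangular stimulus train (period ``bcl``).

    ``S`` is a (N_STATE, 1) state array advanced in place.  ``Vout`` receives
    V every ``sample_every`` steps (pass an empty array to skip recording).
    ``t_offset`` is the absolute time of step 0 modulo bcl.
    """
    nrec = Vout.shape[0]
    k = 0
    for n in range(n_steps):
        t = t_offset + n * dt
        phase = t % bcl
        istim = stim_amp if phase < stim_dur else 0.0
        crn_step_cell(S, 0, dt, fto, fcal, fkr, istim)
        if nrec > 0 and n % sample_every == 0 and k < nrec:
            Vout[k] = S[0, 0]
            k += 1
    return k


@njit(cache=True)
def integrate_fibroblast(S, dt, n_steps, istim, scale):
    for n in range(n_steps):
        fib_step_cell(S, 0, dt, scale, istim)


# ------------------------------------------------------------- tissue loop
@njit(cache=True, fastmath=True)
def tissue_run(S, label, fto, fcal, fkr,
               wxm, wxp, wym, wyp, wzm, wzp,
               stim_mask, stim_amp, stim_start, stim_dur, stim_period,
               dt, n_steps, fib_scale,
               lat, lat_threshold,
               probe_idx, probe_out, probe_every,
               movie_out, movie_every):
    """Operator-split monodomain stepping on a voxel grid.

    ``S`` is (N_STATE, N) with N = nx*ny*nz (C-order flattening of the grid);
    ``label`` holds the per-voxel tissue type; the ``w??`` arrays are
    precomputed face coupling weights (1/ms) already divided by the voxel
    spacing squared, zero across no-flux/non-conducting faces.  Godunov
    splitting: reaction step then explicit diffusion step.  Local activation
    time = first upward crossing of ``lat_threshold``.

    Returns 0 on success, 1 on numerical blow-up (|V| > 200 mV).
    """
    n = S.shape[1]
    nx = wxm.shape[0]
    ny = wxm.shape[1]
    nz = wxm.shape[2]
    Vnew = np.empty(n)
    Vprev = np.empty(n)
    nprobe = probe_idx.shape[0]
    kprobe = 0
    kmovie = 0
    for step in range(n_steps):
        t = step * dt
        if stim_period > 0.0 and t >= stim_start:
            phase = (t - stim_start) % stim_period
            stim_on = phase < stim_dur
        else:
            stim_on = (t >= stim_start) and (t < stim_start + stim_dur)
        for i in range(n):
            Vprev[i] = S[0, i]
        # reaction
        for i in range(n):
            lab = label[i]
            if lab == LABEL_NONCONDUCTING:
                continue
            istim = stim_amp if (stim_on and stim_mask[i]) else 0.0
            if lab == LABEL_FIBROBLAST:
                fib_step_cell(S, i, dt, fib_scale, istim)
            else:
                crn_step_cell(S, i, dt, fto[i], fcal[i], fkr[i], istim)
        # diffusion on V (7-point anisotropic stencil, no-flux boundaries)
        V = S[0]
        for ix in range(nx):
            for iy in range(ny):
                for iz in range(nz):
                    i = (ix * ny + iy) * nz + iz
                    vi = V[i]
                    acc = 0.0
                    if wxm[ix, iy, iz] != 0.0:
                        acc += wxm[ix, iy, iz] * (V[i - ny * nz] - vi)
                    if wxp[ix, iy, iz] != 0.0:
                        acc += wxp[ix, iy, iz] * (V[i + ny * nz] - vi)
                    if wym[ix, iy, iz] != 0.0:
                        acc += wym[ix, iy, iz] * (V[i - nz] - vi)
                    if wyp[ix, iy, iz] != 0.0:
                        acc += wyp[ix, iy, iz] * (V[i + nz] - vi)
                    if wzm[ix, iy, iz] != 0.0:
                        acc += wzm[ix, iy, iz] * (V[i - 1] - vi)
                    if wzp[ix, iy, iz] != 0.0:
                        acc += wzp[ix, iy, iz] * (V[i + 1] - vi)
                    Vnew[i] = vi + dt * acc
        tnext = t + dt
        for i in range(n):
            vo = Vprev[i]
            vn = Vnew[i]
            if vn > 200.0 or vn < -200.0 or vn != vn:
                return 1
            # lat uses a negative sentinel for "not yet activated"
            # (fastmath forbids NaN tests inside this kernel)
            if lat[i] < 0.0 and vo < lat_threshold and vn >= lat_threshold:
                lat[i] = tnext
            V[i] = vn
        if nprobe > 0 and step % probe_every == 0:
            if kprobe < probe_out.shape[1]:
                for p in range(nprobe):
                    probe_out[p, kprobe] = V[probe_idx[p]]
                kprobe += 1
        if movie_every > 0 and step % movie_every == 0:
            if kmovie < movie_out.shape[0]:
                for i in range(n):
                    movie_out[kmovie, i] = V[i]
                kmovie += 1
    return 0
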