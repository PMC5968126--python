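# Versioned ionic-model constants.
#
# CRN: Courtemanche-Ramirez-Nattel human atrial myocyte model (1998),
#      maximum conductances in nS/pF, concentrations in mM, volumes in um^3,
#      time in ms, voltage in mV.  All transmembrane currents evaluate to
#      densities in pA/pF (numerically mV/ms).
# MacCannell: active atrial fibroblast membrane model with four currents
#      (I_Kv, I_K1, I_NaK, I_bNa); Cm = 6.3 pF.
#
# regions: per-region multiplicative factors on g_to, g_CaL, g_Kr plus tissue
#      longitudinal conductivity sigma_l (S/cm), transverse-to-longitudinal
#      anisotropy ratio, and nominal longitudinal conduction velocity (cm/s).

crn:
  R: 8.3143          # J/(mol K)
  T: 310.0           # K
  F: 96.4867         # C/mmol
  Cm: 100.0          # pF
  V_cell: 20100.0    # um^3
  V_i: 13668.0
  V_up: 1109.52
  V_rel: 96.48
  Na_o: 140.0
  K_o: 5.4
  Ca_o: 1.8
  g_Na: 7.8
  g_K1: 0.09
  g_to: 0.1652
  g_Kr: 0.029411765
  g_Ks: 0.12941176
  g_CaL: 0.12375
  g_bCa: 0.001131
  g_bNa: 0.0006744375
  I_NaK_max: 0.59933874
  K_mNai: 10.0
  K_mKo: 1.5
  I_NaCa_max: 1600.0
  K_mNa: 87.5
  K_mCa: 1.38
  k_sat: 0.1
  gamma: 0.35
  I_pCa_max: 0.275
  K_Q10: 3.0
  k_rel: 30.0
  I_up_max: 0.005
  K_up: 0.00092
  Ca_up_max: 15.0
  CMDN_max: 0.05
  TRPN_max: 0.07
  CSQN_max: 10.0
  Km_CMDN: 0.00238
  Km_TRPN: 0.0005
  Km_CSQN: 0.8
  tau_tr: 180.0
  tau_u: 8.0
  tau_fCa: 2.0

crn_initial_state:
  V: -81.18
  m: 0.002908
  h: 0.9649
  j: 0.9775
  oa: 0.03043
  oi: 0.9992
  ua: 0.004966
  ui: 0.9986
  xr: 0.00003296
  xs: 0.01869
  d: 0.0001367
  f: 0.9996
  fCa: 0.7755
  u: 0.0
  v: 1.0
  w: 0.9992
  Na_i: 11.17
  K_i: 139.0
  Ca_i: 0.0001013
  Ca_up: 1.488
  Ca_rel: 1.488

maccannell:
  Cm_fb: 6.3         # pF
  g_Kv: 0.25         # nS/pF, time- and voltage-dependent K+ current
  g_K1: 0.4822       # nS/pF, inward rectifier
  I_NaK_max: 2.002   # pA/pF
  K_mK: 1.0          # mM
  K_mNa: 11.0        # mM
  V_rev_NaK: -150.0  # mV
  B_NaK: -200.0      # mV
  g_bNa: 0.0095      # nS/pF, background Na+
  Na_i: 8.5547       # mM (fixed)
  K_i: 129.4349      # mM (fixed)
  Na_o: 130.011      # mM
  K_o: 5.3581        # mM

# Regional electrophysiological heterogeneity: multiplicative conductance
# factors for three channels, tissue conductivities and nominal CV.
# RA: right atrium, PM: pectinate muscles, CT_BB: crista terminalis /
# Bachmann's bundle, TVR: tricuspid valve ring, RAA: right atrial appendage,
# LA: left atrium, FO: fossa ovalis, MVR: mitral valve ring, LAA: left atrial
# appendage, PV: pulmonary veins, CS: coronary sinus.
regions:
  RA:    {f_gto: 1.00, f_gCaL: 1.00, f_gKr: 1.00, sigma_l: 0.0030, anisotropy: 0.35, cv_l: 63.3}
  PM:    {f_gto: 1.00, f_gCaL: 1.00, f_gKr: 1.00, sigma_l: 0.0075, anisotropy: 0.15, cv_l: 115.4}
  CT_BB: {f_gto: 1.00, f_gCaL: 1.67, f_gKr: 1.00, sigma_l: 0.0085, anisotropy: 0.15, cv_l: 100.0}
  TVR:   {f_gto: 1.00, f_gCaL: 0.67, f_gKr: 1.53, sigma_l: 0.0030, anisotropy: 0.35, cv_l: 63.3}
  RAA:   {f_gto: 0.68, f_gCaL: 1.00, f_gKr: 1.00, sigma_l: 0.0030, anisotropy: 0.35, cv_l: 63.3}
  LA:    {f_gto: 1.00, f_gCaL: 1.00, f_gKr: 1.60, sigma_l: 0.0030, anisotropy: 0.35, cv_l: 63.3}
  FO:    {f_gto: 1.00, f_gCaL: 1.00, f_gKr: 1.60, sigma_l: 0.0000, anisotropy: 1.00, cv_l: 0.0}
  MVR:   {f_gto: 1.00, f_gCaL: 0.67, f_gKr: 2.44, sigma_l: 0.0030, anisotropy: 0.35, cv_l: 62.9}
  LAA:   {f_gto: 0.68, f_gCaL: 1.00, f_gKr: 1.60, sigma_l: 0.0030, anisotropy: 0.35, cv_l: 63.3}
  PV:    {f_gto: 1.00, f_gCaL: 1.00, f_gKr: 2.20, sigma_l: 0.0017, anisotropy: 0.50, cv_l: 75.0}
  CS:    {f_gto: 1.00, f_gCaL: 1.00, f_gKr: 1.60, sigma_l: 0.0060, anisotropy: 0.50, cv_l: 97.2}

# Tissue-level calibration constants (monodomain voxel solver).
# diffusion_scale maps sigma_l to the longitudinal diffusion coefficient
# D_l = diffusion_scale * sigma_l (mm^2/ms per S/cm); calibrated so that a
# planar wave crosses a homogeneous 50 mm LA slab in 59 ms (CV ~ 0.85 m/s).
# fibroblast voxels use D = fib_conductivity_factor * D_l(LA), isotropic, and
# their ionic current density is scaled by fib_current_scale (fibroblast
# density per voxel); both calibrated against the fibroblast-barrier slab
# experiments (one-voxel barrier -> ~+5% activation delay, two voxels ->
# ~+20%, three voxels -> conduction block) and then frozen.
tissue:
  diffusion_scale: 104.5754
  fib_conductivity_factor: 0.285
  fib_current_scale: 1.0
  fib_anisotropy: 0.07
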