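# Frozen parameter manifest for the human atrial cell model used throughout
# this package: the Courtemanche-Ramirez-Nattel (CRN, 1998) ionic model with
# (a) the transient-outward current gating kinetics replaced by the
#     Maleckar et al. (2009) r/s formulation (conductance unchanged),
# (b) the Ca-dependent inactivation gate of I_CaL run with a fixed 2.0 ms
#     time constant (the CRN value), and
# (c) the L-type Ca current expressed as a wild-type/mutant conductance
#     mixture: ICaL' = [(1-f) + f*s_mut] * gCaL * d * h * hCa * (Vm - ECa).
# The I_Kur formulation is the CRN one (see `notes` at bottom).
# Units: potentials mV, time ms, concentrations mM, conductances nS/pF,
# current densities pA/pF, volumes um^3, capacitance pF.

physical:
  R: 8.3143          # J mol^-1 K^-1
  T: 310.0           # K
  F: 96.4867         # C mmol^-1

geometry:
  Cm: 100.0          # pF
  V_i: 13668.0       # intracellular volume
  V_up: 1109.52      # SR uptake compartment volume
  V_rel: 96.48       # SR release compartment volume

external_concentrations:
  Na_o: 140.0
  K_o: 5.4
  Ca_o: 1.8

max_conductances:        # nS/pF
  g_Na: 7.8
  g_K1: 0.09
  g_to: 0.1652
  g_Kr: 0.029411765
  g_Ks: 0.12941176
  g_CaL: 0.12375
  g_bCa: 0.001131
  g_bNa: 0.0006744375

pumps_exchangers:
  I_NaK_max: 0.59933874  # pA/pF
  Km_Na_i: 10.0
  Km_K_o: 1.5
  I_NaCa_max: 1600.0     # pA/pF
  K_mNa: 87.5
  K_mCa: 1.38
  k_sat: 0.1
  gamma: 0.35
  I_pCa_max: 0.275       # pA/pF

ca_handling:
  E_Ca_L: 65.0           # fixed reversal potential of the L-type channel, mV
  tau_hCa: 2.0           # Ca-dependent inactivation time constant, ms (fixed)
  K_rel: 30.0            # ms^-1
  I_up_max: 0.005        # mM/ms
  K_up: 0.00092
  Ca_up_max: 15.0
  tau_tr: 180.0          # ms
  tau_u: 8.0             # ms
  CMDN_max: 0.05
  TRPN_max: 0.07
  CSQN_max: 10.0
  Km_CMDN: 0.00238
  Km_TRPN: 0.0005
  Km_CSQN: 0.8
  K_Q10: 3.0             # IKur/(CRN Ito) kinetics temperature factor

# Mutant relative conductance of the L-type channel (s_mut), relative to the
# wild-type gCaL, from heterologous-expression measurements of the CACNA1C
# loss-of-function variants.
variants:
  WT:         {s_mut: 1.0,  forces_f_zero: true}
  G490R:      {s_mut: 0.07, forces_f_zero: false}
  A39V_exon8A: {s_mut: 0.13, forces_f_zero: false}
  A39V_exon8: {s_mut: 0.20, forces_f_zero: false}

# Regional maximal-conductance scaling factors relative to the right-atrial
# (RA) cell, which carries 1.0 for every current.  Reconstructed from the
# atrial-heterogeneity literature (Seemann 2006 / Colman 2013 lineage): the
# crista terminalis and Bachmann's bundle have augmented I_CaL (longer APD),
# the atrioventricular ring reduced I_CaL and augmented I_Kr, the left atrium
# augmented I_Kr (shorter APD than RA), and pulmonary-vein sleeves reduced
# I_CaL/I_K1/I_to with augmented I_Kr (shortest APD, depolarised RMP).
regional_scalings:
  RA:   {g_Na: 1.0, g_K1: 1.0,  g_to: 1.0,  g_Kur: 1.0, g_Kr: 1.0,  g_Ks: 1.0, g_CaL: 1.0}
  CT:   {g_Na: 1.0, g_K1: 1.0,  g_to: 1.0,  g_Kur: 1.0, g_Kr: 1.0,  g_Ks: 1.0, g_CaL: 1.68}
  BB:   {g_Na: 1.0, g_K1: 1.0,  g_to: 1.0,  g_Kur: 1.0, g_Kr: 1.0,  g_Ks: 1.0, g_CaL: 1.68}
  PM:   {g_Na: 1.0, g_K1: 1.0,  g_to: 1.05, g_Kur: 1.0, g_Kr: 1.0,  g_Ks: 1.0, g_CaL: 1.0}
  AVR:  {g_Na: 1.0, g_K1: 1.0,  g_to: 1.0,  g_Kur: 1.0, g_Kr: 1.63, g_Ks: 1.0, g_CaL: 0.67}
  RAA:  {g_Na: 1.0, g_K1: 1.0,  g_to: 0.68, g_Kur: 1.0, g_Kr: 1.0,  g_Ks: 1.0, g_CaL: 1.06}
  AS:   {g_Na: 1.0, g_K1: 1.0,  g_to: 0.63, g_Kur: 1.0, g_Kr: 1.0,  g_Ks: 1.0, g_CaL: 1.0}
  LA:   {g_Na: 1.0, g_K1: 1.0,  g_to: 1.0,  g_Kur: 1.0, g_Kr: 1.6,  g_Ks: 1.0, g_CaL: 1.0}
  LAA:  {g_Na: 1.0, g_K1: 1.0,  g_to: 0.68, g_Kur: 1.0, g_Kr: 1.6,  g_Ks: 1.0, g_CaL: 1.0}
  PV:   {g_Na: 1.0, g_K1: 0.62, g_to: 0.75, g_Kur: 1.0, g_Kr: 1.6,  g_Ks: 1.0, g_CaL: 0.7}

# Published CRN initial state (used as the starting point before pacing to
# steady state; never used directly for measurements).
initial_state:
  Vm: -81.18
  m: 0.002908
  h: 0.9649
  j: 0.9775
  r: 0.000681    # Maleckar Ito activation at rest (recomputed steady value)
  s: 0.967       # Maleckar Ito inactivation at rest
  ua: 0.004966
  ui: 0.9986
  xr: 0.00003296
  xs: 0.01869
  d: 0.0001367
  f: 0.9996
  hCa: 0.7755
  u: 0.0
  v: 1.0
  w: 0.9992
  Na_i: 11.17
  K_i: 139.0
  Ca_i: 0.0001013
  Ca_up: 1.488
  Ca_rel: 1.488

notes: |
  The I_Kur reformulation cited alongside the Ito/hCa modifications is not
  restated by any distributed source; the CRN 1998 I_Kur (voltage-dependent
  maximal conductance 0.005 + 0.05/(1+exp(-(V-15)/13)) with ua^3*ui gating) is
  retained.  The regional scaling table is a literature reconstruction, not a
  transcription; all entries are audit points.
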