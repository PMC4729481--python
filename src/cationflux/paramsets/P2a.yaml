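# Parameter set P2a: model variant M2 (no K+-ATPase, L_KAr = 0); K+ flux passive via L_KK.
name: P2a
variant: M2
global:
  V_in: 1.8e-11
  V_out: 2.85e-6
  T: 296.0
  Surf: 2.29e-5
  pbc: 200.0
  cf: 1000.0
  Cm: 0.01
  K: 1.0e-6
  C_ATP: 0.316
  delta_phi: -0.168
initial:
  H_out: 3.162e-3
  K_out: 0.1
  Cl_out: 0.1
  Na_out: 0.01
  pH_in: 5.514
  K_in: 75.54
  Cl_in: 0.545
  Na_in: 29.98
  ATP: 2.477
  ATP_stimulus: 2.5
coefficients:
  L_HHinit: 4.8e-7
  L_HHaG: 5.62e-1
  L_HNa: -1.9e-12
  L_HAraG: 5.79e-1
  L_HCl: 3.84e-7
  L_KK: 1.88e-8
  L_NaNa: 8.98e-13
  L_ClCl: 3.08e-7
  k_incrHH: 1.05e-6
  k_incrHAr: 1.08e-6
  k_ATPincr: 10.0
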