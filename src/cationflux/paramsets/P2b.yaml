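# Parameter set P2b: model variant M2 with a sizable positive L_HK (H+/K+ symport reading).
name: P2b
variant: M2
global:
  V_in: 1.8e-11
  V_out: 2.85e-6
  T: 296.0
  Surf: 2.29e-5
  pbc: 200.0
  cf: 1000.0
  Cm: 0.01
  K: 0.294
  C_ATP: 0.298
  delta_phi: -0.124
initial:
  H_out: 3.162e-3
  K_out: 0.1
  Cl_out: 0.1
  Na_out: 0.088
  pH_in: 5.34
  K_in: 99.9
  Cl_in: 0.366
  Na_in: 14.34
  ATP: 2.384
  ATP_stimulus: 2.5
coefficients:
  L_HHinit: 6.54e-8
  L_HHaG: 2.39e-4
  L_HK: 9.79e-9
  L_HAraG: 1.22e-4
  L_HCl: 4.51e-8
  L_KK: 2.2e-8
  L_ClCl: 3.34e-8
  k_incrHH: 1.63e-1
  k_incrHAr: 8.32e-2
  k_ATPincr: 0.018
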