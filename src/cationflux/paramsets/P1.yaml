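# Parameter set P1: model variant M1 (ATP-driven K+ import allowed, L_KAr free).
name: P1
variant: M1
global:
  V_in: 1.8e-11        # m^3, total internal volume of all cells
  V_out: 2.85e-6       # m^3, bath volume
  T: 296.0             # K
  Surf: 2.29e-5        # m^2, total cell surface
  pbc: 200.0           # mM per pH unit, proton buffer capacity
  cf: 1000.0           # mM per M
  Cm: 0.01             # F/m^2, specific membrane capacitance (model default, not a table value)
  K: 0.01136           # ATP/ADP reaction equilibrium constant (dimensionless)
  C_ATP: 0.07255       # mM, equilibrium ATP concentration
  delta_phi: 0.0742    # V, initial membrane potential (inside minus outside)
initial:
  H_out: 3.162e-3      # mM  (pH 5.5)
  K_out: 0.1           # mM
  Cl_out: 0.1          # mM
  Na_out: 0.0863       # mM
  pH_in: 5.528
  K_in: 90.39          # mM
  Cl_in: 8.217         # mM
  Na_in: 5.778         # mM
  ATP: 2.303           # mM
  ATP_stimulus: 2.5    # mM, post-glucose ATP asymptote
coefficients:          # units mol^2/(J m^2 s); k_incr* in mol^2/(J m^2 s^2); k_ATPincr in mol/(m^3 s)
  L_HHinit: 2.64e-8
  L_HHaG: 2.68e-8
  L_HNa: -1.03e-8
  L_HAraG: 4.09e-10
  L_HCl: 1.33e-9
  L_KKinit: 4.05e-22
  L_KKaG: 2.91e-4
  L_KAraG: -1.26e-4
  L_NaNa: 8.74e-9
  L_ClCl: 3.49e-7
  k_incrHH: 3.51e-7
  k_incrHAr: 2.39e-9
  k_incrKK: 5.15e-9
  k_incrKAr: -9.93e-10
  k_ATPincr: 0.0991
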