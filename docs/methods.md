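# Methods

## The model

`cationflux` implements a linear non-equilibrium-thermodynamics (NET)
description of monovalent cation transport across the plasma membrane of
starved yeast cells. Instead of mechanistic kinetics for each transporter
(Pma1, Trk1/2, Nha1, Tok1, ...), all transport pathways for an ion are lumped
into phenomenological coefficients that couple every net flux to every
thermodynamic force:

    J_i = Σ_j L_ij · X_j ,   i, j ∈ {H, K, Na, Cl, Ar}

* `J_H, J_K, J_Na, J_Cl` — net fluxes in mol·m⁻²·s⁻¹, **outward positive**;
  `J_Ar` is the ATP→ADP conversion rate, computed as a diagnostic.
* `X_i = R ln(c_i_in/c_i_out) + z_i F Δφ / T` for the ions (electrochemical
  potential difference over temperature; the standard potential cancels
  between compartments), with Δφ = φ_in − φ_out.
* `X_Ar = A_Ar/T` with the hydrolysis affinity
  `A_Ar = (R T / c̄_ATP)(c_ATP − c̄_ATP)(1 + K_eq)`.
* `L` is symmetric (Onsager reciprocity) — enforced structurally: only one
  triangle is stored. Straight coefficients L_ii ≥ 0 is a hard validation
  rule; positive semidefiniteness (the determinant condition) is checked but
  only warned about, because the fitted parameter sets themselves violate it
  (they contain an ATP coupling L_HAr ≠ 0 with no straight reaction
  coefficient L_ArAr, so the matrix cannot be PSD). Consequently the entropy
  production σ = Σ J_i X_i is guaranteed non-negative — and asserted in the
  tests — only for PSD matrices.

State variables are the eight compartment concentrations (mM; 1 mM ≡ 1
mol·m⁻³), the membrane potential, the ATP concentration, and the live values
of the glucose-responsive coefficients:

* concentrations: `dc_out/dt = J·S/V_out`, `dc_in/dt = −J·S/V_in`; internal
  H⁺ is additionally divided by the buffering factor `Bf` (below);
* membrane potential: `dΔφ/dt = −(2F/C_m)(J_H + J_K + J_Na − J_Cl)` — the
  factor 2 is part of the model definition and kept literally;
* ATP: `dATP/dt = k_ATPincr − k_ATPdecr·ATP` with
  `k_ATPdecr = k_ATPincr/ATP_stimulus`, so the post-glucose plateau is
  exactly `ATP_stimulus` (2.5 mM in all shipped sets);
* glucose-responsive coefficients (L_HH, L_HAr, and in M1 also L_KK, L_KAr):
  `dL/dt = k_incr − k_decr·L` with `k_decr = k_incr/L_aG`, an exponential
  relaxation to the post-glucose asymptote `L_aG`.

Before the glucose event the cells are starved: ATP production and all
coefficient dynamics are frozen (both rate constants zero), and the ATP-
coupling coefficients start at 0.

### Parameter sets and geometry

Three fitted parameter sets ship as YAML (`P1` for model variant M1 with a
free ATP-driven K⁺ import L_KAr; `P2a`, `P2b` for M2 with L_KAr = 0). Keys
mirror the published tables. Global geometry: total cell surface 2.29·10⁻⁵ m²
and internal volume 1.8·10⁻¹¹ m³, corresponding to 3.6·10⁵ round cells of
4.5 µm diameter and 50 fL volume (`Geometry.from_cell_monolayer`); bath
volume 2.85·10⁻⁶ m³; T = 296 K.

Choices where the sources are silent:

* **Membrane capacitance** C_m is not tabulated; default 0.01 F·m⁻² (the
  textbook 1 µF·cm⁻² class), configurable per parameter file. Because Δφ
  relaxes on sub-millisecond timescales at this capacitance, the trajectory
  is insensitive to its exact value (Δφ is quasi-stationary).
* **Proton buffering.** A buffer capacity `pbc` = 200 mM per pH unit is
  converted once to the dimensionless factor
  `Bf = pbc / (ln 10 · c_H_in(0))` (≈ 2.8·10⁴ at pH_in 5.514) and held
  constant, honoring the constant-Bf approximation; an optional
  `buffering="dynamic"` mode recomputes Bf from the instantaneous internal
  H⁺ at every step.
* **Chloride bookkeeping.** The internal-chloride balance is
  `dc_Cl_in/dt = −J_Cl·S/V_in`, consistent with the other ions.
* **No concentration floors:** the model raises a domain error on
  non-positive concentrations instead of clamping; all shipped scenarios
  stay positive.

## Scenarios and integration

Stimuli are instantaneous events: a KCl addition raises external K⁺ and Cl⁻
by the dose (equimolar salt; the 3 ml bath is treated as constant volume),
and glucose is a switch that starts ATP production and coefficient dynamics.
Four canonical schedules are provided per dose (0.01, 0.1, 1, 10 mM KCl):
`fit` (KCl 300 s / glucose 600 s), `standard` (300/660 s — the default for
decomposition readouts), `validation` (180/300 s), and `second_stimulus`
(300/660 s plus 10 mM KCl at 1000 s). Both glucose timings are shipped
because the experimental protocols themselves used both.

Integration is piecewise LSODA (via `scipy.integrate.odeint`, the direct
odepack interface, chosen after the generic `solve_ivp` wrapper proved two
orders of magnitude slower on this stiff system; a BDF path is available for
cross-checking and agrees to ~10⁻⁸ relative). Integration restarts exactly
at each event; the state recorded at an event time is the post-event state.
Default tolerances rtol 10⁻⁸ / atol 10⁻¹⁰ (estimation uses 10⁻⁶/10⁻⁹). The
system is stiff because the membrane potential equilibrates within
milliseconds while concentrations move over minutes. The derivative kernel
is numba-compiled with an equivalent pure-Python fallback.

## Flux decompositions

For the M2 model class (K⁺ coupled only to H⁺ and itself) the net K⁺ flux
splits exactly two ways:

* by ion: `J_K(H) = L_KH·X_H`, `J_K(K) = L_KK·X_K`;
* by potential: `J_K(CP) = R(L_KH ln r_H + L_KK ln r_K)`,
  `J_K(EP) = (L_KH + L_KK)·F·Δφ/T`, with r_i = c_in/c_out.

Both identities hold to round-off at every grid point and are tested as such.
The ratio `J_K(EP)/J_K(CP)` is masked (not an error) where the chemical part
vanishes. The "directly after glucose" readout of the ratio is
operationalized as the first output grid point ≥ 5 s after the glucose event
on a 1 s grid; the delay is configurable. Note that the simulated ratio is
not slowly varying there — it falls by ~20% within 30 s of the event — so
the reported value depends materially on this choice; the package keeps the
5 s default and reports what it computes. Under the shipped P2a coefficients
the pre-glucose internal K⁺ pool is substantially depleted after a 10 mM KCl
step (Surf/V_in = 1.27·10⁶ m⁻¹ turns figure-scale fluxes into tens of mM of
drift over 6 min), which steepens ln(K_in/K_out) at the readout and yields a
ratio near 4.7 at 5 s, relaxing through 3.5 about 35 s after the event.

Chloride and sodium predictions: per-trajectory peak Cl⁻ influx magnitude,
and a Na⁺-negligibility flag (max |J_Na| below 1% of max |J_K| by default).
The second-stimulus analysis reports post-glucose and post-second-stimulus
peak fluxes per ion and detects a transient H⁺ influx as a sign change of
J_H (efflux immediately before the second KCl, influx within 60 s after).
Under the shipped P2a values this transient occurs at all four first doses,
deepest at the lowest dose; the published claim concerns the two highest
doses and those are what the acceptance tests assert.

Local sensitivities are central finite differences of a scalar observable,
symmetric in log space for positive parameters (p → p·e^±h, default
h = 0.05), reported as d ln(observable)/d ln(p); non-finite evaluations flag
the entry instead of raising.

## Parameter estimation

The objective simulates every condition with shared parameters (only the KCl
dose differs) and sums squared residuals between simulated and measured
fluxes at the data timestamps. Residual weighting is not specified by the
original workflow; the default weights each trace by the inverse of its mean
squared flux so K⁺ and H⁺ traces of different magnitude contribute
comparably, with plain SSE as an option. A failed simulation returns a large
finite penalty, 10⁶·(1 + unfinished fraction of the horizon), so the swarm
survives stiff corners.

The optimizer is a global-best particle swarm (inertia 0.729, cognitive =
social = 1.49445 — the standard constriction values; velocities clamped to
half the box width, positions clipped; Mersenne-Twister stream, bit-wise
deterministic per seed). It stops at the iteration limit (default 400, swarm
40) or when the swarm's objective standard deviation falls below 10⁻⁶.
`multistart` repeats the search with per-run random start points and random
sub-bounds of the declared envelope (log-uniform endpoints for non-negative
parameters, uniform otherwise). If a winning parameter lies on the bounds it
was optimized under, the corresponding envelope bound is extended by a
factor of 100 and a follow-up round is run (at most two extension rounds).
The full published protocol used 1000 restarts; the package default is 50
with every knob exposed.

The recovery study used in the tests fits three free coefficients (L_KK,
L_ClCl, L_HCl) of a single-condition problem on a compressed protocol
(KCl 10 mM at 60 s, glucose at 180 s, 360 s span, 10 s sampling) with
noise-free and 5%-relative-noise synthetic data, 20 restarts, swarm 10, 80
iterations, envelopes spanning a factor 30 each way around the generating
values. Noise-free recovery lands within a few percent of truth (well inside
the 10% requirement); with 5% noise within the 30% requirement.

## Synthetic MIFE-like data

The generator samples simulated J_K and J_H (optionally J_Cl) on a regular
grid (default 5 s — a typical microelectrode ion flux (MIFE) acquisition
cadence), converts to nmol·m⁻²·s⁻¹, and adds independent Gaussian noise with
sd = relative_sd·|J| + floor_sd (defaults 0.05 and 2 nmol·m⁻²·s⁻¹, chosen to
visually resemble published MIFE scatter — synthetic values, not fitted to
any dataset). Ground truth (parameter set, seed, events) travels in the
dataset's provenance and in the CSV metadata header, so estimation tests can
close the loop. What the generator does **not** emulate: electrode physics,
drift/autocorrelated noise, boundary-layer artefacts, or biological
variability between monolayers — so passing recovery tests demonstrate
identifiability under the model's own assumptions, not robustness to real
measurement pathologies.

Datasets are plain CSV with a `# key: value` metadata header; the sign
convention (`outward_positive` or `influx_positive`) is declared explicitly
and converted to the model convention on load. A spreadsheet importer with
the same column layout is provided as an optional convenience.

## Known limitations

* The printed coefficient magnitudes span eight orders across the fitted
  sets and their unit regime cannot be fully reconciled with the figures'
  absolute flux scales; ratio- and sign-based results are the reliable
  outputs, absolute flux magnitudes should be treated with caution.
* Constant cell volume and turgor; no organellar compartments; no
  transcriptional regulation — the model covers minutes-scale responses of
  starved cells to mild stimuli.
* Glucose is a switch, not a metabolite: no glycolysis model stands behind
  the ATP balance.
* The linear force–flux law is a near-equilibrium approximation; large
  gradients (e.g. strong salt shock) fall outside its validated range.
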