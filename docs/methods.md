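# Methods

## The system being modelled

A bench CVVHD circuit: a 25 L well-mixed glass container of antibiotic-spiked
dialysate stands in for the patient, its contents are pumped through the blood
side of a high-flux hemodialysis filter, and fresh dialysate (at 0, 16 or
64 mg/L meropenem) runs countercurrent on the other side before draining to
waste. Because the spent dialysate is discarded, the circuit is *open*: the
container volume is constant and only solute leaves or enters it through the
membrane. The measured quantity at each sampling port (access line AL, return
line RL, effluent line EL, container controls) is absorbance at 300 nm,
converted to concentration by Beer–Lambert.

## Transport model and assumptions

Transport across the filter is purely diffusive — the bench circuit runs no
ultrafiltration, so there is no convective term — and is lumped into the
classical K0A exchanger model. Assumptions:

- both streams are in steady state within a pass (transit time ≪ session
  time) and radially well mixed;
- membrane properties are uniform along the fiber bundle and constant over a
  session (an optional `permeability_reduction` fraction scales K0A down to
  represent fouling; default 0, as observed on the bench);
- flow geometry is countercurrent, the standard configuration of CVVHD
  filters; a cocurrent solution is included for sensitivity analysis;
- solute behaviour is linear (no saturable binding or adsorption).

Membrane hindrance (sieving, `s`) is applied as an overall factor on the
exchanger clearance, `K = s · K_exchanger(A)` with `A = k0a·(1−ρ)`. This
placement is a deliberate design choice: it keeps the per-pass driving force
proportional to `(C_AL − C_d)` — so equilibrium-enriched dialysate produces
exactly zero flux — while giving the two physically required limits,
`K → k0a(1−ρ)s` as `k0a → 0` and an effluent/inlet saturation ratio of `s`.
Embedding `s` inside the exponent instead would drive the saturation ratio to
1 for any `s`, contradicting how a hindered membrane behaves. For the bench
drug the observed hindrance is ~1.0 (unobstructed passage of a 383.5 Da
molecule through a 30–40 kDa cut-off membrane), so `s = 1` is the default and
0.93 (the nominal literature sieving coefficient for meropenem) is available
as configuration.

Back-filtration — the bench conditions (low transmembrane pressure, no
oncotic pressure, high-flux filter) favour dialysate→blood transfer — is
represented by a single multiplicative factor `alpha_backfiltration` applied
to clearance when the gradient runs dialysate→blood, capped at
`min(Qb, Qd)`. `alpha = 1` recovers a symmetric membrane. No attempt is made
to model transmembrane-pressure physics.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `k0a` | ml/min | (required / fitted) | overall mass-transfer–area coefficient |
| `sieving_membrane` | — | 1.0 | membrane hindrance factor, (0, 1] |
| `alpha_backfiltration` | — | 1.0 | dialysate→blood clearance multiplier |
| `permeability_reduction` | — | 0.0 | fractional K0A loss (fouling) |
| `qb` | ml/min | grid {100,150,200} | blood flow |
| `qd_ml_h` | ml/h | grid {1000,2000,3000} | dialysate flow as prescribed |
| container volume | L | 25 | bench compartment |
| `vd_l` | L | 21 | meropenem distribution volume (patient mode) |
| `protein_binding` | — | 0.02 | bound fraction; only free drug crosses |
| `container_start_conc` | mg/L | 16 | working concentration (4× common MIC) |
| `extinction_coefficient` | A·L·mg⁻¹·cm⁻¹ | **none** | instrument-specific; must be supplied |
| `assay_cv` | — | 0.02 | multiplicative absorbance noise CV |
| `degradation_rate_per_h` | 1/h | 0.0 | container first-order loss |

Dialysate flow is prescribed in ml/h and every transport formula runs in
ml/min; the conversion `qd = qd_ml_h/60` happens exactly once, at
`FlowSetting` construction, because this single unit conversion is the most
likely implementation bug in the domain. The extinction coefficient has no
default on purpose: it is a property of the instrument and drug batch, and
all synthetic fixtures use an arbitrary documented value of 1.0 (every
conversion is self-consistent regardless of the value).

## Numerical choices

- **Equal-flow branch.** The countercurrent formula is singular at
  `R = Qb/Qd = 1`; for `|R − 1| ≤ 1e−9` (below the float noise of the
  exponential expression) the analytic limit `K = s·Qb·N/(1+N)` is used.
  Continuity across the switch is tested to `1e−6·Qb`.
- **Overflow guard.** For `N(1−R) > 700` the exponential would overflow;
  the analytic saturation limit `K = s·Qb` is returned instead.
- **Mass-balance tolerance.** Per-pass solute conservation
  `Qb(C_AL − C_RL) = Qd(C_EL − C_d)` is verified to a relative `1e−12`,
  normalized by the stream mass flows `max(Qb·C_AL, Qd·C_d)`: when the flux
  is many orders below the stream scale, float cancellation makes a
  flux-relative `1e−12` unattainable in double precision.
- **Container ODE.** The trajectory approaches the dialysate level
  monotonically and never crosses it, so the gradient sign — hence the
  direction-dependent clearance — is constant along any trajectory and the
  exponential closed form is exact, asymmetric membrane included. The closed
  form is the default; `method="numeric"` (LSODA, rtol 1e−10) exists for
  cross-validation, and the two agree to `1e−6` mg/L in tests. Effluent and
  dialysate-import masses are accumulated analytically so that global mass
  accounting closes to a relative `1e−8`.
- **Patient mode.** With a symmetric membrane the ODE is linear with constant
  coefficients and solved in closed form; with asymmetry the right-hand side
  is piecewise linear in the gradient sign and LSODA integrates it. The
  steady state is solved analytically with the clearance direction chosen
  self-consistently.
- **Clearance inversion.** Clearance is strictly increasing in `k0a` with
  asymptote `s·min(Qb, Qd)`, so the target is bracketed (expanding the upper
  bracket geometrically) and solved by Brent's method at machine-precision
  relative tolerance; targets at or above the ceiling raise an
  infeasible-target error naming the ceiling.
- **Least-squares calibration.** The objective is the sum of squared
  *extraction-fraction* residuals — dimensionless and concentration-scale
  free, matching how per-pass results are reported. A 40-point log-spaced
  scan seeds a bounded trust-region least-squares solve
  (xtol = ftol = gtol = 1e−15); residual-based solving reaches
  machine-precision recovery on noise-free data where a scalar minimizer
  would stall at √ε. Default `k0a` bounds are `(1e−3, 10·max(Qb, Qd))`
  ml/min. With `fit_alpha`, loss-side records identify `k0a`, gain-side
  records identify `alpha` given `k0a` (alternating 1-D solves), and a joint
  2-D solve polishes both — exploiting the model's separable structure.
- **Limit testing.** The small-`k0a` limit `K → k0a(1−ρ)s` carries an O(N)
  relative correction, so it is asserted deep in the linear regime
  (`k0a = 1e−8·Qb`) at relative `1e−6`.

## Synthetic experiments

`generate_dataset` replays the full factorial bench design — dialysate
{0, 16, 64} mg/L × blood flow {100, 150, 200} ml/min × dialysate flow
{1000, 2000, 3000} ml/h, three replicates per cell, container controls at
0/2/4 h — through the forward model and perturbs the *absorbance* (the
actually measured quantity) with mean-one multiplicative lognormal noise,
CV 2% by default, a typical UV-spectrophotometry figure exposed as
configuration. Measured concentrations are derived from the noisy
absorbances, so each record stays Beer–Lambert-consistent. Output is
byte-identical under a fixed seed.

`bench_scenario` chooses K0A by inverting the clearance formula at the
most loss-favourable flow corner (Qb 100 ml/min, Qd 3000 ml/h) against a
35.6% per-pass extraction — the maximum loss the bench study reported —
which makes the nine flow cells span roughly 8–36% loss, the reported
spread. The resulting K0A is 80.47 ml/min.

What the generator does **not** emulate: filter clotting or pump pulsatility,
temperature effects, spectral interference from degradation products,
heteroscedastic port-specific assay error, or within-session container
depletion between samples (per-pass sampling is treated as instantaneous at
the working concentration). Passing recovery tests therefore demonstrates
statistical correctness of the estimation chain under the stated noise model,
not robustness to every bench artifact.

## Design decisions where the ground truth is open

- The published flow-stratified loss figures (14.23% at Qd 1000 ml/h vs
  11.89% at 3000 ml/h) are non-monotonic in the direction pure diffusion
  requires and may be averaged, mislabeled or effluent-side values; they are
  packaged as data (`reported_summary.csv`) with caveats and excluded from
  model-consistency tests. Likewise the 8.8% minimum loss exceeds the
  diffusive ceiling `Qd/Qb = 8.33%` of its most favourable corner, so no
  symmetric diffusive parameterization can reproduce it exactly; it is
  treated as measurement scatter, not a target.
- The mapping of the published extraction endpoints to specific grid corners
  is not reported; the packaged dataset's assignments are labelled
  assumptions.
- "No significant change" in the container controls is operationalized as a
  relative range `(max − min)/mean ≤ 5%` rather than a hypothesis test:
  three single measurements support no more.
- Replicate count (3) and sampling schedule are configuration, not claims
  about the bench protocol, which did not report them.
- Session-level container depletion is a model extrapolation: the bench
  study sampled per pass and never reported depletion trajectories.

## Known limitations

Single-compartment kinetics with constant volume and binding (sepsis-driven
Vd expansion and binding variability enter only as user-settable parameters);
no citrate/calcium chemistry, no cytokine adsorption, no clotting dynamics;
back-filtration is phenomenological; clinical dosing recommendations are out
of scope.
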