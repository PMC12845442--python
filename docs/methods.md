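# Methods

## Model structure and assumptions

The simulator treats the oral cavity as five linked regions: a well-mixed
saliva pool (S), a pellicle surface layer on the mucosa (M) described by a
single Langmuir-type surface density Γ over the saliva–mucosa area A_SM, a
well-mixed mucosal tissue compartment (T), a one-dimensional biofilm slab
(B) of thickness L_B, and a well-mixed periodontal pocket (P) cleared by
gingival crevicular fluid at flow Q_GCF. All kinetics are deterministic;
there is no random number use anywhere in the transport model.

Key structural assumptions:

- **Well-mixedness** of S, T and P. Saliva turnover (minutes) and the
  microlitre pocket volume make this reasonable; it fails for spatially
  heterogeneous mouths (see Limitations).
- **The pellicle exchanges with saliva only.** The transmucosal flux
  J_SM = P_SM·(C_S − C_T/K_p,T) bypasses Γ, i.e. adsorbed drug must desorb
  into saliva before it can enter tissue. This follows the compartment
  diagram most simply; an alternative pellicle→tissue shunt would need a
  rate constant for which no measurement basis exists.
- **The saliva balance carries an explicit −A_SM·dΓ/dt term.** A surface
  layer that stores drug must remove it from the fluid phase; without this
  term the model would create mass whenever the pellicle loads. The printed
  saliva equation omits it, the narrative ("a portion of the dose becomes
  temporarily stored in this layer") requires it, and the mass-balance gate
  settles the question.
- **Desorption is first-order**, −k_des·Γ, the standard Langmuir kinetic
  form and the only one dimensionally consistent with k_des in min⁻¹.
- **The biofilm is a homogeneous 1-D slab** with effective diffusivity
  D_eff and a first-order binding sink k_bind·C_B. The saliva face is a
  Dirichlet boundary pinned to C_S(t).

## The far biofilm boundary: two modes

The biofilm–pocket interface condition is genuinely ambiguous: a literal
zero-gradient condition at x = L_B forces the biofilm→pocket flux to zero,
yet pocket scenarios need that pathway. Both readings are implemented:

- `sealed` — zero-flux wall, J_BP = 0. The literal reading; appropriate
  when the formulation and the pocket communicate only through saliva.
- `coupled` — a Robin-type mass-transfer flux J_BP = k_m·(C_B(L_B) − C_P).
  Default k_m = D_eff/δ with a fixed interfacial boundary-layer thickness
  δ = 10 µm. An earlier candidate default, the discrete-gradient surrogate
  k_m = D_eff/Δx, was rejected because it ties the *continuum problem* to
  the numerical grid: refining the mesh stiffens the coupling toward a
  Dirichlet condition and the solution never grid-converges. With a fixed δ
  the pocket AUC changes by ≪ 0.5% when the grid spacing is halved at the
  N_x = 200 baseline. D_eff/Δx remains available through the explicit
  `k_m` argument.

`simulate()` auto-selects `coupled` when any dose is a pocket formulation,
`sealed` otherwise; both can be forced.

Two further constitutive choices where the compartment diagram is silent:
the saliva→biofilm flux is the discrete diffusive flux into the slab face
(J_SB = D_eff·(C_S − C_B,1)/Δx, exactly the flux the first interior node
receives, so the exchange is mass-consistent by construction), and the
direct saliva→pocket flux is zero by default (the pocket is semi-isolated),
with an optional permeability term P_SP·(C_S − C_P).

## Numerics

- **Discretization**: vertex-centred finite volumes on a uniform grid,
  N_x = 200 unknown nodes by default, second-order central differences,
  Dirichlet node eliminated at x = 0, half-cell at x = L_B. The biofilm's
  stored mass uses the same finite-volume weights as the flux stencil
  (cross-sectional area A_SB), so the semi-discrete system conserves mass
  identically and the audit measures only integrator error.
- **Integration**: SciPy's BDF with a supplied Jacobian sparsity pattern
  (tridiagonal slab plus a handful of coupling entries). Default
  tolerances rtol = 1e-8, atol = 1e-10 µg/mL, which hold the mass-balance
  defect near 1e-12 in practice — comfortably inside the 1e-6 gate.
- **Mass accounting**: the state vector is augmented with six cumulative
  integrals (swallowed, GCF wash-out, tissue clearance, biofilm binding,
  formulation release, saliva infusion input), so dosed-so-far equals
  stored plus outflows at every output time without post hoc quadrature.
- **Dose events**: salivary boluses are instantaneous jumps of amount/V_S
  with the integrator restarted at the event time (no delta-function
  sources); infusion windows and formulation starts are also breakpoints.
- **Non-negativity**: excursions below −10·atol abort the run; smaller
  solver noise is clipped to zero in the returned trajectories.
- **Release-rate singularities**: families with an unbounded initial rate
  (Higuchi, power laws with exponent < 1, Weibull b < 1, Baker–Lonsdale)
  are evaluated at max(t, ε) with ε = 1e-6 min; the mass this forfeits is
  below 1e-4 of the dose. After the cumulative fraction reaches 1 the rate
  is identically zero, making every profile a globally defined,
  mass-conserving source. Weibull and the biphasic profile approach F = 1
  only asymptotically; their rates decay smoothly instead of clamping.
- **Baker–Lonsdale** is evaluated by bracketed root-finding of
  (3/2)[1 − (1−F)^{2/3}] − F = k_BL·t on F ∈ [0, 1] (the left side is
  continuous and increasing, so the bracket cannot fail), with the rate
  from the implicit-function derivative dF/dt = k_BL/g′(F).

## Units

Internally everything runs in (cm, min, µg, mL). On canonicalization D_eff
converts cm²/s → cm²/min (×60), V_P and Q_GCF convert µL → mL (×10⁻³), and
k_bind converts s⁻¹ → min⁻¹ (×60) — the binding rate is quoted per second
alongside D_eff, and leaving it unconverted would silently slow the sink
sixty-fold. Parameter objects carry a unit tag so double conversion is a
no-op rather than a bug, and round-tripping user → canonical → user units
is identity to 12 significant digits.

## Parameters

Typical ranges enforced as *warnings* (the printed values are illustrative,
not a clinical case): V_S 0.7–1.0 mL; Q_S 0.3–0.5 (resting) to 1–2 mL/min
(stimulated); Γ_max 5–15 µg/cm²; k_ads 0.1–1.2 mL·cm⁻²·min⁻¹; k_des
0.01–0.1 min⁻¹; P_SM 10⁻⁵–10⁻⁴ cm/min; K_p,T 2–10; V_T 0.05–0.1 mL; A_SM
2–6 cm²; CL_local 0.01–0.1 mL/min; D_eff 1–5×10⁻⁷ cm²/s; L_B 100–300 µm;
V_P 0.5–2 µL; Q_GCF 0.05–0.1 (healthy) to 0.2–0.5 µL/min (inflamed).
Non-positive structural parameters raise; zero flows are permitted at the
container level so closed-system limits can be simulated, while the
validator still flags them as errors for user-facing configurations.

No published values exist for the remaining interface areas; the presets
fix A_SB = 2 cm², A_BP = 0.1 cm², A_SP = 0.05 cm² (with A_SM = 4 cm², mid
range) as explicit geometric assumptions for a posterior interproximal
site, identical across presets so that scenario comparisons isolate flow
and release effects. The preset k_bind = 2×10⁻⁴ s⁻¹ represents weak
reversible biofilm binding; it likewise has no printed range.

## Scenario presets

- `healthy_pocket` / `inflamed_pocket`: a 2 mg salivary bolus; identical
  physiologies except Q_GCF (0.075 vs 0.3 µL/min, the mid-points of the
  healthy and inflamed ranges). Inflammation shortens pocket residence.
- `periochip_like`: 2.5 mg, biphasic burst (40% over ~24 h) then
  zero-order to day 8.5, inflamed pocket, pellicle binding active.
- `arestin_like`: 1 mg, Peppas–Sahlin kinetics (k₁ = 8×10⁻³, k₂ = 4×10⁻⁵,
  m = 0.45, ≈ 14-day window), with a paired healthy variant for the
  wash-out comparison.
- `atridox_like`: 50 mg deposited directly in the pocket, ~7-day sustained
  release with a 20% early burst.

Presets are *illustrative*, chosen once from the published qualitative
profiles (burst + zero-order chip; diffusion-plus-relaxation microspheres;
week-long gel) and mid-range physiology; they are not product label claims,
and the preset MICs are documented placeholders, not clinical breakpoints.

## Release fitting and model selection

Nonlinear least squares (scipy `least_squares`, trust-region reflective)
with positivity bounds, exponents constrained to (0, 1.5) and the Weibull
shape to (0, 5); data-driven starting values anchor the scale coefficient
to the last observed point. AIC = n·ln(RSS/n) + 2p and
BIC = n·ln(RSS/n) + p·ln n come from the profiled Gaussian likelihood with
additive i.i.d. error — an explicit modelling choice, so ΔAIC is comparable
only across families fitted to the same data. Fits with fewer than p + 1
points are refused as under-determined; non-convergent families are
reported with their final RSS and skipped during ranking rather than
aborting the comparison. Ranking ties break by fewer parameters, then
family name.

## Synthetic data generator

`synth_release_data` emulates a noisy in vitro dissolution curve:
log-spaced sampling over three decades up to the time of 95% release,
multiplicative Gaussian noise F·(1 + cv·ε) at 5% CV by default, clamped to
[0, 1.05] to mimic small experimental overshoot, driven by a seeded PCG64
generator for cross-platform reproducibility. It does **not** emulate
apparatus effects (USP hydrodynamics, sampling-volume depletion, pH or
ionic-strength drift) or autocorrelated assay error, so parameter-recovery
results bound identifiability under idealized noise only. Under these
conditions the Korsmeyer–Peppas exponent is recovered with median absolute
error well under 0.05 from 15 points at 5% noise (100 seeded replicates).

## What the tests do and do not show

The suite checks the simulator against closed-form limits (dilution
exponential, Langmuir isotherm, tissue and pocket steady states, wash-out
half-life, semi-infinite erfc diffusion at early times), structural
invariants (mass balance ≤ 1e-6, non-negativity, linear superposition with
binding off to 1e-8, AUC monotonicity in Q_GCF and dose, spatial grid
convergence), and the desk-checkable worked examples (≈ 40% first-minute
dilution; L²/D ≈ 1300 s across a 200 µm film; 2.3 min pocket half-life).
These validate the mathematics and the implementation, not clinical
predictivity: no time-resolved human GCF concentration data are bundled,
so agreement with patient profiles is untested by construction.

## Known limitations

- 1-D homogeneous biofilm; no micro-channels, density gradients or 2-D/3-D
  structure.
- Single effective salivary flow; no spatial variation or shear.
- Deterministic single-patient parameter sets; population variability is
  out of scope (presets stand in for patient classes).
- Saturable (Michaelis–Menten) elimination exists only in the classical
  module, not inside the oral transport loop.
- The Hixson–Crowell family is defined in mass units (W₀, W_t); its
  fraction form F = 1 − (W₀^{1/3} − k_HC·t)³/W₀ is an interpretation and
  is flagged as such.
- Biofilm-adjusted MICs must be supplied by the user; no
  planktonic-to-biofilm conversion is computed.
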