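# Methods

## Model structure

The muscle–tendon unit (MTU) is the serial arrangement of two parallel
pairs: contractile element ∥ parallel elastic element (CE ∥ PEE) in
series with serial elastic element ∥ serial damping element (SEE ∥ SDE).
The simulated state vector is (γ̃, ℓCE, [Pi]):

1. **Activation.** dγ̃/dt = m·(u − γ̃) relaxes normalized free calcium
   toward the piecewise-constant stimulation u(t). Troponin activity is
   the sigmoid q̃ = (q_min + (ρ·γ̃)^ν) / (1 + (ρ·γ̃)^ν) with the
   length-dependent calcium sensitivity ρ = ϖ_opt·ℓ̃CE³. The cubic
   length exponent is Hatze's classical choice; it is a module constant
   (`activation.RHO_LENGTH_EXPONENT`) because only the length coupling,
   not the sigmoid shape, depends on it.
2. **Contraction.** dℓCE/dt = vCE solves the force balance
   F_CE(vCE) + F_PEE = F_SEE + d_SE·(vMTU − vCE). Per force–velocity
   branch this is a quadratic in vCE (the Hill relation is hyperbolic
   and d_SE is linear in the instantaneous CE force); the analytic root
   is verified by substitution to 1e−9·Fmax and a bracketed bisection
   fallback covers rejected roots. The eccentric branch is constructed
   so that value and S_e-scaled slope are continuous at vCE = 0 with
   asymptote F_e·a·F̃isom·Fmax. Hill constants scale with activity as
   Q_A = (1+3a)/4, Q_B = (3+4a)/7 (the convention of the base model
   family; `activity_scaling=False` disables it) and A_rel carries the
   force–length value on the descending limb.
3. **Phosphate kinetics.** d[Pi]/dt = k_hyd·[ATP] − k_con·[ADP]·[Pi]/c0
   with k_hyd = k̂_hyd·q̃/ℓ̃CE. The division by c0 = 1 M makes the
   mass-action pair dimensionally consistent with rate constants in 1/s
   while preserving the equilibrium ratio
   [ATP]·c0/([ADP]·[Pi]) = k_con/k_hyd.

After every evaluation the remaining metabolites are projected onto the
manifold defined by the creatine-kinase equilibrium
K_ck = [ATP][Cr]/([ADP][PCr]), the adenylate-kinase equilibrium
K_adk = [ATP][AMP]/[ADP]², and conservation of the adenine, creatine and
phosphate pools (operator splitting of the underlying DAE). The
projection is a scalar root-find **in [ATP]**: parametrized by [ADP] the
manifold folds at ADP = c_ad/(1+2√K_adk) (the two adenylate-kinase
quadratic roots are literally ATP and AMP, which coalesce there), so
[ADP] is not a unique coordinate, while [ATP] traverses the manifold
monotonically. Inside the integrator a warm-started secant iteration
(2–4 evaluations) replaces the bisection.

Phosphate accounting is nucleotide-inclusive by default,
c_ph = [Pi] + [PCr] + 3[ATP] + 2[ADP] + [AMP], which yields a resting
[Pi] ≈ 5.6 mM — physiologically plausible for resting skeletal muscle.
A free-only alternative (c_ph = [Pi] + [PCr], resting [Pi] ≈ 26.6 mM) is
selectable via `MetabolicConstants(accounting="free")`.

The relative chemical potential
μ̃ATP = (−ΔG°ATP + R·T·ln([ATP]c0/([ADP][Pi])))/μATP,max discounts
troponin activity to the muscle activity ã = q̃·μ̃ATP used by the Hill
force. ΔG°ATP is calibrated at startup so that μ̃ATP = 1 exactly in the
resting equilibrated fiber (−29.53 kJ/mol for the default constants,
close to the standard −30.5 kJ/mol, which is available as a fixed-value
mode); this keeps Fmax interpretable at t = 0.

**ATP floor.** [ATP]min = 1.2 mM is a hard floor without a printed
mechanism: if the projection would cross it, [ATP] is clamped, the
creatine-kinase constraint is released (the pool split is then fixed by
the adenylate-kinase and conservation equations), the state is flagged,
and the simulator zeroes the hydrolysis flux while the flag binds. With
the default pools the floor is unreachable on the equilibrium manifold
(its minimum [ATP] is c_ad/3 ≈ 2.33 mM), so the clamp only matters for
nonstandard constants.

## Parameters

The 24 mechanical/activation/kinetic parameters (units in
`params.MTUParameters`) ship as four presets: `GAS_plus`/`PLA_plus`
(fitted with phosphate dynamics; k̂_hyd = 1.45 / 2.27 s⁻¹) and
`GAS_minus`/`PLA_minus` (classical fits; k̂_hyd = 0). The nine metabolic
constants default to literature values for mammalian skeletal muscle
([ADP]₀ = 0.01 mM, [ATP]min = 1.2 mM, pools 7/25/46 mM, K_adk = 1,
K_ck = 200, k_con = 0.1 s⁻¹, μATP,max = 60 kJ/mol). Temperature defaults
to 312.15 K (39 °C), matching the heated preparation the mechanical
parameters were fitted against. Estimation bounds per muscle are in
`params.BOUNDS`. Lengths are meters internally; configs may declare
`length_unit: mm`.

## Simulation and numerics

Integration is LSODA, piecewise between stimulation breakpoints (so the
discontinuous u(t) never crosses a solver step), with rtol 1e−8 and
per-state atol (1e−10 γ̃, 1e−12 m, 1e−9 mM), dense output on the
protocol's sampling grid (default 1 kHz, matching the experimental
sampling). Halving the tolerances moves the peak force by <0.1%.
Runs start from rest: γ̃ = 0, metabolites at the resting equilibrium
([ADP] = [ADP]₀), ℓCE at the passive mechanical equilibrium including
the q_min-level resting activity. The degenerate passive equilibrium
(MTU shorter than the combined slack lengths, zero resting activity)
returns ℓCE = ℓMTU − ℓSEE,0, the continuous limit of the equilibrium as
the resting activity goes to zero.

Because q_min > 0, a resting fiber hydrolyzes ATP (~0.1 mM/s here) and
its force creeps by ~2e−5·Fmax over a 1.2 s hold; an exactly constant
passive hold requires k̂_hyd = 0.

## Estimation

All experiments of one muscle are fitted simultaneously. The objective
is the L2 residue scaled to 1000 data points,
sqrt((1000/N)·Σr²); the per-point L1 residue is reported alongside.
Optimization is trust-region-reflective least squares inside the bound
hyperrectangle, multi-started (default 8) from the starting parameter
point plus scrambled-Sobol samples — the Sobol sequence is prefix-stable,
so adding starts can only improve the best objective, and everything is
deterministic for a fixed seed. The finite-difference step of the
optimizer is relative 1e−3: the default square-root-of-eps step would
probe force changes below the integrator noise floor (~rtol·F) and stall.
Experiments are stacked unweighted.

Sensitivity time courses are relative central differences
S_θ(t) = (∂F/∂θ)(θ/F) with relative step 1e−4; where F(t) is numerically
zero the row switches to the absolute scale (∂F/∂θ·θ) and is flagged.
Truncation at |1| applies only to exported matrices, never internally.

## Synthetic experiments

`io.generate_fixtures` emulates the isometric rabbit experiments the
presets were fitted to, which are not available as machine-readable
files: 1.2 s runs at 1 kHz, stimulation 0→1 at 0.1 s for 0.7 s, the
muscle-specific MTU length series (GAS: 114–120 and 128–132 mm, n = 7;
PLA: 114–124 mm, n = 6), and additive i.i.d. Gaussian force noise
(default σ = 0.5 N, the order of the per-point L1 residues of the
original fits), seeded. What the fixtures do **not** emulate: measurement
drift, stimulation-artifact transients, trial-to-trial variability of the
preparation, or any model-mismatch component — so parameter-recovery
tests on fixtures demonstrate the correctness and identifiability of the
estimation pipeline, not the model's adequacy for real recordings.

## Exhaustion analyses

Exhaustion time is the first instant force is more than a threshold
(default 5%) below its reference. The default reference is the running
maximum of the trace: constant-stimulation runs start passive, so the
literal value at t = 0 (a few newtons of passive force) would never
trigger; for runs started at an activated steady state the two
conventions coincide, and `reference="initial"` provides the literal
mode. Map runs apply constant u from t = 0, are integrated in 2 s chunks
at 100 Hz output, and stop at the first crossing, so high-stimulation
cells are cheap. The ∞ sentinel is encoded as −1 plus a
`never_exhausts` flag in exports.

The quasi-steady force decay rate is the mean dF/dt over the 0.58–0.68 s
window of the standard tetanus, normalized by Fmax. That window still
contains the tail of the activation transient (≈ +0.02 Fmax/s with
hydrolysis off), so analyses that need the hydrolysis-driven component
alone should difference against a k̂_hyd = 0 control, as the test suite
does. The theoretical counterpart is rate = −κ·F̃isom(ℓCE)·ℓCE,opt/ℓCE —
the same ℓ̃CE-scaling as the hydrolysis rate; κ is fitted in closed form
(ratio of sums, clamped at zero). The q̃ = 1 premise behind that formula
holds only near optimal length: at short CE lengths the cubic calcium
sensitivity collapses q̃ and realized decay rates fall well below the
F̃isom/ℓ̃CE profile.

## Known limitations

- The creatine-kinase/adenylate-kinase refueling is an *instantaneous*
  equilibrium. It holds [ATP] within 3% of its resting value until the
  phosphocreatine buffer is nearly depleted (~1.7 s of full tetanus for
  GAS), so prolonged-tetanus force decay here (~9% over 1.4 s of
  stimulation) is weaker than decay produced by finite-rate refueling,
  and the chemical potential cannot fall below ≈0.61 on the manifold.
- With the default c0 normalization the condensation flux is negligible
  against the pools, so the hydrolysis/condensation equilibrium is
  unreachable and [Pi] accumulates at every stimulation level, including
  rest. Under a 5%-decay criterion with a 60 s horizon every constant-u
  run eventually exhausts; a strict non-exhaustion boundary does not
  exist for this parameterization (the measured boundary force is the
  u→0 limit, ≈0.9% of Fmax).
- Exhaustion time increases with CE length *at fixed force*; at fixed
  stimulation the relation inverts at short lengths, where troponin
  activity, not phosphate kinetics, limits force.
- Not modeled: pH/proton kinetics, lactate, calcium-sensitivity
  modulation by Pi, magnesium, glycolytic ATP supply, temperature or
  fiber-type dependence of the rate constants, pennation/gearing,
  history-dependent force enhancement, and motor-unit recruitment
  (exhaustion under constant stimulation is not the ergonomic endurance
  time, which includes recruitment compensation).
- Parameters were identified from isometric data only; dynamic
  (shortening) protocols are out of scope and quick-release behavior is
  untested.

## Problem sizes used in the checks

The packaged verification uses desk-scale problems: 1.2–1.9 s tetani at
1 kHz, 30–60 s constant-stimulation runs at 100 Hz, a 12-run bisection
for the non-exhaustion boundary, a 5×5 exhaustion map with a 30 s
horizon, 150 random force-balance states per muscle against a bisection
oracle, 100 random phosphate targets against a dense-grid projection
oracle, and single-parameter refits on seven 1 kHz traces.
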