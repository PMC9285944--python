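# Methods

`cardiobo` estimates the passive stiffness of the left ventricle (LV) from
the kind of data a routine cardiac MR study provides — one end-diastolic
cavity volume, 24 regional circumferential strains and an early-diastolic
volume — by Bayesian optimisation of a reduced Holzapfel–Ogden (HO)
parametrisation against a forward model of diastolic inflation.  This note
records the model, the algorithms, the numerical choices, and what the
idealised forward model does and does not share with a patient-specific
finite-element study.

## Constitutive model and reduced parametrisation

Passive myocardium is modelled as an incompressible, invariant-based
hyperelastic material with a layered fibre architecture:

    W = a/(2b) exp[b(I1−3)]
      + Σ_{i∈{f,s}} a_i/(2b_i) ( exp[b_i ⟨I4i−1⟩²] − 1 )
      + afs/(2bfs) ( exp[bfs I8fs²] − 1 ),

with I1 = tr C, I4f = f0·C f0, I4s = s0·C s0, I8fs = f0·C s0 for
C = FᵀF, and ⟨x⟩ = max(x, 0).  The eight coefficients
ϑ = (a, b, af, bf, as, bs, afs, bfs) — a-types in kPa, b-types
dimensionless — are strongly correlated and not identifiable from sparse
in vivo data, so estimation operates on four positive scalings
θ = (θ1..θ4) of a literature reference vector ϑ0:

    a = θ1 a0, b = θ1 b0;  af = θ2 af0, as = θ2 as0;
    bf = θ3 bf0, bs = θ3 bs0;  afs = θ4 afs0, bfs = θ4 bfs0.

Two reference vectors ship with the package: an ex vivo fit
(`ex_vivo_wang`) and an in vivo population average (`in_vivo_gao`).
The anisotropic terms are tension-only (⟨·⟩): collagen fibre families do
not stiffen in compression.  Cauchy stress for the homogeneous deformations
used here is

    σ = 2ψ1 B + 2ψ4f f⊗f + 2ψ4s s⊗s + ψ8fs (f⊗s + s⊗f) − p I,

with B = FFᵀ, f = F f0, s = F s0, and the pressure-like multiplier p
resolved algebraically from the stated traction-free directions.  If the
listed traction-free axes imply inconsistent values of p the configuration
is rejected rather than averaged silently.  Consistency of σ with a
central-finite-difference gradient of W through F is enforced by test at
1e−5 relative accuracy on random unimodular deformations.

Stress–stretch summaries use incompressible uniaxial extension
F = diag(λ, λ^−1/2, λ^−1/2) along the myocyte or the sheet direction,
reported for λ ∈ [1, 1.3].

## The idealised forward model

The FEM solve of a patient-specific LV is replaced by a desk-scale
idealisation: the LV is a stack of four thick-walled incompressible
cylindrical slices (base → mid-ventricle), each split into six regional
sectors, 24 sectors in all, mirroring the four short-axis slices with six
segments each of the strain protocol.  For each sector, incompressibility
at fixed axial stretch gives the through-wall map
r(R)² = ri² + (R² − Ri²)/λz, and radial equilibrium reduces to one
quadrature per sector,

    P(ri) = ∫ (σθθ − σrr)/r dr,

in which the incompressibility multiplier cancels.  The inner radius is
found by Brent root bracketing (tolerance 1e−10·Ri); the integral uses
32-point Gauss–Legendre quadrature (64 points changes volumes by < 1e−10
relative, far inside the 0.1% requirement).  Pressures are accepted in
mmHg and converted at 1 mmHg = 0.133322 kPa.  Readouts are the cavity
volume V (per-slice mean sector radius) and the regional strains
ε_i = h_i (λθ,mid − 1), with h_i fixed regional heterogeneity multipliers
near 1.

Geometry features and why they are there:

* **Slice taper** (default radii ×1.0, 0.95, 0.85, 0.70) — base-to-mid
  narrowing; slices operate at different stretches.
* **Per-region wall thickness** (six factors per slice, 0.8–1.3 on
  per-slice base thicknesses 12/24/18/19 mm) — septal/free-wall thickness
  variation; each region equilibrates at its own wall stretch, so the 24
  strains probe the stiffening response at 24 strain levels.
* **Per-slice helix range** (±60° at the base rotating towards
  longitudinal, (60→78)° endo and (−60→15)° epi) — where fibres leave the
  circumferential direction, the hoop load is matrix-borne, which
  separates the matrix scaling θ1 from the fibre scalings.
* **Per-slice axial pre-stretch** (1.0, 1.03, 1.09, 1.14) — a base-to-mid
  longitudinal strain profile; mid-wall fibres are nearly circumferential
  and blind to λz while the isotropic term is not, a second θ1/θ2–θ3
  discriminator.
* **Optional torsion and sheet tilt** (used by fixtures `toyC`/`toyD`) —
  give the shear pair (afs, bfs), i.e. θ4, a pathway into the
  observations; with both zero, θ4 is exactly inert, as expected from the
  low shear sensitivity of circumferential data.

These features were fixed by an identifiability analysis: with them, exact
multistart local optimisation of the volume-weighted objective on
noise-free synthetic data recovers θ1–θ3 uniquely from any start; without
them, a single-pressure observation of a homogeneous cylinder collapses to
essentially one independent observable and no optimiser could recover the
material curves.

**Crash rule.**  Forward solvers for soft-tissue models fail at parameter
values that violate their physiological assumptions.  The toy reproduces
this deterministically: if any sector's inner-wall circumferential stretch
at the requested pressure exceeds its slice's limit (defaults 1.63, 1.74,
2.10, 2.60), or the equilibrium bracket fails, the solve reports a crash
and returns no payload.  The crash set is the overall-soft corner of the
scaling box — predominantly low θ2/θ3, since at high stretch the
circumferential load is fibre-borne for the in vivo reference — and it is
exactly monotone in θ1 (wall pressure strictly increases with θ1, so
reducing θ1 can only keep a crash).  At 30 mmHg the region reaches to
roughly θ2 ≲ 0.5 / θ3 ≲ 0.65; at 8 mmHg only a deeper corner crashes.

**What the toy is not.**  Strains are engineering analogues
(h_i(λθ,mid − 1)) of Lagrangian segmental strains; sectors equilibrate
independently (no inter-sector shear); there is no residual stress,
no unloaded-geometry estimation and no apex.  Passing tests demonstrate
the estimation machinery end-to-end on a nonlinear, exponentially
stiffening, crash-prone forward problem — they do not validate any
statement about real LV mechanics.

## Objectives and the Klotz high-pressure penalty

Three least-squares objectives match a simulation to an observation
(V*, ε*_1..24 at the assumed end-diastolic pressure P* = 8 mmHg):

    fO1       = (V − V*)²      + Σ (ε_i − ε*_i)²
    fO2       = (V − V*)²/V*   + Σ (ε_i − ε*_i)²
    fO2_klotz = ((V8 − V8*)/V8*)² + Σ (ε_i − ε*_i)² + ((V30 − V̂30)/V̂30)²

The two relative-volume conventions (÷V* vs squared relative error) are
deliberately non-uniform; both are implemented exactly as stated.  The
Klotz empirical law P = A·Ṽ^B (A = 27.78 mmHg, B = 2.76), with the
normalised volume Ṽ = (V − V0)/(V30 − V0), predicts the unobservable
30 mmHg volume from the measurement and the early-diastolic volume proxy
V̂0:  V̂30 = V̂0 + (V* − V̂0)/(P*/A)^{1/B}.  The penalty anchors the
estimate's high-pressure behaviour to a population curve.  Note the
consequence, visible in the synthetic studies: because the penalty
references an *empirical* law rather than the generating model, the
Klotz-penalised optimum on noise-free synthetic data sits slightly off the
generating parameters (the law and the toy model disagree by a few percent
at 30 mmHg).  Recovery experiments therefore score the pure data match
fO2; the Klotz objective is for realism under extrapolation, not for
recovering a known truth.

Every objective also returns its vector of partial error terms (25 terms
for fO1/fO2, 26 with the Klotz penalty); the partials sum to the total at
float accuracy by construction.

## Surrogates

The objective surrogate is a zero-mean GP with Matérn 3/2 ARD kernel,
k = σk²(1 + √3 r) e^{−√3 r}, r² = Σ (Δx_i/l_i)², plus observation-noise
variance σ² and diagonal jitter 1e−9 (escalated ×10 to at most 1e−4 on
factorisation failure).  Hyperparameters maximise the log marginal
likelihood by L-BFGS with analytic gradients in log-space, with 8
Latin-hypercube restarts on the first fit and 2 warm-started restarts on
the periodic refits.  The forward model is deterministic, so the driver
bounds σ² at jitter scale (1e−12..1e−8); the GP then interpolates.
Predictive variances are floored at zero.  Training-set growth between
refits uses a rank-one Cholesky extension; a near-duplicate point triggers
a full refactorisation instead.

Two surrogate paradigms share one implementation: the *target* surrogate
(one GP on the total) and *partial error surrogates* (one independent GP
per squared-error term; 25 or 26 of them).  Outputs are standardised per
term with moments frozen on the initial design (sd floored at 1e−12 for
degenerate terms); de-standardised posterior moments are
μ = m0 + s0 μ̃ and k = s0² k̃, and under the independence assumption the
total's moments are the sums of the per-term moments — exactly, which is
tested.  With one term the partial machinery reduces to the target
surrogate, so the driver treats both uniformly.

**Crash classifier.**  Feasibility is learned by a GP classifier with a
probit likelihood and the same Matérn 3/2 ARD kernel, fitted by
expectation propagation (damping 0.8, falling back to 0.24 before
failing; site tolerance 1e−4, 40 sweep cap).  Kernel hyperparameters are
selected by a seeded candidate search over the EP evidence (8 candidates
on the first fit, warm-started afterwards); full refits happen on the same
cadence as the surrogate refits, and site parameters are refreshed every
iteration by warm-started EP (one sweep after a success, three after a
crash).  Until the first crash is observed there is no second class and
the feasibility probability is identically 1.

**V30 emulator.**  With the Klotz objective, the 30 mmHg volume can come
from a second forward solve or from a pre-trained GP emulator over
(θ1..θ4, V̂0).  The training design is a Latin hypercube over the search
box and a V̂0 range, with geometry size varied by shape-preserving
scaling to hit target load-free volumes (pressure–stretch response is
scale-invariant, so one reference shape spans the size axis); crashed
design points are dropped.  Queries far outside the training hull
(10% margin per axis) raise a flag.  Held-out accuracy on a 200/50 split
is below 2% of the mean V30, and re-scoring an emulator-driven optimum
with the simulator moves the Klotz objective by well under 1e−2.

## Acquisition and the optimisation loop

Expected Improvement in closed form,
EI = (f*−μ)Φ(z) + s φ(z), z = (f*−μ)/s (s → 0 degenerates to
max(f*−μ, 0)), weighted by the classifier's success probability:
EIcon = EI·P.  No exploration offset is used.

The inner maximisation of EIcon uses a documented, seeded scheme in place
of the commercial scatter-search optimisers often used for this step: a
64-point
Latin-hypercube scan of the box (plus centre), Nelder-Mead refinement of
the 8 best scan points *and* of a scatter-search-style reference set — the
5 best evaluated points, random pairwise convex combinations of them, and
small perturbations of the incumbent — with deduplication of converged
optima (1e−4; ties towards the lexicographically smallest point).  The
reference-set starts matter: EI's exploitation peaks sit in the gaps
between good samples, where a space-filling scan rarely lands.  If the
whole surface is numerically zero the highest-posterior-variance scan
point is returned (pure exploration).

A run is a seeded Latin hypercube of n_init = 10·d = 40 points, each
pushed through the forward model (crashes become classifier labels only;
at least two successes are required, otherwise initialisation aborts with
advice to widen the box), followed by n_iter = 500 acquisition-driven
queries (540 forward evaluations in total; crashed queries count — each is
a simulator invocation).  Surrogate hyperparameters are refit every 10
iterations.  The incumbent trace is the running minimum over successful
evaluations, one row per evaluation.  A single seed fixes the design, all
restarts, and the per-iteration acquisition seeds; identical seeds give
bit-identical runs.

The search box defaults to [0.1, 5]⁴, bracketing θ = 1 and the crash
region.  Coordinates are searched linearly by default; a `log_scale`
option works in log-θ instead.  On the 2-d reduced problem (θ3, θ4
fixed; 20+60 evaluations) the linear parametrisation reaches an objective
below 1e−3 in 9/10 seeds versus 6/10 for the log variant, which decided
the default; in the full 4-d problem the two are statistically
indistinguishable.  Bounds with lower = upper pin a coordinate and remove
it from the search (used by reduced-dimension studies).

### Convergence at the study budget — a known limitation

At the study budget of 540 (or 240 in the scaled tests) evaluations, the
optimiser reliably reaches objective values around 1e−3 on noise-free
synthetic subjects and ~1e−3–1e−2 noise floors on noisy ones — the typical
BO signature of fast initial descent followed by a plateau.
Noise-free *curve recovery to 5%*, however, requires pushing
the objective another one-to-two orders of magnitude down the narrow
amplitude/exponent valley of the HO family (θ2↓ vs θ3↑ with θ1
compensating), and EI-driven search achieves that in only ~2 of 10 seeds
at 240 evaluations; exact local optimisation needs roughly 1500
evaluations for the same feat.  The corresponding acceptance check is
therefore expected to fail at its stated threshold; it is kept at the
stated conditions rather than weakened.  Practical advice outside tests:
give the optimiser more iterations (the default 540 helps), or polish the
incumbent with a local search if simulator calls are cheap.

## Baseline (multi-step) estimator

The staged baseline rescales parameter groups against staged objectives:
Step 1 fits (Ca, Cb) — all a-types ×Ca, all b-types ×Cb — under fO1;
Step 2 frees (af, bf, as, bs) under fO2; the final step fits a single C3
rescaling, (a, afs) in the original variant under fO2, (a, b) in the
updated variant under fO2_klotz, the updated variant also inserting a
(Ca, Cb) refinement under fO2_klotz after Step 2.  The published step
listings are not machine-readable, so this schedule is a reconstruction of
their prose description; it is config-driven so alternative step orders
remain pluggable.  Each step is a bounded Nelder-Mead search in log-space
(60 evaluations by default); every simulator call is counted, Klotz-step
calls twice (8 and 30 mmHg).  By convention the original variant starts
from the ex vivo reference and the updated one from the in vivo reference.
Paired evaluation reports the BO incumbent at the baseline's evaluation
count and the first BO evaluation matching the baseline's final objective.

## Residual bootstrap

Uncertainty for a point estimate θ̂ uses a residual bootstrap: strain
residuals at θ̂ are resampled with replacement and added back to the
fitted strains to form B pseudo-observations; each is re-optimised by a
surrogate-assisted local search — GP emulators of the simulator *outputs*
(volume and each strain) trained on a ~60-point local design around θ̂
(±50%, clipped to the box), then Nelder-Mead from θ̂ on the emulated
objective, costing no further simulator calls per replicate.  Noise-free
data give identically zero residuals, hence degenerate (flagged)
intervals; interval widths grow monotonically with the injected
observation noise.  Per-coordinate quantile intervals are nested across
coverage levels by construction.

## Synthetic subjects

A subject is (θ_true, geometry, noise): seeded heterogeneity multipliers
h_i ~ N(1, 0.05²) (clipped to [0.5, 1.5]), a forward solve at 8 mmHg,
additive Gaussian noise (strain sd 0.005, volume sd 1 mL — a few percent
of signal, so recovery tests stay informative; zero for noise-free
studies), and V̂0 set to the zero-pressure solve.  Ground truths live in
truth sidecars that only tests read.  Four fixture geometries
(`toyA`–`toyD`, ~22 mm cavity radius, 68–78 mm length, volumes in the
human range: V̂0 ≈ 70–105 mL, V8 ≈ 130–170 mL, strains ≈ 0.04–0.22)
and interior ground truths (θ ∈ [0.7, 2.2] approx.) make up the
four-subject fixture suite; all fixture subjects are feasible at both 8
and 30 mmHg by construction.

## Problem sizes used by the test suite

The full study design is 40 + 500 evaluations per run.  To keep the test
suite fast the end-to-end checks run scaled studies, with thresholds kept
at their stated proportions: curve recovery at 40+200 evaluations over 3
seeds; crash learning at 40+200 over 5 seeds; the baseline comparison on
4 subjects × 2 seeds with the BO budget matched to each baseline's own
evaluation count; the 2-d convergence check over 6 seeds; bootstrap checks
at B = 8–30.  The command-line default remains the full 540-evaluation
study.
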