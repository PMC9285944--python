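# cardiobo

Bayesian optimisation of passive left-ventricular myocardial stiffness from
routinely measurable end-diastolic data.

## The problem

Passive myocardial stiffness is a key marker in diastolic heart failure,
but it cannot be measured directly in vivo.  It can be *inferred*: a
biomechanical model of the left ventricle (LV) in diastole, built on the
Holzapfel–Ogden (HO) hyperelastic constitutive law, is calibrated so that
its predicted end-diastolic cavity volume and 24 regional circumferential
strains match the measurements extracted from cardiac MR images at an
assumed end-diastolic pressure of 8 mmHg.  Each forward evaluation of such
a model is expensive, so the number of model evaluations is the budget
that matters.

`cardiobo` implements this inverse problem as a crash-aware, constrained
Bayesian-optimisation (BO) framework, exercised end-to-end against a fast
idealised LV inflation model standing in for a finite-element solver.
It is aimed at researchers in cardiac-model calibration and at
methodologists who want a complete, reproducible BO-for-inverse-problems
reference implementation with a nontrivial, crash-prone forward model.

## The method in brief

* **Constitutive model.**  Incompressible HO strain energy
  `W = a/2b·e^{b(I1−3)} + Σ_{i∈{f,s}} a_i/2b_i (e^{b_i⟨I4i−1⟩²}−1)
  + afs/2bfs (e^{bfs·I8fs²}−1)` with eight parameters
  ϑ = (a, b, af, bf, as, bs, afs, bfs).  Estimation operates on four
  positive scalings θ of a literature reference vector (matrix pair,
  fibre/sheet stiffnesses, fibre/sheet exponents, shear pair), which
  restores identifiability from sparse data.
* **Objectives.**  Least-squares matches of volume and 24 strains
  (`fO1`, `fO2`), optionally with a high-pressure penalty
  (`fO2_klotz`): the Klotz empirical law P = A·Ṽ^B (A = 27.78 mmHg,
  B = 2.76) predicts the unobservable 30 mmHg volume from the measurement
  and the early-diastolic volume, anchoring the estimate's behaviour at
  pressures never seen in vivo.
* **Surrogates.**  Zero-mean Matérn 3/2 ARD Gaussian processes — either
  one GP for the objective or one *partial error surrogate* per
  squared-error term (the total's posterior moments are then the sums of
  the de-standardised per-term moments, and Expected Improvement stays in
  closed form).
* **Acquisition.**  Expected Improvement weighted by the probability that
  the forward solve will not crash, learned online by a probit GP
  classifier fitted with expectation propagation; the inner maximisation
  is a seeded multistart with a scatter-search-style reference set.
* **Baseline.**  The multi-step rescaling algorithm used in the field
  (group scalings Ca/Cb, fibre/sheet step, final C3 rescale; original and
  updated variants) for head-to-head comparison, plus a residual
  bootstrap for uncertainty and a GP emulator of the 30 mmHg volume.

The forward model is a tapered four-slice, 24-sector thick-walled-cylinder
LV with transmural fibre helices, regional wall-thickness variation and a
deterministic crash rule — see `docs/methods.md` for its assumptions and
for what it does and does not share with a patient-specific FEM study.

## Worked example

Generate a synthetic subject and estimate its stiffness scalings with the
Klotz-penalised objective (a scaled run; the full study default is
40 + 500 evaluations):

```yaml
# study.yaml
seed: 7
output_dir: out
subject:
  geometry: toyA
  theta_true: [1.4, 0.8, 1.1, 1.0]
bo:
  objective: fO2_klotz
  v30_source: simulator
  n_init: 40
  n_iter: 100
```

```bash
$ cardiobo run-bo --config study.yaml
{"ymin": 0.0005409791069737456, "imin": 140, "crash_count": 3}
```

The run writes `out/trace.csv` (one row per forward evaluation:
θ, objective, crash status, incumbent), `out/summary.json` and
`out/curves.csv` (stress–stretch curves of the estimate in the myocyte and
sheet directions).  Here the best objective 5.4e−4 was reached at
evaluation 140 of 140, three queries crashed the forward solve (and taught
the feasibility classifier), and the recovered scalings were

```
theta_best = [1.394, 0.732, 1.447, 4.605]
```

against a ground truth of (1.4, 0.8, 1.1, 1.0): the matrix scaling θ1 is
recovered well, the fibre amplitude/exponent pair (θ2, θ3) sits slightly
along its compensation valley (the Klotz penalty references an empirical
law, so the optimum is intentionally not the generating truth), and θ4 is
unidentifiable here because this geometry activates no fibre–sheet shear —
its value is meaningless and the stress–stretch curves do not depend on
it.

Other verbs: `simulate-subject`, `run-hgo` (the multi-step baseline),
`train-v30` (the high-pressure volume emulator), `bootstrap` (residual
bootstrap intervals), `curves`.  Every verb takes `--seed` to override the
config seed; a run's effective configuration is echoed next to its
outputs, and identical seeds reproduce runs bit-for-bit.

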