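# Methods

## Forward model

A fascicle model class is a pair (fiber content `f_r`, helix angle `θ`),
with `θ` measured in degrees from the plane perpendicular to the tendon axis
(the angle from the axis is `90° − θ`). The default grids — contents 35–65 %
in 5 % steps, angles 70–76° in 1° steps — give 49 classes and reflect the
composition and helix ranges reported for real fascicles.

**Elasticity.** The initial fascicle modulus uses a pluggable surrogate
`E_fasc(0) = f_r E_f g(θ) + (1 − f_r) E_m` with the default angle factor
`g ≡ 1` (plain rule of mixtures). A detailed helical finite-element
homogenization would make `E_fasc` a nonlinear function of `θ` as well; the
plain mixture reproduces the published MAP fiber-modulus extremes at the
content-grid endpoints to within a few percent but deliberately does not
reproduce the ~150 MPa spread across angles at fixed content. Angle-penalty
variants (`cos²`/`cos⁴` of the axial angle) were considered and rejected:
they overshoot the published moduli. `g` is an injectable callable so a
higher-fidelity elastic model can be swapped in without touching anything
else; when a non-default `g` is used, the absolute relaxation curve is
anchored as `q1 · Ē(t)` so the elastic and viscoelastic observables can
never disagree at `t = 0`.

**Poisson's ratio.** Fascicles show Poisson's ratios of 1–3, far above
classical bounds, driven by the helical fiber architecture and the large
fiber/matrix stiffness contrast. The surrogate interpolates between the
near-incompressible matrix value `ν_m = 0.5` (stiff-matrix limit) and the
rigid-fiber kinematic limit `ν_h = cot²(90° − θ)`:

```
ν = ν_m + (ν_h − ν_m) / (1 + κ x),   x = (E_m/E_f)(1 − f_r)/f_r
```

It is a constructed closed form, contract-tested only on its limits and
monotonicities (strictly decreasing in `E_m`, increasing in `θ`). The
blending constant `κ = 4·10⁴` (dimensionless, default) places `E_m` in the
few-tenths-of-MPa range when a fascicle Poisson's ratio of 1 is observed
with `E_f ≈ 1400 MPa`, consistent with the sub-MPa matrix moduli reported by
analytical studies. Inference can exclude the Poisson block entirely
(`observables=("elastic", "relaxation")`), making the fiber results
independent of this surrogate.

**Viscoelasticity.** Fibers are a standard linear solid with equilibrium
modulus `E_∞ = r_∞ E_f`, relaxing modulus `E_R = (1 − r_∞) E_f` and a single
viscosity `η_f`, so `τ = η_f / E_R`; the matrix is treated as elastic and
time-constant because it is more than two orders of magnitude softer than
the fibers and contributes negligibly to relaxation. The retained fraction
`r_∞` is an explicitly inferred parameter (uniform prior on [0.05, 0.95]):
the three-parameter vector (`E_f`, `η_f`, `E_m`) cannot by itself fix the
relaxation asymptote, and inferring `r_∞` is preferred over pinning it to
each curve's empirical plateau, which would couple a parameter to one noisy
datum. Units are SI-consistent internally (MPa, MPa·s, s); `η_f` is reported
in GPa·s (1 GPa·s = 1000 MPa·s).

## Probability model

Every datum carries proportional Gaussian error: mean `F`, standard
deviation `σ_n F` (variance `σ_n² F²`). The likelihood is the product over
the enabled observable blocks — elastic replicates vs. `q1`, the Poisson
value vs. `q2`, each relaxation point vs. `q3(t_j)` — with one shared `σ_n`
and equal weight per datum. A covariance of the form `σ_n² diag(F)` was
rejected as dimensionally inconsistent with the proportional-error statement.
Priors are independent uniforms on a closed box; boundary points carry
finite density. Non-positive forward predictions (impossible for parameters
inside the box) yield `−inf` with a logged warning.

## TMCMC

The sampler follows the standard transitional/tempered scheme: stage
exponents chosen by bisection (to 1e−10) so the incremental-weight COV hits
the target (1.0 by default, returning exactly 1 when attainable), multinomial
resampling, and Gaussian random-walk rejuvenation with proposal covariance
`β² Σ_w` (`β = 0.2`, `Σ_w` the plausibility-weighted sample covariance,
regularized by a 1e−10 diagonal jitter). Proposals outside the prior box are
rejected through the prior term. The log-evidence is the sum of stage
log-mean-weights. Acceptance rates outside [0.05, 0.95] raise a log warning,
not a failure.

One deliberate departure from the scheme's textbook defaults: **five** MH
rejuvenation steps per resampled particle rather than one. At 1000 particles
a single step leaves the final ensemble visibly underdispersed — credible
intervals come out too narrow and the noise-scale marginal skewed, which we
verified by comparing against a long affine-invariant ensemble (emcee)
reference run on the identical posterior; with five steps the TMCMC
marginals match that reference to ~1 % at negligible extra cost. MAP values
are insensitive to this choice because they are polished by a bounded
Nelder–Mead search of the exact log-posterior (points outside the prior box
score `−inf`, so the search cannot leave it; the refined point is kept only
if it improves the posterior).

Determinism: one `numpy` generator seeded from the config drives the whole
run; identical config + seed gives bit-identical ensembles. Grid runs derive
one seed per (class, dataset) cell from a SHA-256 hash of the master seed
and the cell identity, so cells are independent, reproducible, and
order-insensitive.

## Synthetic data

The generator emulates the statistical structure the likelihood assumes:
elastic replicates `q1(1 + ε_k)`, Poisson value `q2(1 + ε)`, and relaxation
points `q3(t_j)(1 + ε_j)` at equally spaced times, all with the same
proportional noise (default `σ_gen = 0.05`, the scale consistent with the
published ≤8 % model-error bound). Noisy curves are kept raw — no clipping
to 1 and no re-monotonization — because noise handling belongs to the
likelihood; consequently a dataset's normalized modulus may slightly exceed
1 near `t = 0`, and the dataset validator allows values up to 1.25 while
still enforcing strict positivity and strictly increasing times.

The five-dataset fixture suite mirrors the study layout: every dataset
carries the three printed fascicle moduli {640, 480, 550} MPa verbatim
(so printed-number checks are exact rather than resampled), Poisson's ratio
1 except for the second dataset's 3, and relaxation curves generated from
versioned ground truths chosen inside the reported experimental envelope —
40–70 % modulus loss over horizons of 300–500 s and viscosities of tens of
GPa·s (`E_f = 1400` MPa throughout; D1/D2 share `τ = 50 s`, `r_∞ = 0.40`
over 300 s; D3–D5 vary `r_∞ ∈ {0.50, 0.35, 0.45}` and `τ ∈ {120, 100, 90}` s
over 400–500 s). The exact time grids of the source figures are unknown;
these horizons are representative, not replicas.

What the fixtures do *not* emulate: correlated noise along a relaxation
curve, strain-rate and strain-magnitude dependence, multi-exponential
relaxation, preconditioning effects, and any angle dependence of the elastic
modulus. Passing recovery tests therefore demonstrate that the inference
machinery is correct and calibrated *under the model's own assumptions*, not
that the model captures every feature of real fascicle data.

## Numerical choices and problem sizes

- Bisection tolerance 1e−10 on tempering exponents; `max_stages = 50`
  (typical runs need 7–17 stages).
- 95 % central credible intervals are plain quantiles of the final-stage
  samples; for skewed posteriors the MAP may legitimately fall outside a
  central interval, so only `lower < upper` is asserted.
- Degenerate inputs: `r_∞ = 1` (no relaxing branch, flat curve) and
  `f_r = 1` (pure fiber) are accepted as limiting test values though outside
  the inference grids; `θ = 90°` is rejected (undefined helical limit).
- Test-suite problem sizes are chosen for fast, well-converged runs: 400–1000
  particles per stage for inference cells, 20 seeded replicates for recovery
  and calibration checks, 50 seeds for the evidence-bias check on the 1-D
  closed-form target, a 401² grid quadrature as the bimodal-evidence oracle,
  and an explicit-Euler integration at `Δt = 10⁻³ s` as the independent
  oracle for the closed-form relaxation curve.

## Known limitations

- The elastic and Poisson surrogates are stand-ins for a full helical
  finite-element homogenization; angle trends at fixed content are not
  reproduced, and `E_m` inferences made *without* the Poisson block are
  prior-dominated.
- One shared `σ_n` across heterogeneous observable blocks is an assumption;
  per-block noise scales would need a config extension.
- Evidence values are reported per class but deliberately not used for
  model averaging or selection across the 49 classes.
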