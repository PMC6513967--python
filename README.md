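# fasciclebayes

Bayesian inference of tendon **fiber-scale** viscoelastic properties from
**fascicle-scale** experimental observations.

Tendon fascicles (hundreds of µm) are composites of helically wound collagen
fibers (µm scale) embedded in a soft matrix. Fascicle-scale quantities —
elastic modulus, Poisson's ratio, and stress-relaxation curves — are routinely
measured, but the mechanical properties of the embedded fibers themselves
(their elastic modulus `E_f` and, especially, their effective viscosity
`η_f`) are not directly measurable. This package infers them, together with
the matrix modulus `E_m`, by inverting a composite viscoelastic forward model
inside a Bayesian framework. The resulting (`E_f`, `η_f`) pairs are the kind
of quantitative basis needed for designing biomimetic artificial tendon
fibers and scaffolds.

## Model

For a fascicle model class `M_{f_r,θ}` (fiber area fraction `f_r`, helix
angle `θ` from the plane perpendicular to the tendon axis), the fibers follow
a standard linear solid (equilibrium spring `E_∞ = r_∞ E_f` in parallel with
a Maxwell arm `E_R = (1 − r_∞) E_f`, viscosity `η_f`), while the matrix is
elastic and time-constant:

```
E_fasc(t) = f_r (E_∞ + E_R e^{−(E_R/η_f) t}) + (1 − f_r) E_m
```

Three observables are predicted per class: `q1 = E_fasc(0)`, `q2 = ν_fasc`
(a helical-constraint Poisson surrogate), and `q3 = Ē(t) = E_fasc(t)/E_fasc(0)`.
Every datum `d` is modeled with proportional Gaussian error,
`d = F(φ)(1 + ε)`, `ε ~ N(0, σ_n²)`, and the parameter vector
`ϑ = (E_f, η_f, E_m, r_∞, σ_n)` carries independent uniform priors
(`E_f ∈ [500, 2500]` MPa, `η_f ∈ [0.1, 2500]` GPa·s, `E_m ∈ [0.01, 5]` MPa,
`r_∞ ∈ [0.05, 0.95]`, `σ_n ∈ [0.001, 0.3]`).

The posterior `p(ϑ | D, M_{f_r,θ}) ∝ p(D | ϑ, M) p(ϑ)` is sampled with
**Transitional MCMC** (tempered prior→posterior stages whose exponents are
set by the coefficient of variation of the importance weights, with
resample-and-move rejuvenation), which also yields the model evidence
`p(D | M)`. Maximum-a-posteriori (MAP) values are polished by a bounded
derivative-free local search.

Because the digitized experimental relaxation curves behind the original
study exist only as figures, the package ships a synthetic-data generator
(`fasciclebayes.synthetic_data`) that emulates the study's data layout — the
three printed fascicle elastic moduli {640, 480, 550} MPa, Poisson's ratios
of 1 or 3, and monotone relaxation curves losing 40–70 % of the initial
modulus over 200–500 s — from known ground truth, so the whole pipeline is
testable end to end.

## Worked example

Infer fiber properties for the lowest- and highest-content model classes
from a study-layout dataset (printed elastic moduli plus a synthetic
relaxation curve, 5 % proportional noise):

```python
from fasciclebayes import FascicleClass, PriorSpec, TmcmcConfig, make_fixture_suite
from fasciclebayes.pipeline import run_cell

d1 = make_fixture_suite(seed=1)[0][0]          # D1-layout dataset
for f_r, theta in [(0.35, 70.0), (0.65, 76.0)]:
    ens = run_cell(d1, FascicleClass(f_r, theta), PriorSpec(),
                   TmcmcConfig(samples_per_stage=1000, seed=42),
                   observables=("elastic", "relaxation"))
    e_f, eta, e_m, r_inf, sigma = ens.map_sample
    print(f"f_r={f_r:.0%}: MAP E_f={e_f:.0f} MPa, eta_f={eta:.1f} GPa s, "
          f"r_inf={r_inf:.2f}, sigma_n={sigma:.3f}")
```

prints

```
f_r=35%: MAP E_f=1607 MPa, eta_f=44.3 GPa s, r_inf=0.41, sigma_n=0.055
f_r=65%: MAP E_f=863 MPa, eta_f=23.8 GPa s, r_inf=0.41, sigma_n=0.055
```

The MAP fiber modulus falls with fiber content (the same fascicle stiffness
must be carried by more fiber cross-section), spanning roughly 860–1600 MPa
across the content grid; the retained fraction `r_∞ ≈ 0.4` and noise scale
`σ_n ≈ 5 %` recover the generator settings; the fiber viscosity lands in the
tens of GPa·s, quantifying the fibers' substantial stress-relaxation
capacity.

The same workflow is available from the shell:

```sh
fasciclebayes simulate --out-dir fixtures --seed 1
fasciclebayes infer --datasets fixtures/D1.csv --seed 3 --out-dir results
fasciclebayes report --results-dir results --datasets fixtures/D1.csv
```

`infer` runs the full 49-class grid by default and writes `grid_results.csv`
(MAP + 95 % credible interval per class × dataset), `range_summary.csv`
(per-parameter MAP ranges across the grid) and per-cell posterior samples.

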