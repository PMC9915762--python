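# valuebind

Neural population geometry of value–space binding: when an animal weighs two
offers shown at different places, the brain must keep track not only of the
two values and two positions but of *which value belongs to which position*.
`valuebind` implements a complete, testable pipeline for the
subspace-orthogonalization account of that binding problem: populations
encode the value of left and right offers in *semi-orthogonal* subspaces,
and the degree of orthogonalization trades off binding reliability against
the ability to generalize a value code across positions.

The package is aimed at systems/computational neuroscientists who want to
run, test, or extend this analysis without access to private recordings:
every stage is exercised end to end on a synthetic generator with known
ground truth.

## The model

Population responses to the 2×2 grid of (value level, context level) follow
a linear–nonlinear code

    r(x) = L·x_z + M·f_N(x) + ε,   ε ~ N(0, σ²I)

where L carries a factorized rectangular scaffold with side lengths d_LV
(value) and d_LA (context), and M carries conjunctive one-hot perturbations
with pairwise displacement d_N. The geometry fixes three quantities:

* subspace correlation ρ = d_LV² / (d_LV² + d_N²),
* binding error rate ≈ N_S · Φ(−√2·d_N / 2σ), with N_S = 1/4 by enumeration
  of linearly confusable two-stimulus sets,
* generalization (CCGP) error ≈ Φ(−d_LV² / (2σ·√(d_LV² + d_N² + ε²))),

with Φ the standard normal CDF and ε the standard-error distance of the
estimated centroids. The pipeline estimates (d_LV, d_LA, d_N, σ, ε) from
cross-validated (crossnobis) condition distances and validates both
closed-form error rates against brute-force Monte-Carlo decoder oracles.

Around this core the package provides: a risky-choice task generator and
Prelec/power-utility softmax choice models with Laplace model selection;
per-neuron regression (linear/spline value, side, interaction) with exact
leave-one-out Bayesian model stacking; bootstrap subspace correlations with
a noise ceiling; pseudopopulation SVM decoding and cross-condition
generalization; and population-structure statistics (sensitivity index,
Hartigan dip test, participation-ratio contributions, gain-vs-heterogeneous
classification).

## Worked example

```python
from valuebind import geometry
from valuebind.syndata import PopulationCodeSpec, grid_labels, simulate_population

# --- recover the geometry of a semi-orthogonal population (rho = 0.5) ---
spec = PopulationCodeSpec.create(n_neurons=100, d_lv=1.0, d_la=2.0,
                                 d_n=1.0, sigma=0.5, seed=5)
labels = grid_labels(500)                      # 500 trials per condition
data = simulate_population(spec, labels, seed=6)
est = geometry.estimate_geometry(data, labels, seed=7)
print(f"d_LV={est.d_lv:.2f}  d_LA={est.d_la:.2f}  d_N={est.d_n:.2f}  "
      f"sigma={est.sigma:.2f}  rho={est.rho:.2f}")

# --- error-rate theory against brute-force decoder oracles ---
code = PopulationCodeSpec.create(n_neurons=30, d_lv=6.0, d_la=6.0,
                                 d_n=1.0, sigma=1.0, seed=8)
b_pred = geometry.predicted_binding_error(code.d_n, code.sigma)
b_mc, b_se = geometry.binding_error_oracle(code, n_mc=100_000, seed=9)
print(f"binding error: theory={b_pred:.4f}  oracle={b_mc:.4f} (SE {b_se:.4f})")
g_pred = geometry.predicted_ccgp_error(spec.d_lv, spec.d_n, spec.sigma)
g_mc, g_se = geometry.ccgp_oracle(spec, n_mc=100_000, seed=10)
print(f"ccgp error:    theory={g_pred:.4f}  oracle={g_mc:.4f} (SE {g_se:.4f})")
```

prints

```
d_LV=1.10  d_LA=1.99  d_N=0.92  sigma=0.50  rho=0.59
binding error: theory=0.0599  oracle=0.0599 (SE 0.0008)
ccgp error:    theory=0.2398  oracle=0.2396 (SE 0.0013)
```

The recovered distances sit within ~10% of the generative values
(d_LV = 1, d_LA = 2, d_N = 1, σ = 0.5) with the implied subspace correlation
near the true 0.5, and both closed-form error rates agree with their
brute-force decoder oracles within Monte-Carlo error. The misbinding rate
depends only on d_N and σ — the binding comparison uses a large scaffold
(d_LV = d_LA = 6) because the union-bound formula counts only chimeric
confusions, which dominate exactly when the scaffold distances are large
relative to the noise.

A full synthetic run (task → choices → behavioral model → neural simulation
→ subspaces, geometry, decoding, population structure) with a reproducibility
manifest:

```bash
valuebind run --seed 7 --out runs/demo
```

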