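# hydrofowl

Annual-cycle distribution modelling of migratory waterfowl with a
depth-to-water-table covariate.

Distribution models for migratory, wetland-affiliated birds are notoriously
weaker than for other bird groups: the birds move with the seasons, and the
wetlands they depend on are poorly and inconsistently mapped.  `hydrofowl`
implements a modelling strategy that attacks both problems at once:

* **species-specific annual cycles** — spring and fall migration windows are
  delineated per species from band-recovery movement data (peaks in average
  weekly travel rate of birds recovered within 30 days of banding), and every
  model is fitted per season;
* **a process-based wetland proxy** — depth to water table (DWT), the
  equilibrium depth at which climate-driven recharge balances lateral
  groundwater drainage, computed by a gridded solver with depth-decaying
  transmissivity `T(d) = T0 e^(-d/f) + T_min`;
* **target-group pseudo-absences** — background points are the recorded
  locations of the *other* study species where the focal species is absent,
  so presences and background share the survey-effort bias;
* **a from-scratch presence-background maximum-entropy model** (linear /
  quadratic / product / hinge features, L1 regularization, raw and logistic
  output) evaluated by AUC over 100 randomized 70–30 train/test splits;
* **permutation variable importance** (mean decrease in out-of-bag accuracy
  over 1000 bagged trees) and **DWT response curves** (1000 random surface
  points, binned means, GCV smoothing spline).

Because the banding archives and continental rasters that motivated this
design are access-restricted, the package ships a first-class synthetic data
generator (`hydrofowl.synthetic`) that emulates their statistical structure
with known ground truth: species niches `s ∝ e^(-dwt/δ) · N(T; T_opt, σ_T) ·
N(lat; c_season, σ_r)`, survey stations with Gaussian effort kernels,
hunter-style terminal recoveries, and season-dependent movement velocities.
Every headline behaviour is demonstrated on data where the truth is known by
construction.

## The model

For presences `x_1..x_m` and a background cell set `B`, the fitted
distribution is the Gibbs density

    q(x) = exp(λ·f(x)) / Z_λ,   Z_λ = Σ_{x∈B} exp(λ·f(x))

maximizing the L1-penalized likelihood

    (1/m) Σ_i λ·f(x_i) − log Z_λ − Σ_j β_j |λ_j|,

with features `f` scaled to [0,1] and per-feature penalties
`β_j = rate(class, m) · sd(f_j) / √m`.  The logistic output
`p = e^H q / (1 + e^H q)` (H = entropy of q) is the mapped "probability of
occurrence" at default prevalence 0.5.  Fitting is monotone proximal-gradient
ascent; on tiny instances the solution is verified against exhaustive grid
search, and with β = 0 the fitted feature expectations equal the presence
means — the defining maximum-entropy property.

## Worked example

Does adding DWT to the base covariates (temperature, precipitation,
elevation) improve a winter model for a species with moderately strong
wetland affinity (δ = 0.5 m)?

```python
import numpy as np
from hydrofowl.synthetic import (generate_landscape, default_niches, default_effort,
                                 simulate_banding_records, BASE_COVARIATES)
from hydrofowl.background import presence_cells, target_group_background
from hydrofowl.maxent import replicate_fit
from hydrofowl.evaluate import compare_models

stack = generate_landscape(seed=11)
niches = default_niches()
effort = default_effort(stack, seed=12)
records = simulate_banding_records(niches, effort, stack, seed=13)
windows = {n.species: n.true_windows() for n in niches}

focal = "AFFN"  # wetland affinity delta = 0.5 m
pres = sorted(presence_cells(records, focal, "winter", windows[focal]))
cand = target_group_background(records, focal, "winter", windows)
print(f"{focal} winter: {len(pres)} presence cells, {len(cand)} background candidates")

base = tuple(BASE_COVARIATES)
values = lambda names: (lambda cells: stack.covariate_matrix(list(cells), names))
reps = {
    "base": replicate_fit(pres, cand, values(base), base,
                          n_runs=100, n_background=1000, seed=17),
    "base+dwt": replicate_fit(pres, cand, values(base + ("dwt",)), base + ("dwt",),
                              n_runs=100, n_background=1000, seed=17),
}
a = np.array([r.auc for r in reps["base+dwt"]])
b = np.array([r.auc for r in reps["base"]])
result = compare_models(a, b)
print(f"mean test AUC base+dwt: {a.mean():.4f}")
print(f"mean test AUC base:     {b.mean():.4f}")
print(f"paired wins: {np.sum(a > b)}/100, better={result.better}, p={result.p_value:.2e}")
```

Output:

```
AFFN winter: 338 presence cells, 632 background candidates
mean test AUC base+dwt: 0.6591
mean test AUC base:     0.6168
paired wins: 100/100, better=A, p=7.71e-47
```

Adding DWT raises the held-out AUC in every one of the 100 paired
replicates.  The absolute AUC values are moderate by design: target-group
background shares the survey bias of the presences *and* all four synthetic
species are wetland-affiliated, so the models discriminate habitat, not
effort — exactly the contrast the protocol is built to isolate.

There is also a CLI for file-based work:

```sh
hydrofowl simulate --seed 3 --out world/          # rasters + records + truth
hydrofowl simulate-dwt --landscape scape.yaml --out dwt.asc
hydrofowl delineate --records world/records.csv --species SPEC \
    --grid grid.yaml --prior prior.yaml --out windows.yaml
hydrofowl run --config run.yaml --out results/    # full pipeline + manifest
```

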