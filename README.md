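# hierdsm

Bayesian hierarchical density surface models (DSMs) for double-observer
line-transect surveys of cetaceans and other diving megafauna.

## The problem

Abundance estimation from shipboard and aerial line-transect surveys has to
combine several imperfectly known pieces: a distance-sampling detection
function, the probability of detecting a group on the trackline
(*g(0)*, estimated from two-observer capture histories), the probability a
group is at the surface and available at all, a flexible density–habitat
surface, and mean group size. The common two-stage practice — estimate
detection first, then feed `p_hat * A` into a GAM as a fixed offset — makes
it easy to *forget* the first-stage variance, producing abundance estimates
whose coefficients of variation (CVs) can understate the real uncertainty by
half or more.

`hierdsm` fits the whole model in one stage. For analysis unit *i*,

    E(n_i) = p_i A_i exp(B0 + Σ_j f_j(X_ij)),

with mark-recapture distance sampling (half-normal or hazard-rate key,
point independence, `θ_i = g(0, z_i)·esw(z_i, W)/W`), an informative beta
prior on surface availability `a` (aerial `p_i = θ_i a`), penalized-spline
smooths `f_j` with conjugate Gibbs updates of their smoothing parameters, a
compound Poisson–gamma (Tweedie, `1 < ρ < 2`) count likelihood with
latent-count augmentation, and a shifted-Poisson group-size model. Cell
abundance is `N_i = (λ_s + 1) D_i A_i^G`. Every posterior summary —
density maps, CV maps, total abundance — carries all component
uncertainties. The package also implements the two-stage comparator (ML
detection fit + frozen offsets, with optional delta-method variance
propagation), a line-transect survey simulator with known truth, and a
variance-component experiment that refits the model with individual
components frozen to attribute shares of the final CV.

Intended users: marine-mammal survey analysts and quantitative ecologists
who already work with distance-sampling data and want one-stage variance
propagation alongside the familiar two-stage workflow.

## Worked example

Simulate a survey with known truth, fit both methods, and compare:

```python
import numpy as np
from hierdsm import simulator as sim
from hierdsm.abundance import predict_surface
from hierdsm.hier_model import run_mcmc
from hierdsm.two_stage import fit_two_stage

design = sim.SimDesign(n_cells=400, n_surveyed=300, base_seed=20)
rng = np.random.default_rng(20)
truth = sim.simulate_landscape(design, rng)
cells, sightings = sim.simulate_survey(truth, design, rng)
grid = truth[["cell_id", "cell_area_km2", "habitat"]]

cfg = sim.default_study_config(design, n_iter=6000, n_burn=2000, thin=5)
draws = run_mcmc(cells, sightings, cfg, seed=20)
surf = predict_surface(draws, grid)
print(f"true N        = {truth.attrs['total_true_N']:.0f}")
print(f"Bayesian N_hat = {surf.total_mean:.0f} (CV {surf.total_cv:.3f}), "
      f"95% CI {tuple(round(v) for v in surf.total_interval())}")

ts = fit_two_stage(cells, sightings, grid, cfg, propagate="delta", seed=21)
print(f"two-stage N_hat = {ts.n_hat:.0f} "
      f"(CV {ts.cv_spatial:.3f} spatial-only, {ts.cv_delta:.3f} delta)")
```

Output:

```
true N        = 2704
Bayesian N_hat = 2662 (CV 0.123), 95% CI (2068, 3339)
two-stage N_hat = 2653 (CV 0.092 spatial-only, 0.120 delta)
```

The Bayesian CV (0.123) and the delta-propagated two-stage CV (0.120) agree
because they carry the same uncertainty sources; the spatial-only CV (0.092)
is what an analysis that ignores detection variance would report — here
about a quarter of the CV is missing. The 95% interval covers the true
landscape total.

A command-line interface mirrors the library: `hierdsm fit-bayes`,
`hierdsm fit-twostage`, `hierdsm variance-components`, `hierdsm simulate`,
each taking `--config` (YAML), `--seed` and `--out-dir`. Input tables are
plain CSV; the header contract is documented in `hierdsm/survey_io.py`.

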