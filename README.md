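# smlmfit

Maximum-likelihood fitting of parameterized geometric models to
single-molecule localization microscopy (SMLM) coordinates.

SMLM experiments do not produce pixel images but tables of fluorophore
coordinates `x_k` with per-localization precisions `σ_k`.  `smlmfit`
turns such point clouds into quantitative structural measurements:
it fits an arbitrary geometric model `f(p)` to the localizations of one
structure ("site") by maximizing

    LL(p) = Σ_k ln M(x_k, σ_k | p),
    M(x, σ | p) = (Σ_j q_j)⁻¹ Σ_j q_j N(x; v_j, diag(σ² + ε²)),

where `v_j, q_j` are the model's (discretized) fluorophore positions and
weights, ε an extra uncertainty absorbing linkage error and drift, plus a
uniform background over the site with weight `w_bg`.  On top of this core
the package provides

* a library of models — nuclear-pore dual rings, discrete 8-fold corners,
  elliptical pores, microtubule splines and tubes, a two-channel
  endocytic dome + ring, line segments — and a plug-in registry;
* chained fitting (smooth to detailed) with global evolutionary, simplex
  and gradient optimizers, Hessian-based 95% confidence intervals, and
  model selection by the small-sample Akaike criterion
  `AICc = 2P − 2 ln L̂ + (2P² + 2P)/(K − P − 1)`;
* a realistic two-state blinking simulator (labeling efficiency,
  exponential on-times, geometric reactivation, Poisson photons,
  photon-dependent precision) used for validation throughout;
* reference-based multi-color averaging, pseudotime reconstruction of
  dynamic processes from static snapshots, and model-free particle
  fusion (particles register to each other by the same likelihood, no
  template geometry assumed);
* depth-dependent axial distortion correction and ring-kernel NPC site
  segmentation.

It is aimed at microscopists and image analysts who want parameter
estimates with uncertainties from individual structures — not just
rendered images — and at method developers who need a seeded, fully
scriptable validation loop.

## Worked example

Simulate one nuclear pore (Nup96 geometry: ring radius 53.4 nm, ring
separation 50.2 nm, twist 8.8°) and refit it with the standard
three-step chain:

```python
import math
import smlmfit as sf
from smlmfit.fitting import fit_npc_chain

site = sf.simulator.simulate_npc_study(1, seed=11)[0]
print(f"K = {site.n_locs} localizations")

results = fit_npc_chain(site, seed=1, compute_ci=True)
final = results[-1]
e = final.estimates
print(f"r = {e['r']:.1f} nm   s = {e['s']:.1f} nm   "
      f"theta = {math.degrees(e['theta']):.1f} deg")
print(f"CI95(r) = [{final.ci95['r'][0]:.1f}, {final.ci95['r'][1]:.1f}] nm")
print(f"AICc/K = {final.aicc_per_loc:.2f}")
```

prints

```
K = 63 localizations
r = 52.2 nm   s = 55.1 nm   theta = 17.5 deg
CI95(r) = [50.2, 54.2] nm
AICc/K = 29.33
```

The 95% confidence interval of the radius covers the generating value;
single-site estimates scatter (about ±2 nm in r, ±7 nm in s and ±10° in
θ at this precision), which is exactly the per-site heterogeneity the
method is built to quantify.  Averaged over hundreds of simulated sites
the estimators are unbiased to well below 1 nm / 1° (see the validation
studies in `smlmfit.studies` and `docs/methods.md`).

The same machinery drives the CLI:

```bash
smlmfit simulate --model npc_discrete --n-sites 50 --seed 7 --out sites.csv
smlmfit fit --locs site0.csv --config chain.yaml --seed 1 --out report.json
smlmfit average --mode model-free --sites sites.csv --seed 1 --out avg.csv
```

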