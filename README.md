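# regsi — regularized selection indices

`regsi` predicts the **genetic merit** of a target trait (e.g. wheat grain
yield) from a **high-dimensional measured phenotype** (e.g. 250 hyper-spectral
reflectance wavebands per field plot) using regularized selection indices.
It is aimed at plant and animal breeders and quantitative geneticists who
want to turn high-throughput phenotyping data into a selection criterion,
and at methodologists studying genetic analysis of high-dimensional
phenotypes.

## The model

A linear selection index weights the measured phenotypes
**x**ᵢ = (x_{i1}, …, x_{ip})′ of individual *i*:

    Iᵢ = xᵢ′ β

The classical (Smith–Hazel) weights minimize E[(g_y − x′β)²], where g_y is
the genetic merit of the target, giving

    β = P_x⁻¹ G_xy

with P_x the phenotypic covariance matrix of the measured traits and G_xy
the vector of genetic covariances between each measured trait and the
target. With hundreds of correlated bands, the plug-in estimate of this
index overfits estimation noise in (P̂_x, Ĝ_xy) and loses accuracy. `regsi`
regularizes it four ways:

* **L2-PSI** (ridge): β = (P_x + λI)⁻¹ G_xy;
* **L1-PSI / EN-PSI** (lasso / elastic net): minimize
  −G′β + ½β′Pβ + λ[½(1−α)‖β‖₂² + α‖β‖₁], solved by covariance-form
  coordinate descent and by a covariance-based LARS homotopy that returns
  the exact piecewise-linear L1 path (with drop steps);
* **PC-SI** (reduced rank): regress on the top-q principal components of X
  with the method-of-moments PC covariance D²_q/(n−1), then back-map
  β = (n−1) V_q D_q⁻² G_wy.

Around the solvers the package provides the full workflow:

* **Pre-adjustment**: REML/BLUP mixed models y = μ + genotype + trial +
  rep(trial) + sub-block(trial, rep) [+ time-point] with iid random
  effects; y* = y − μ̂ − nuisance BLUPs keeps genotype signal + residual.
  A 3×IQR fence removes target outliers (bands dropped in tandem) and all
  traits are standardized to unit variance.
* **Genetic parameters**: plot-basis heritability h² = σ²_g/(σ²_g+σ²_ε)
  from the one-factor genotype model, and genetic covariances by the
  sum-of-traits identity Ĝ(y, x) = ½[σ̂²_g(y+x) − σ̂²_g(y) − σ̂²_g(x)].
* **Evaluation**: trial-blocked training/testing partitions (no plot of a
  trial on both sides), index heritability h²_I, genetic correlation r_g,
  accuracy of indirect selection Acc(I) = √h²_I · r_g and relative
  efficiency RE = √(h²_I/h²_y) · r_g, with tuning of λ/α/q by mean test-set
  accuracy. RNDVI/GNDVI vegetation indices and L1-penalized phenotypic
  prediction serve as baselines.
* **Synthetic data**: a generator with known genetic/environmental band
  covariances (smooth spectra, low-rank genetic factors, alpha-lattice
  field design), so the accuracy of any index is available in closed form:
  Acc = β′G_xy / √(β′(G_x+E_x)β · σ²_gy).

## Worked example

Simulate a 12-trial, 480-plot dataset with 50 bands and 5 informative
genetic factors, run the full pipeline and tune an L1-PSI:

```python
import numpy as np
from regsi import (make_covariance_structures, simulate, preprocess_dataset,
                   make_partitions, tune, standard_si, true_accuracy)
from regsi.evaluation import _training_covariances

truth = make_covariance_structures(p=50, n_factors=5, decay=60.0)
sim = simulate(truth, n_trials=12, genotypes_per_trial=20,
               replicates=2, subblocks=4, seed=7)
data = preprocess_dataset(sim.target, sim.reflectance, sim.band_labels)
parts = make_partitions(data.trial_ids(), n_train_trials=8,
                        n_partitions=10, seed=7)
curve, coef = tune(data, "L1", parts, grid=np.geomspace(1.0, 0.01, 20))
best = curve.argmax
print(f"optimal L1-PSI: {int(curve.mean_active[best])} active bands, "
      f"Acc = {curve.mean_acc[best]:.3f} (SD {curve.sd_acc[best]:.3f})")
cov, _, _, _ = _training_covariances(data)
print(f"true accuracy of the tuned L1 index:      "
      f"{true_accuracy(coef.beta, truth):.3f}")
print(f"true accuracy of the plug-in standard SI: "
      f"{true_accuracy(standard_si(cov).beta, truth):.3f}")
```

prints

```
optimal L1-PSI: 4 active bands, Acc = 0.407 (SD 0.060)
true accuracy of the tuned L1 index:      0.431
true accuracy of the plug-in standard SI: 0.287
```

The tuning curve peaks at intermediate complexity (here 4 of 50 bands):
the sparse index estimated on ~320 training plots is genuinely closer to
the best attainable index than the full-rank plug-in solution, and the
trial-blocked estimate (0.407) tracks the closed-form truth (0.431).

The same workflow is available from the shell:

```bash
regsi simulate --p 50 --n-trials 12 --seed 7 --out run/sim
regsi preadjust --target run/sim/target.csv \
    --reflectance run/sim/reflectance.csv --out run/adj
regsi tune --plotdata run/adj/plotdata.csv --method L1 \
    --n-partitions 10 --seed 7 --out run/tune
regsi evaluate --plotdata run/adj/plotdata.csv \
    --coefficients run/tune/coefficients.json --out run/eval
```

Every run writes a `manifest.json` (config, seed, versions, input digests);
re-running with the same inputs and seed reproduces all outputs
byte-for-byte.

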