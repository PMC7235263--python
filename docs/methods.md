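# Methods

## Setting

A breeder observes, on each field plot, a target trait y (grain yield) and
a p-vector x of measured phenotypes (hyper-spectral reflectance bands).
Genotypes are replicated across plots; the goal is a linear index I = x′β
maximally correlated with the *genetic merit* g_y of the target — not with
the phenotype y itself. The best linear predictor of g_y given x (both
null-mean) is β = P_x⁻¹G_xy, with P_x = Cov(x) and G_xy = Cov(x, g_y); the
latter is a vector of genetic covariances because environmental deviations
of x are assumed orthogonal to g_y. When p is large, plug-in estimates of
(P_x, G_xy) carry enough sampling noise that the unregularized index
overfits; penalization (L1/L2/elastic net) or rank reduction (principal
components) trades a little bias for a large variance reduction and a more
accurate index.

## Mixed-model pre-processing

Raw plot records follow, within an environment,

y_jklm = μ + g_j + t_k + r_l(k) + b_m(kl) + ε_jklm

with genotype, trial, replicate-within-trial and sub-block effects all iid
normal random effects with factor-specific variances (reflectance models add
a time-point main effect). Pre-adjusted phenotypes subtract the estimated
mean and the *nuisance* BLUPs only:

y* = y − μ̂ − t̂ − r̂ − b̂  ( = ĝ + ε̂ ),

keeping the genotype signal in the data. Records whose adjusted target
value falls outside [Q1 − 3·IQR, Q3 + 3·IQR] are discarded (quartiles by
linear interpolation, "type 7"; the reading of the fence as quartile ±
3·IQR is an interpretation choice, fixed here for reproducibility), and the
corresponding reflectance records are dropped in tandem. All retained
traits are scaled to unit sample variance. Inside cross-validation the
centering/scaling constants always come from the training plots and are
applied unchanged to test plots.

### REML

Variance components maximize the restricted likelihood. Rather than EM or
average-information iterations we optimize the *profiled* criterion
directly over the log variance ratios log λ_k = log(σ²_ε/σ²_k): with the
scaled mixed-model equations C* = [[X′X, X′Z], [Z′X, Z′Z + diag(λ_k I)]],
the residual variance has the closed form σ̂²_ε = (y′y − θ̂′W′y)/(n − f) and

−2 logL_R = (n − f) log σ̂²_ε − Σ_k q_k log λ_k + log|C*| + const.

Coordinate-wise bounded Brent searches are swept until the relative change
of the criterion falls below 1e-8 (cap 200 sweeps; non-convergence is
flagged). log λ is bounded in [−20, 35]; estimates below 1e-10 are reported
as exactly 0. This reaches zero boundaries exactly (where EM crawls),
matches the balanced one-way ANOVA closed form to <1e-6, and — because the
sufficient statistics are accumulated in a canonical record order — is
bitwise invariant to row permutations of the input.

The one-factor genotype model y_ij = g_j + ε_ij (no intercept: data are
pre-adjusted and null-mean) has a dedicated fast path used for
heritabilities and genetic covariances: the profiled criterion depends on
the data only through per-genotype sums, so hundreds of traits sharing one
grouping are fitted simultaneously; a grid scan brackets the optimum of
each column and bisection on the analytic derivative refines it to ~1e-13
relative precision. The derivative-based refinement matters: criterion-value
comparisons go blind inside a plateau of width ~1e-8 around the optimum,
which would break the exact identities below.

Plot-basis heritability is h² = σ̂²_g/(σ̂²_g + σ̂²_ε) (clipped to [0, 1]).
Genetic covariances use the sum-of-traits identity
Ĝ(y, x) = ½[σ̂²_g(y+x) − σ̂²_g(y) − σ̂²_g(x)] from three univariate fits —
no multivariate REML anywhere. Consequences worth knowing: Ĝ(y, y) equals
the fitted genetic variance to ~1e-12; Ĝ is exactly symmetric; uniform
rescaling scales it exactly; but Ĝ(ay, bx) for a ≠ b is only equal to
ab·Ĝ(y, x) after rescaling the fitted components, because REML itself is
not bilinear. Components clipped at 0 can make Ĝ (and hence genetic
correlations) exceed their natural bounds; r_g is clipped to [−1, 1] with a
logged count.

## Index solvers

All solvers consume a `CovariancePair` (P̂_x symmetric, Ĝ_xy, σ̂²_gy).

* **standard**: solve P β = G; refuses condition numbers above 1e12 and
  points the user at the regularized alternatives (no silent
  pseudo-inverse).
* **L2**: solve (P + λI) β = G. ‖β‖₂ is non-increasing in λ.
* **Elastic net**: cyclic coordinate descent on
  −G′β + ½β′Pβ + λ[½(1−α)β′β + α‖β‖₁], updates
  β_j ← S(G_j − Σ_{k≠j}P_jkβ_k, λα)/(P_jj + λ(1−α)), warm-started down a
  decreasing grid. Default grid: 100 log-spaced points from
  λ_max = max_j|G_j|/max(α, 1e-3) down to 1e-4·λ_max. Convergence: max
  coefficient change < 1e-9 or 10,000 sweeps (flagged, not silent).
* **L1 path (LARS homotopy)**: within an active set A with signs s,
  β_A(λ) = P_AA⁻¹(G_A − λ s); knots occur where an inactive band's
  "correlation" |G_j − (Pβ)_j| reaches λ (entry) or a coefficient crosses
  zero (drop — the lasso modification). Ties break toward the lowest band
  index and are logged. The path object evaluates the exact solution at any
  λ; at every knot the KKT conditions hold to 1e-8.
* **PC**: thin SVD X = UDV′ of the training-centered panel; PC covariance
  D̃²/(n−1) by method of moments; γ = (n−1)D̃⁻²G_wy; β = Ṽγ. G_wy can be
  estimated directly on the PC scores by the sum-of-traits trick (default —
  scores are just derived traits) or rotated from band-level estimates as
  Ṽ′G_xy; q = p reproduces the standard index.

The primary correctness oracle for the L1/EN solvers is the KKT certificate
of the convex objective; brute-force QP solutions and an independent LARS
implementation corroborate it in the tests. The reduction chain
EN(α=0)=L2, L2(λ=0)=standard, EN(α=1)=LARS, PC(q=p)=standard is enforced at
tolerances 1e-8/1e-10/1e-5/1e-8.

There is no intercept anywhere: every trait entering a solver is
pre-adjusted, null-mean and standardized.

## Evaluation

Complete trials are assigned to training or testing sets (default 2/3 of
trials in training, mirroring a 26-of-39 split), representing calibration
on historical trials and application to future ones. Coefficients are fit
from training covariances only; on the test plots we estimate h²_I, h²_y
and r_g = Ĝ(I, y)/√(σ̂²_g,I σ̂²_g,y) and report

Acc(I) = √h²_I · r_g,  RE = √(h²_I/h²_y) · r_g.

h enters on the square-root scale — the only scale on which both formulas
cohere. Zero genetic variances yield a flagged "undefined" result rather
than NaN propagation. Tuning curves aggregate mean/SD across partitions;
the optimum is the *smallest* complexity attaining the maximal mean Acc
(parsimony tie-break); the returned coefficients are refit on the full
dataset at that complexity. Summaries report mean, SD and the normal
95% CI mean ± 1.96·SD/√n.

Baselines: RNDVI/GNDVI with configurable windows (defaults Red 660–680 nm,
Green 540–560 nm, NIR 780–850 nm — standard definitions within a
392–850 nm camera range), and L1-penalized *phenotypic* prediction, which
reuses the identical solver with X′y/(n−1) in place of Ĝ_xy — the cleanest
illustration that the index differs from phenotypic prediction only through
genetic vs phenotypic covariance inputs.

## Synthetic data generator

The generator emulates the structure of a multi-environment wheat trial
system: genotypes nested in trials (28 lines/trial), alpha-lattice layout
(3 replicates × 6 sub-blocks by default), p bands on 392–850 nm.
Band genetic covariance G_x is a low-rank structure of smooth Gaussian
factor loadings (width `decay` nm, default 60 — chosen so neighbouring
bands are strongly genetically correlated, as in real spectra) plus a 5%
diagonal nugget, scaled so diag(G_x) equals the requested band
heritabilities (default 0.5) with unit total band variance. Environmental
covariance E_x has exp(−d/ℓ) correlation (ℓ = `decay` by default). The
band–target genetic covariances follow a requested genetic-correlation
profile (default: 0.6 times the leading factor loading — a moderate,
low-dimensional genetic link); the joint (p+1)-dimensional genetic
covariance is verified PSD, shrinking G_x toward its diagonal (logged) or
raising an error naming the violated bound. Nuisance variances default to
trial 0.5, rep 0.1, sub-block 0.05 on the unit-variance trait scale —
trial-to-trial differences comparable to half the plot variance, as is
typical of managed-stress trial systems. Genetic effects are drawn per
genotype from the joint covariance; plot-level environmental deviations are
independent of them (the orthogonality assumption that makes the index the
BLP); each effect type has its own seeded substream, and the field-layout
stream is separate so the design does not change with p.

Because the generating covariances are known, the accuracy of *any*
coefficient vector is available in closed form,
Acc = β′G_xy/√(β′(G_x+E_x)β·σ²_gy), which serves as the oracle for the
evaluation machinery and for the headline experiment.

What the generator does **not** emulate: spatial field trend within trials,
genotype-by-environment interaction across environments, non-Gaussian
reflectance artifacts (cloud shadow, soil pixels), temporal correlation of
repeated flights, and selection/relatedness structure among lines. Passing
tests therefore demonstrate correctness of the estimators and solvers under
the stated generative assumptions, not robustness to every field reality.

## Verification experiments and problem sizes

The acceptance experiments run at sizes chosen to keep the whole suite in
the single-digit minutes on one CPU while leaving Monte-Carlo error well
below the tolerances tested:

* parameter recovery: balanced 500 genotypes × 3 replicates, 200 draws;
  mean ĥ² and sum-trick Ĝ within 0.03 of the generating 0.5 and 0.3;
* accuracy-estimator consistency: 200 independently simulated 30-trial
  datasets, one trial-blocked split each (independent replicates make the
  across-replicate SD an honest Monte-Carlo SE for the mean);
* headline phenomenon: p = 250 bands, 5 genetic factors, 10 trials × 20
  genotypes × 2 replicates (400 plots), tuning by 3 internal trial-blocked
  partitions; 100 replicates. These experiments run the generator in its
  pre-adjusted regime (nuisance variances 0), isolating the estimation-noise
  phenomenon; the pre-adjustment chain itself is verified separately by the
  mixed-model tests and the full-pipeline run in the acceptance script.

## Known limitations

* Univariate REML plus the sum trick is the design point; no multivariate
  REML, pedigree/genomic relationship matrices, or spatial correction.
* Method-of-moments genetic correlations can exceed 1 in small test sets;
  clipping is logged but still truncates the sampling distribution.
* The LARS homotopy stops if an active-set system becomes numerically
  singular (possible when p approaches the training rank); the coordinate
  descent path remains available there.
* Vegetation-index windows assume wavelength metadata in nm and windows
  inside the camera range; no radiometric correction is attempted.
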