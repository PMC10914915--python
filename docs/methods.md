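# Methods

This note documents the models behind `glaidyn`, the choices made where
the design was genuinely open, and what the synthetic studies do and do
not establish about real field data.

## The curve model and trait extraction

A seasonal GLAI trajectory is treated as piecewise linear in thermal time
(GDD6, base 6 °C) with four sloped segments — early vegetative, late
vegetative, slow senescence, rapid senescence — a flat plateau around the
maximum, and quadratic bends of half-width γ at every junction so the
curve has a continuous first derivative. The two interior breaks are
estimated by *bent-cable regression*,

    f(t) = b0 + b1 t + b2 q(t; tau, gamma),
    q = 0 for t <= tau - gamma,
    q = (t - tau + gamma)^2 / (4 gamma) for |t - tau| < gamma,
    q = t - tau for t >= tau + gamma,

fitted by least squares: the linear coefficients are solved exactly on a
(τ, γ) grid (τ over interior observation points, thinned to at most 60; γ
on a 12-point geometric grid from 1 GDD6 to half the window) and the best
few nodes are polished with Nelder–Mead. A fit is flagged
non-identifiable when it improves on a single straight line by less than
1e-6 in relative residual sum of squares — exactly linear data carry no
bend information.

Numerical choices that matter:

* **Limb trimming.** The vegetative limb [t_e, t_M] and senescence limb
  [t_o, t_z] each contain curvature at their ends (emergence bend, plateau
  shoulders) that does not belong to the single bend being estimated; a
  margin of 60 GDD6 (capped at 10% of the window) is excluded from each
  end before fitting. On generator curves this makes the recovered breaks
  exact; on arbitrary smooth curves it removes the dominant boundary bias.
* **Plateau ties.** The time of maximum is the *earliest* grid point
  within a 1e-9 relative tolerance of the maximum, so a float-flat plateau
  resolves to its left edge.
* **Dense grids are thinned** to ≤ 250 points before fitting — a
  5-parameter model gains nothing from 2,000 collinear points.
* **Senescence onset** is the first grid time *strictly below* 95% of the
  maximum; a curve that touches 0.95·GLAI_M exactly crosses on the next
  step.
* **Truncated seasons.** If the curve never returns to zero, t_z is
  clipped to the end of the grid and the trait row carries a truncation
  flag; traits are still computed.
* **D_75/D_50/D_25** are the *total* grid time at or above the relative
  threshold (not the time from peak to first crossing); being relative
  thresholds they are exactly invariant under rescaling of the curve.

AUCs are trapezoidal integrals on the unit grid; durations are boundary
differences; slopes come from the two bent-cable fits. The 24 traits obey
exact partition identities (D_EV+D_LV=D_V, AUC_V+AUC_F+AUC_S=AUC_C, …)
which the tests assert to 1e-6 relative.

When only sparse "flight" observations are available, a monotone cubic
(PCHIP) interpolant maps them onto the unit grid first, clipped at zero.
This stands in for the physiological dynamics model used in UAV pipelines,
which is out of scope here.

## Synthetic study system

The generator is the package's definition of the study conditions, not a
tuning knob.

* **Genotypes.** 16 founder haplotypes with per-marker alternate-allele
  frequencies drawn U(0.1, 0.9); each doubled-haploid line is a Markov
  mosaic of founders per chromosome with Poisson(6) funnel-equivalent
  crossovers; funnel structure is approximated by 8 line families sharing
  a Dirichlet founder-usage prior. Dosages are {0, 2} (no heterozygotes);
  markers below 3.5% minor allele frequency are removed. Founder 0 plays
  the role of B73: the B73-allele indicator (0/1) is the genotype coding
  for every effect estimate, so signs are directly interpretable.
* **Trials.** Per environment, two replicate blocks in a row/column
  layout, genotype order randomised within block — a simplified
  alpha-lattice.
* **Curves.** Baseline parameters (t_e = 80, τ_v = 350, t_M = 820,
  t_o = 1020, τ_s = 1500, t_z = 1850 GDD6, GLAI_M = 3.2 m² m⁻², bend
  half-width 30 GDD6) were set once to the scale of a temperate maize
  panel: vegetative duration near 750 GDD6, senescence duration near
  800 GDD6, maximum GLAI around 3.2 with a genetic CV near 10%.
  Genotype effects, G×E effects and planted QTL effects perturb the
  parameters additively; water-deficit environments multiply GLAI_M by
  0.8 and advance senescence.
* **Observations.** The true curve sampled at 10 flights between 150 and
  1800 GDD6, plus a block effect, a separable AR1×AR1 (ρ = 0.5) field
  error, and independent noise (SD 0.25 m² m⁻²).
* **Agronomic traits.** Grain yield is environment mean (95 q ha⁻¹ WW,
  70 WD) plus weighted, centred contributions of the true flowering-phase
  and senescence-phase areas (weights chosen once so corr(GY, AUC_S) lands
  near 0.4, the middle of the plausible range for moderate drought),
  direct QTL effects, genetic and G×E deviations and plot noise; female
  flowering tracks the true vegetative duration; kernel number,
  thousand-kernel weight and anthesis-silking interval are correlated
  derivatives of yield.
* **Yield network.** The 11-environment water-deficit network is simulated
  at the genotype×environment level: planted QTL signal scaled to a target
  share of the environment-centred variance (default 18%), a polygenic
  term, G×E, and per-environment errors drawn so generalized heritability
  is heterogeneous across sites (≈ 0.6–0.8). Sign-flipping per-environment
  QTL effects are available to emulate unstable QTLs.

What the generator does **not** emulate: reflectance calibration and the
image-processing chain of real UAV data, dominance and epistasis,
realistic recombination maps, weather-driven stress dynamics, or the
tester-hybrid genetic model (dosage of the DH line is used directly as the
additive predictor; a common tester adds a constant under additivity).
Passing tests therefore establish the correctness and calibration of the
*methods*, not the field realism of any particular biological conclusion.

## Adjusted means, heritability, variance decomposition

Model per trait and environment: fixed genotype and block effects with
residual covariance σ²·AR1(ρ_row)⊗AR1(ρ_col) over the plot grid; (ρ_row,
ρ_col) chosen by REML profile over {0, 0.1, …, 0.9}² (step configurable);
the adjusted mean is the grand mean plus the sum-to-zero genotype effect.
With a genotype absent the value is simply missing, not an error.

Generalized heritability follows Cullis: with genotype random (variance
ratio by 1-D REML), H² = 1 − v̄_Δ/(2σ̂²_g), where v̄_Δ is the mean
prediction-error variance of pairwise genotype-BLUP differences —
computed in closed form over all pairs from the PEV matrix (no pair
sampling is needed at these panel sizes). A variance ratio driven to the
search boundary is reported as σ̂²_g = 0 and H² = 0 with a warning.

The multi-environment decomposition fits y = env (fixed) + genotype
(random) + G×E (random) + residual by REML. The covariance is
block-diagonal by genotype, and genotypes sharing an environment pattern
share one block factorisation, so the optimisation is O(G·b³) per
evaluation; a dense mixed-model-equation solve at the optimum supplies the
network-level BLUP prediction-error variances for the network H². Each
random term is tested by a restricted likelihood-ratio test with the
50:50 χ²₀/χ²₁ boundary mixture — the standard null for a variance
component on the boundary. Plot-level replicates are required to separate
G×E from residual variance; a single observation per cell triggers a
confounding warning.

## GWAS

Kinship is identity-by-state: the fraction of markers at which two lines
carry the same homozygous genotype, missing calls excluded pairwise; LOCO
matrices exclude the focal chromosome so a tested marker never informs its
own correction.

**Univariate.** In the eigenbasis of K^(−c) the model is a weighted
regression with weights 1/(s_i + δ), δ = σ²_e/σ²_g. δ is estimated *by
REML* once per chromosome under the null and reused for every marker on
that chromosome (an exact mode re-optimises per marker). REML rather than
ML matters in practice: the ML plug-in δ gave a null rejection rate of
~0.056 at n = 324 where REML restores 0.050. The per-marker statistic is
the profiled likelihood ratio n·log(RSS₀/RSS₁) against χ²₁. Monomorphic
markers are reported with p = 1 and flagged.

**Calibration caveat for LOCO.** The null-calibration studies draw the
polygenic background from the global kinship and scan with the global
kinship — a correctly specified model, which is the right object for
checking test calibration. Scanning the same phenotypes with LOCO
matrices shows mild inflation (size ≈ 0.067): markers tag their own
chromosome's polygenic signal, which LOCO deliberately leaves uncorrected.
That is the known cost of avoiding proximal contamination, not an
implementation defect.

**Multivariate.** The t-trait model (rows of the genetic term
matrix-normal over K and Vg; residual rows iid with Ve) is fitted per
chromosome by EM on the rotated data, alternating with GLS for the
intercept; covariance updates are projected to the PSD cone with a 1e-8
eigenvalue floor. Convergence is a 1e-6 relative log-likelihood change or
1,000 iterations; hitting the cap (which happens when Vg is essentially
singular, e.g. a single shared genetic factor) returns the current fit
with a warning and a `converged=False` flag rather than failing — the
marker-level Wald tests are insensitive to the last EM crumbs. Each
marker's t-vector effect is tested jointly against χ²_t; per-trait
assignment uses a Wald screen at α = 0.01 (χ²₁ 99% quantile). Complete
cases only (listwise deletion). Genetic correlations come from the null
Vg.

**q-values.** Storey's smoother: π₀(λ) on λ = 0.05 … 0.95, a cubic
polynomial smoother evaluated at λ = 0.95 (equivalent flexibility to the
customary df = 3 smoothing spline), clipped to (0, 1]; below 100 tests the
smoother is unstable and π̂₀ is fixed at 1 with a warning. The step-up
q-values are monotone in p and reduce to Benjamini–Hochberg at π̂₀ = 1.

## QTL pipeline

Clustering is greedy and peak-seeded: the most significant unassigned
marker absorbs all unassigned markers on its chromosome with dosage-R²
≥ 0.6 (squared Pearson correlation of dosages — the natural LD measure
for fully homozygous lines); clusters with overlapping physical intervals
are aggregated; clusters spanning more than 30% of the chromosome are
discarded as artifacts. A single-linkage chaining variant is available
behind `method="chain"`. Intervals are half-open base-pair ranges covering
the members; the peak is the smallest-p member, ties to the smaller
position.

Backward selection fits genotype×environment adjusted means with
environment-specific fixed allele effects per candidate (B73 indicator at
the peak), an iid genotype random effect and iid residuals. Both random
terms being iid makes the covariance block-diagonal by genotype, so a
per-genotype orthonormal (Helmert) rotation turns each REML evaluation
into weighted least squares; the variance ratio is re-estimated at every
elimination step. Each candidate is tested by a joint Wald test of its
full environment-effect block when added last; the worst candidate is
dropped until all survive at α = 0.01 (ties broken by genomic position,
making the procedure invariant to candidate input order). Candidates with
identical peak genotype vectors are collapsed to the one with the smaller
peak p, with a warning. A kinship-correlated genotype effect was
considered and deliberately not used: with n_geno×n_env observations the
iid form is tractable and the LOCO correction has already absorbed
relatedness at the scan stage.

Interval extension scans a 1 Mb window outward from each extremity and
extends to the most distant marker with R² ≥ 0.6 against the extremity
member. Colocalization is overlap of half-open extended intervals on the
same chromosome; direction concordance compares effect signs in the
environments where both QTLs are significant.

Variance explained is a fixed-effects refit on the peak indicators:
within an environment, r² = 1 − RSS(peaks)/RSS(intercept); network r² is
computed on environment-centred means with common (across-environment)
peak effects — the mixed-model alternative was rejected because a fixed
refit is what "variance explained by the selected markers" means
operationally and it keeps per-QTL partial r² (leave-one-out differences)
well defined. Per-environment r² therefore uses environment-specific
fits, network r² common effects; the two scales are reported separately.

Grain-yield prediction first merges GLAI QTLs into unique regions —
connected components of the interval-overlap graph, represented by the
member QTL with the smallest joint p — then backward-selects them against
the network yield means at α = 0.05 (a softer threshold is appropriate
for candidates that already survived one selection).

## Validation studies and problem sizes

The calibration/recovery studies in `glaidyn.benchmarks` run at the
reference scale of n = 324 lines and ~2,000 markers on 10 chromosomes;
replicate counts (200 null replicates for univariate calibration, 20
studies for the multivariate power comparison and the yield network, 50
for selection retention) were chosen as the package's own defaults to
give Monte-Carlo errors comfortably below the effect sizes being checked.
The multivariate-vs-univariate comparison plants three QTLs acting through
the curve architecture and adds a *shared plot-level error* across traits
(loading 0.5 SD) on top of independent noise (0.15 SD): traits measured on
the same plots share non-genetic error, and that residual correlation is
precisely the structure the multivariate model exploits and the
trait-by-trait scan cannot. In that regime the joint scan detects at least
as many planted QTLs as the union of eight univariate scans in ≥ 80% of
replicate studies — a qualitative, not quantitative, mirror of the power
advantage reported for multi-trait mixed models.

## Known limitations

* The spatial model is a separable AR1×AR1 on plot indices; irregular or
  missing-plot geometries fall back to the same index metric.
* The EM fit of (Vg, Ve) is first-order and can be slow near singular Vg;
  it is capped rather than accelerated.
* The bent-cable τ grid is thinned for dense inputs; pathological curves
  with many near-equal local optima could in principle land one grid step
  away from the global optimum (the oracle tests bound this).
* Backward selection tests environment-effect blocks jointly; a main
  effect + interaction decomposition is not provided.
* The generator's agronomic traits are linear in the true curve features;
  no saturation or threshold physiology is modelled.
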