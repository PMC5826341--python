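# Methods

This note documents the models and procedures the package implements, the
synthetic worlds it calibrates them on, the numerical choices involved, and
what the calibration results do and do not establish about real data.

## 1. The synthetic world generator

Real typological databases have a characteristic dependence structure:
languages are nested in families (shared descent) and geographic areas
(contact), climate covariates are spatially smooth, and traits can converge
within regions through borrowing.  `world_sim.generate_world` emulates this
structure explicitly:

1. **Geography.**  Family centres are uniform on a map (|latitude| ≤ 65°);
   member languages scatter around their centre with sd 14° latitude / 24°
   longitude, so large families span several areas (as real families do).
   Areas are equal-width grid cells; the number of cells is configurable
   (the default 25 approximates coarse macro-area schemes).
2. **Humidity.**  Mean specific humidity (kg water vapour / kg air) is a
   latitude gradient — wet at the equator — plus seeded area-level
   (sd 0.15) and language-level (sd 0.10) Gaussian noise on the gradient
   scale, affinely mapped into `humidity_range` (default 0.002–0.022, the
   span of observed climatological values).  Humidity is z-scored before
   entering any linear predictor, so all effect sizes are per standard
   deviation of humidity.
3. **Tone.**  `log E[n_tones] = log(baseline_tone_rate) +
   beta_humidity_tone · z(h) + family intercept + family slope · z(h) +
   area intercept + area slope · z(h) + borrowing_strength · D`, with
   independent Gaussian random effects (sds configurable) and Poisson
   counts capped at 10 (the empirical range; the cap is numerically
   irrelevant at the default rate).  A second measurement `n_tones_alt`
   adds rounded Gaussian error (sd `measurement_error_sd`) truncated at 0.
   The complex-tone class is `n_tones ≥ 3`.
4. **The diffusion field `D` (the borrowing confound).**  Tone borrowing
   spreads between neighbouring languages, so its imprint is a *spatially
   smooth field*, not a set of flat per-cell offsets.  `D` mixes a
   between-area geographic signal (weight 0.9), a within-area geographic
   gradient whose strength grows with the area-level signal
   (0.22 + 1.0 × area signal — borrowing activity is strongest where tone
   is areally prevalent), and idiosyncratic per-area noise (0.3).  `D`
   involves no causal humidity effect, but it is correlated with humidity
   at every spatial scale through shared geography.  This is Galton's
   problem in generative form, and it is why discrete-area controls
   under-correct: a grid cell absorbs the field's cell-mean but not its
   within-cell gradient.  The mixing weights were fixed once by a pilot
   calibration so that the fixture exhibits the defining behaviour of an
   areal confound (a strongly significant naive association, and
   significance that appears exactly when area random-effect terms are
   ablated) and then frozen.
5. **Vowels.**  Inventory size is 15 + Poisson(15) segments; the vowel
   share follows a logistic model with base 30%, a humidity effect
   (`beta_humidity_vowel`), a humidity × inventory-size interaction
   (`interaction_vowel`, formed after z-scoring both), and family/area
   intercepts; `n_vowels` is a binomial draw clipped so both vowel and
   consonant counts stay positive.
6. **Corpora and formants.**  `generate_corpus` draws multinomial
   tone-token counts per corpus × month × condition from a base simplex
   (default 0.23/0.22/0.21/0.34 over four tonemes), with a log-linear tilt
   of the contour-tone categories by z-scored monthly humidity
   (sinusoidal seasonal cycle) and a per-corpus contour offset (the
   random-intercept structure the seasonal analysis assumes); the
   trouble-source condition adds `shift_tone3` to the tone-3 probability
   with proportional renormalisation of the rest.  `generate_formants`
   places vowel targets on the perimeter of a template (F1, F2) triangle
   ((300, 800), (800, 1100), (300, 2300) Hz), scaled per language about the
   centroid, plus Gaussian jitter.

All randomness flows through numpy's PCG64 `default_rng`; identical config
and seed give bit-identical tables.

**What the generator does not emulate:** real family-size distributions and
tree topology (families are exchangeable), climate-model realism (humidity
is an abstract spatially smooth covariate), lexical word lists (vowel usage
is simulated at proportion level), and any dialect/diglossia structure.
Passing calibration here shows the procedures behave correctly *under the
stated dependence structure*; it cannot certify them against dependence
mechanisms the generator lacks.

### Frozen study fixtures

Four canonical configurations freeze the calibration conditions
(`world_sim.null_percentile_config`, `strong_suppression_world`,
`confound_world_config`, `recovery_world_config`):

* **Null world** (percentile test): 50 families × 10 languages, 16 areas,
  baseline tone rate 1.2 (complex-tone share ≈ 12%, near empirical tone
  distributions), no humidity effect, no borrowing.  The proportion the
  test reports is a property of the drawn world, not just of the
  iteration noise; a modest complex share and a coarse area scheme keep
  that world-level variability inside the calibration band.
* **Strong suppression world**: 170 families × 3 languages and 150 areas
  (a global database with hundreds of small lineages), tone-rich baseline
  (rate 3), strong continuous humidity effect (1.5 per sd) and graded dry
  suppression (probability 1 in the driest climate, fading to zero at the
  median).  Two features carry the test's power: humid regions saturate
  with complex tone (so the non-complex group loses humid-area coverage),
  and the graded fade means families and areas that straddle the gradient
  keep complex tone only on their humid side.
* **Confound world** (ablation sweep): 50 × 20 languages, 25 areas, no
  causal effect, borrowing strength 0.8, small residual area-slope sd 0.1.
* **Recovery world**: 50 × 20 languages, true tone effect 0.2, mild
  clustering (intercept sds 0.05, slope sds 0.02).

## 2. The percentile resampling test

Groups R (all languages), C (complex tone) and N (non-complex) are drawn by
a greedy randomized scan — shuffle, accept a language iff its family and its
area are both unused — giving a subset that is maximal for its scan order.
Group sizes are equalised by random deletion; for each level x
(default 15th/25th/50th/75th) the linear-interpolation quantile
(h = (n−1)·x between order statistics) of humidity is computed per group,
and the iteration scores a success if (C − N) > (C − R) strictly, which is
equivalent to q_N < q_R (asserted internally away from ties; ties count as
failures).  Languages may appear in R and in C or N within an iteration: the
three draws are independent.  A result is treated as positive when the
proportion exceeds 0.95.

Note an important structural property found during calibration: because the
independence constraint keeps roughly one language per family/area in every
group, the test is essentially insensitive to *within-unit* differences in
tone class; its power comes from whole families and areas being uniformly
complex-tone in humid regions (which thins N's coverage there) and from
units that straddle the humidity gradient keeping complex tone only on the
humid side.  A world with a sharp humidity threshold but no unit-level
saturation defeats the test entirely — worth knowing before interpreting a
negative result on real data.

## 3. The mixed-model engine

`fit_mixed` maximises a Laplace-approximated marginal likelihood for
Poisson-log, binomial-logit and gaussian-identity responses with independent
Gaussian random-effect blocks (one variance per term; a term is an intercept
or a slope-on-a-covariate for one grouping factor, e.g. the tone model's
`(1|family) + (z(h)|family) + (1|area) + (z(h)|area)`).

* **Inner step**: penalized Newton over the fixed effects and random-effect
  modes jointly (step-halving line search; the joint problem is concave for
  all three families).  The marginal log-likelihood is
  `l(y|η̂) − b̂ᵀD⁻¹b̂/2 − log|D|/2 − log|ZᵀWZ + D⁻¹|/2`, exact for the
  gaussian family.
* **Outer step**: the log-sds (plus log residual sd for gaussian) are
  optimised by a scipy optimizer (default Nelder-Mead; the choice is what
  the estimation-robustness sweep varies).  Starting values are
  method-of-moments (spread of group means on the link scale; pooled
  within-group sd for the gaussian residual); if the optimum lands on the
  log-sd clamp (a stalled plateau walk), the fit retries once from a
  generic start and keeps the better optimum.  Non-convergence is flagged
  on the fit, never silent.
* **Standard errors** come from the joint Hessian of the penalized
  log-likelihood at the optimum, upgraded for mixed fits to the observed
  information of the marginal likelihood over (β, θ) jointly (numeric
  Hessian; variance parameters collapsed to ~0 sit on the boundary and are
  excluded), so interval width also reflects variance-parameter
  uncertainty.  Confidence intervals use a t reference with containment
  degrees of freedom — levels of the smallest grouping factor minus one —
  the standard remedy for the mild anticonservatism of normal-reference
  Wald intervals when the covariate of interest varies mostly between
  clusters.  Wald z and p in the coefficient table use the normal
  reference (the convention of published ablation tables).
* **Likelihood-ratio tests** are forwards nested comparisons,
  χ² = 2·(ll_full − ll_null) with df = parameter-count difference.
  Variance components are tested with the boundary-corrected 50:50 mixture
  (p = ½·P(χ²₁ > stat), p = 1 at stat ≤ 0).
* **Degenerate inputs** (zero-variance predictors) are dropped from the
  design and reported on the fit rather than raised.

The ablation sweep refits the tone model under the five structures (full,
minus each random term) and reports the humidity coefficient per row; the
estimation sweep refits one spec under seven scipy optimizers and jittered
starts and reports per-coefficient spread (for specs without random terms
the outer optimizer runs on the fixed effects directly — a convex GLM — so
agreement to ~1e-4 is expected and checked).

## 4. Agreement and bias

Weighted kappa is `1 − Σw·O / Σw·E` with disagreement weights |i−j|/(K−1)
(linear, the default), squared (quadratic) or 0/1 (unweighted = Cohen's κ);
categories are the sorted union of values observed in either series, so κ is
defined when one source never uses a category; a single shared category
makes the expected disagreement zero and κ is reported as NaN.  The bias
test fits gaussian mixed models to the between-source differences: each
random intercept (family, area) is tested by the boundary-corrected LRT, the
covariate by an ordinary LRT; constant differences short-circuit to p = 1
everywhere.

## 5. Vowel-space geometry

Hull areas use scipy's convex hull (Qhull); degenerate point sets (< 3
distinct or collinear points) have area 0 and are flagged.  Areas are raw
Hz² by default; log-Hz and Bark (Traunmueller) transforms are provided for
sensitivity analyses, not applied by default.  All of a language's formant
rows are pooled; `n_vowels` counts distinct vowel labels so duplicated rows
are harmless.

## 6. Corpus statistics

The repair contingency is a 2 × K Pearson homogeneity χ² without continuity
correction (df = K − 1); a goodness-of-fit variant against the baseline
proportions is also provided.  Percentages are computed within condition;
the table's difference row is the *unrounded* percentage-point difference
rounded half-away-from-zero — rounding the differences, not differencing
the rounded percentages, is the convention that matches published tables.

The seasonal analysis aggregates token counts to corpus × month cells and
fits a binomial-logit mixed model of the contour-tone count with corpus
random intercepts; humidity enters z-scored and is tested by LRT.  A single
month or constant humidity is reported as degenerate, not an error.

The vowel-ratio series transcribes tokens through a user-supplied lexicon
and phoneme-class map (V/C); out-of-lexicon tokens lower the coverage
statistic, and documents with no consonants get a flagged NaN ratio.  The
seasonal smooth uses fixed bases — a Fourier basis (3 harmonics) over day of
year for the periodic trend, and a cubic B-spline with df = 4 (interior
knots at quantiles) in the covariate for the association — with a classical
OLS F-test of the spline fit against the intercept-only model.  A fixed-df
regression basis was chosen over a penalized smoother because it admits an
exact F reference distribution; with the default df this is a close,
transparent stand-in for a small-basis additive model.  The sign of the
linear projection of the fitted association is reported so a planted
monotone effect can be checked for direction.

## 7. Ancestral states and phylomorphospace

Ancestral values under Brownian motion are the minimisers of
Σ_edges (x_parent − x_child)²/length — maximum likelihood under the model
and identical to weighted squared-change parsimony — obtained by solving the
weighted-Laplacian linear system with tips fixed.  Consequences used as
tests: estimates are linear in tip values, stay within the tip range, and
are invariant to rescaling all branch lengths.  Missing branch lengths
default to 1.  The phylomorphospace layout places every node at its
(trait_x, trait_y) pair with edges mirroring the topology; plotting
adjustments (jitter for overlapping branches) are the caller's concern.

## 8. Causal graphs

Graphs are qualitative DAGs (no parametric structural model).  d-separation
enumerates simple skeleton paths and applies the standard blocking rules
(chains/forks blocked by conditioning on the middle node; colliders open
iff the collider or a descendant is conditioned on); the first open path is
returned as a witness.  Backdoor screening keeps paths whose first edge
points into the exposure, discards those blocked by the supplied controls,
and returns the interior nodes of surviving paths minus mediators — an
empty set certifies that the chosen controls make all other candidate
confounders redundant.  Path enumeration is exponential in principle but
instantaneous at the size of hypothesis graphs (tens of nodes).  The
shipped example graph (`humidity_tone_example_graph`) is a synthetic,
interpretive encoding of the humidity→tone hypothesis in its wider
demographic/contact context, built for illustration and tests.

## 9. Calibration studies and their sizes

The acceptance script and the heavyweight tests run: percentile-test null
calibration (one 500-language null world, 5000 iterations; band 0.40–0.55)
and suppression power (5000 iterations; > 0.95 at the 15th/25th
percentiles); parameter recovery (20 worlds of 1000 languages; MAE < 0.1,
≥ 90% interval coverage); the confound-ablation signature (20 worlds;
pattern in ≥ 80%); oracle-equivalence suites (kappa vs an independent
chance-corrected-agreement implementation, hulls vs a brute-force
half-plane construction, d-separation vs networkx on every canonical DAG up
to 5 nodes, ancestral states vs a numeric least-squares minimiser); and
type-I rates at α = 0.05 over 50 replicates for the bias tests, the vowel
interaction LRT, the seasonal LRT and the seasonal smooth (each ≤ 10%).
These sizes keep the whole suite comfortably within a few minutes while
leaving the Monte-Carlo noise well below the tolerances tested.

## Known limitations

* The Laplace approximation can bias variance estimates for Poisson data
  with very small counts and few observations per group; fixed-effect
  recovery is calibrated here, variance components are not certified.
* The greedy independent sample is maximal per scan order, not a maximum
  independent set; group sizes therefore vary by iteration (a resampling
  procedure, not an optimisation).
* The seasonal smooth's fixed bases trade flexibility for exact inference;
  strongly non-smooth seasonal patterns would need more harmonics/knots.
* d-separation witnesses are single paths; no minimal adjustment sets or
  effect estimation are attempted.
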