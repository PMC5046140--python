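# Methods

## The model

The pipeline evaluates where a medicinal conifer both grows well and
accumulates its effective needle constituents, on a common analysis grid
of square cells (ESRI ASCII convention: lower-left origin, row 0 at the
northern edge, cell-center coordinates; when layers differ in resolution
they are aligned to the *maximum* input cell size — bilinear for
continuous layers, nearest-neighbour for categorical ones).

### Growth: presence–background maximum entropy

Given presence sites and a background sample of cells with ecological
factor values, the growth model is the Gibbs distribution

  q_λ(x) = exp(λ·f(x)) / Z,  Z = Σ_background exp(λ·f(x)),

whose coefficients minimize the L1-penalized negative log-likelihood of
the presence sample. Features are linear and quadratic terms (hinge
optional, off by default — a deliberately small feature space for the
small-sample regime the method is chosen for; full Maxent-software feature
auto-selection is not replicated) of variables min–max scaled by their
training range; values outside that range at prediction time are clamped
and counted.

* **Regularization.** The per-feature penalty is
  β·sd(f | background)/√(n_presence) with β = 0.1 per feature class. The
  sample-size scaling is the standard maxent rule; a flat per-feature
  penalty does not shrink as data accumulate and, at realistic
  presence/background feature-mean shifts of a few hundredths, zeroes
  every coefficient.
* **Optimization.** The L1 term is handled exactly by splitting each
  coefficient into non-negative positive and negative parts and running
  L-BFGS-B with bounds at zero; the objective and gradient are exact, the
  stopping rule is a projected-gradient infinity norm of 1e-6 or 500
  iterations, and the recorded objective path is monotone non-increasing.
  Constant variables are dropped with a warning; non-convergence returns
  the best iterate with a warning.
* **Outputs.** `raw` is the normalized density (sums to 1 over the
  training background). `logistic` is τ·r/(1 − τ + τ·r) with
  r = exp(H)·raw (H the Shannon entropy of the background distribution)
  and τ = 0.5, so a featureless model scores 0.5 everywhere.
* **Evaluation.** AUC is the Mann–Whitney statistic (ties count ½),
  computed by midranks and identical to the all-pairs count. Presences are
  split 75/25 into train/test by a seeded permutation. Percent
  contribution is permutation importance: each variable's values are
  permuted across the pooled presence+background rows (10 draws, seeded),
  the drop in training AUC is averaged, floored at zero and normalized to
  sum to 100. Response curves vary one variable across its training range
  with the others held at background means; the optimal range is the span
  of grid values whose response is at least a stated fraction (default
  0.8) of the peak, with a warning if that region is non-contiguous.

### Quality: fuzzy K-t membership standardization

Each ecological factor is standardized to a suitability membership in
[0, 1] by the K-th-parabolic ("ridge") fuzzy distribution with support
(a, d), plateau [b, c] and limb exponent K:

  μ(x) = ((x − a)/(b − a))^K on (a, b), 1 on [b, c],
  ((d − x)/(d − c))^K on (c, d), else 0.

A negative fitted `a` for a physically positive quantity simply means the
rising limb's root lies below the observed range. Thresholds invert in
closed form on each limb: μ(x) ≥ t on
[a + (b − a)·t^{1/K}, d − (d − c)·t^{1/K}]. Degenerate limbs (b = a or
d = c) become step edges and warn. Alternative families — trapezoidal,
gaussian, rising/falling sigmoid — stand in for the other candidate
distributions of the original curve-fitting selection, whose exact
algebraic forms are not available to this package; family selection picks
the lowest parsimony-penalized residual RSS·n/(n − p).

The observed quality signal is the **aggregative indicator**: each of the
four compound contents (shikimic acid, procyanidins, total flavonoids,
total lignans) min–max normalized across samples, then averaged with equal
weights (the compounds are treated as equally important; a z-score
normalization and custom weights exist as options). A constant compound
column is uninformative and set to 0.5 with a warning.

**Calibration.** Per-factor marginal fits use nonlinear least squares on
quantile-binned data (20 bins, bin means; unbinned is an option),
multi-started from 10–11 data-quantile-derived initializations with the
a ≤ b ≤ c ≤ d ordering enforced by an increment parametrization and the
support bounded within one data span (wider supports are unidentifiable
and let the optimizer run away). The binned response is optionally min–max
rescaled to [0, 1] before fitting: in a multi-factor composite the
marginal response of factor i is wᵢ·μᵢ plus a baseline contributed by the
other factors, and a unit-plateau family cannot fit an un-rescaled,
baseline-shifted curve.

The pipeline then calibrates all factors **jointly**:
indicator ≈ α + Σᵢ vᵢ·μᵢ(xᵢ), vᵢ ≥ 0, by backfitting (each factor
refitted against its partial residual with the marginal fitter, dominant
factors first, amplitudes re-estimated by bounded linear least squares,
accepted only on RSS improvement) followed by a single bounded joint
least-squares polish of all parameters. Factor weights are the normalized
amplitudes v/Σv. Joint calibration removes the cross-factor baseline that
biases purely marginal fits; the maxent percent-contribution weights serve
as the initialization and remain available as an alternative weight source
(`weight_source="maxent"`) mirroring the pure objective-weighting
approach. They are reported alongside in every run.

### Overlay, masking, classification, validation

Quality suitability is the cellwise weighted mean Σ wᵢ μᵢ (weights ≥ 0,
summing to 1; nodata in any layer propagates; the result is a convex
combination and stays within the inputs' range). Growth and quality maps
are combined cellwise by minimum by default — a site must satisfy both —
with product and mean as options. Cells outside the allowed land-cover
classes (default: coniferous forest only) become nodata. The composite is
cut at t_high = 0.7 and t_low = 0.4 (both configurable; the class
boundaries are not externally given, and explicit numeric cutoffs are
required for reproducible class areas) into highly suitable (≥ t_high),
marginally suitable ([t_low, t_high)) and unsuitable classes; per-class
area is cell count × cell_size² in the grid's own units, percentages are
over classified cells and always partition 100. The area report adds a
"suitable total" row (classes 1 + 2). Validation is the RMSE between the
quality map extracted at sample sites (nearest cell, no interpolation)
and the observed indicator; points over nodata are excluded and the
usable count reported.

## Synthetic study conditions

The generator emulates the study system with one integer seed feeding
every stream (`numpy` SeedSequence spawning: one child per factor raster
plus one for land cover; presence sampling and content noise have their
own derived seeds).

* **Grid.** 100 × 100 cells, unit cell size.
* **Factors.** Five: April/June precipitation (mm), February/August mean
  temperature (°C), altitude (m). Each is a Gaussian random field (white
  noise smoothed with a Gaussian kernel of 10 cells, rescaled to the
  stated mean/sd); marginals are centered on each factor's true plateau
  with sd = (d − a)/6 so the landscape spans both limbs.
* **Truth.** True memberships are the published per-factor K-t fits
  (e.g. February temperature a = −42.4, b = 5, c = 8, d = 33.6, K = 13);
  true weights are the published normalized percent contributions
  (0.034, 0.139, 0.258, 0.439, 0.130).
* **Samples.** 200 presence points drawn with probability proportional to
  true composite suitability (cell centers, with replacement). Compound
  contents are scale·(true composite at the point) + Gaussian noise
  truncated at zero, noise sd = 5% of each compound's scale; all four
  compounds share one composite truth at different scales (12, 6, 45, 3
  arbitrary mass/mass units), so the equal-weight indicator is well-posed.
* **Land cover.** Five classes from a smoothed field quantile-sliced to
  proportions 0.55 coniferous forest, 0.15 broadleaf, 0.15 farmland,
  0.05 water, 0.10 urban.

What this emulates — and what it does not: the landscapes have realistic
smoothness and marginals but no climate physics, no cross-factor
correlation by construction (sampling induces some), and no geographic
structure; presence is a pure suitability-weighted draw with no survey
bias. Passing recovery tests therefore shows the *estimators* are correct
and well-conditioned under the stated noise, not that real field data
would behave as well.

## Numerical choices

* Min–max feature scaling; prediction-time clamping to the training range.
* Membership fits: `scipy.optimize.least_squares` (trust-region
  reflective) with xtol = ftol = 1e-10..1e-12; K bounded to [0.05, 60].
* A constant indicator at full membership short-circuits to a plateau
  covering the observed range (RSS 0).
* Ties in factor selection break deterministically by variable name.
* ESRI ASCII values are written in shortest-repr form, so write→read
  round-trips are bit-exact for finite values.
* Classification requires 0 ≤ t_low < t_high ≤ 1 and errors otherwise.

## Known limitations

* **Low-weight factors sit at the identifiability edge.** Over 20 seeds
  of the default conditions the calibration recovers weights within
  ±0.04 and plateaus within 2% of each factor's range — except April
  precipitation (weight 0.034), whose mean plateau error is ~10% of range
  with occasional wrong-region fits: its signal amplitude in the
  indicator (0.034) is at the per-point noise floor (~0.025), and
  suitability-weighted sampling induces explaining-away correlation with
  the dominant factors. More samples or lower noise would be needed, not
  a better optimizer (an unbinned variant and extra backfit/polish cycles
  were tried and do not help).
* **The SDM signal is weak by design.** Presence drawn proportional to a
  [0, 1] suitability bounds the achievable presence-vs-background AUC near
  2/3 (observed ≈ 0.62 train / 0.57 test); the growth map rarely exceeds
  the default t_high, so the default classification of the combined map
  is driven by the marginal class. Permutation contributions remain
  rank-correct but are unreliable as *quantitative* overlay weights under
  these conditions — the reason the quality stage calibrates weights
  against the indicator instead.
* Areas are reported in the grid's own map units; no CRS handling or
  reprojection, and no administrative attribution of classes.
* GeoTIFF is not supported; ESRI ASCII is the interchange format.
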