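# Methods

This note documents the statistical machinery behind `tdol`, the
choices made where several designs were defensible, and what the test
suite's synthetic validations do and do not establish.

## 1. Capacity model and identification

A capacity (fuzzy measure) on n attributes is stored as a vector over
the 2ⁿ subset bitmasks in the input attribute order; serialized keys
join sorted attribute names with `+`.  Two representations are used:
direct values v(S) and Möbius coefficients m(S) with
v(S) = Σ_{T⊆S} m(T).  Normalisation means Σ_S m(S) = 1; k-additivity
zeroes m(S) for |S| > k.  The Shapley value and pairwise Shapley
interaction index are computed in closed form from either
representation (φᵢ = Σ_{S∋i} m(S)/|S|; I_ij = Σ_{S⊇{i,j}} m(S)/(|S|−1));
the test suite checks both against brute-force permutation and subset
enumeration.

**Identification.**  `ChoquetRegression` minimises

    Σₛ (C_m(xₛ) − yₛ)² + ρ · ‖m − m_unif‖²

over active Möbius coefficients, subject to Σ m = 1 and all
monotonicity constraints v(S∪i) ≥ v(S), which are linear in m.  The
Choquet integral is linear in m (C_m(x) = Σ_S m(S) · min_{i∈S} xᵢ), so
this is a convex quadratic programme.  It is solved by an exact KKT
solve of the equality-constrained problem; if any monotonicity
constraint is violated there, an SLSQP polish with analytic gradients
runs from the strictly feasible uniform capacity (tolerance 1e-14,
residual constraint slack repaired by blending toward the feasible
start).  After solving, m is renormalised exactly, which makes Shapley
efficiency (Σφᵢ = 1) an identity rather than a solver tolerance.

Defaults: `k_additive=2`, `ridge=1e-6`.  With 3 products and 4
attributes the 2-additive model still has 10 coefficients for 3
observations; the ridge term shrinks toward the uniform additive
capacity m_unif (all attributes equal, no interactions), yielding a
unique deterministic solution.  Every fit reports `underdetermined`
(n_samples < n_parameters).  Requesting `ridge=0` in that regime is an
error unless explicitly allowed, because the optimum is then
non-unique.

**Commensurability.**  The Choquet integral requires all inputs on one
scale.  Every attribute column and the liking vector are min–max
scaled to [0,1] using the fit set's own extrema, with scaling records
kept for exact inversion.  A constant column is mapped to 0.5 and
flagged; it contributes nothing to the fit but preserves the sample
count.  Monotonicity validation tolerance is 1e-9; constraints inside
the QP are imposed exactly.

## 2. LMG decomposition

`LMGImportance` computes the share of each predictor *group* as the
Shapley value of the game S ↦ R²(S): exact subset enumeration up to
`max_exact_groups=8` groups (the subset-sum form, which equals the
average over orderings — the test suite verifies this against explicit
ordering enumeration), with a seeded Monte-Carlo fallback over sampled
orderings beyond that.  R² of a subset uses least squares with
intercept; rank-deficient designs fall back to the minimum-norm
(pseudoinverse) solution with a warning rather than failing, since
resampled consumer subsets can lose factor levels.  Shares are
normalised to sum to one by default (`normalized=True`); with zero
total R² normalised shares are undefined and an error is raised.

Just-about-right attributes are expanded to indicator columns with
"just about right" as reference level; a group's share is invariant to
the reference-level choice (tested).  An attribute with a single
observed level is dropped with a warning.

## 3. B-spline smoothing

Basis: clamped B-splines of order 4 (cubic) with equally spaced
interior knots; `n_basis` defaults to min(n_points, 20).  The
roughness penalty matrix ∫B″ᵢB″ⱼ is assembled by per-knot-span
Gauss–Legendre quadrature with `max(order, 3)` points per span, exact
for the piecewise-polynomial integrand.  Coefficients solve
(BᵀB + λP)c = Bᵀy.  λ=0 with a full basis reproduces interpolation;
λ→∞ with a second-derivative penalty converges to the ordinary
least-squares straight line (both are acceptance-tested limits).

When λ is not supplied it is selected by generalized cross-validation,
GCV(λ) = mean((y−ŷ)²) / (1 − tr(H)/n)², over the fixed grid
10⁻⁶…10⁴ (41 log-spaced points), keeping the whole procedure
deterministic: identical inputs give bitwise-identical coefficients.
Curves never extrapolate: evaluation outside the observed time domain
is an error.

## 4. Pipeline conventions

* Panelist ratings are averaged at each raw sampling time per
  (product, attribute) *before* smoothing, so each product contributes
  one functional curve per attribute; liking likewise enters as a
  per-product (consumer-mean) series for the Choquet path, while raw
  per-consumer tables feed only the LMG path.
* Default grids: 3–90 s step 3 (panel line-scale, 30 points), 1–25 s
  (first-bite check-all-that-apply proportions, 25 points), 14–90 s
  step 4 (just-about-right consumer data, 20 points).  All overridable.
* CATA proportions are already in [0,1] and enter the Choquet path
  like scaled attributes, with no extra transformation.
* Importance trajectories are smoothed column-wise; the smoother does
  not enforce the unit row sum, so evaluated rows sum to 1 only
  approximately (observed within ±0.02 on the observation grid in the
  validation runs; renormalisation is available as a flag but off by
  default, to keep curves faithful to the pointwise fits).
* Dynamics: zero crossings of f′ are found by sign change on a 201-
  point grid and refined by bisection; classification uses the sign of
  f″ at the root.  Stability thresholds default to 10% of each curve's
  max |f′| and max |f″|.  A curve whose first derivative is
  numerically zero everywhere (below 1e-9 relative to its value scale)
  is reported as having no extrema and being stable throughout — the
  relative threshold would otherwise chase round-off noise.

## 5. Synthetic data: what it emulates, what it does not

The generator mirrors a small industrial chew-down study: 3 products ×
4 texture attributes × 9 panelists on a 0–150 line scale, sampled every
3 s over 3–90 s; 40 consumers; 3 just-about-right flavour attributes;
5 check-all-that-apply items over 1–25 s.  Time-intensity curves use
the unit-peak gamma shape a·(t/p)^k·e^{k(1−t/p)} (default peak p ≈ 10 s,
steepness k = 2.5), with product-specific amplitudes, Gaussian rating
noise (sd 5 on the 0–150 scale) truncated to the legal range, and all
randomness drawn from one seeded generator per call.

Liking for the Choquet path is generated as 100·C_v(x) from a known
2-additive capacity applied to per-time min–max-scaled attribute
means.  Product amplitude sets include a low and a high *anchor*
product (the amplitude extremes of every attribute), so the pipeline's
per-time min–max scaling maps the anchors to the 0- and 1-profiles and
the generated liking is exactly representable by the model class —
this is what makes exact recovery a well-posed check.  The end-to-end
Shapley-recovery validation uses a 12-product variant of this design:
with 12 products the 2-additive fit is identified and the pipeline
must reproduce the generating Shapley vector to numerical precision
(observed MAE ~10⁻⁶).  The 3-product study-sized regime is validated
separately: there the ridge prior dominates, so recovery within 0.05
is only claimed (and tested) for a generating capacity whose Shapley
values lie within 0.04 of uniform.

The just-about-right generator draws levels per consumer and time from
smooth probability curves in which "too strong" stays rare and
"too weak"/"just right" mirror each other and cross mid-consumption;
liking is a 70-point baseline minus a fixed penalty per
non-just-right response (defaults 18/5/3 points for the three
attributes) plus Gaussian noise (sd 8).  The 3.5× penalty separation
makes the dominant attribute statistically identifiable from 40
consumers per time point; with near-equal penalties the per-time LMG
ranking at n = 40 is unstable, which is a property of the sample size,
not of the estimator.

None of the generators model panelist response styles, session or
carry-over effects, or consumer segmentation.  Passing recovery tests
therefore demonstrates the correctness of the estimation chain under
the stated model, not robustness to those real-data complications.

## 6. Known limitations

* The capacity fit treats the min–max scaling as fixed rather than
  estimating scale commensuration jointly; with very few products the
  liking rescaling can distort the target when the extreme products do
  not bracket the attribute space.
* Interaction trajectories from under-determined fits inherit the
  ridge prior's pull toward zero; their sign pattern is more reliable
  than their magnitude in the 3-product regime.
* LMG shares are reported without uncertainty; bootstrap intervals are
  out of scope.
* Importance-curve smoothing does not constrain rows to the simplex.
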