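# Methods

## Problem and model

Branch morphology in woody plants is typically well described by power
laws y = b·x^a between pairs of dimensions (length L, basal diameter D,
oven-dry mass M, and the cylinder-derived surface area SA = πDL and
volume V = π(D/2)²L). `allomtree` estimates the exponent a and
multiplier b for such pairs from per-branch measurement tables of
orchard trees, at three nested branch classifications, and places the
estimates against two process-based predictions:

* **Flow Similarity (FS)** parameterises everything by the L~D exponent
  α_F and derives the other pairwise exponents from cylinder geometry
  (e.g., SA ~ V^((α_F+1)/(α_F+2))). Hydraulics (area-preserving
  branching, constant flow rate and velocity) pins α_F = 2; biomechanics
  (branches at the elastic buckling limit under self-weight) pins
  α_F = 2/3. FS therefore predicts a *range* per pair, bounded by the
  flow and elastic endpoints.
* **WBE** (West–Brown–Enquist fractal branching) predicts point values;
  the branch-level anchor is M ~ D^(8/3). The companion points
  L ~ D^(2/3) and L ~ M^(1/4) are taken from the standard WBE derivation
  (they compose: (8/3)·(1/4) = 2/3) and are flagged `reconstructed=True`
  wherever they are reported, since only the 8/3 value is treated as
  canonical here.

All predictions are exact `fractions.Fraction` values internally and are
converted to floats only when compared with fitted CIs.

## Branch classification levels

* **segment** — the branch's own measurements; SA and V from the
  cylinder formulas above.
* **path** — the branch plus the longest continuous chain of distal
  branches. The chain is selected by cumulative *length* only; mass, SA
  and V are then summed along that length-maximal chain. Ties are broken
  by larger child diameter, then lexicographically smallest branch id,
  so recomputation is deterministic. (An alternative reading — focal
  segment plus terminal extension only — was considered and rejected;
  summing the whole chain keeps path values between segment and subtree
  for every additive quantity, which the pipeline asserts as an
  invariant.)
* **subtree** — the branch plus all distal branches; additive quantities
  are summed over the subtree in one post-order traversal.

At every level the diameter stays the branch's own basal diameter. A
missing mass anywhere in a chain/subtree makes the aggregate mass NaN
(propagated, never zero-filled), and mass-based fits then drop those
rows pairwise with a logged count.

Twigs (stems bearing only buds or short fruiting spurs, < 2 cm basal
diameter) are excluded from all levels by default; `include_twigs=True`
restores them. Twig status is partly observational, so it is read from a
table column when present and otherwise defaults to a configured
constant — it is never inferred from geometry alone.

## Estimation

Fits are reduced (standardized) major axis regressions on log10
coordinates: â = sign(r)·sd(log10 y)/sd(log10 x),
b̂ = mean(log10 y) − â·mean(log10 x). The slope CI is the standard SMA
construction Q = F(0.95; 1, n−2)·(1−r²)/(n−2),
CI = â·(√(Q+1) ∓ √Q), ordered low < high (mirrored automatically for
negative slopes, whose sign comes from the correlation). The intercept
CI re-evaluates b̂ at the slope CI endpoints; this is an approximation
(it ignores the covariance of mean and slope) and is labelled as such.
The analytic CI is used rather than resampling; R's `smatr`
(`sma(y ~ x)`) implements the same construction and can serve as an
external cross-check.

Base-10 logs are used throughout, so b̂ is a log10 intercept (this is
what makes mass~diameter intercepts negative at gram/centimetre scales).

Linear-vs-quadratic comparisons use OLS in log-log space with Gaussian
likelihood and AICc = AIC + 2k(k+1)/(n−k−1), k counting coefficients
plus the variance (3 linear, 4 quadratic). Ties within 1e-9 prefer
"linear". When the linear RSS is numerically zero the Gaussian
likelihood diverges for both models and parsimony decides: "linear".
AICc is a small-sample criterion; its preference for the true linear
model on linear data is strongest at small n (at n = 12 per dataset the
linear model is preferred in ≈93% of replicates at σ = 0.05, while as
n → ∞ AICc → AIC and the rate falls toward ≈84%), which is why the
calibration checks run at n = 12.

Model placement (`classify_fit`) uses closed intervals with 1e-9 slack
on the boundary comparisons: a numerically perfect fit (r² = 1) has a
zero-width CI whose endpoints carry only floating error, and without the
slack such a CI would spuriously miss the exact prediction it equals.
The `tendency` of a fit sequence across segment→path→subtree is
`toward_flow`/`toward_elastic` when the distance to that endpoint is
monotonically non-increasing with at least one strict decrease; constant
sequences, and sequences qualifying for both endpoints, are `mixed`.
CI-overlap comparisons between groups use raw 95% intervals with no
multiple-comparison correction, and the report footer says so.

## Synthetic generator

`SynthConfig`/`generate` build full n-ary self-similar architectures:
depth-i branches have diameter β^i·D₀ and length γ^i·L₀, so the
segment-level L~D exponent is exactly a_true = ln γ / ln β and the M~D
exponent is 2 + a_true (mass = density·πD²L/4). The `wbe_geometry`
preset (β = n^(−1/2), γ = n^(−1/3)) realises area-preserving branching
with M ~ D^(8/3) exactly when noiseless.

Defaults, chosen once as a realistic orchard-scale architecture:
bifurcating topology, 10 cm root diameter, 100 cm root segment length,
wood density 0.6 g/cm³ (typical temperate fruitwood), WBE-geometry
ratios, no noise. Measurement noise, when enabled, is multiplicative
lognormal on D and L independently (σ on the ln scale; σ = 0.05 in the
validation fixtures), with mass computed from the *noised* dimensions
times its own lognormal factor — this keeps log-log residuals
homoscedastic, the error structure SMA assumes. All draws come from one
seeded generator in a fixed order (per-branch D, L, M factors in
breadth-first order, then pruning uniforms in sorted-id order), so every
fixture is bit-reproducible.

Two pruning operators idealise orchard cuts: *branch-removing* deletes
each surviving subtree at depth ≥ `prune_min_depth` with probability
`prune_fraction` (root protected); *length-reducing* multiplies terminal
lengths and masses by 1 − `tip_trim` (SA and V, derived from length
downstream, scale along). The removed-mass fraction is returned; it is
exactly linear in `tip_trim` for fixed topology. These are idealisations
of qualitative cut types, not a regrowth model.

What the generator does **not** emulate: asymmetric branching, crotch
angles and 3D geometry, within-tree density variation, fruit load, and
regrowth after pruning. Passing the validation suite therefore shows the
estimators and traversals are correct under the stated error model — not
that field data satisfy that model. a_true is a segment-level quantity
only; path/subtree exponents of a finite-depth tree depend on truncation
and are validated against brute-force aggregation oracles instead of
closed forms.

## Numerical choices and degenerate inputs

* n ≥ 3 pairs required per fit (n ≥ 6 for AICc); zero variance in a log
  coordinate or exactly zero correlation abort a fit with an explicit
  error, and grid sweeps carry such cells as failure records rather than
  dropping them.
* Aggregation invariants asserted in tests: root subtree mass equals the
  sum of segment masses to 1e-9 relative; subtree ≥ path ≥ segment for
  every additive quantity, with equality exactly at terminal branches.
* Validation problem sizes: noiseless and σ = 0.05 recovery on 255-branch
  trees (8 bifurcation levels); CI calibration over 200 simulated
  datasets of n = 50 with the error split between coordinates so the
  population sd-ratio equals the nominal slope exactly; oracle-agreement
  sweeps over 100 random datasets.
* Ingest accepts tables with or without an explicit trunk row convention
  (any single record with an empty/NA/ROOT parent marker is the root);
  unit conversions are multiplicative factors in the schema config, with
  cm/g canonical.

## Known limitations

* The intercept CI is an endpoint re-evaluation, not a full SMA
  intercept CI.
* WBE L~D and L~M points are derivation-based reconstructions (flagged).
* Analytic SMA CIs only; no bootstrap alternative is implemented.
* No major-axis or ranged-major-axis variants, and no slope-heterogeneity
  test beyond CI overlap.
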