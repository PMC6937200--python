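# Methods

This note documents the models and procedures implemented in `dietstat`,
the conventions adopted where the field's practice is ambiguous, the design
of the synthetic survey generator, and the numerical choices that affect
results. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Survey data model

The observation unit is one fish stomach at one trawl station. Prey items
are classified into ten analysis groups (molluscs, copepods, amphipods,
euphausiids, large crustaceans, small crustaceans, fish, appendicularians,
chaetognaths, ova); `unidentified` matter and `parasite` records are kept in
the data model but flagged and excluded from every statistic, and a stomach
whose only contents are excluded items counts as empty. Counts are stored
as reals: volumetric subsample expansion (count and weight scaled by
total/subsample volume, the factor kept as provenance) produces non-integer
counts, and rounding them would break the additivity of numerical
composition.

Grouping conventions, applied identically everywhere:

- **Length groups.** S ≤ 33 cm, M 34–38 cm, L ≥ 39 cm, on integer-centimetre
  survey measurements. (Published descriptions of such groupings sometimes
  carry inverted inequality signs; this is the only internally consistent
  partition.)
- **Time periods.** Four half-open six-hour blocks of local hour:
  [00,06), [06,12), [12,18), [18,24), labelled P1–P4. Closed five-hour
  notations like "00:00–05:00" leave gaps; the half-open reading does not.
- **Distance-to-shore (depth-profile) classes.** By bottom depth:
  0–200 m, 201–500 m, 501–1000 m, > 1000 m (D1–D4).
- **Sub-areas.** Five labels (N, E, SE, SW, W) from point-in-polygon tests
  (shapely) against a configurable polygon set; the default is a rectangle
  partition of the waters around Iceland split at 66° N, 15° W, 19° W and
  64° N. Points on shared edges take the first covering polygon in the
  fixed precedence order N > E > SE > SW > W; points outside every polygon
  are labelled `unassigned` rather than guessed.

The modelling filters remove fish under 25 cm first, then stations left
with fewer than ten stomachs, and report the counts removed at each step;
filtering is idempotent, and an empty post-filter result raises an error
instead of propagating silently.

## Diet indices

For prey group *i* over a stomach set: vacuity `Vi = 100·Es/Ts`; pooled
composition `%W_i` (and `%N_i`) as group total over grand total; frequency
of occurrence `FO_i` with **all** stomachs in the denominator by default
(vacuity is reported separately; a flag restricts the denominator to
feeding stomachs); prey-specific abundance `PW_i`/`PN_i` over the stomachs
containing *i*; and `PSIRI_i = FO_i (PW_i + PN_i) / 200`.

Two conventions for prey-specific abundance circulate and differ on
heterogeneous stomachs:

- **mean** (default): the average of per-stomach proportions
  `mean_s(w_is / W_s)`. This is the canonical form of the PSIRI index:
  with it, `Σ_i FO_i·PW_i / 100 = 100` exactly on complete data (every
  stomach's proportions sum to one), so PSIRI sums to 100 over exhaustive,
  mutually exclusive groups.
- **pooled**: the ratio of sums `Σ w_is / Σ W_s`, i.e. a fullness-weighted
  mean of the same proportions. Reported formulas written as `ΣWi/ΣSWi`
  suggest this reading, but it does **not** satisfy the sum-to-100 property
  (two stomachs {A:1, B:1} and {B:9} give a pooled PSIRI-sum of 107.95).

Both are implemented; tables default to `mean`. On data with empty stomachs
the PSIRI sum falls below 100 by exactly the vacuity share, which is why
published tables computed over all stomachs sum to less than 100.

Never-observed groups are reported as absent rows (NaN prey-specific
abundance), not zero rows. Report output rounds to one decimal in percent;
all internal computation is full precision. The feeding-strategy diagram
plots `(FO_i, Pi)` with `Pi = PW_i`; quadrants split at the 50/50 midlines,
with the boundary assigned to the upper/right side.

## Community statistics

All distance-based machinery is implemented directly on numpy arrays;
scipy supplies only reference distributions.

- **Transform and distance.** Fourth-root on gravimetric matrices, then
  Bray–Curtis `d = Σ|x−y|/Σ(x+y)`. A pair of all-zero rows (two empty
  stomachs) has an undefined ratio; it is defined as distance 0 with a
  warning. Reported "percent similarity" is `100·(1 − d)`.
- **UPGMA.** Group-average linkage via the Lance–Williams update
  (size-weighted mean of member pair distances), which is exactly the mean
  over all leaf pairs — verified against a brute-force oracle. Ties are
  broken deterministically: clusters are represented by their
  lexicographically smallest leaf label and the smallest label-sorted pair
  merges first. Average linkage is reducible, so merge heights never
  decrease. Newick export halves merge heights into ultrametric node
  depths; children are ordered by smallest leaf label; reserved characters
  are quoted.
- **One-way PERMANOVA.** `SS_total = (1/N)Σ_{i<j} d²_ij`, `SS_within`
  analogously per group, `pseudo-F = (SS_between/(a−1))/(SS_within/(N−a))`.
  The p-value counts permutations with `F_perm ≥ F_obs` (tolerance 1e-12 on
  the comparison) with the +1 Monte-Carlo correction; when the number of
  distinct relabellings is at most the requested permutation count, the
  full enumeration is used and p is exact. 9999 permutations by default.
  Degenerate inputs (zero total SS) return a flagged result, not a number.
- **Two-way PERMANOVA.** Additive (no interaction), matching the
  area + year layout such surveys report. Squared dissimilarities are
  Gower-centred and sums of squares partitioned sequentially (type-I)
  through hat matrices of the expanding design `[1] ⊂ [1 A] ⊂ [1 A B]`;
  with a squared-Euclidean distance on univariate data this reproduces
  classical two-way ANOVA main effects exactly. Term order matters in
  unbalanced designs and is reported; empty cells warn. Permutation is
  unrestricted permutation of raw observations by default, with
  within-block restricted permutation available (`scheme="within-b"`).
  A constant second factor degenerates to the one-way test.
- **Pairwise comparisons** re-run the one-way test per group pair,
  unadjusted by default (pairwise tables are conventionally reported with
  raw significance bands); Bonferroni is available.
- **Kruskal–Wallis / Dunn.** Mid-rank H with tie correction and chi-square
  reference; Dunn's z on mean ranks with the tie term
  `Σ(t³−t)/(12(N−1))`, pairs in sorted label order so the sign convention
  is well defined, two-sided normal p, optional Bonferroni.

Analysis units: tests can run on individual stomachs or on pooled strata
(`pool_matrix` sums stomach rows per area, area × year, ...). Clustering of
sub-areas operates on pooled gravimetric vectors; stomach-level PERMANOVA
retains within-stratum variation. Both levels are exposed because reported
degrees of freedom in the literature are sometimes consistent only with
pooled units.

## Stomach-weight model

Response: `log(stomach weight)` as recorded at sea (the organ weighed with
its content; the generator can separate tissue from content to probe the
difference, which field data cannot). Candidate terms are smooth effects
of zooplankton biomass, bottom depth, 0–50 m salinity and temperature, log
total catch and Fulton's K (`K = 100·W/L³`), a joint longitude–latitude
surface, and the factors time period, distance-to-shore class, week and
year. Gaussian family, identity link.

The spline engine is a Gaussian penalized-least-squares fit written on
numpy/scipy: cubic B-spline bases on equally spaced knots with
second-order difference penalties (P-splines), k = 10 per 1-D term; the
geographic surface is a tensor product of two k = 5 marginal bases with an
isotropic Kronecker-sum penalty under one smoothing parameter; every
smooth carries a sum-to-zero constraint absorbed by an orthonormal basis
rotation. Smoothing parameters minimize the profiled Gaussian REML score

    V(λ) = (n − M) log RSS_p + log|X'X + S(λ)| − log|S(λ)|_+

(`RSS_p` the penalized residual sum of squares, `M` the number of
unpenalized coefficient directions, `|·|_+` the pseudo-determinant) over
log-λ with a Nelder–Mead simplex started at log λ = 0 and clamped to
[−25, 30]; the fit is deterministic given data and specification. On an
identical basis this engine reproduces mgcv's REML P-spline fit (one test
drives mgcv through Rscript and compares fitted values and effective
degrees of freedom). Effective df are `tr((X'X+S)⁻¹X'X)`; AIC is the
conditional Gaussian AIC `−2ℓ̂ + 2(edf + 1)` counting the scale parameter;
deviance explained is `1 − RSS/RSS_null` and adjusted R² uses `n − edf`.
Setting a smoothing parameter to `+inf` restricts the term exactly to its
penalty null space (the linear trend), so the infinite-penalty fit equals
ordinary least squares on the linearised design — an oracle the tests
exploit. Smooth-term significance is a Wald-type quadratic form referred
to F(edf, n − edf_total); it is approximate and labelled as such.
Unsupported basis columns (no data in a knot span, common for skewed
covariates) are left to the penalty; only genuinely aliased parametric
terms raise an error. A pairwise-correlation collinearity check
(threshold 0.95) is provided and should be run before modelling. Factor
baselines are the first sorted level (P1, D1), matching how such
coefficient tables omit their reference classes.

Model selection enumerates every subset of the term pool (the geographic
surface counts as one term; the candidate count is capped, default 256),
ranks by AIC, and computes ΔAIC, Akaike weights and the 95% confidence set
(smallest weight-ordered prefix with cumulative weight ≥ 0.95). Weight
arithmetic accepts a bare ΔAIC column, since published selection tables
often print only deltas.

## Synthetic survey generator

The generator emulates the *structure* the analyses assume, not any
particular sea: stations per area × year with jittered positions inside the
area polygons, July–August date-times, environment fields
(area-anchored 0–50 m temperature with ±1.5 °C spread, salinity
U(33, 35.5), bottom depth U(80, 1500) m, zooplankton biomass
lognormal(log 80, 0.6) mg/m³, catch lognormal(log 1500, 0.8) kg), ten
stomachs per station, fish of 26–47 cm with condition factor around 0.85.

Per stomach: empty with probability 0.083 (the vacuity level typical of
continuously feeding summer mackerel); otherwise a content weight from a
lognormal covariate model (below) is split across the ten groups by a
Dirichlet draw around the area × year base composition with concentration
50. Default base compositions are illustrative, not fitted: copepods
dominate everywhere, euphausiids are elevated in E/SE, large crustaceans in
the N, and a year multiplier on the large-crustacean share gives a real
year signal. Counts are derived from weights via a mean individual mass
per group (copepods 0.3 mg … fish 5 g, with lognormal jitter), which
reproduces the characteristic divergence of numerical and gravimetric
composition. Items below 1% of the content weight go unrecorded
(a detection threshold), giving frequency-of-occurrence values a realistic
spread instead of every group appearing in every stomach.

The covariate truth for log content weight is
`log C = log 2.0 + f(SST) + β_z·z + 1[P4]·δ + ε`, with `f` a half-sine
(amplitude 0.25 by default) over the 6–13 °C range or a quadratic, `z`
standardized log zooplankton biomass (slope 0 by default), an evening
offset δ = −0.065 and ε ~ N(0, 0.3²). Empty stomachs weigh zero (or the
organ tissue weight when `include_tissue` is on, which also adds tissue to
the recorded weight — field protocols weigh organ plus content, and the
flag lets both readings be generated).

Determinism: one seed; each station draws from a child generator keyed by
(seed, year, area index, station index), so datasets are byte-identical
across runs and stable under station reordering. The truth manifest
records the configuration, each station's base composition and expected
log content weight, and the covariate model, which suffices to recompute
the expected value of every downstream statistic.

`make_null_dataset` equalizes the named factor (area/year compositions, or
the SST/zooplankton/time-period effects) and is the basis of the
calibration checks: under the area null, one-way PERMANOVA p-values are
uniform (Kolmogorov–Smirnov check over 500 replicates), and rejection
rates rise monotonically as area compositions are pulled apart.

### What the generator does and does not emulate

It reproduces the sampling design, the compositional structure, the
count/weight divergence, empty stomachs, and a known covariate signal. It
does **not** simulate prey evacuation dynamics, spatial autocorrelation
beyond area labels, length-dependent diet shifts, or taxonomic richness
within groups (one representative taxon each). Passing tests therefore
demonstrate that the estimators recover the structure they assume — not
that any particular sea behaves like the generator.

### Design of the model-recovery study

The acceptance-level check of AIC term selection generates surveys whose
truth is a smooth SST effect (amplitude 0.5) plus a smooth zooplankton
effect (slope 0.2) with σ = 0.3, and asks how often the exact true term
set is AIC-best against a pool that adds a null week factor, over 100
replicates of 300 observations. Two deliberate choices:

- **One stomach per station.** Station-level covariates are shared by all
  stomachs of a station; with ten stomachs per station the rows are
  pseudo-replicated and AIC retains spurious *station-level* terms far more
  often than the nominal `P(χ²_k > 2k)`. The recovery study therefore
  samples one stomach per station so rows are independent. The caveat cuts
  both ways for field analyses that model stomach-level responses on
  station-level covariates, and is worth keeping in mind when reading such
  model tables.
- **A multi-level null factor.** AIC's false-inclusion probability for a
  k-parameter null term is about `P(χ²_k > 2k)`: ≈ 16% at k = 1, ≈ 11% at
  k = 3, ≈ 6% at k = 6. A winner-take-all recovery criterion is therefore
  intrinsically limited by the dimension of the smallest null candidate;
  the study uses the week factor (5–6 levels) so that the recovery rate
  reflects the machinery rather than this irreducible AIC property.

## Numerical conventions

- Tolerances: matrix symmetry and index identities asserted at 1e-12;
  sums-to-100 and SS additivity at 1e-9; ANOVA equivalence at 1e-8.
- Permutation p-values always carry the +1 correction except under exact
  enumeration; fixed seeds give bit-identical results.
- Degenerate inputs fail loudly: empty filters, all-empty stomach sets,
  zero total SS, singleton PERMANOVA groups, non-positive lengths and
  volumes all raise typed errors.
- CSV round-trips preserve numeric fields via `repr` (shortest
  re-readable float form) and text fields verbatim.

## Known limitations

- The additive-model engine covers the Gaussian/identity case only, which
  is what stomach-weight modelling needs; other families would need a
  different engine behind the same interface.
- Smooth-term p-values are first-order Wald approximations; treat them as
  screening values, as one should in any penalized-spline summary table.
- Sequential (type-I) sums of squares make unbalanced two-way PERMANOVA
  order-dependent; the order is reported, and the restricted permutation
  scheme is available for block structure.
- The area polygon defaults are schematic rectangles; real analyses should
  supply survey-specific polygons.
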