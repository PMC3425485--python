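# Methods

## The GUD-Peck model

The estimator's premise is that pecking is a stereotyped motion, so a
species' peck count is a usable proxy for its foraging effort and — at
roughly constant yield per peck — for the seed it removed. Trays whose
final GUD was measured (sifted and weighed) provide training pairs linking
the tray-wide peck total to the remaining mass; the fitted relationship is
then evaluated at the *cumulative* peck count standing when each earlier
species quit, which includes depletion by all previous visitors and none
by later ones.

The fitted form is additive ordinary least squares:

    GUD_i = β0 + β_pecks · P_i + β_density · d_i + α_{s(i)} + ε_i

* `P_i` — total pecks on tray *i* (all species);
* `d_i` — tray density: the sum over species of the minimum number of
  distinct individuals (see below);
* `α_s` — categorical offset for the final forager's species, treatment
  coding with the alphabetically first species as reference;
* no interactions. The density and species terms absorb systematic
  differences in per-peck yield and in crowding.

Reported diagnostics are training r² and the Pearson correlation between
observed and model-predicted GUDs. Assumptions worth keeping in mind:
every peck is equally likely to yield food, all species gain about the
same per peck, and the GUD–peck relationship is approximately linear over
the observed range. In a diminishing-returns patch the true curve is
convex (exponential-like), so the linear fit is a local approximation —
adequate for interpolation across the observed peck range, biased at the
extremes.

Estimation rules:

* the final forager's estimate is the prediction at the tray's total peck
  count, so it tracks the measured GUD up to residual error;
* visitors with fewer than `peck_min_threshold` (default 40) own pecks
  are flagged `few_pecks` and omitted — the model extrapolates poorly and
  regularly predicts negative consumption for such light visits;
* species never observed as a final forager have no offset and cannot be
  estimated (`species_not_in_model`);
* an unvisited tray keeps its full provisioning (`G0`, default 20 g) as
  its GUD;
* predictions are *not* clamped at zero; impossible values are omitted,
  not truncated, so they remain visible in diagnostics.

Consumption per species-tray is `G0 − predict(own pecks)` (a config
switch allows cumulative pecks instead; own pecks is the default because
the quantity of interest is what that species removed), and the rate
divides by the species' summed bout time in hours. Rows with non-positive
estimated consumption are flagged `negative_consumption`; a positive peck
count with zero bout time (all single-peck bouts) leaves the rate
undefined rather than infinite.

## Event analysis

* **Bouts.** A foraging bout is a maximal run of one species' pecks on
  one tray with every inter-peck gap < `bout_gap_s` (default 60 s). A gap
  of exactly 60 s terminates the bout ("at least one minute" is read
  inclusively). Summed bout lengths are minimum residency: the time
  before the first and after the last peck of a bout is not counted.
* **Quitting points.** A species quits at its last peck;
  `cum_pecks_at_quit` counts all species' pecks at or before that time.
  Time ties between species at the very last peck are broken toward the
  lexicographically smallest code purely for determinism.
* **Minimum individuals.** Birds are unmarked, so density is bounded
  below by combining two facts: distinguishable demographic classes
  cannot share individuals, and within a class the bound is the maximum
  simultaneous presence (sweep line over visit intervals; touching
  endpoints do not overlap). The species minimum is the sum of class-wise
  maxima; whether the field rule summed class maxima across disjoint time
  windows in every case is not documented, so this generalization of the
  worked example (3 concurrent females + later 2 males & 1 female = 5) is
  an explicit modeling choice. Yard-level community matrices sum the
  tray-level minima over a yard's trays.

## Community statistics

* **MRPP.** Bray–Curtis distance `Σ|x−y| / Σ(x+y)` on the yards × species
  matrix after row normalization (rows sum to 1; all-zero rows dropped
  with a warning) and rare-species filtering (occurrence below
  `rare_species_min_prop` of sites, strict `<`; with 20 sites the 5%
  default removes only species occurring nowhere, so the boundary-
  inclusive reading is available as `rare_filter_inclusive`). The
  observed delta is the group-size-weighted (`C_g = n_g/N`) mean
  within-group distance; the null distribution is `n_permutations`
  (default 999) random relabelings preserving group sizes; `p` uses the
  +1/+1 convention so it is never zero; `A = 1 − δ_obs/δ_exp`. These
  conventions match vegan's `mrpp` defaults, verified in the test suite.
* **Evenness** is Pielou's `J = H′/ln S` over species with positive
  counts — reported as an interpretation, since evenness can be indexed
  several ways; undefined below two species.
* **ANOVA / ANCOVA.** One-way ANOVA of per-species-per-yard mean GUDs on
  yard type (bush and open trays pooled, mirroring the analysis flow
  after the paired test finds no microhabitat effect); ANCOVA adds yard
  mean density and the type × density interaction via OLS and reports the
  interaction t and two-sided p.
* **Paired microhabitat test.** Paired t on bush − open differences per
  species-yard; optionally, a pair whose one side was never visited is
  completed by imputing the full 20 g provisioning. All-identical
  differences are handled explicitly (zero mean → t = 0, p = 1).
* **Rank tests.** Per-species two-sample Wilcoxon rank-sum between yard
  types (normal approximation, average ranks) and Kruskal–Wallis
  (tie-corrected) on consumption rates among species within each yard
  type. Two-sided p-values throughout; no multiple-testing correction is
  applied.

## The simulator

Each tray is an event-driven simulation of a 20 g patch over 24 h.

* **Arrivals** per species are Poisson with a per-yard-type rate
  (arrivals/h), each arrival a group (size distribution per species) of
  individuals with sampled demographic class tags. A lognormal yard-level
  multiplier (σ = 0.4) makes some yards busier than others.
* **Foraging.** An individual starts pecking within 5 s of landing and
  pecks at exponential inter-peck intervals (mean `60/peck_rate`). Per
  peck it harvests the expected yield: `y_max` (default 0.01 g) in
  `constant_yield` mode, `y_max · G/G0` in `diminishing_returns` mode —
  deterministic harvests keep the mass ledger exact and the quitting
  threshold sharp. It departs voluntarily with probability
  `1/mean_visit_pecks` per peck, pauses long enough to split a bout with
  per-peck probability `bout_pause_prob/peck_rate`, and quits
  *permanently* the moment expected yield drops below its quitting
  threshold `q` — hence the sharp theoretical giving-up density
  `GUD* = G0·q/y_max`. Later conspecific arrivals inspect the tray and
  leave without pecking once it is below their threshold.
* **Measurement.** The recorded GUD is the true final mass plus
  `N(0, 0.05 g)` weighing noise, truncated to `[0, G0]` and rounded to
  0.01 g like the lab balance; event times are continuous (video frames
  are not snapped). Visit intervals span first arrival to 1–10 s after
  the last peck; zero-peck inspections are not logged.

The default community has eight species with quitting thresholds giving
theoretical GUDs of 3–10 g, synanthropic granivores commoner in mesic
yards, natives commoner in xeric yards, and all thresholds scaled by 1.25
in xeric yards (richer alternative resources make foragers choosier).
These choices reproduce the qualitative study structure — lower GUDs in
mesic yards, overlapping species pools, tray densities around 8–20
minimum individuals — at a 40-tray scale a desk machine simulates in
under a second.

What the simulator does **not** emulate: interference competition (density
affects GUDs only through faster depletion), predation-risk responses
(bush/open labels are behaviorally neutral, matching the null field
finding), within-species individual variation, return visits by the same
individual, and observation errors in peck scoring. Tests that pass on
this generator therefore validate the estimators' arithmetic and
statistical behavior under the stated mechanism, not robustness to
scoring noise or behavioral complexity in real video data.

## Recovery benchmarks

Two recovery suites exercise the full chain end to end:

* **Slope recovery.** In `constant_yield` mode the data-generating law is
  exactly `GUD = G0 − y_max·P`, so the fitted `β_pecks` must land within
  5% of `−y_max` on a 20-yard study. It does, typically within 1%.
* **Threshold rank recovery.** Rank-ordering species by mean estimated
  GUD should reproduce the order of their true quitting thresholds. This
  is only an identifiable target when thresholds are separated by more
  than the model's residual noise (~0.7 g here) *and* trays are visited
  heavily enough for every threshold to bind — in sparse traffic a
  low-threshold species' last peck reflects when arrivals stopped, not
  its threshold (the same confound field studies face at low bird
  density). The benchmark community (`recovery_profiles`) therefore uses
  four species with theoretical GUDs 3/6/9/12 g and equal 0.3/h arrival
  rates; the default field-like community, with 0.5–1 g threshold
  spacings, is intentionally *not* a rank-recovery benchmark. Across 100
  seeded replicates the rank order is recovered in ≥ 95 (measured: 100).

## Numerical choices and degenerate inputs

* OLS via statsmodels on an explicitly built design matrix; a rank
  check precedes fitting and names the collinear columns. Fewer rows than
  parameters is an error, not a silent pseudo-inverse fit.
* Stage CSVs are written at six decimal places with fixed column order;
  write → read → write is byte-stable. Measured GUDs carry the 0.01 g
  balance precision.
* Permutation procedures take an explicit seed and are exactly
  reproducible; the observed labeling counts in both numerator and
  denominator of p.
* Degenerate statistical inputs (all-tied ranks, zero within-group
  variance everywhere, single-group designs, all-zero abundance vectors)
  raise a dedicated error or return a flagged row rather than NaN-ing
  silently; the CLI maps them to exit code 3, validation problems to 2.

## Problem sizes

Default analyses and tests run at the study's own scale (20 yards × 2
trays × 24 h, ≈ 50–90 k pecks per study). The stochastic suites use 100
replicates for rank recovery and 200 scaled-down replicates (12 sites,
199 permutations) for null-calibration checks of MRPP and the ANCOVA
interaction — sizes chosen to keep Monte-Carlo error well inside the
asserted bounds.

## Known limitations

* The GUD-Peck model is linear while diminishing-returns depletion is
  not; estimates for species quitting far from the training peck range
  inherit extrapolation bias.
* `species_not_in_model` visitors (never final foragers) are
  unestimable by construction — the same censoring the field method has.
* The minimum-individuals rule is a lower bound, not an abundance
  estimate; its sum across trays of a yard can double-count mobile
  individuals.
* MRPP group weights, the rare-species boundary, and the evenness index
  are field conventions with alternatives; all are configurable and the
  defaults are documented above.
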