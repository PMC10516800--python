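# Methods

## Model and assumptions

The analysis treats regional brain activity as a random vector over
animals: group *g* contributes n_g independent draws of a 176-dimensional
uptake vector, one coordinate per ROI of the cortico-basal
ganglia-thalamic parcellation. Metabolic connectivity between ROIs *i* and
*j* is the Pearson correlation of coordinates *i* and *j* across the
animals of one group. This is cross-sectional: there is no time axis, and
nothing here estimates within-subject temporal coupling.

The inferential machinery assumes approximate bivariate normality of
uptake pairs (for the t-based p-value of a single r) and independence of
the two groups (for the Fisher Z-test). Global uptake differences between
animals are removed beforehand by proportional scaling: each subject row
is multiplied by `target_mean / row_mean`, so every animal has the same
mean over ROIs (default target 100; only the ratio matters). Scaling is
idempotent, and it genuinely changes correlations when animals differ in
global gain — that is its purpose, not a side effect.

## Statistics

**Edge p-values.** For one correlation at sample size n,
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, two-sided. The exact
method for a single edge's p-value is a convention choice; this is the
standard one, and the test suite cross-checks it against a permutation
p-value. `|r| = 1` is treated as p = 0; the Fisher transform is clamped to
atanh(1 − 1e−15) only where a finite value is needed for display, with raw
r stored untouched.

**Jackknife reliability (within group).** n leave-one-out iterations; an
edge survives iff p < α (strict) in every iteration *and* its r keeps one
sign throughout. Sign consistency is our addition: an edge that flips sign
across iterations cannot be booked as reliably positive or negative in the
density tables. Consequence: the criterion is monotone in α (flagged sets
nest), but even at α → 1 sign-flipping near-zero edges are never returned.
The recorded sign is the full-sample sign. Full-sample significance is
*not* additionally required by default; `strict_full_sample=True` adds it.

**Fisher Z double jackknife (between groups).** Z = [atanh(r₁) −
atanh(r₂)]/√(1/(n₁−3) + 1/(n₂−3)), two-sided normal p, sign carried
separately (positive Z: group 1's correlation is larger). With matched
groups of n, 2n iterations each drop one subject from exactly one group;
reliability again requires p < α with consistent Z sign in all iterations.
Unequal group sizes are supported (n₁ + n₂ iterations) with a warning,
since the 2n phrasing assumes matched designs.

Both procedures are strictly more conservative than their single
full-sample tests: under a global null the empirical per-edge flag rate is
about 0.01 at α = 0.05 (the acceptance script reports it). They perform no
explicit multiplicity correction beyond this; with ~15k simultaneous
edges, tens of false edges per network are expected and visible in any
two-independent-sample comparison.

## Density, degree, hubs, layout

Connectivity density for structures (a, b) and sign s is
100 · (# reliable s-edges joining a and b) / pair_count(a, b), with
pair_count(a,a) = k(k−1)/2 and pair_count(a,b) = k_a·k_b. Degree counts
incident edges of either sign equally; hubs are the top ⌈fraction·N⌉ nodes
by degree (default fraction 0.10 → exactly 18 of 176), with ties at the
cutoff broken by registry order so the hub count is deterministic. Degree
changes between groups are ranked descending with the same tie rule.
Layouts use the Kamada–Kawai algorithm (networkx) on the unsigned,
unweighted graph, per connected component from a seeded circular start;
isolated nodes are placed on a peripheral ring. Layout is visualisation
only; no statistic depends on it.

## The shipped parcellation

The registry fixes 176 ROIs: CP 66, SNr 25, GPe 27, motor cortex 18, PFC
19, thalamus 21, grouped by structure and ordered rostral → caudal by
bregma level. The CP and TH counts are part of the published arithmetic
(2145 = 66·65/2 within-CP pairs; 1386 = 66·21 CP–TH pairs). The remaining
four counts are derived, not copied: every published density percentage is
an integer edge count divided by a pair count, and 25/27/18/19 are the
unique integers consistent with all fourteen printed within- and
between-structure densities (e.g. 21.00% = 63/300 forces SNr = 25;
8.77% between GPe and PFC = 45/513 forces 27·19). The per-bregma domain
lists inside each structure are plausible reconstructions of the published
scheme — they fix ordering and labels but carry no statistical weight; any
registry CSV with the documented header can replace them.

## Synthetic generator

`CovarianceSpec` assembles a target correlation matrix: unit diagonal,
constant r within each structure block (scalar or per-structure mapping),
zeros elsewhere, planted edges overriding. Matrices assembled this way can
be jointly infeasible, so the builder clips negative eigenvalues at zero,
re-normalises to unit diagonal, and reports the largest entry change; if
that exceeds a tolerance (default 0.05) the spec is rejected rather than
silently distorted. Sampling uses an eigendecomposition factor (robust for
singular PSD matrices) of the repaired matrix, times `noise_sd` (default
5), plus `baseline_mean` (default 100, matching the scaling target), with
a single `numpy.random.default_rng(seed)` stream per group. Degenerate
draws with a constant column are resampled with an incremented seed
(probability ~0 for continuous data). Defaults emulate the study design:
10 subjects per group, 176 ROIs.

What the generator does *not* emulate: film/digitisation noise,
section-alignment artefacts, spatial autocorrelation between neighbouring
ROIs beyond the block structure, non-Gaussian tails, and outlier animals.
Passing tests therefore demonstrate correctness of the statistical
machinery under its own assumptions, not robustness of the biology-facing
conclusions to violations of those assumptions.

## Problem sizes and tolerances in the test suite

Oracle-equivalence tests compare both jackknife procedures against
explicit pairwise leave-one-out loops (scipy.stats.pearsonr per pair) on
8-ROI instances with n = 6–10 over 50 seeds — exact set equality, no
tolerance. Calibration uses 20 ROIs, n = 10/group, 200 replicates, and
asserts the mean per-edge flag rate ≤ α; power uses 100 replicates and
asserts ≥ 0.90 recovery of a planted within-group r = 0.95 edge and
≥ 0.50 detection of a planted 0-vs-0.95 group difference, with null edges
held inside a two-standard-error binomial envelope around α. Monte-Carlo
checks of the generator (mean sample r within 0.05 of target over 200
seeds; type-I rate 0.05 ± 0.035) match binomial/sampling error at those
replicate counts. These sizes keep the full suite under a minute while
leaving each stochastic bound several standard errors away from its
expected value.

## Known limitations

- The jackknife controls reliability per edge, not family-wise error or
  FDR; downstream density comparisons inherit this.
- The t-based p-value is exact only under normality; a permutation option
  exists in the test oracles but is not part of the pipeline.
- Hub identity (not count) is sensitive to ties and to α; only the count
  is guaranteed stable.
- The registry's non-CP/TH per-structure *counts* are exact by the density
  arithmetic, but individual ROI labels within structures are
  reconstructions.
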