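# Methods

## Matched sets

The unit of analysis is the matched set: one index rater plus all other
raters tied at the minimum inter-rater distance, provided that distance
does not exceed `max_radius` (default 500 m, the distance within which
two residents are taken to rate overlapping neighborhood environments).
Every rater with a qualifying neighbor is the index of exactly one set;
isolated raters are excluded and counted. Ties share a single unit of
neighbor weight (`1/m` each), so each set contributes like a two-rater
pair regardless of `m`. Co-located raters (distance 0, e.g. one
multistory building) are ordinary neighbors; a rater is never its own
neighbor.

Distances are planar Euclidean on projected coordinates in meters
(`distance_metric="planar-euclidean"`); a great-circle option treats
coordinates as (lon, lat) degrees, maps them to the unit sphere, searches
in chord space and converts chords back to arc meters, so KD-tree
correctness carries over unchanged. Ties are detected with an absolute
tolerance of 1e-9 m — far below geocoding precision, large enough to
absorb floating-point noise; exact distance computations make genuinely
equal distances (lattice or co-located coordinates) compare equal anyway.
The KD-tree query retrieves 8 candidates per point and escalates to a
ball query whenever the tie cutoff reaches the last candidate, so
arbitrarily large tie groups are handled; an O(n²) scan is the test
oracle for this machinery.

## The weighted contingency table and margin conventions

Cell `(j, k)` holds `o_jk = (1/n) Σ_i (1/m_i) x_i(j, k)`. Row sums are
then exactly the index raters' relative counts `p_j`, computed over the
*included* raters only — the analyzed population is the set of matched
sets, so excluded isolated raters contribute to nothing. Column sums are
the weighted neighbor relative counts. All chance expectations use the
index margins `p_j` alone, assuming neighbors share the index raters'
overall rating distribution; the neighbor margins are reported so the
accuracy of that assumption (and hence of the CLQ→kappa identity below)
can be checked per table. Cells are proportions, not counts; the
effective sample size for inference is the number of sets.

## CLQ, kappa, and their interconversion

With `p_a`, `p_b` index margins and `o_ab` the observed colocation:

* `CLQ(a,b) = o_ab / (p_a p_b)`. The chance term deliberately includes
  the index rating itself (sampling with replacement), so no `N/(N−1)`
  correction is applied.
* `CLQ_max(a,b) = (p_a + p_b) / (2 p_a p_b)`: conditioning on the total
  share `p_a + p_b` and assuming the two categories occur equally often,
  the colocation proportion can at most reach `(p_a + p_b)/2`, while the
  chance denominator keeps the actual `p_a p_b`. For `a = b` this is
  `1/p_a`, and the constraint `p_a + p_b ≤ 1` does not apply.
* `kappa(a,b) = (P_O − P_E)/(1 − P_E)` where `P_O` sums the two agreement
  cells of the dichotomized `{a,¬a}×{b,¬b}` table and
  `P_E = p_a p_b + (1−p_a)(1−p_b)`. For `a = b` this equals the overall
  kappa of the a/not-a collapse — an identity asserted to 1e-12 in tests.
* `kappa ≈ (CLQ − 1)/(CLQ_max − 1) = 2 p_a p_b (CLQ − 1)/(p_a + p_b − 2 p_a p_b)`.
  Using `P_O ≈ 1 − p_a − p_b + 2 o_ab` (exact when neighbor margins equal
  index margins) the two definitions coincide algebraically; the property
  suite verifies equality to 1e-9 on random equal-margin tables.

Both ordered directions `(a,b)` and `(b,a)` are always computed — the
measures are asymmetric in general — together with the diagnostic
`max |CLQ(a,b) − CLQ(b,a)|`. Statistics that do not exist for a table
(zero margin, `P_E = 1`) raise `UndefinedStatisticError` from the scalar
functions and appear as NaN / "NA" in matrices and rendered tables, never
as 0 or infinity.

## Uncertainty: approximate SE and its known miscalibration

`null_se` implements the large-sample no-agreement variance of kappa for
two raters (Fleiss–Cohen–Everitt) on the dichotomized table, with row
margins `r` (index), column margins `s` (weighted neighbor),
`P_E = Σ r_i s_i` and `n` = number of matched sets:

```
SE0 = sqrt( (P_E + P_E² − Σ_i r_i s_i (r_i + s_i)) / (n (1 − P_E)²) )
```

(for symmetric 0.5 margins this is `1/√n`). Two-sided normal p-values and
the star bands `*` (0.01 ≤ p < 0.05), `**` (p < 0.01), `***` (p < 0.001)
are derived from it.

This SE treats the n sets as independent pairs. They are not: in planar
point patterns roughly 60% of raters are each other's mutual nearest
neighbors, so those pairs enter the table twice, and neighbors are also
shared across sets. Simulation shows the true random-labeling SD of kappa
exceeds SE0 by a factor of ~1.3–1.5 for same-category statistics (less,
~1.0–1.4, for cross-category pairs), which makes the |kappa|/SE0 test
anti-conservative: its measured type-I error at nominal 5% is ~13–15%.
The package therefore ships `permutation_null`, which permutes ratings
over the fixed geometry (margins preserved, seeded, reproducible) and
recomputes CLQ and kappa per draw; permutation SDs or tail probabilities
are the calibrated choice whenever the uncertainty matters, and the
`analyze` pipeline attaches permutation SDs and p-values to the
same-category results when `--permutations` is set. The corresponding
calibration checks in the acceptance suite are intentionally left
failing at their stated tolerances rather than loosened: they document
the approximation honestly. With n in the tens of thousands the absolute
inflation is small; with hundreds of sets it is not.

## Collapsing categories

`collapse_table` sums cells and margins over a user partition
(`"1+2,3+4,5+6"` syntax); mass and margin additivity are exact.
`evaluate_collapse(table, a, b, tau)` merges one candidate pair (other
categories kept) and reports the three criteria: (i) cross CLQ > 1 and
cross kappa > 0; (ii) cross CLQ ≥ (1 − τ)·min(same-category CLQs); (iii)
merged same-category kappa strictly greater than both originals. "Of the
same magnitude" has no canonical quantification, so τ is a surfaced
parameter; the default τ = 0.15 reproduces the qualitative accept /
borderline calls one would make on published tables of this kind. A
degenerate collapse into a single group yields a valid 1×1 table whose
kappa is undefined (category schemes therefore allow a single code even
though analytical input schemes require at least two).

## Synthetic data generator

`generate(SimulationConfig(...))` emulates a geocoded survey of a
spatially shared environment. Raters are uniform on a square domain; a
square grid of patches (side `patch_size`) each draws one latent level
i.i.d. from `latent_probs`; a rater reports its patch's level through a
misclassification matrix and is then overridden to the indefinite code
with probability `p_indefinite` or the missing code with `p_missing`
(independent of location). Identical seeds give identical datasets
byte-for-byte.

Defaults are fixed at the package's study conditions: four informative
levels with prevalences (0.144, 0.344, 0.378, 0.134), indefinite/missing
rates 0.07 and 0.042, 5 000 raters on a 7 km × 7 km domain (median
nearest-neighbor distance a few tens of meters), 200 m patches (a
5–10-minute-walk neighborhood), and adjacent-level perception noise with
fidelity 0.7. Helper constructors give the two analytically important
regimes: `null_confusion` (all rows equal — ratings independent of
location, the calibration null) and identity confusion (perfect
within-patch agreement).

What the generator does *not* emulate: heterogeneous population density
(urban/rural gradients in neighbor distance), spatially smooth or
autocorrelated latent fields beyond the patch mosaic, systematic
rater-level perception bias, and spatial clustering of non-response
(optional patch-linking of the overrides was considered and dropped —
independent overrides keep the null constructions exact). Passing tests
therefore demonstrate correctness of the statistical machinery under a
clean spatially-shared-environment model, not robustness to real survey
artefacts.

Two latent-class regimes matter for interpretation. With *two-sided*
adjacent noise, two common adjacent levels compete for the same latent
patches and their cross CLQ can fall below 1 even though the noise is
adjacent-level — which is exactly the published pattern where the
agree/disagree divide separates (cross CLQ < 1) while pairs within one
side of the scale cluster. The pattern-recovery test therefore generates
levels 1–2 and 3–4 from two latent sides (within-side adjacent mixing)
and asserts clustering within sides and separation across them, rather
than the naive "all adjacent pairs cluster".

## Problem sizes and numerical choices

Simulation-based tests use: 200 replicates of 5 000 raters for null
calibration; 2 000 permutations on 600 sets for the SE comparison; 1 000
random tables for the normalization identity; 100 configurations of up to
500 points for the brute-force neighbor oracle; 4 000–20 000 raters for
parameter recovery — sizes at which Monte-Carlo error is a few percent
and the full suite runs in well under a minute. Table validation accepts
mass deviations up to 1e-8 (accumulated rounding over tens of thousands
of weighted increments) while freshly built small tables are tested to
1e-12. Tie tolerance, τ, and all seeds are explicit parameters; display
rounding (CLQ and percentages to two significant figures, kappa to
integer percent with one decimal below 10%) is confined to the renderer,
with machine outputs at full precision, and the rendered table is a pure
function of the long-format CSV so the round trip is exact.
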