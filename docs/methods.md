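# Methods

## The assessment model

A repertory grid is a C×E integer matrix: C bipolar constructs (rows),
E elements (columns), each cell a rating on a symmetric Likert scale
(default 1–7, midpoint 4). Exactly one element has the *self* role and
one the *ideal* role; all others are significant people in the rater's
life. The package treats the grid as complete data: missing cells are
rejected, not imputed, because every downstream rule assumes a full
matrix and any imputation scheme would be an untested invention laid
under a clinical instrument.

Only symmetric scales are accepted (`min + max = 2·midpoint`). The
midpoint is load-bearing: the dilemmatic-construct rule is defined by
it, and pole membership is defined relative to it. Asymmetric scales
would make "neither pole" ill-defined, so the validator rejects them.

## Detection rules and their parameters

**Classification.** Verbal definitions ("rates self and ideal
similarly", "at opposite poles") are operationalized as integer gap
bands on the 1–7 scale: gap ≤ 1 → congruent, gap ≥ 4 → discrepant,
2–3 → neutral (ineligible for dilemma pairing). The dilemmatic check
(ideal exactly at the midpoint) runs first and overrides the bands.
gap ≥ 4 is the smallest gap that forces self and ideal onto opposite
sides of the midpoint on a 7-point scale, which is what "opposite
poles" means geometrically; gap ≤ 1 is the tightest non-trivial
reading of "similarly". Both bands are exposed as
`DetectionParameters(congruent_gap_max, discrepant_gap_min)` so other
conventions can be explored without code changes.

**Pair correlation.** The dilemma statistic is the Pearson
product-moment correlation of the two rating rows — the grid tradition
analyses raw ratings, and the threshold is quoted as an `r`. Each row
is first *oriented*: reflected about the midpoint when its reference
rating lies above it, so that the congruent construct's valued pole
(the ideal's side; self and ideal coincide there up to the small gap)
and the discrepant construct's present/symptom pole (the self's side)
both sit at the low end. The references are chosen so orientation is
defined in every reachable case: a congruent construct's ideal is never
at the midpoint (that row would be dilemmatic), and a discrepant
construct's self cannot be at the midpoint on a 7-point scale when the
gap is ≥ 4. On wider scales that corner case can occur; the detector
then skips the pair with a warning rather than guess an orientation.

**Flagging.** A pair is an implicative dilemma iff oriented r is
*strictly* greater than `correlation_threshold` (default 0.35). Rows
with zero variance over the correlation element set have no defined r;
such pairs are skipped with a logged warning rather than silently
scored 0, so degenerate grids stay visible. Output order is
deterministic (descending r, then index pair) to keep reports and JSON
diffable.

**Element set.** By default the correlation runs over all E columns,
self and ideal included, matching the convention that the whole score
matrix is analysed; `include_self_ideal_in_correlation=False` restricts
it to significant others. The default is a genuine judgement call — the
method's verbal description does not pin it down — and the flag makes
the ambiguity explorable. Note that including self/ideal systematically
*lowers* the oriented r of a true dilemma pair: on the congruent
construct self and ideal sit together, while on the discrepant one they
sit on opposite poles, so the ideal column is a guaranteed discordant
point. The synthetic-recovery numbers below reflect that.

**Prototypical figures.** For an implicative dilemma, the current side
collects others rated on the congruent construct's self pole AND the
discrepant construct's present pole; the change side the two opposite
poles. "On a pole" means at least `pole_membership_margin` (default 1)
scale steps beyond the midpoint, so midpoint ratings belong to neither
side and the two sides are disjoint by construction. For a dilemmatic
construct, each side returns the others at the most extreme rating
actually used on that side — the rater's own range, not the theoretical
1/7 — with ties kept.

## Grid indices

The four named indices have no published closed forms, so the package
uses the simplest defensible operationalizations and says so:

| index | definition | range |
|---|---|---|
| self-ideal discrepancy | mean over constructs of \|self − ideal\| / span | 0–1 |
| self isolation | mean over others of city-block(self, other) / (C·span) | 0–1 |
| adequacy of others | 1 − mean over others of city-block(ideal, other) / (C·span) | 0–1 |
| polarization | % of all C·E ratings at the scale extremes | 0–100 |

City-block distance is used because it is exactly invariant under
construct reflection (|x − y| is preserved by the mirror map), so a
purely presentational pole swap cannot move any index. These are NOT
certified equivalents of any legacy grid program's internal formulas;
they are documented, tested operationalizations of the named concepts.

**Pre/post comparison** matches constructs by index and requires
verbatim pole-label equality (fuzzy matching would be guesswork). For
each pre-grid dilemma it reports Δ(self-ideal discrepancy),
Δ(association strength), and `resolved` (the pair is no longer flagged
post). The post correlation is computed with the *pre* grid's
orientation reflections held fixed, so the association delta measures
the same quantity on both occasions even when the pair reclassifies
after treatment (e.g. the self rating moved onto the ideal, changing
the self pole).

## Synthetic grids

The generator emulates the conflict structures, not any patient
population. A pair plant draws the two rows over significant others
from a shared-latent-factor construction (`x₁ = √|ρ|·z + √(1−|ρ|)·e₁`,
`x₂ = sign(ρ)√|ρ|·z + √(1−|ρ|)·e₂`), scales by SD 1.5 around the
midpoint, rounds and clamps to the scale. Self/ideal cells are set
directly from the plant (defaults 2/1 congruent, 2/7 discrepant), so
the intended classification holds by construction and is re-verified at
generation time. The default roster of significant others in examples
and operating-characteristic runs is 13 (a 15-element grid), the
realistic size of a clinical grid.

Two things attenuate the realized correlation relative to the latent
target: discretization (round + clamp), and the fixed self/ideal
columns entering the default correlation (the ideal column is
discordant by design, as noted above). A latent ρ = 0.9 at 13 others
realizes an oriented r of about 0.47 on average and is flagged in
roughly 70–75 % of replicates; at 30 others the rate reaches 99 %. Tests therefore
assert against *realized* correlations
(`realized_plant_correlations`) and against Monte-Carlo rates, never
against the latent target. Replicate streams derive from
`SeedSequence([base_seed, replicate_index])`, so every rate is exactly
reproducible from one integer seed.

What the generator does **not** emulate: real grids' elicited
construct semantics, rater response styles (acquiescence, extreme
responding), correlated backgrounds across many constructs, or any
clinical prevalence of dilemmas. Passing synthetic tests shows the
rules are implemented and behave correctly, not that any population
figure would be reproduced.

**Boundary location.** `bracket_threshold` finds the detector's
decision boundary empirically: a hill-climb over integer rating rows
(self/ideal cells fixed to an eligible pattern, one random other-cell
mutation per step, random restarts off plateaus) pushes the pair's
brute-force correlation toward the threshold from both sides while
querying the real detector, and returns the supremum of non-flagged
correlations. With 10 mutable cells per row the achievable r values are
dense enough that the returned boundary sits within about 2·10⁻⁴ of the
configured threshold across seeds, always from below (strict
inequality).

## Numerical choices

- Correlations are computed with `numpy.corrcoef` and clamped to
  [−1, 1]; the test suite checks agreement with an explicit two-pass
  sums implementation to 1e−12 on 1,000 random grids.
- Serialized floats are rounded to 6 decimals — correlations and
  indices are the only floats, and 6 decimals keeps JSON diffs stable
  well beyond their meaningful precision.
- Dilemma confidence intervals in `summary()` use the Fisher
  z-transform with SE 1/√(n−3); with grid-sized n they are wide and are
  shown to discourage over-reading small grids, not for testing.
- The results-document schema is generated from the pydantic models and
  shipped as a static JSON file; a test keeps the two in sync.

## Run sizes

Operating-characteristic checks use 200 replicates per latent-ρ level
at 15 elements (recovery curve) and 2,000 replicates for the null rate,
compared against an independent 20,000-draw Monte-Carlo of the null
tail; these sizes give rate standard errors of about 0.01–0.03, small
against the effects being checked, while the whole suite runs in
seconds.

## Known limitations

- The gap bands, correlation element set and index formulas are
  reasoned choices where the method's verbal description is silent;
  all are parameterized or documented rather than hidden.
- Only complete, symmetric-scale grids are accepted; there is no
  missing-data handling and no import of legacy grid-program file
  formats.
- No significance testing of pair correlations: the method is a fixed
  threshold rule, and n per grid is small enough that formal tests
  would mostly reflect the element roster size.
- Pre/post matching assumes the same construct list in the same order;
  re-elicited grids with changed constructs cannot be compared
  automatically.
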