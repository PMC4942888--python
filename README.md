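# gridconflict

Cognitive-conflict analysis for repertory grids, the assessment format of
personal construct psychology used in psychotherapy research and clinical
case formulation.

A repertory grid rates E significant people ("elements" — always including
the *current self* and the *ideal self*) on C bipolar personal constructs
elicited in the patient's own words (e.g. "shy–sociable",
"depressed–happy"), on a symmetric 7-point Likert scale. From that single
integer matrix this package computes the structures a dilemma-focused case
formulation is built on:

- **Construct classification.** With self rating `s_c` and ideal rating
  `i_c` on construct `c` (midpoint `m`): *dilemmatic* iff `i_c = m`;
  otherwise *congruent* iff `|s_c − i_c| ≤ 1` (no change wished),
  *discrepant* iff `|s_c − i_c| ≥ 4` (a desired change), else *neutral*.
  The gap bands are parameters.
- **Implicative dilemmas.** For each congruent construct `c` and
  discrepant construct `d`, orient each rating row so that its reference
  pole (ideal's pole for `c`, self's pole for `d`) lies at the low end of
  the scale, and compute the Pearson correlation `r` of the two oriented
  rows. The pair is an implicative dilemma iff `r > 0.35` (strict): the
  desired change on `d` would drag the valued pole of `c` along with it.
- **Prototypical figures.** The significant others whose ratings
  exemplify each side of a dilemma ("generous but depressed" people vs
  "happy but selfish" people), and, for dilemmatic constructs, the others
  at the most extreme scores the rater actually used on each side.
- **Grid indices.** Normalized self–ideal discrepancy, self isolation and
  adequacy of others (city-block profile distances), and polarization
  (percent of ratings at the scale extremes).
- **Pre/post comparison.** For each dilemma in a pre-treatment grid,
  whether it is resolved in a post grid and through which pathway
  (reduced self–ideal discrepancy, or weakened pair association).
- **Synthetic grids.** A generator that plants congruent–discrepant pairs
  with a controlled latent correlation, null pairs, and dilemmatic
  constructs, so every detector is testable without patient data.

## Worked example

```python
from gridconflict import DilemmaAnalysis, make_grid

grid = make_grid(
    ["Self", "Ideal", "Mother", "Father", "Friend"], "Self", "Ideal",
    [("generous", "selfish"), ("depressed", "happy")],
    [[2, 1, 2, 6, 5],    # generous–selfish: self 2, ideal 1 -> congruent
     [2, 7, 1, 6, 6]],   # depressed–happy: self 2, ideal 7 -> discrepant
)
print(DilemmaAnalysis(grid).fit().summary())
```

```text
Repertory grid conflict analysis
========================================
Elements:   5 (3 significant others)
Constructs: 2
Scale:      1-7 (midpoint 4)

Construct classification:
 construct left_pole right_pole  self  ideal  gap   category
         0  generous    selfish     2      1    1  congruent
         1 depressed      happy     2      7    5 discrepant

Implicative dilemmas (r > 0.35): 1
 congruent  discrepant  oriented_r  ci95_low  ci95_high     keep   avoid   present desired
         0           1       0.367    -0.762      0.944 generous selfish depressed   happy

Indices:
  self-ideal discrepancy: 0.500
  self isolation:         0.444
  adequacy of others:     0.500
  polarization:           30.0%
```

Read: the person sees themself as generous (and wants to stay so) and as
depressed (and wants to become happy), but across the people in their
grid, generosity and depression go together (r = 0.367 > 0.35) — becoming
happy implicitly threatens becoming selfish. The prototypical figures
make the two positions concrete: Mother is rated generous-and-depressed
(the current position), Father and Friend happy-but-selfish (the
implication of change).

The same pipeline runs from the shell:

```bash
gridconflict analyze patient.grid                 # JSON results document
gridconflict analyze patient.grid --format text   # case-formulation report
gridconflict simulate --others 13 --dilemma-r 0.8 --seed 7 -o sim.grid
gridconflict report results.json
```

The grid file dialect (TAB-delimited, `SELF:`/`IDEAL:` header prefixes)
and the JSON results schema are documented in `gridconflict.io`; the
schema ships at `src/gridconflict/schemas/results.schema.json`.

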