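# Methods

## The staging model

The package stages one ovary at a time from coded histology. The model of
the underlying biology is deliberately simple and deterministic:

* **Before the first ovulation**, the final wave of antral follicle growth
  advances one diameter class per day over the last five pre-ovulatory
  days. The most advanced *healthy* follicle class therefore indexes the
  days remaining to ovulation and maps to scores −5 … −1 (atretic
  follicles are excluded; an ovary with only atretic antral follicles
  falls back to SF with a warning). The score of a non-ovulating animal
  is a maturation stage, not a prediction: whether and when ovulation
  follows also depends on the hypothalamic-pituitary axis, which is
  outside this model.
* **After the first ovulation**, the corpus luteum matures on a fixed
  4-day program (day 1 non-luteinized with rupture site; day 2 partially
  luteinized with abundant mitoses and a marked vascular pattern; days 3–4
  fully luteinized, discriminated by the companion follicle class and, in
  the mouse, by the day-3 fibrous center and the day-4 apoptosis
  landmark), while ovulated oocytes transit the oviduct on a parallel
  clock (ampulla COCs on day 1, nude isthmus oocytes on day 2, utero-tubal
  junction/uterine on day 3 in the mouse, absent thereafter). Each
  completed cycle demotes the previous CL generation, recognizable by an
  increasing stromal-to-steroidogenic cell ratio; the rat retains two
  regressing generations, the mouse at most one.

The score of an ovulating animal is `4·g + d` — days since ovulation,
counting the ovulation day as day 1 — and the first-ovulation age is
`age − score + 1`. The package also ships a literal decision-tree
traversal (`score_via_flowchart`) with hard-coded leaf scores; the test
suite and the acceptance script verify leaf by leaf that it agrees with
the closed form.

## CL dating: priority and conflicts

When recorded features disagree, dating resolves them in a fixed priority
order: (1) oocyte position, (2) the apoptosis landmark, (3) luteinization
and mitoses, (4) rupture site / fibrous center / vascular pattern, (5)
companion follicle class. Candidate day sets are intersected in that
order; a signal that would empty the intersection is recorded as a
conflict, the best-supported (earliest remaining, i.e. minimum elapsed)
day is still reported, and the observation is flagged `inconsistent` and
never dated. This covers both outright contradictions (a non-luteinized
CL with abundant apoptosis) and the case the staging rules do not
adjudicate, a companion follicle class more than one day away from the CL
cytology (e.g. day-2 cytology with preovulatory follicles present).

Two deliberate conventions: `oocyte_location = none` is treated as
uninformative rather than as evidence for days 3–4, because a negative
oviduct finding is fragile (sectioning may simply miss the oocytes); and
unrecorded feature fields (`None`) are skipped rather than defaulted,
since a reader notes the discriminating features of the stage at hand,
not every field of every CL.

## Censoring

A mouse ovary showing more regressive material than one cycle can retain
(two-cycle-old remnants, or more regressing generations than the species
cap) is *censored*: the engine returns the ceiling score +8 with no
first-ovulation estimate, so cohort tables can report "at least 8 days
since ovulation" instead of silently mis-dating. The rat, whose
regressing CL stay recognizable for three cycles, supports scores to +12.

## Species parameters

All species-specific knowledge lives in one YAML per species
(`data/rat.yaml`, `data/mouse.yaml`): follicle diameter edges, the
class→score map, cycle length (4 days), the per-day CL feature schedule
for each generation, the companion follicle classes and the oocyte
schedule. Validation enforces contiguous ordered diameter intervals, a
class→score map that is non-decreasing overall and strictly increasing
over the antral classes, and the ceiling identity
`max_score = 4·max_regressing_generations + 4` (rat 12, mouse 8).

Two edges of the parameterization deserve flagging:

* **Rat diameter edges.** Only the rat small-follicle threshold
  (< 275 μm) is established; the F1–F5 diameter edges in `rat.yaml` are
  placeholders so that the diameter-classification plumbing works, and are
  marked non-normative in the file. Rat observations should carry the
  follicle class directly; replace the edges with laboratory-calibrated
  values before classifying raw rat diameters.
* **Rat SF score.** The published class→score mapping collapses six rat
  classes onto five scores; SF ties with F1 at −5 and the result carries
  an explicit "below F1" evidence note.

## The simulator

`simulate_cohort` draws, per animal, a VO age and a VO→FO lag from
truncated normal distributions rounded to integer postnatal days (daily
observation is the native resolution; truncation at PND-25 and at lag 0),
a per-cycle length sequence, and a sacrifice age (fixed PND or a uniform
integer offset from VO or FO). Defaults mirror the validation cohort
structure: mouse VO 31.8 ± 1.8 PND and lag 6.8 ± 2.3 days, rat VO
33.2 ± 0.9 and lag 0.8 ± 0.7, 4-day cycles. All draws flow from one
`numpy` generator seeded with the single config seed.

`render_observation` maps ground truth deterministically onto the coded
histology: day −k before FO renders the class scoring −k; day e ≥ 0 after
FO renders the scheduled current-CL features, one feature set per
regressing generation, the companion class and the oocyte position.
Mouse elapsed days 8–11 render an unidentifiable two-cycle-old remnant,
which the scorer censors; elapsed times beyond any recognizable histology
(rat ≥ 12, mouse ≥ 12 days) raise, as does nothing meaningful existing
to render. Optional uneven 5-day mouse cycles insert the extra day in
diestrus, so the rendered CL day — and hence the score — undercounts true
elapsed time by exactly the accumulated extra diestrus days: the score
remains a minimum elapsed time, and the estimated FO age is never earlier
than the truth.

What the simulator does *not* emulate: reader disagreement or
misclassification noise, partial/missing feature recording, atresia
dynamics, endocrine mechanism (LH surges), litter effects, or any
follicle-growth difference between prepubertal and adult cycles. Passing
round-trip tests therefore demonstrate the internal consistency of the
rules and the exactness of the retrodating arithmetic under the model's
own schedules — not robustness of the method to real histological
ambiguity.

## Cohort statistics

Summaries report mean ± SD (SD with `ddof=1`) and two-sided Student-t
confidence intervals with `df = n − 1` (cohorts under 30 animals are the
norm), via `scipy.stats.t`; the VO–FO association is the squared Pearson
correlation with the two-sided p-value from `scipy.stats.pearsonr`.
Censored, prepubertal and inconsistent animals are excluded from FO
statistics with a logged count, but censored animals still count toward
the reported ovulating proportion (they did ovulate). Display rounding is
one decimal; internal values keep full precision. Under the simulator's
independent-lag model the population R² equals
`Var(VO) / (Var(VO) + Var(lag))`; the test suite checks simulated cohorts
against this analytic value within Monte-Carlo error (se(r²) ≈
2·r·(1−r²)/√n).

Of the published follicle-diameter confidence intervals, only two bounds
(the proestrus lower bound 428.2 μm and the metestrus upper bound
338.0 μm) recompute exactly from the printed mean/SD/n under this t
method; the remaining bounds differ by 0.1–0.5 μm and are therefore not
used as reference values.

## Problem sizes and numerical choices

The validation suite enumerates the datable windows exhaustively (they
are small: ≤ 17 elapsed-day states per species) and uses 1,000-animal
simulated cohorts for parameter-recovery checks — large enough that the
elapsed-time mean is pinned to ±3 standard errors (≈ 0.2 days) and r² to
a few hundredths, while the whole suite runs in seconds. Ages are integer
PNDs throughout (animals are killed in a fixed morning window, so sub-day
timing is out of model). Tie-breaking in CL dating is deterministic
(earliest remaining day); degenerate inputs (zero SD, all-atretic
ovaries, empty tables) are handled explicitly rather than propagated.

## Known limitations

* The method's own blind spots carry over: scores cannot predict a future
  first ovulation for negative-scored animals, and in mice nothing beyond
  +8 is datable.
* Rat cycles are modelled as strictly 4 days; uneven rat cycles are not
  modelled (the minimum-elapsed semantics is implemented for the mouse,
  where uneven 4–5 day cycles are common).
* The CL feature schedules encode one canonical feature set per
  (generation, day); real slides show within-day variability the
  simulator does not reproduce.
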