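# pubscore

Staging of peripubertal ovarian maturation and retrospective dating of the
first ovulation in laboratory rats and mice, from coded histological
observations.

## The problem

In female rodents the external signs of puberty — vaginal opening (VO) and
first vaginal estrus — are estrogen-driven and only indirectly related to
the event that actually completes puberty, the **first ovulation (FO)**.
In rats the two are nearly simultaneous; in mice the first ovulation
follows VO by about a week, with substantial variability, and the two can
be uncoupled in both species under experimental manipulation. Plain
ovarian histology answers only the binary question "has this animal
ovulated?". This package implements a rule-based maturation score that
turns one ovary section's worth of coded observations into

* a **stage** for non-ovulating animals, read off the most advanced
  healthy antral follicle class, and
* a **retrospective date of the first ovulation** for ovulating animals,
  read off the maturational and regressive state of the corpora lutea (CL).

## The score

Antral follicle classes are defined by diameter (mouse: SF < 250 μm,
F1 250–300, F2 301–350, F3 351–400, F4 > 400; rat: SF < 275 μm and classes
F1–F5). Non-ovulating animals score **−5 … −1** by their most advanced
healthy follicle class. Ovulating animals score

```
score = 4·g + d        (d = current-cycle CL day 1…4, g = regressing CL generations)
```

which equals the number of days since the first ovulation, counting the
ovulation day as day 1. The current CL is dated by its cytology
(luteinization, mitoses, apoptosis, vascular pattern, rupture site,
fibrous center), the position of ovulated oocytes along the oviduct, and
the companion follicle class; regressing generations are recognized by
their increasing stromal-to-steroidogenic cell ratio. The first-ovulation
age then follows from

```
age at first ovulation = age − score + 1
```

Rat scores reach +12 (regressing CL stay recognizable for three cycles);
mouse scores stop at **+8** because mouse CL are eliminated within one
cycle of regression — a mouse ovary showing older remnants is *censored*:
its +8 is a minimum elapsed time since ovulation, never a date. There is
no score 0; the scale jumps −1 → +1 across ovulation.

## Worked example

The bundled example table contains a rat killed at PND-40 whose ovary
shows two CL generations — the current one with metestrus features
(partially luteinized cells, abundant mitoses, marked vascular pattern) —
plus nude oocytes in the oviductal isthmus and class F3 follicles:

```
$ pubscore score --species rat \
    --in src/pubscore/data/examples/rat_example.csv --out scored.csv
scored 3 animal(s): prepubertal=1, ovulating=2
```

`scored.csv` then holds, for that animal,

```
animal_id,species,age_pnd,vo_age_pnd,score,status,estimated_fo_age_pnd,...
rat-metestrus-2nd-cycle,rat,40,33,6,ovulating,35,...
```

i.e. the isthmus oocytes and metestrus cytology date the current CL to
day 2, the regressing generation adds 4, the score is **+6**, and the
first ovulation is dated to PND-35 (40 − 6 + 1). A final `evidence`
column lists every rule that fired.

The full pipeline on synthetic data:

```
$ pubscore simulate --config cohort.yaml --out-prefix sim     # ground truth + rendered histology
$ pubscore score --species mouse --in sim_observations.csv --out scored.csv
$ pubscore summarize --in scored.csv --out summary.csv --plot vo_fo.png
n = 893 ovulating (107 excluded; 100% ovulating)
VO age (PND): 31.8 ± 1.8  95% CI (31.7–31.9)
FO age (PND): 38.6 ± 2.8  95% CI (38.4–38.8)
Time elapsed VO→FO (days): 6.8 ± 2.3  95% CI (6.6–6.9)
R² (VO vs FO) = 0.36 (p = 3.6e-87)
```

where `cohort.yaml` described 1,000 mice (VO ~ 31.8 ± 1.8 PND, VO→FO lag
~ 6.8 ± 2.3 days, 4-day cycles, sacrifice 0–8 days after FO, seed 1); the
107 excluded animals were sacrificed past the +8 window and censored.
Summaries report mean ± SD with Student-t confidence intervals (cohorts
are small in real designs) and the squared Pearson correlation between VO
age and estimated FO age.

## Observation format

One CSV row per animal: `animal_id, species, age_pnd, vo_age_pnd,
follicle_class` (or `follicle_diameters_um`/`follicle_health`,
`;`-separated), `cl_generations`, `oocyte_location`. CL generations are
`|`-separated `key=value` groups, e.g.
`gen=current,lut=partial,mit=abundant,vasc=1|gen=r1,lut=full,apo=abundant,grade=1`;
omitted keys mean "not recorded". See `pubscore/io.py` for the full key
table and `pubscore/data/*.yaml` for the species parameter schema (the
rat diameter edges there are placeholders — rat observations should carry
the follicle class directly; see `docs/methods.md`).

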