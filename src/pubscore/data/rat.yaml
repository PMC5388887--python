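# Rat species parameters.
#
# Follicle class diameter edges above 275 um are NON-NORMATIVE placeholders
# (the published rat classes are defined only as "small follicles < 275 um"
# plus F1..F5 without printed edges); supply the follicle class directly, or
# replace these edges with laboratory-calibrated values before classifying
# raw rat diameters.
species: rat
cycle_length_days: 4
max_regressing_generations: 2
max_score: 12
follicle_bounds:
  - {class: SF, max_um: 275}
  - {class: F1, max_um: 320}
  - {class: F2, max_um: 365}
  - {class: F3, max_um: 410}
  - {class: F4, max_um: 455}
  - {class: F5, max_um: null}
prepubertal_score_map:
  # SF ties with F1 at -5: the published class-to-score mapping collapses
  # the sub-F1 baseline onto the lowest score.
  SF: -5
  F1: -5
  F2: -4
  F3: -3
  F4: -2
  F5: -1
cl_feature_schedule:
  current:
    # day 1 (estrus): rupture site at the ovarian surface, non-luteinized
    # granulosa cells, mitotic figures.
    1: {luteinization: none, mitoses: present, apoptosis: absent,
        vascular_pattern: false, rupture_site: true, fibrous_center: false,
        stromal_ratio_grade: 0}
    # day 2 (metestrus): non-fully luteinized, marked vascular pattern,
    # abundant mitotic figures.
    2: {luteinization: partial, mitoses: abundant, apoptosis: absent,
        vascular_pattern: true, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 0}
    # day 3 (diestrus): full luteinization, full vascularization, mitoses
    # nearly absent.
    3: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: true, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 0}
    # day 4 (proestrus): as day 3; the F5 companion follicle discriminates.
    4: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: true, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 0}
  r1:
    # apoptotic burst at the proestrus-estrus transition, then structurally
    # stable with an increased stromal-to-steroidogenic ratio.
    1: {luteinization: full, mitoses: absent, apoptosis: abundant,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 1}
    2: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 1}
    3: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 1}
    4: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 1}
  r2:
    # a new apoptotic round at estrus; further increased stromal ratio.
    1: {luteinization: full, mitoses: absent, apoptosis: abundant,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 2}
    2: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 2}
    3: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 2}
    4: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 2}
companion_schedule:
  1: [F1]
  2: [F2, F3]
  3: [F4]
  4: [F5]
oocyte_schedule:
  1: ampulla_coc
  2: isthmus_nude
  3: none
  4: none
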