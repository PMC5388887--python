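# Mouse species parameters.
#
# Follicle bounds are the measured class edges of the largest healthy
# antral follicles per cycle stage (SF < 250 um; F1 250-300; F2 301-350;
# F3 351-400; F4 > 400), with the integer convention F1 closed at 300 um.
species: mouse
cycle_length_days: 4
max_regressing_generations: 1
max_score: 8
follicle_bounds:
  - {class: SF, max_um: 250}
  - {class: F1, max_um: 300}
  - {class: F2, max_um: 350}
  - {class: F3, max_um: 400}
  - {class: F4, max_um: null}
prepubertal_score_map:
  SF: -5
  F1: -4
  F2: -3
  F3: -2
  F4: -1
cl_feature_schedule:
  current:
    # day 1 (estrus): newly formed CL, non-luteinized cells.
    1: {luteinization: none, mitoses: present, apoptosis: absent,
        vascular_pattern: false, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 0}
    # day 2 (metestrus): non-fully luteinized, abundant mitotic figures,
    # prominent vascular pattern.
    2: {luteinization: partial, mitoses: abundant, apoptosis: absent,
        vascular_pattern: true, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 0}
    # day 3 (diestrus): full luteinization with a fibrous center.
    3: {luteinization: full, mitoses: absent, apoptosis: absent,
        vascular_pattern: true, rupture_site: false, fibrous_center: true,
        stromal_ratio_grade: 0}
    # day 4 (proestrus): landmark is abundant apoptotic cells (unlike the
    # rat, whose current CL stay apoptosis-free until late proestrus).
    4: {luteinization: full, mitoses: absent, apoptosis: abundant,
        vascular_pattern: true, rupture_site: false, fibrous_center: false,
        stromal_ratio_grade: 0}
  r1:
    # regressing CL shrink through the cycle and are practically demised at
    # its end.
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
    # unidentifiable third-cycle remnants: presence signals censoring, the
    # features are never used for dating.
    1: {luteinization: full, mitoses: absent, apoptosis: absent,
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
  2: [F2]
  3: [F3]
  4: [F4]
oocyte_schedule:
  1: ampulla_coc
  2: isthmus_nude
  3: uterotubal_junction
  4: none
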