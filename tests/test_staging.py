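"""Follicle classification, CL dating and regressing-generation counting."""
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pubscore import (
    Apoptosis,
    CLFeatureSet,
    FollicleClass,
    Generation,
    HealthFlag,
    Luteinization,
    Mitoses,
    OocyteLocation,
    classify_follicle,
    count_regressing_generations,
    date_current_cl,
    most_advanced_class,
)
from pubscore.species import CL_DAYS


class TestClassifyFollicle:
    @pytest.mark.parametrize(
        "diameter,expected",
        [
            (272.2, FollicleClass.F1),  # estrus mean of the largest follicles
            (323.9, FollicleClass.F2),  # metestrus mean
            (372.5, FollicleClass.F3),  # diestrus mean
            (440.5, FollicleClass.F4),  # proestrus mean
            (249.9, FollicleClass.SF),
            (250.0, FollicleClass.F1),  # F1 closed at both ends
            (300.0, FollicleClass.F1),
            (300.5, FollicleClass.F2),
            (400.0, FollicleClass.F3),
            (400.1, FollicleClass.F4),
        ],
    )
    def test_mouse_class_boundaries(self, mouse_config, diameter, expected):
        assert classify_follicle(diameter, mouse_config) is expected

    def test_rat_small_follicle_floor(self, rat_config):
        assert classify_follicle(274.9, rat_config) is FollicleClass.SF
        assert classify_follicle(275.0, rat_config) is FollicleClass.F1

    def test_rat_top_class_is_f5(self, rat_config):
        assert classify_follicle(500.0, rat_config) is FollicleClass.F5

    def test_nonpositive_diameter_rejected(self, mouse_config):
        with pytest.raises(ValueError, match="positive"):
            classify_follicle(0.0, mouse_config)

    @given(st.floats(min_value=1.0, max_value=800.0), st.floats(min_value=0.0, max_value=200.0))
    def test_monotone_in_diameter(self, d, delta):
        mouse = _MOUSE_CFG
        assert classify_follicle(d + delta, mouse) >= classify_follicle(d, mouse)


class TestMostAdvancedClass:
    def test_max_over_healthy(self, mouse_config):
        assert (
            most_advanced_class([260, 320, 410], ["healthy"] * 3, mouse_config)
            is FollicleClass.F4
        )

    def test_atretic_excluded(self, mouse_config):
        flags = [HealthFlag.HEALTHY, HealthFlag.HEALTHY, HealthFlag.ATRETIC]
        assert most_advanced_class([260, 320, 410], flags, mouse_config) is FollicleClass.F2

    def test_single_small_follicle(self, mouse_config):
        assert most_advanced_class([200], ["healthy"], mouse_config) is FollicleClass.SF

    def test_all_atretic_falls_back_to_sf_with_warning(self, mouse_config):
        with pytest.warns(UserWarning, match="atretic"):
            got = most_advanced_class([410], ["atretic"], mouse_config)
        assert got is FollicleClass.SF

    def test_empty_list_rejected(self, mouse_config):
        with pytest.raises(ValueError, match="empty"):
            most_advanced_class([], [], mouse_config)

    @given(
        st.lists(st.floats(min_value=1.0, max_value=800.0), min_size=1, max_size=8),
        st.data(),
    )
    def test_excluding_atretic_never_raises_class(self, diameters, data):
        flags = data.draw(
            st.lists(
                st.sampled_from([HealthFlag.HEALTHY, HealthFlag.ATRETIC]),
                min_size=len(diameters),
                max_size=len(diameters),
            )
        )
        all_healthy = most_advanced_class(diameters, None, _MOUSE_CFG)
        if any(f is HealthFlag.HEALTHY for f in flags):
            assert most_advanced_class(diameters, flags, _MOUSE_CFG) <= all_healthy


class TestDateCurrentCL:
    def test_rat_metestrus_signals_day2(self, rat_config):
        feats = CLFeatureSet(
            luteinization=Luteinization.PARTIAL,
            mitoses=Mitoses.ABUNDANT,
            vascular_pattern=True,
        )
        dating = date_current_cl(
            feats, FollicleClass.F3, OocyteLocation.ISTHMUS_NUDE, rat_config
        )
        assert dating.day == 2
        assert dating.consistent

    def test_mouse_apoptosis_landmark_signals_day4(self, mouse_config):
        feats = CLFeatureSet(luteinization=Luteinization.FULL, apoptosis=Apoptosis.ABUNDANT)
        dating = date_current_cl(feats, FollicleClass.F4, OocyteLocation.NONE, mouse_config)
        assert dating.day == 4
        assert dating.consistent

    def test_rat_f5_discriminates_proestrus_from_diestrus(self, rat_config):
        feats = CLFeatureSet(luteinization=Luteinization.FULL, mitoses=Mitoses.ABSENT)
        with_f5 = date_current_cl(feats, FollicleClass.F5, OocyteLocation.NONE, rat_config)
        with_f4 = date_current_cl(feats, FollicleClass.F4, OocyteLocation.NONE, rat_config)
        assert with_f5.day == 4
        assert with_f4.day == 3
        assert with_f5.consistent and with_f4.consistent

    def test_contradictory_features_reported(self, mouse_config):
        # abundant apoptosis (day 4) on a non-luteinized CL (day 1)
        feats = CLFeatureSet(luteinization=Luteinization.NONE, apoptosis=Apoptosis.ABUNDANT)
        dating = date_current_cl(feats, None, OocyteLocation.NONE, mouse_config)
        assert not dating.consistent
        assert dating.day == 4  # apoptosis landmark takes priority

    def test_companion_two_days_off_reported(self, rat_config):
        # day-2 cytology with preovulatory F5 follicles present
        feats = CLFeatureSet(luteinization=Luteinization.PARTIAL, mitoses=Mitoses.ABUNDANT)
        dating = date_current_cl(feats, FollicleClass.F5, OocyteLocation.NONE, rat_config)
        assert not dating.consistent

    def test_requires_current_generation(self, rat_config):
        feats = CLFeatureSet(luteinization=Luteinization.FULL, generation=Generation.R1)
        with pytest.raises(ValueError, match="current"):
            date_current_cl(feats, None, OocyteLocation.NONE, rat_config)

    @pytest.mark.parametrize("species_fixture", ["rat_config", "mouse_config"])
    def test_schedule_rows_recover_their_day_uniquely(self, species_fixture, request):
        """Dating restricted to the rendered schedules is a bijection onto 1-4."""
        cfg = request.getfixturevalue(species_fixture)
        recovered = []
        for day in CL_DAYS:
            feats = cfg.cl_feature_schedule[Generation.CURRENT][day]
            companion = cfg.companion_schedule[day][-1]
            dating = date_current_cl(feats, companion, cfg.oocyte_schedule[day], cfg)
            assert dating.consistent, (day, dating.conflicts)
            recovered.append(dating.day)
        assert recovered == list(CL_DAYS)


def _regressing(grade, gen):
    return CLFeatureSet(
        luteinization=Luteinization.FULL, generation=gen, stromal_ratio_grade=grade
    )


_CURRENT = CLFeatureSet(luteinization=Luteinization.PARTIAL, stromal_ratio_grade=0)


class TestCountRegressingGenerations:
    def test_rat_one_regressing(self, rat_config):
        got = count_regressing_generations([_CURRENT, _regressing(1, Generation.R1)], rat_config)
        assert (got.n_regressing, got.censored) == (1, False)

    def test_rat_two_regressing(self, rat_config):
        gens = [_CURRENT, _regressing(1, Generation.R1), _regressing(2, Generation.R2)]
        got = count_regressing_generations(gens, rat_config)
        assert (got.n_regressing, got.censored) == (2, False)

    def test_mouse_two_regressing_is_censored(self, mouse_config):
        gens = [_CURRENT, _regressing(1, Generation.R1), _regressing(2, Generation.R2)]
        got = count_regressing_generations(gens, mouse_config)
        assert got.censored

    def test_mouse_r2_remnant_alone_is_censored(self, mouse_config):
        gens = [_CURRENT, _regressing(2, Generation.R2)]
        got = count_regressing_generations(gens, mouse_config)
        assert got.censored

    def test_current_identified_by_grade_when_untagged(self, rat_config):
        # both carry the default "current" tag; the stromal ratio grades
        # disambiguate (grade 0 = current cycle)
        gens = [_CURRENT, CLFeatureSet(luteinization=Luteinization.FULL, stromal_ratio_grade=1)]
        got = count_regressing_generations(gens, rat_config)
        assert (got.n_regressing, got.censored) == (1, False)
        assert got.current is _CURRENT

    def test_ambiguous_current_rejected(self, rat_config):
        gens = [_CURRENT, CLFeatureSet(luteinization=Luteinization.FULL, stromal_ratio_grade=0)]
        with pytest.raises(ValueError, match="current"):
            count_regressing_generations(gens, rat_config)

    def test_no_cl_counts_zero(self, rat_config):
        got = count_regressing_generations([], rat_config)
        assert (got.n_regressing, got.censored, got.current) == (0, False, None)


# module-level config for hypothesis tests (fixtures cannot feed @given directly)
from pubscore import builtin_config  # noqa: E402

_MOUSE_CFG = builtin_config("mouse")
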