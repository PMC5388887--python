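import pytest
from hypothesis import HealthCheck, settings

from pubscore import (
    Apoptosis,
    CLFeatureSet,
    FollicleClass,
    Generation,
    Luteinization,
    Mitoses,
    OocyteLocation,
    OvaryObservation,
    Species,
    builtin_config,
)

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rat_config():
    return builtin_config(Species.RAT)


@pytest.fixture(scope="session")
def mouse_config():
    return builtin_config(Species.MOUSE)


def rat_metestrus_second_cycle(age_pnd=40, vo_age=33):
    """Ovulating rat: current metestrus CL + one regressing generation,
    nude oocytes at the isthmus, class F3 companion follicles."""
    return OvaryObservation(
        animal_id="rat-metestrus",
        species=Species.RAT,
        age_pnd=age_pnd,
        follicle_class=FollicleClass.F3,
        cl_generations=[
            CLFeatureSet(
                luteinization=Luteinization.PARTIAL,
                mitoses=Mitoses.ABUNDANT,
                vascular_pattern=True,
            ),
            CLFeatureSet(
                luteinization=Luteinization.FULL,
                generation=Generation.R1,
                apoptosis=Apoptosis.ABUNDANT,
                stromal_ratio_grade=1,
            ),
        ],
        oocyte_location=OocyteLocation.ISTHMUS_NUDE,
        vo_age_pnd=vo_age,
    )


def mouse_proestrus_first_cycle(age_pnd=42, vo_age=32):
    """Ovulating mouse: current CL with abundant apoptotic cells and class
    F4 companion follicles (proestrus of the first cycle)."""
    return OvaryObservation(
        animal_id="mouse-proestrus",
        species=Species.MOUSE,
        age_pnd=age_pnd,
        follicle_class=FollicleClass.F4,
        cl_generations=[
            CLFeatureSet(luteinization=Luteinization.FULL, apoptosis=Apoptosis.ABUNDANT)
        ],
        vo_age_pnd=vo_age,
    )
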