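"""Domain types for peripubertal ovarian staging.

The vocabulary here is the standard histological one: antral follicle
classes (SF, F1..F5) defined by diameter, corpus-luteum (CL) generations
(current cycle vs. one- or two-cycle-old regressing CL), per-CL cytological
features (luteinization state, mitotic and apoptotic figures, vascular
pattern, rupture site, fibrous center, stromal-to-steroidogenic cell
ratio), and the position of ovulated oocytes along the oviduct.

Feature fields on :class:`CLFeatureSet` are optional (``None`` means "not
recorded"): a slide reader typically notes the discriminating features for
the stage at hand, not every field for every CL.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Species(str, enum.Enum):
    RAT = "rat"
    MOUSE = "mouse"


class FollicleClass(enum.IntEnum):
    """Antral follicle classes, totally ordered by diameter.

    SF are small ("baseline") antral follicles below the F1 floor.
    F5 exists only in the rat; the mouse preovulatory class is F4.
    """

    SF = 0
    F1 = 1
    F2 = 2
    F3 = 3
    F4 = 4
    F5 = 5


class Luteinization(str, enum.Enum):
    NONE = "none"        # newly formed CL, non-luteinized granulosa cells
    PARTIAL = "partial"  # non-fully luteinized
    FULL = "full"        # fully luteinized cells with large cytoplasm


class Mitoses(str, enum.Enum):
    ABSENT = "absent"
    PRESENT = "present"
    ABUNDANT = "abundant"


class Apoptosis(str, enum.Enum):
    ABSENT = "absent"
    ABUNDANT = "abundant"


class Generation(str, enum.Enum):
    """CL generation identity: current cycle, or regressing (R1 = one-cycle-old,
    R2 = two-cycle-old).  In the mouse, an R2-tagged CL is an unidentifiable
    remnant and triggers censoring rather than dating."""

    CURRENT = "current"
    R1 = "r1"
    R2 = "r2"


class OocyteLocation(str, enum.Enum):
    """Position of ovulated oocytes in the oviduct — a day-resolved clock.

    Cumulus-oocyte complexes sit in the dilated ampulla on the day of
    ovulation; nude (even fragmented) oocytes reach the isthmus the next
    day; in the mouse they are found at the utero-tubal junction or in the
    uterine cavity on day 3 and are gone by proestrus.
    """

    NONE = "none"
    AMPULLA_COC = "ampulla_coc"
    ISTHMUS_NUDE = "isthmus_nude"
    UTEROTUBAL_JUNCTION = "uterotubal_junction"
    UTERINE = "uterine"


class ScoreStatus(str, enum.Enum):
    PREPUBERTAL = "prepubertal"
    OVULATING = "ovulating"
    CENSORED = "censored"
    INCONSISTENT = "inconsistent"


class HealthFlag(str, enum.Enum):
    HEALTHY = "healthy"
    ATRETIC = "atretic"


@dataclass(frozen=True)
class CLFeatureSet:
    """Cytological features of one corpus luteum (or CL generation).

    ``stromal_ratio_grade`` grades the stromal-to-steroidogenic cell ratio:
    0 = current cycle, 1 = one-cycle-old, 2 = two-cycle-old.
    """

    luteinization: Luteinization
    generation: Generation = Generation.CURRENT
    mitoses: Mitoses | None = None
    apoptosis: Apoptosis | None = None
    vascular_pattern: bool | None = None
    rupture_site: bool | None = None
    fibrous_center: bool | None = None
    stromal_ratio_grade: int | None = None

    def validate(self) -> None:
        if self.stromal_ratio_grade is not None and self.stromal_ratio_grade not in (0, 1, 2):
            raise ValueError(
                f"stromal_ratio_grade must be 0, 1 or 2, got {self.stromal_ratio_grade}"
            )


@dataclass
class OvaryObservation:
    """One animal's coded ovarian histology at sacrifice.

    Either ``follicle_class`` (the most advanced healthy antral follicle
    class, read directly) or raw ``follicle_diameters_um`` with per-follicle
    ``follicle_health`` flags must be supplied.  An empty ``cl_generations``
    list means the animal has not yet ovulated.
    """

    animal_id: str
    species: Species
    age_pnd: int
    follicle_class: FollicleClass | None = None
    follicle_diameters_um: list[float] | None = None
    follicle_health: list[HealthFlag] | None = None
    cl_generations: list[CLFeatureSet] = field(default_factory=list)
    oocyte_location: OocyteLocation = OocyteLocation.NONE
    vo_age_pnd: int | None = None

    def validate(self) -> None:
        if self.age_pnd < 1:
            raise ValueError(f"age_pnd must be >= 1 (PND-1 is the day of birth), got {self.age_pnd}")
        if self.follicle_class is None and self.follicle_diameters_um is None:
            raise ValueError("either follicle_class or follicle_diameters_um is required")
        if self.species is Species.MOUSE and self.follicle_class is FollicleClass.F5:
            raise ValueError("follicle class F5 exists only in the rat")
        if self.follicle_diameters_um is not None:
            if self.follicle_health is not None and len(self.follicle_health) != len(
                self.follicle_diameters_um
            ):
                raise ValueError("follicle_health and follicle_diameters_um differ in length")
            if any(d <= 0 for d in self.follicle_diameters_um):
                raise ValueError("follicle diameters must be positive")
        for g in self.cl_generations:
            g.validate()
        if self.species is Species.RAT and self.oocyte_location in (
            OocyteLocation.UTEROTUBAL_JUNCTION,
            OocyteLocation.UTERINE,
        ):
            raise ValueError(
                "oocytes at the utero-tubal junction / uterine cavity are a mouse feature"
            )
        if self.vo_age_pnd is not None and self.vo_age_pnd < 1:
            raise ValueError("vo_age_pnd must be >= 1")


@dataclass
class PubScoreResult:
    """Outcome of scoring one ovary.

    ``score`` is the integer maturation score: −5..−1 for pre-ovulatory
    follicle stages, +1..+max for days elapsed since first ovulation
    (there is no score 0 — the scale jumps −1 → +1 across ovulation).
    ``estimated_fo_age_pnd`` is present exactly when status is
    ``ovulating``; a censored mouse keeps score +8 as a *minimum* elapsed
    time but is never dated.
    """

    animal_id: str
    species: Species
    age_pnd: int
    score: int
    status: ScoreStatus
    estimated_fo_age_pnd: int | None = None
    evidence: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.score == 0:
            raise ValueError("score 0 does not exist on the scale")
        if (self.estimated_fo_age_pnd is not None) != (self.status is ScoreStatus.OVULATING):
            raise ValueError("estimated_fo_age_pnd present iff status is ovulating")
        if self.score >= 1 and self.status is ScoreStatus.PREPUBERTAL:
            raise ValueError("positive score is incompatible with prepubertal status")
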