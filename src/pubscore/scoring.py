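"""Pub-score assignment and retrospective dating of the first ovulation.

The score encodes ovarian maturation on one integer scale:

* non-ovulating animals: −5 (small antral follicles only) to −1 (the
  preovulatory class present), read off the most advanced *healthy*
  antral follicle class;
* ovulating animals: +1 to the species maximum (+12 rat, +8 mouse),
  computed as ``4·g + d`` where ``g`` is the number of regressing CL
  generations and ``d`` the day (1–4) of the current-cycle CL — i.e. the
  number of days elapsed since the first ovulation, counting the day of
  ovulation as day 1.

There is no score 0: the scale jumps from −1 to +1 across ovulation.
For an ovulating animal the age at first ovulation follows as

    age at first ovulation = age − score + 1.

A mouse whose ovary shows more regressing material than one cycle can
retain is *censored*: it keeps the ceiling score +8 as a minimum elapsed
time since ovulation but is never assigned a first-ovulation age.
"""
from __future__ import annotations

from .species import SpeciesConfig
from .staging import count_regressing_generations, date_current_cl, most_advanced_class
from .types import (
    FollicleClass,
    OvaryObservation,
    PubScoreResult,
    ScoreStatus,
    Species,
)


def estimate_first_ovulation_age(age_pnd: int, score: int) -> int:
    """Retrospective first-ovulation age: ``age − score + 1`` (score ≥ +1).

    Negative scores mean the animal has not ovulated; a censored score
    carries no date.  Both refuse here.
    """
    if score < 1:
        raise ValueError(
            "retrospective dating needs a positive score: the animal has not yet "
            "ovulated or is outside the dating window"
        )
    return age_pnd - score + 1


def _resolve_follicle_class(obs: OvaryObservation, config: SpeciesConfig) -> FollicleClass:
    if obs.follicle_class is not None:
        return obs.follicle_class
    return most_advanced_class(obs.follicle_diameters_um, obs.follicle_health, config)


def assign_pubscore(obs: OvaryObservation, config: SpeciesConfig) -> PubScoreResult:
    """Score one ovary observation against its species configuration.

    Returns a :class:`~pubscore.types.PubScoreResult` whose ``evidence``
    lists every rule that fired, for auditability.
    """
    if obs.species is not config.species:
        raise ValueError(
            f"observation species {obs.species.value!r} does not match config "
            f"{config.species.value!r}"
        )
    obs.validate()
    fclass = _resolve_follicle_class(obs, config)
    evidence: list[str] = [f"most advanced healthy follicle class: {fclass.name}"]

    if not obs.cl_generations:
        score = config.prepubertal_score_map[fclass]
        if fclass is FollicleClass.SF:
            evidence.append("below F1: reported with the lowest pre-ovulatory score")
        evidence.append(f"no corpora lutea -> pre-ovulatory score {score}")
        return PubScoreResult(
            animal_id=obs.animal_id,
            species=obs.species,
            age_pnd=obs.age_pnd,
            score=score,
            status=ScoreStatus.PREPUBERTAL,
            evidence=evidence,
        )

    gen_count = count_regressing_generations(obs.cl_generations, config)
    evidence.extend(gen_count.evidence)
    if gen_count.censored:
        evidence.append(
            f"score {config.max_score} is a minimum elapsed time since ovulation; "
            "first ovulation not datable"
        )
        return PubScoreResult(
            animal_id=obs.animal_id,
            species=obs.species,
            age_pnd=obs.age_pnd,
            score=config.max_score,
            status=ScoreStatus.CENSORED,
            evidence=evidence,
        )

    dating = date_current_cl(gen_count.current, fclass, obs.oocyte_location, config)
    evidence.extend(dating.evidence)
    score = 4 * gen_count.n_regressing + dating.day
    if not dating.consistent:
        evidence.extend(f"CONFLICT: {c}" for c in dating.conflicts)
        evidence.append(f"best-supported score {score}; observation inconsistent")
        return PubScoreResult(
            animal_id=obs.animal_id,
            species=obs.species,
            age_pnd=obs.age_pnd,
            score=score,
            status=ScoreStatus.INCONSISTENT,
            evidence=evidence,
        )
    evidence.append(
        f"current CL day {dating.day} + 4 x {gen_count.n_regressing} regressing "
        f"generation(s) -> score +{score}"
    )
    fo_age = estimate_first_ovulation_age(obs.age_pnd, score)
    evidence.append(f"first ovulation dated to PND-{fo_age}")
    return PubScoreResult(
        animal_id=obs.animal_id,
        species=obs.species,
        age_pnd=obs.age_pnd,
        score=score,
        status=ScoreStatus.OVULATING,
        estimated_fo_age_pnd=fo_age,
        evidence=evidence,
    )


# --------------------------------------------------------------------- #
# Literal flowchart traversal.
#
# assign_pubscore computes positive scores with the closed form 4g + d.
# The published assignment procedure is a decision tree; this function
# walks that tree leaf by leaf with literal score constants and exists as
# an independent route for cross-checking the closed form.

_RAT_PREPUBERTAL = {
    FollicleClass.SF: -5,
    FollicleClass.F1: -5,
    FollicleClass.F2: -4,
    FollicleClass.F3: -3,
    FollicleClass.F4: -2,
    FollicleClass.F5: -1,
}
_MOUSE_PREPUBERTAL = {
    FollicleClass.SF: -5,
    FollicleClass.F1: -4,
    FollicleClass.F2: -3,
    FollicleClass.F3: -2,
    FollicleClass.F4: -1,
}
# leaves of the ovulating branch: (regressing generations, CL day) -> score
_FLOWCHART_LEAVES = {
    (0, 1): 1, (0, 2): 2, (0, 3): 3, (0, 4): 4,
    (1, 1): 5, (1, 2): 6, (1, 3): 7, (1, 4): 8,
    # rat only: reiteration with a second regressing generation
    (2, 1): 9, (2, 2): 10, (2, 3): 11, (2, 4): 12,
}


def score_via_flowchart(obs: OvaryObservation, config: SpeciesConfig) -> tuple[int, ScoreStatus]:
    """Walk the species decision tree and return (score, status).

    Independent of the closed form in :func:`assign_pubscore`; used as a
    cross-check in the test-suite and validation runs.
    """
    if obs.species is not config.species:
        raise ValueError("observation species does not match config")
    obs.validate()
    fclass = _resolve_follicle_class(obs, config)
    if not obs.cl_generations:
        table = _RAT_PREPUBERTAL if obs.species is Species.RAT else _MOUSE_PREPUBERTAL
        return table[fclass], ScoreStatus.PREPUBERTAL
    gen_count = count_regressing_generations(obs.cl_generations, config)
    if gen_count.censored:
        ceiling = 12 if obs.species is Species.RAT else 8
        return ceiling, ScoreStatus.CENSORED
    dating = date_current_cl(gen_count.current, fclass, obs.oocyte_location, config)
    status = ScoreStatus.OVULATING if dating.consistent else ScoreStatus.INCONSISTENT
    return _FLOWCHART_LEAVES[(gen_count.n_regressing, dating.day)], status
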