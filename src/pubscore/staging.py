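"""Follicle classification and corpus-luteum dating.

CL dating resolves the day since ovulation (1-4) from whichever
discriminating features were recorded, in a fixed priority order:

1. oocyte position in the oviduct (a positive finding is day-specific;
   "none" means oocytes were not found and is treated as uninformative,
   since absence is the expected state on the later cycle days and a
   fragile negative otherwise),
2. the apoptosis landmark (abundant apoptotic cells mark the day-4 CL in
   the mouse; rat current-cycle CL stay apoptosis-free),
3. luteinization state and mitotic figures,
4. accessory structural features (rupture site, fibrous center, vascular
   pattern),
5. the companion follicle class (discriminates diestrus from proestrus:
   F5 vs F4 in the rat).

Signals are intersected in that order against the species feature
schedule; a signal that would empty the intersection is recorded as a
conflict and the best-supported day (earliest remaining, i.e. the minimum
elapsed time) is still reported so the caller can flag the observation as
inconsistent rather than fail.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .species import CL_DAYS, SpeciesConfig
from .types import (
    CLFeatureSet,
    FollicleClass,
    Generation,
    HealthFlag,
    OocyteLocation,
)


def classify_follicle(diameter_um: float, config: SpeciesConfig) -> FollicleClass:
    """Classify one antral follicle by diameter (μm).

    The class intervals are contiguous: SF spans (0, edge0) open at the
    top, the first antral class [edge0, edge1] is closed at both ends, and
    each later class spans (previous edge, own edge]; the top class is
    unbounded.  A monotone step function of diameter.
    """
    if diameter_um <= 0:
        raise ValueError(f"follicle diameter must be positive, got {diameter_um}")
    bounds = config.follicle_bounds
    if diameter_um < bounds[0].max_um:
        return bounds[0].label
    for b in bounds[1:-1]:
        if diameter_um <= b.max_um:
            return b.label
    return bounds[-1].label


def most_advanced_class(
    diameters_um: Sequence[float],
    health_flags: Sequence[HealthFlag | str] | None,
    config: SpeciesConfig,
) -> FollicleClass:
    """Most advanced class among *healthy* antral follicles.

    Atretic follicles are excluded from staging.  If every follicle is
    atretic the stage falls back to SF with a warning.
    """
    if not len(diameters_um):
        raise ValueError("empty diameter list")
    if health_flags is None:
        health_flags = [HealthFlag.HEALTHY] * len(diameters_um)
    if len(health_flags) != len(diameters_um):
        raise ValueError("diameters and health flags differ in length")
    healthy = [
        d
        for d, h in zip(diameters_um, health_flags)
        if HealthFlag(h) is HealthFlag.HEALTHY
    ]
    if not healthy:
        warnings.warn(
            "all follicles atretic; staging falls back to SF", stacklevel=2
        )
        return FollicleClass.SF
    return max(classify_follicle(d, config) for d in healthy)


@dataclass
class CLDating:
    """Dated current-cycle CL: the day since ovulation plus the audit trail."""

    day: int
    evidence: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.conflicts


def _ordered_signals(
    config: SpeciesConfig,
    features: CLFeatureSet,
    companion_class: FollicleClass | None,
    oocytes: OocyteLocation,
):
    """Yield (signal name, candidate day set) in dating priority order."""
    current = config.cl_feature_schedule[Generation.CURRENT]
    if oocytes is not OocyteLocation.NONE:
        yield (
            f"oocytes:{oocytes.value}",
            {d for d in CL_DAYS if config.oocyte_schedule[d] is oocytes},
        )
    if features.apoptosis is not None:
        yield (
            f"apoptosis:{features.apoptosis.value}",
            {d for d in CL_DAYS if current[d].apoptosis is features.apoptosis},
        )
    yield (
        f"luteinization:{features.luteinization.value}",
        {d for d in CL_DAYS if current[d].luteinization is features.luteinization},
    )
    if features.mitoses is not None:
        yield (
            f"mitoses:{features.mitoses.value}",
            {d for d in CL_DAYS if current[d].mitoses is features.mitoses},
        )
    for name in ("rupture_site", "fibrous_center", "vascular_pattern"):
        value = getattr(features, name)
        if value is not None:
            yield (
                f"{name}:{value}",
                {d for d in CL_DAYS if getattr(current[d], name) is value},
            )
    if companion_class is not None and companion_class is not FollicleClass.SF:
        yield (
            f"companion_follicle:{companion_class.name}",
            {d for d in CL_DAYS if companion_class in config.companion_schedule[d]},
        )


def date_current_cl(
    features: CLFeatureSet,
    companion_class: FollicleClass | None,
    oocytes: OocyteLocation,
    config: SpeciesConfig,
) -> CLDating:
    """Date the current-cycle CL in days since ovulation (1-4)."""
    if features.generation is not Generation.CURRENT:
        raise ValueError("date_current_cl applies to the current-cycle CL only")
    remaining = set(CL_DAYS)
    evidence: list[str] = []
    conflicts: list[str] = []
    informative = False
    for name, candidates in _ordered_signals(config, features, companion_class, oocytes):
        if candidates == set(CL_DAYS):
            continue  # matches every day: no information
        if not candidates:
            conflicts.append(f"{name} matches no day of the schedule")
            continue
        narrowed = remaining & candidates
        if narrowed:
            remaining = narrowed
            informative = True
            evidence.append(f"{name} -> day(s) {sorted(candidates)}")
        else:
            conflicts.append(
                f"{name} -> day(s) {sorted(candidates)} contradicts day(s) {sorted(remaining)}"
            )
    if not informative:
        conflicts.append("no discriminating feature recorded")
    day = min(remaining)
    if len(remaining) > 1 and not conflicts:
        evidence.append(
            f"days {sorted(remaining)} undiscriminated; earliest (minimum elapsed) reported"
        )
    return CLDating(day=day, evidence=evidence, conflicts=conflicts)


@dataclass
class GenerationCount:
    """Regressing-generation count for one ovary."""

    n_regressing: int
    censored: bool
    current: CLFeatureSet | None
    evidence: list[str] = field(default_factory=list)


def count_regressing_generations(
    cl_generations: Sequence[CLFeatureSet], config: SpeciesConfig
) -> GenerationCount:
    """Count regressing CL generations, capped at the species maximum.

    Generation identity is taken from the ``generation`` tag; where tags
    are ambiguous the stromal-to-steroidogenic ratio grade orders the
    generations (grade 0 = current).  More regressing generations than the
    species supports — including any two-cycle-old remnant in the mouse —
    signals censoring: elapsed time exceeds the datable window.
    """
    if not cl_generations:
        return GenerationCount(0, False, None, ["no corpora lutea"])
    gens = list(cl_generations)
    tagged_current = [g for g in gens if g.generation is Generation.CURRENT]
    if len(tagged_current) > 1:
        # fall back to ratio grade if it disambiguates
        graded = [g for g in tagged_current if g.stromal_ratio_grade == 0]
        if len(graded) == 1:
            tagged_current = graded
        else:
            raise ValueError("more than one CL generation tagged as current cycle")
    if not tagged_current:
        by_grade = [g for g in gens if g.stromal_ratio_grade == 0]
        if len(by_grade) == 1:
            tagged_current = by_grade
        else:
            raise ValueError("no CL generation identifiable as the current cycle")
    current = tagged_current[0]
    regressing = [g for g in gens if g is not current]
    cap = config.max_regressing_generations
    censored = len(regressing) > cap
    if not censored:
        # a generation older than the species can retain (e.g. an R2-tagged
        # remnant in the mouse) also exceeds the window
        oldest_idx = {Generation.CURRENT: 0, Generation.R1: 1, Generation.R2: 2}
        censored = any(oldest_idx[g.generation] > cap for g in regressing)
    evidence = [f"{len(regressing)} regressing CL generation(s)"]
    if censored:
        evidence.append(
            f"beyond the {config.species.value} window of {cap} regressing generation(s): censored"
        )
    return GenerationCount(min(len(regressing), cap), censored, current, evidence)
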