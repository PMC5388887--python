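"""Synthetic peripubertal cohorts and their rendered histology.

``simulate_cohort`` draws per-animal ground truth (age at vaginal opening,
VO→first-ovulation lag, per-cycle lengths, sacrifice age);
``render_observation`` maps that ground truth deterministically onto the
coded histology a slide reader would record at sacrifice — the most
advanced follicle class before the first ovulation, and afterwards the
current-cycle CL day, the regressing generations with their feature sets,
and the oviductal oocyte position.  The round trip
``render → score → retrodate`` recovers the true first-ovulation age
exactly for every animal with 4-day cycles inside the species dating
window; this is the headline validation property of the scorer.

VO ages and lags are truncated normals rounded to integer postnatal days
(observations are daily).  Mouse cohorts may include uneven 5-day cycles
(``p_long_cycle``), with the extra day spent in diestrus; the rendered
score then under-counts elapsed time by at most the accumulated extra
diestrus days, i.e. it remains a minimum elapsed time since ovulation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .species import SpeciesConfig
from .types import CLFeatureSet, FollicleClass, Generation, OocyteLocation, OvaryObservation, Species

#: CL day rendered on each day of a long (5-day) cycle: the extra day is a
#: second diestrus day.
_LONG_CYCLE_DAYS = (1, 2, 3, 3, 4)
_MAX_CYCLES = 8


@dataclass
class SacrificeRule:
    """When animals are killed: at a fixed PND, or at a (uniform integer)
    offset from VO or from the first ovulation."""

    kind: str  # "fixed" | "offset_vo" | "offset_fo"
    age_pnd: int | None = None
    offset_min: int = 0
    offset_max: int = 0

    def validate(self) -> None:
        if self.kind not in ("fixed", "offset_vo", "offset_fo"):
            raise ValueError(f"unknown sacrifice rule kind {self.kind!r}")
        if self.kind == "fixed":
            if self.age_pnd is None or self.age_pnd < 25:
                raise ValueError("fixed sacrifice requires age_pnd >= 25")
        elif self.offset_min > self.offset_max:
            raise ValueError("offset_min must not exceed offset_max")


@dataclass
class CohortConfig:
    """Configuration of one simulated cohort."""

    species: Species
    n: int
    vo_age_mean: float
    vo_age_sd: float
    lag_mean: float
    lag_sd: float
    sacrifice: SacrificeRule
    seed: int
    vo_age_min: float = 25.0
    lag_min: float = 0.0
    cycle_length_days: int = 4
    p_long_cycle: float = 0.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.vo_age_sd < 0 or self.lag_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not 0 <= self.p_long_cycle <= 1:
            raise ValueError("p_long_cycle must lie in [0, 1]")
        if self.species is Species.RAT and self.p_long_cycle > 0:
            raise ValueError("long (5-day) cycles are modelled for the mouse only")
        self.sacrifice.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        sac = SacrificeRule(**raw.pop("sacrifice"))
        cfg = cls(species=Species(raw.pop("species")), sacrifice=sac, **raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "species": self.species.value,
            "n": self.n,
            "vo_age_mean": self.vo_age_mean,
            "vo_age_sd": self.vo_age_sd,
            "vo_age_min": self.vo_age_min,
            "lag_mean": self.lag_mean,
            "lag_sd": self.lag_sd,
            "lag_min": self.lag_min,
            "cycle_length_days": self.cycle_length_days,
            "p_long_cycle": self.p_long_cycle,
            "seed": self.seed,
            "sacrifice": {
                "kind": self.sacrifice.kind,
                "age_pnd": self.sacrifice.age_pnd,
                "offset_min": self.sacrifice.offset_min,
                "offset_max": self.sacrifice.offset_max,
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class AnimalTrajectory:
    """Ground truth for one simulated animal."""

    animal_id: str
    vo_age_pnd: int
    fo_age_pnd: int
    cycle_lengths: list[int] = field(default_factory=list)
    sacrifice_age_pnd: int = 0

    def validate(self) -> None:
        if self.fo_age_pnd < self.vo_age_pnd:
            raise ValueError("first ovulation cannot precede vaginal opening")
        if self.sacrifice_age_pnd < 25:
            raise ValueError("sacrifice before PND-25 is outside the peripubertal design")


def _draw_truncated_int(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    """Truncated-normal draws (lower tail cut) rounded to integer days."""
    if sd == 0:
        return np.full(size, int(round(max(mean, lower))))
    a = (lower - mean) / sd
    if stats.norm.sf(a) < 1e-12:
        raise ValueError(
            f"truncation at {lower} leaves essentially no mass for mean={mean}, sd={sd}"
        )
    draws = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)
    return np.rint(draws).astype(int)


def simulate_cohort(config: CohortConfig) -> list[AnimalTrajectory]:
    """Draw ``config.n`` animal trajectories; reproducible under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    vo = _draw_truncated_int(rng, config.vo_age_mean, config.vo_age_sd, config.vo_age_min, config.n)
    lag = _draw_truncated_int(rng, config.lag_mean, config.lag_sd, config.lag_min, config.n)
    fo = vo + lag
    width = len(str(config.n))
    out: list[AnimalTrajectory] = []
    for i in range(config.n):
        if config.p_long_cycle > 0:
            long = rng.random(_MAX_CYCLES) < config.p_long_cycle
            cycles = [5 if flag else config.cycle_length_days for flag in long]
        else:
            cycles = [config.cycle_length_days] * _MAX_CYCLES
        if config.sacrifice.kind == "fixed":
            sac = config.sacrifice.age_pnd
        else:
            base = vo[i] if config.sacrifice.kind == "offset_vo" else fo[i]
            sac = base + int(
                rng.integers(config.sacrifice.offset_min, config.sacrifice.offset_max + 1)
            )
        traj = AnimalTrajectory(
            animal_id=f"sim-{i + 1:0{width}d}",
            vo_age_pnd=int(vo[i]),
            fo_age_pnd=int(fo[i]),
            cycle_lengths=cycles,
            sacrifice_age_pnd=int(sac),
        )
        traj.validate()
        out.append(traj)
    return out


def _locate_in_cycle(cycle_lengths: list[int], elapsed: int) -> tuple[int, int, int]:
    """Return (completed cycles, CL day, extra diestrus days accumulated)."""
    rem = elapsed
    generations = 0
    extra = 0
    for length in cycle_lengths:
        if rem < length:
            if length == 4:
                day = rem + 1
            else:
                day = _LONG_CYCLE_DAYS[rem]
                extra += (rem + 1) - day
            return generations, day, extra
        rem -= length
        generations += 1
        extra += length - 4
    raise ValueError("elapsed time exceeds the simulated cycle horizon")


def render_observation(traj: AnimalTrajectory, config: SpeciesConfig) -> OvaryObservation:
    """Render the coded histology observed at sacrifice.

    Deterministic in the trajectory.  Pre-ovulatory animals carry the
    follicle class scheduled for day −k before the first ovulation (the
    class scoring −k); more than 5 days before, only small follicles are
    present (with a warning).  Post-ovulatory animals carry the
    current-cycle CL for the elapsed day, one feature set per regressing
    generation, the scheduled companion follicle class and oocyte
    location.  A mouse past the one-regressing-generation window renders
    an additional unidentifiable remnant (R2 tag), which the scorer
    censors; elapsed times beyond any recognizable histology raise.
    """
    elapsed = traj.sacrifice_age_pnd - traj.fo_age_pnd
    species = config.species

    if elapsed < 0:
        k = -elapsed
        if k > 5:
            warnings.warn(
                f"sacrifice {k} days before first ovulation: before the final "
                "pre-ovulatory follicle wave, rendering SF",
                stacklevel=2,
            )
            fclass = FollicleClass.SF
        else:
            fclass = config.class_for_score(-k)
        return OvaryObservation(
            animal_id=traj.animal_id,
            species=species,
            age_pnd=traj.sacrifice_age_pnd,
            follicle_class=fclass,
            cl_generations=[],
            oocyte_location=OocyteLocation.NONE,
            vo_age_pnd=traj.vo_age_pnd,
        )

    cap = config.max_regressing_generations
    generations, day, _ = _locate_in_cycle(traj.cycle_lengths, elapsed)
    schedule = config.cl_feature_schedule
    order = [Generation.R1, Generation.R2]
    if generations <= cap:
        gens: list[CLFeatureSet] = [schedule[Generation.CURRENT][day]]
        gens += [schedule[order[g]][day] for g in range(generations)]
    elif species is Species.MOUSE and generations == cap + 1:
        # third cycle: the oldest CL are no longer identifiable, but their
        # remnants betray that the window is exceeded
        gens = [
            schedule[Generation.CURRENT][day],
            schedule[Generation.R1][day],
            schedule[Generation.R2][day],
        ]
    else:
        raise ValueError(
            f"sacrifice {elapsed} days after first ovulation is beyond the "
            f"{species.value} rendering window"
        )
    fclass = config.companion_schedule[day][-1]
    return OvaryObservation(
        animal_id=traj.animal_id,
        species=species,
        age_pnd=traj.sacrifice_age_pnd,
        follicle_class=fclass,
        cl_generations=gens,
        oocyte_location=config.oocyte_schedule[day],
        vo_age_pnd=traj.vo_age_pnd,
    )
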