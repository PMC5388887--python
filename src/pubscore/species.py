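"""Species parameterization: follicle class bounds, score maps and the
per-day corpus-luteum feature schedules for rat and mouse.

Two configurations ship with the package (``builtin_config("rat")`` /
``builtin_config("mouse")``).  The mouse follicle bounds are the measured
class boundaries (SF < 250 μm; F1 250–300; F2 301–350; F3 351–400;
F4 > 400, with the integer convention F1 closed at 300 and F2 starting
just above).  Rat bounds below/above 275 μm are placeholders chosen for
plumbing only — rat observations normally carry the follicle class
directly; see the methods note.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

try:  # Python >= 3.9
    from importlib import resources
except ImportError:  # pragma: no cover
    import importlib_resources as resources  # type: ignore

from .types import (
    Apoptosis,
    CLFeatureSet,
    FollicleClass,
    Generation,
    Luteinization,
    Mitoses,
    OocyteLocation,
    Species,
)

CL_DAYS = (1, 2, 3, 4)


class ConfigError(ValueError):
    """Raised when a species configuration fails validation."""


@dataclass(frozen=True)
class FollicleBound:
    """One follicle class with its upper diameter edge (μm).

    Classes are contiguous: the first (SF) spans (0, max_um) open at the
    top; the second is closed at both ends; subsequent classes span
    (previous max, max_um]; the last class has ``max_um=None`` (unbounded).
    """

    label: FollicleClass
    max_um: float | None


@dataclass
class SpeciesConfig:
    """All species-specific parameters the scorer, stager and simulator use."""

    species: Species
    follicle_bounds: list[FollicleBound]
    prepubertal_score_map: dict[FollicleClass, int]
    cycle_length_days: int
    max_regressing_generations: int
    max_score: int
    #: generation -> CL day (1..4 of the current cycle) -> expected features
    cl_feature_schedule: dict[Generation, dict[int, CLFeatureSet]]
    #: CL day -> acceptable companion follicle classes (last entry is the
    #: one the simulator renders)
    companion_schedule: dict[int, tuple[FollicleClass, ...]]
    #: CL day -> expected oocyte location in the oviduct
    oocyte_schedule: dict[int, OocyteLocation]

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        if self.cycle_length_days < 4:
            raise ConfigError("cycle_length_days must be >= 4")
        if self.max_regressing_generations < 0:
            raise ConfigError("max_regressing_generations must be >= 0")
        if self.max_score != 4 * self.max_regressing_generations + 4:
            raise ConfigError(
                "max_score must equal 4*max_regressing_generations + 4, got "
                f"{self.max_score} with {self.max_regressing_generations} generations"
            )
        self._validate_bounds()
        self._validate_score_map()
        self._validate_schedules()

    def _validate_bounds(self) -> None:
        if len(self.follicle_bounds) < 2:
            raise ConfigError("follicle_bounds needs at least SF and one antral class")
        if self.follicle_bounds[0].label is not FollicleClass.SF:
            raise ConfigError("follicle_bounds must start with SF")
        if self.follicle_bounds[-1].max_um is not None:
            raise ConfigError("follicle_bounds: the top class must be unbounded (max_um null)")
        labels = [b.label for b in self.follicle_bounds]
        if labels != sorted(labels):
            raise ConfigError("follicle_bounds must be ordered by advancing class")
        edges = [b.max_um for b in self.follicle_bounds[:-1]]
        if any(e is None for e in edges):
            raise ConfigError("follicle_bounds: only the top class may be unbounded")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigError(
                "follicle_bounds: upper edges must strictly increase (intervals must "
                "be non-overlapping and contiguous)"
            )
        if self.species is Species.MOUSE and FollicleClass.F5 in labels:
            raise ConfigError("follicle class F5 exists only in the rat")

    def _validate_score_map(self) -> None:
        ordered = [b.label for b in self.follicle_bounds]
        missing = [c.name for c in ordered if c not in self.prepubertal_score_map]
        if missing:
            raise ConfigError(f"prepubertal_score_map missing classes: {missing}")
        scores = [self.prepubertal_score_map[c] for c in ordered]
        if any(not -5 <= s <= -1 for s in scores):
            raise ConfigError("prepubertal scores must lie in [-5, -1]")
        # SF may tie with the first antral class (rat); antral classes must
        # strictly advance the score.
        if any(b < a for a, b in zip(scores, scores[1:])):
            raise ConfigError("prepubertal_score_map must be non-decreasing with class")
        antral = scores[1:]
        if any(b <= a for a, b in zip(antral, antral[1:])):
            raise ConfigError("prepubertal_score_map must strictly increase over antral classes")
        if scores[-1] != -1:
            raise ConfigError("the preovulatory class must map to score -1")

    def _validate_schedules(self) -> None:
        if Generation.CURRENT not in self.cl_feature_schedule:
            raise ConfigError("cl_feature_schedule must define the current generation")
        required = [Generation.CURRENT]
        if self.max_regressing_generations >= 1:
            required.append(Generation.R1)
        if self.max_regressing_generations >= 2:
            required.append(Generation.R2)
        for gen in required:
            days = self.cl_feature_schedule.get(gen, {})
            if sorted(days) != list(CL_DAYS):
                raise ConfigError(f"cl_feature_schedule[{gen.value}] must cover days 1-4")
        for gen, days in self.cl_feature_schedule.items():
            for day, feats in days.items():
                feats.validate()
                if feats.generation is not gen:
                    raise ConfigError(
                        f"schedule entry for {gen.value} day {day} is tagged {feats.generation.value}"
                    )
        if sorted(self.oocyte_schedule) != list(CL_DAYS):
            raise ConfigError("oocyte_schedule must cover days 1-4")
        if sorted(self.companion_schedule) != list(CL_DAYS):
            raise ConfigError("companion_schedule must cover days 1-4")
        valid = {b.label for b in self.follicle_bounds}
        for day, classes in self.companion_schedule.items():
            if not classes or any(c not in valid for c in classes):
                raise ConfigError(f"companion_schedule day {day} lists unknown classes")

    # ------------------------------------------------------------------ #

    @property
    def top_class(self) -> FollicleClass:
        """The preovulatory follicle class (F5 in rat, F4 in mouse)."""
        return self.follicle_bounds[-1].label

    def class_for_score(self, score: int) -> FollicleClass:
        """Most advanced follicle class mapping to a given pre-ovulatory score."""
        if not -5 <= score <= -1:
            raise ValueError(f"pre-ovulatory scores lie in [-5, -1], got {score}")
        hits = [c for c, s in self.prepubertal_score_map.items() if s == score]
        if not hits:
            # scores below the lowest mapped one collapse onto SF
            return FollicleClass.SF
        return max(hits)


# ---------------------------------------------------------------------- #
# serialization

def _features_from_dict(d: dict, gen: Generation) -> CLFeatureSet:
    def opt(key, enum_cls):
        v = d.get(key)
        return None if v is None else enum_cls(v)

    def opt_bool(key):
        v = d.get(key)
        return None if v is None else bool(v)

    return CLFeatureSet(
        luteinization=Luteinization(d["luteinization"]),
        generation=gen,
        mitoses=opt("mitoses", Mitoses),
        apoptosis=opt("apoptosis", Apoptosis),
        vascular_pattern=opt_bool("vascular_pattern"),
        rupture_site=opt_bool("rupture_site"),
        fibrous_center=opt_bool("fibrous_center"),
        stromal_ratio_grade=d.get("stromal_ratio_grade"),
    )


def _features_to_dict(f: CLFeatureSet) -> dict:
    out: dict = {"luteinization": f.luteinization.value}
    if f.mitoses is not None:
        out["mitoses"] = f.mitoses.value
    if f.apoptosis is not None:
        out["apoptosis"] = f.apoptosis.value
    for key in ("vascular_pattern", "rupture_site", "fibrous_center"):
        v = getattr(f, key)
        if v is not None:
            out[key] = v
    if f.stromal_ratio_grade is not None:
        out["stromal_ratio_grade"] = f.stromal_ratio_grade
    return out


def _config_from_dict(raw: dict) -> SpeciesConfig:
    try:
        species = Species(raw["species"])
        bounds = [
            FollicleBound(FollicleClass[b["class"]], b["max_um"]) for b in raw["follicle_bounds"]
        ]
        score_map = {FollicleClass[k]: int(v) for k, v in raw["prepubertal_score_map"].items()}
        schedule = {
            Generation(gen): {
                int(day): _features_from_dict(feats, Generation(gen))
                for day, feats in days.items()
            }
            for gen, days in raw["cl_feature_schedule"].items()
        }
        companions = {
            int(day): tuple(FollicleClass[c] for c in classes)
            for day, classes in raw["companion_schedule"].items()
        }
        oocytes = {int(day): OocyteLocation(v) for day, v in raw["oocyte_schedule"].items()}
        cfg = SpeciesConfig(
            species=species,
            follicle_bounds=bounds,
            prepubertal_score_map=score_map,
            cycle_length_days=int(raw["cycle_length_days"]),
            max_regressing_generations=int(raw["max_regressing_generations"]),
            max_score=int(raw["max_score"]),
            cl_feature_schedule=schedule,
            companion_schedule=companions,
            oocyte_schedule=oocytes,
        )
    except ConfigError:
        raise
    except KeyError as e:
        raise ConfigError(f"species config missing or misnaming field: {e}") from e
    except (TypeError, ValueError) as e:
        raise ConfigError(f"species config field malformed: {e}") from e
    cfg.validate()
    return cfg


def _config_to_dict(cfg: SpeciesConfig) -> dict:
    return {
        "species": cfg.species.value,
        "cycle_length_days": cfg.cycle_length_days,
        "max_regressing_generations": cfg.max_regressing_generations,
        "max_score": cfg.max_score,
        "follicle_bounds": [{"class": b.label.name, "max_um": b.max_um} for b in cfg.follicle_bounds],
        "prepubertal_score_map": {c.name: s for c, s in cfg.prepubertal_score_map.items()},
        "cl_feature_schedule": {
            gen.value: {day: _features_to_dict(f) for day, f in days.items()}
            for gen, days in cfg.cl_feature_schedule.items()
        },
        "companion_schedule": {
            day: [c.name for c in classes] for day, classes in cfg.companion_schedule.items()
        },
        "oocyte_schedule": {day: loc.value for day, loc in cfg.oocyte_schedule.items()},
    }


def load_species_config(path: str | Path) -> SpeciesConfig:
    """Load and validate a species configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse species config {path}: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"species config {path} is not a mapping")
    return _config_from_dict(raw)


def save_species_config(cfg: SpeciesConfig, path: str | Path) -> None:
    """Write a species configuration to YAML (round-trips with the loader)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)


def builtin_config(species: Species | str) -> SpeciesConfig:
    """Return the bundled configuration for ``"rat"`` or ``"mouse"``."""
    species = Species(species)
    ref = resources.files("pubscore").joinpath(f"data/{species.value}.yaml")
    with resources.as_file(ref) as path:
        return load_species_config(path)
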