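"""CSV readers/writers for observation, scored-result and trajectory tables.

Observation CSV columns (UTF-8, comma separated, header mandatory):

``animal_id, species, age_pnd, vo_age_pnd, follicle_class,
follicle_diameters_um, follicle_health, cl_generations, oocyte_location``

Either ``follicle_class`` (token SF/F1../F5) or ``follicle_diameters_um``
(``;``-separated μm values, with matching ``;``-separated
``follicle_health`` tokens healthy/atretic) must be present per row.
``cl_generations`` encodes one ``|``-separated entry per CL generation as
``key=value`` pairs, e.g.::

    gen=current,lut=partial,mit=abundant,vasc=1|gen=r1,lut=full,apo=abundant,grade=1

with keys gen, lut (required), mit, apo, vasc, rupt, fib, grade; omitted
keys mean "not recorded".  An empty cell means no corpora lutea.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .species import SpeciesConfig
from .types import (
    Apoptosis,
    CLFeatureSet,
    FollicleClass,
    Generation,
    HealthFlag,
    Luteinization,
    Mitoses,
    OocyteLocation,
    OvaryObservation,
    PubScoreResult,
    ScoreStatus,
    Species,
)

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = [
    "animal_id",
    "species",
    "age_pnd",
    "vo_age_pnd",
    "follicle_class",
    "follicle_diameters_um",
    "follicle_health",
    "cl_generations",
    "oocyte_location",
]
SCORED_COLUMNS = [
    "animal_id",
    "species",
    "age_pnd",
    "vo_age_pnd",
    "score",
    "status",
    "estimated_fo_age_pnd",
    "evidence",
]


class ObservationParseError(ValueError):
    """One or more rows of an observation table failed to parse."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


_FEATURE_KEYS = {"gen", "lut", "mit", "apo", "vasc", "rupt", "fib", "grade"}


def _encode_features(f: CLFeatureSet) -> str:
    parts = [f"gen={f.generation.value}", f"lut={f.luteinization.value}"]
    if f.mitoses is not None:
        parts.append(f"mit={f.mitoses.value}")
    if f.apoptosis is not None:
        parts.append(f"apo={f.apoptosis.value}")
    for key, attr in (("vasc", "vascular_pattern"), ("rupt", "rupture_site"), ("fib", "fibrous_center")):
        v = getattr(f, attr)
        if v is not None:
            parts.append(f"{key}={int(v)}")
    if f.stromal_ratio_grade is not None:
        parts.append(f"grade={f.stromal_ratio_grade}")
    return ",".join(parts)


def _decode_features(token: str) -> CLFeatureSet:
    kv: dict[str, str] = {}
    for part in token.split(","):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed CL feature {part!r} (expected key=value)")
        key, value = part.split("=", 1)
        if key not in _FEATURE_KEYS:
            raise ValueError(f"unknown CL feature key {key!r}")
        kv[key] = value
    if "lut" not in kv:
        raise ValueError("CL generation entry lacks required key 'lut'")

    def opt_bool(key):
        return None if key not in kv else bool(int(kv[key]))

    return CLFeatureSet(
        luteinization=Luteinization(kv["lut"]),
        generation=Generation(kv.get("gen", "current")),
        mitoses=None if "mit" not in kv else Mitoses(kv["mit"]),
        apoptosis=None if "apo" not in kv else Apoptosis(kv["apo"]),
        vascular_pattern=opt_bool("vasc"),
        rupture_site=opt_bool("rupt"),
        fibrous_center=opt_bool("fib"),
        stromal_ratio_grade=None if "grade" not in kv else int(kv["grade"]),
    )


def encode_generations(gens: list[CLFeatureSet]) -> str:
    return "|".join(_encode_features(g) for g in gens)


def decode_generations(cell: str) -> list[CLFeatureSet]:
    if not cell or not cell.strip():
        return []
    return [_decode_features(tok) for tok in cell.split("|")]


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


def _row_to_observation(row: pd.Series) -> OvaryObservation:
    fclass = None if _is_blank(row["follicle_class"]) else FollicleClass[str(row["follicle_class"]).strip()]
    diameters = None
    health = None
    if not _is_blank(row.get("follicle_diameters_um")):
        diameters = [float(v) for v in str(row["follicle_diameters_um"]).split(";")]
        if not _is_blank(row.get("follicle_health")):
            health = [HealthFlag(v.strip()) for v in str(row["follicle_health"]).split(";")]
    oocyte = (
        OocyteLocation.NONE
        if _is_blank(row.get("oocyte_location"))
        else OocyteLocation(str(row["oocyte_location"]).strip())
    )
    obs = OvaryObservation(
        animal_id=str(row["animal_id"]),
        species=Species(str(row["species"]).strip()),
        age_pnd=int(row["age_pnd"]),
        follicle_class=fclass,
        follicle_diameters_um=diameters,
        follicle_health=health,
        cl_generations=decode_generations("" if _is_blank(row.get("cl_generations")) else str(row["cl_generations"])),
        oocyte_location=oocyte,
        vo_age_pnd=None if _is_blank(row.get("vo_age_pnd")) else int(row["vo_age_pnd"]),
    )
    obs.validate()
    return obs


def read_observations(
    path: str | Path, config: SpeciesConfig | None = None, lenient: bool = False
) -> list[OvaryObservation]:
    """Read and validate an observation table.

    Row-level problems are collected with their line numbers; by default
    any problem raises :class:`ObservationParseError`, under
    ``lenient=True`` offending rows are dropped with a logged warning.
    """
    df = pd.read_csv(path, dtype=str)
    if df.empty and not len(df.columns):
        warnings.warn(f"{path}: empty observation file", stacklevel=2)
        return []
    missing = [c for c in ("animal_id", "species", "age_pnd") if c not in df.columns]
    if missing:
        raise ObservationParseError([f"missing required column(s): {missing}"])
    observations: list[OvaryObservation] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            obs = _row_to_observation(row)
            if config is not None and obs.species is not config.species:
                raise ValueError(
                    f"species {obs.species.value!r} does not match config "
                    f"{config.species.value!r}"
                )
            observations.append(obs)
        except (ValueError, KeyError) as e:
            errors.append(f"row {idx + 2}: {e}")  # +2: header + 1-based
    if errors:
        if not lenient:
            raise ObservationParseError(errors)
        for e in errors:
            logger.warning("dropped %s", e)
    if not observations:
        warnings.warn(f"{path}: no usable observation rows", stacklevel=2)
    return observations


def observations_to_frame(observations: list[OvaryObservation]) -> pd.DataFrame:
    rows = []
    for o in observations:
        rows.append(
            {
                "animal_id": o.animal_id,
                "species": o.species.value,
                "age_pnd": o.age_pnd,
                "vo_age_pnd": o.vo_age_pnd,
                "follicle_class": None if o.follicle_class is None else o.follicle_class.name,
                "follicle_diameters_um": None
                if o.follicle_diameters_um is None
                else ";".join(f"{d:g}" for d in o.follicle_diameters_um),
                "follicle_health": None
                if o.follicle_health is None
                else ";".join(h.value for h in o.follicle_health),
                "cl_generations": encode_generations(o.cl_generations),
                "oocyte_location": o.oocyte_location.value,
            }
        )
    df = pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)
    df["vo_age_pnd"] = df["vo_age_pnd"].astype("Int64")
    return df


def write_observations(observations: list[OvaryObservation], path: str | Path) -> None:
    observations_to_frame(observations).to_csv(path, index=False)


def scored_to_frame(
    results: list[PubScoreResult], vo_ages: dict[str, int | None] | None = None
) -> pd.DataFrame:
    """Tabulate scoring results; the evidence trail lands in the last column."""
    rows = []
    for r in results:
        rows.append(
            {
                "animal_id": r.animal_id,
                "species": r.species.value,
                "age_pnd": r.age_pnd,
                "vo_age_pnd": None if vo_ages is None else vo_ages.get(r.animal_id),
                "score": r.score,
                "status": r.status.value,
                "estimated_fo_age_pnd": r.estimated_fo_age_pnd,
                "evidence": "; ".join(r.evidence),
            }
        )
    df = pd.DataFrame(rows, columns=SCORED_COLUMNS)
    for col in ("vo_age_pnd", "estimated_fo_age_pnd"):
        df[col] = df[col].astype("Int64")  # keep integer PNDs despite missing values
    return df


def write_scored(
    results: list[PubScoreResult],
    path: str | Path,
    vo_ages: dict[str, int | None] | None = None,
) -> None:
    scored_to_frame(results, vo_ages).to_csv(path, index=False)


@dataclass
class ScoredRow:
    """One row of a scored table, as needed for cohort summaries."""

    animal_id: str
    vo_age_pnd: int | None
    age_pnd: int
    result: PubScoreResult


def read_scored(path: str | Path) -> list[ScoredRow]:
    df = pd.read_csv(path)
    rows: list[ScoredRow] = []
    for _, row in df.iterrows():
        status = ScoreStatus(row["status"])
        fo = row.get("estimated_fo_age_pnd")
        result = PubScoreResult(
            animal_id=str(row["animal_id"]),
            species=Species(row["species"]),
            age_pnd=int(row["age_pnd"]),
            score=int(row["score"]),
            status=status,
            estimated_fo_age_pnd=None if pd.isna(fo) else int(fo),
            evidence=[] if _is_blank(row.get("evidence")) else str(row["evidence"]).split("; "),
        )
        vo = row.get("vo_age_pnd")
        rows.append(
            ScoredRow(
                animal_id=str(row["animal_id"]),
                vo_age_pnd=None if pd.isna(vo) else int(vo),
                age_pnd=int(row["age_pnd"]),
                result=result,
            )
        )
    return rows


def write_trajectories(trajectories, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": t.animal_id,
                "vo_age_pnd": t.vo_age_pnd,
                "fo_age_pnd": t.fo_age_pnd,
                "cycle_lengths": ";".join(str(c) for c in t.cycle_lengths),
                "sacrifice_age_pnd": t.sacrifice_age_pnd,
            }
            for t in trajectories
        ]
    ).to_csv(path, index=False)
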