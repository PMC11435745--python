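"""Domain types, CSV schemas, run configuration and packaged reference tables.

Units are fixed by schema and never auto-converted: residue concentrations in
ng/g wet weight, food intake in g/person/day, acceptable daily intake (ADI) in
mg/kg body weight/day. CSV files use a dot decimal separator, UTF-8 encoding
and a mandatory header row.

Censoring is explicit: a monitoring record is either *detected* (``censored``
false, ``concentration`` present) or *censored* (``censored`` true,
``concentration`` absent, meaning below the limit of quantification). Sentinel
values such as 0 or LOQ/2 are never stored in the data model; left-censored
handling happens only in the exposure estimators that define it.
"""

from __future__ import annotations

import logging
from importlib.resources import files
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

logger = logging.getLogger("fishres")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: The 15 monitored species: 13 finfish, one crustacean, one shellfish.
SPECIES: tuple[str, ...] = (
    "abalone",
    "carp",
    "chinese muddy loach",
    "crucian carp",
    "eel",
    "far eastern catfish",
    "flathead mullet",
    "korean rockfish",
    "mirror carp",
    "olive flounder",
    "rainbow trout",
    "red seabream",
    "sea bass",
    "starry flounder",
    "whiteleg shrimp",
)

#: The 24-analyte pesticide panel (triazines, triazoles, amides, carbamates,
#: neonicotinoids, anilines and others).
PESTICIDES: tuple[str, ...] = (
    "acetamiprid",
    "azimsulfuron",
    "azinphos-methyl",
    "azoxystrobin",
    "carbendazim",
    "carbofuran",
    "clothianidin",
    "daimuron",
    "dichlorvos",
    "difenoconazole",
    "dinotefuran",
    "diuron",
    "fenobucarb",
    "flubendiamide",
    "hexaconazole",
    "indoxacarb",
    "lufenuron",
    "pyrimisulfan",
    "tebufenozide",
    "terbuthylazine",
    "thiacloprid",
    "thiamethoxam",
    "tricyclazole",
    "trifloxystrobin",
)

#: Matrix class of each species, used as the intermediate step when resolving
#: species-specific limits: species -> matrix class -> "default".
MATRIX_CLASS: dict[str, str] = {
    **{s: "fish" for s in SPECIES if s not in ("whiteleg shrimp", "abalone")},
    "whiteleg shrimp": "crustacean",
    "abalone": "shellfish",
}

_VALID_MATRICES = set(SPECIES) | set(MATRIX_CLASS.values()) | {"default"}


class SchemaError(ValueError):
    """A CSV row or header violates its declared schema."""


class ConfigError(ValueError):
    """A configuration document is malformed or holds an invalid value."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


class ResidueRecord(BaseModel):
    """One sample x pesticide measurement with explicit censoring state."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    species: str
    region: Optional[str] = None
    pesticide: str
    concentration: Optional[float] = None  # ng/g wet weight, detections only
    censored: bool

    @model_validator(mode="after")
    def _check(self) -> "ResidueRecord":
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.pesticide not in PESTICIDES:
            raise ValueError(f"unknown pesticide {self.pesticide!r}")
        if self.censored == (self.concentration is not None):
            raise ValueError(
                "censored records must omit concentration; detected records must carry one"
            )
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        return self


class LimitEntry(BaseModel):
    """LOD/LOQ pair for one pesticide in one matrix (species, class or default)."""

    model_config = ConfigDict(frozen=True)

    pesticide: str
    matrix: str
    lod: float = Field(gt=0)  # ng/g wet weight
    loq: float  # ng/g wet weight

    @model_validator(mode="after")
    def _check(self) -> "LimitEntry":
        if self.pesticide not in PESTICIDES:
            raise ValueError(f"unknown pesticide {self.pesticide!r}")
        if self.matrix not in _VALID_MATRICES:
            raise ValueError(f"unknown matrix {self.matrix!r}")
        if not self.lod < self.loq:
            raise ValueError("require 0 < lod < loq")
        return self


class ConsumptionRecord(BaseModel):
    """Daily intake of one species: survey mean and 99th-percentile extreme."""

    model_config = ConfigDict(frozen=True)

    species: str
    mean_intake: float = Field(ge=0)  # g/person/day
    extreme_intake: float  # g/person/day, 99th percentile
    imputed: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ConsumptionRecord":
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.extreme_intake < self.mean_intake:
            raise ValueError("extreme_intake must be >= mean_intake")
        return self


class ToxRef(BaseModel):
    """Toxicological reference: ADI and the assumed consumer body weight."""

    model_config = ConfigDict(frozen=True)

    pesticide: str
    adi: float = Field(gt=0)  # mg/kg body weight/day
    body_weight: float = Field(default=60.0, gt=0)  # kg

    @model_validator(mode="after")
    def _check(self) -> "ToxRef":
        if self.pesticide not in PESTICIDES:
            raise ValueError(f"unknown pesticide {self.pesticide!r}")
        return self


LEVEL_CLASSES = ("LOQ", "10xLOQ", "50xLOQ")


class ValidationRun(BaseModel):
    """One spiked-recovery experiment: spike level plus replicate measurements."""

    model_config = ConfigDict(frozen=True)

    pesticide: str
    matrix: str
    spike_level: float = Field(gt=0)  # ng/g
    level_class: str
    replicates: tuple[float, ...]  # measured concentrations, ng/g

    @model_validator(mode="after")
    def _check(self) -> "ValidationRun":
        if self.pesticide not in PESTICIDES:
            raise ValueError(f"unknown pesticide {self.pesticide!r}")
        if self.level_class not in LEVEL_CLASSES:
            raise ValueError(f"level_class must be one of {LEVEL_CLASSES}")
        if len(self.replicates) < 2:
            raise ValueError("at least 2 replicates required")
        if any(r < 0 for r in self.replicates):
            raise ValueError("replicates must be non-negative")
        return self


class CalibrationSeries(BaseModel):
    """(level, response) pairs for one analyte, in solvent or in a matrix extract."""

    model_config = ConfigDict(frozen=True)

    pesticide: str
    matrix_label: str  # "solvent" or "matrix:<name>"
    points: tuple[tuple[float, float], ...]  # (level ng/g, response a.u.)

    @model_validator(mode="after")
    def _check(self) -> "CalibrationSeries":
        if self.pesticide not in PESTICIDES:
            raise ValueError(f"unknown pesticide {self.pesticide!r}")
        if self.matrix_label != "solvent" and not self.matrix_label.startswith("matrix:"):
            raise ValueError("matrix_label must be 'solvent' or 'matrix:<name>'")
        levels = {lv for lv, _ in self.points}
        if len(levels) < 3:
            raise ValueError("at least 3 distinct calibration levels required")
        if any(lv <= 0 for lv in levels):
            raise ValueError("calibration levels must be positive")
        return self


class ScenarioResult(BaseModel):
    """One (intake tier, concentration option) cell of the 9-scenario grid."""

    model_config = ConfigDict(frozen=True)

    intake_tier: int = Field(ge=1, le=3)
    dpc_option: str  # A | B | C
    scenario_id: int = Field(ge=1, le=9)
    dfi: Optional[float] = None  # g/person/day
    dpc: Optional[float] = None  # ng/g
    edi: Optional[float] = None  # ng/person/day
    percent_adi: Optional[float] = None  # %
    evaluable: bool = True

    @model_validator(mode="after")
    def _check(self) -> "ScenarioResult":
        if self.dpc_option not in ("A", "B", "C"):
            raise ValueError("dpc_option must be A, B or C")
        expected = 3 * (self.intake_tier - 1) + "ABC".index(self.dpc_option) + 1
        if self.scenario_id != expected:
            raise ValueError(f"scenario_id {self.scenario_id} inconsistent, expected {expected}")
        if self.evaluable:
            if self.edi is None or self.percent_adi is None:
                raise ValueError("evaluable scenario must carry edi and percent_adi")
            if self.edi < 0 or self.percent_adi < 0:
                raise ValueError("edi and percent_adi must be non-negative")
        return self


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Tunable run parameters with the study defaults.

    tier1_rule / tier3_rule select the aggregation behind intake tiers 1 and 3
    (the tier-2 rule — the detected species' extreme intake — is fixed):
    ``detected_species`` uses the detected species' own intake;
    ``sum_all_species`` sums the intake column over all species in the table.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    body_weight: float = Field(default=60.0, gt=0)  # kg
    n_tests_per_species: int = Field(default=20, gt=0)
    risk_threshold: float = Field(default=10.0, gt=0)  # %ADI
    tier1_rule: str = "detected_species"
    tier3_rule: str = "sum_all_species"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        for name in ("tier1_rule", "tier3_rule"):
            if getattr(self, name) not in ("detected_species", "sum_all_species"):
                raise ValueError(f"{name} must be 'detected_species' or 'sum_all_species'")
        return self


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML key/value config; missing file section keys fall back to defaults."""
    if path is None:
        return RunConfig()
    try:
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:  # pragma: no cover - depends on yaml internals
        raise ConfigError(f"malformed config {path}: {exc}") from exc
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a key/value mapping")
    try:
        return RunConfig(**raw)
    except ValidationError as exc:
        detail = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        )
        raise ConfigError(f"invalid config {path}: {detail}") from exc


# ---------------------------------------------------------------------------
# CSV schemas
# ---------------------------------------------------------------------------

_SCHEMA_COLUMNS: dict[str, list[str]] = {
    "residues": ["sample_id", "species", "region", "pesticide", "concentration", "censored"],
    "limits": ["pesticide", "matrix", "lod", "loq"],
    "consumption": ["species", "mean_intake", "extreme_intake", "imputed"],
    "toxref": ["pesticide", "adi", "body_weight"],
    "validation": ["pesticide", "matrix", "spike_level", "level_class", "replicate", "measured"],
    "calibration": ["pesticide", "matrix_label", "level", "response"],
}


def _parse_bool(value: str, row: int, field: str) -> bool:
    v = str(value).strip().lower()
    if v in ("true", "1", "yes"):
        return True
    if v in ("false", "0", "no"):
        return False
    raise SchemaError(f"row {row}: field {field!r}: not a boolean: {value!r}")


def _parse_float(value, row: int, field: str) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"row {row}: field {field!r}: not a number: {value!r}") from None


def _is_blank(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or str(value).strip() == ""


def _read_frame(path: str | Path, schema_name: str) -> pd.DataFrame:
    if schema_name not in _SCHEMA_COLUMNS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[""])
    expected = _SCHEMA_COLUMNS[schema_name]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema_name!r}")
    return df


def read_table(path: str | Path, schema_name: str) -> list:
    """Read and validate a CSV against one of the declared schemas.

    Returns a list of typed records. ``validation`` rows (long form, one row
    per replicate) are grouped into :class:`ValidationRun` and ``calibration``
    rows into :class:`CalibrationSeries`. Row numbers in error messages are
    1-based data rows (the header is row 0).
    """
    df = _read_frame(path, schema_name)

    def fail(row: int, field: str, msg: str) -> SchemaError:
        return SchemaError(f"{path}: row {row}: field {field!r}: {msg}")

    def build(model, row: int, **kwargs):
        try:
            return model(**kwargs)
        except ValidationError as exc:
            err = exc.errors()[0]
            loc = ".".join(str(p) for p in err["loc"]) or "?"
            raise fail(row, loc, err["msg"]) from exc

    records: list = []
    if schema_name == "residues":
        for i, r in enumerate(df.itertuples(index=False), start=1):
            censored = _parse_bool(r.censored, i, "censored")
            conc = None if _is_blank(r.concentration) else _parse_float(r.concentration, i, "concentration")
            records.append(
                build(
                    ResidueRecord, i,
                    sample_id=str(r.sample_id), species=str(r.species),
                    region=None if _is_blank(r.region) else str(r.region),
                    pesticide=str(r.pesticide), concentration=conc, censored=censored,
                )
            )
    elif schema_name == "limits":
        for i, r in enumerate(df.itertuples(index=False), start=1):
            records.append(
                build(
                    LimitEntry, i,
                    pesticide=str(r.pesticide), matrix=str(r.matrix),
                    lod=_parse_float(r.lod, i, "lod"), loq=_parse_float(r.loq, i, "loq"),
                )
            )
    elif schema_name == "consumption":
        for i, r in enumerate(df.itertuples(index=False), start=1):
            records.append(
                build(
                    ConsumptionRecord, i,
                    species=str(r.species),
                    mean_intake=_parse_float(r.mean_intake, i, "mean_intake"),
                    extreme_intake=_parse_float(r.extreme_intake, i, "extreme_intake"),
                    imputed=_parse_bool(r.imputed, i, "imputed"),
                )
            )
    elif schema_name == "toxref":
        for i, r in enumerate(df.itertuples(index=False), start=1):
            records.append(
                build(
                    ToxRef, i,
                    pesticide=str(r.pesticide), adi=_parse_float(r.adi, i, "adi"),
                    body_weight=_parse_float(r.body_weight, i, "body_weight"),
                )
            )
    elif schema_name == "validation":
        groups: dict[tuple, list] = {}
        meta: dict[tuple, int] = {}
        for i, r in enumerate(df.itertuples(index=False), start=1):
            key = (str(r.pesticide), str(r.matrix),
                   _parse_float(r.spike_level, i, "spike_level"), str(r.level_class))
            groups.setdefault(key, []).append(_parse_float(r.measured, i, "measured"))
            meta.setdefault(key, i)
        for (pest, matrix, spike, level), reps in groups.items():
            records.append(
                build(
                    ValidationRun, meta[(pest, matrix, spike, level)],
                    pesticide=pest, matrix=matrix, spike_level=spike,
                    level_class=level, replicates=tuple(reps),
                )
            )
    elif schema_name == "calibration":
        groups = {}
        meta = {}
        for i, r in enumerate(df.itertuples(index=False), start=1):
            key = (str(r.pesticide), str(r.matrix_label))
            groups.setdefault(key, []).append(
                (_parse_float(r.level, i, "level"), _parse_float(r.response, i, "response"))
            )
            meta.setdefault(key, i)
        for (pest, label), pts in groups.items():
            records.append(
                build(
                    CalibrationSeries, meta[(pest, label)],
                    pesticide=pest, matrix_label=label, points=tuple(pts),
                )
            )
    logger.debug("read %d %s record(s) from %s", len(records), schema_name, path)
    return records


def write_table(records: list, path: str | Path, schema_name: str) -> None:
    """Write typed records back to CSV; inverse of :func:`read_table`."""
    if schema_name not in _SCHEMA_COLUMNS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    rows: list[dict] = []
    if schema_name == "residues":
        for rec in records:
            rows.append(
                {
                    "sample_id": rec.sample_id, "species": rec.species,
                    "region": rec.region if rec.region is not None else "",
                    "pesticide": rec.pesticide,
                    "concentration": "" if rec.concentration is None else repr(rec.concentration),
                    "censored": str(rec.censored).lower(),
                }
            )
    elif schema_name == "limits":
        rows = [
            {"pesticide": r.pesticide, "matrix": r.matrix, "lod": repr(r.lod), "loq": repr(r.loq)}
            for r in records
        ]
    elif schema_name == "consumption":
        rows = [
            {
                "species": r.species, "mean_intake": repr(r.mean_intake),
                "extreme_intake": repr(r.extreme_intake), "imputed": str(r.imputed).lower(),
            }
            for r in records
        ]
    elif schema_name == "toxref":
        rows = [
            {"pesticide": r.pesticide, "adi": repr(r.adi), "body_weight": repr(r.body_weight)}
            for r in records
        ]
    elif schema_name == "validation":
        for run in records:
            for rep in run.replicates:
                rows.append(
                    {
                        "pesticide": run.pesticide, "matrix": run.matrix,
                        "spike_level": repr(run.spike_level), "level_class": run.level_class,
                        "replicate": "", "measured": repr(rep),
                    }
                )
    elif schema_name == "calibration":
        for series in records:
            for level, resp in series.points:
                rows.append(
                    {
                        "pesticide": series.pesticide, "matrix_label": series.matrix_label,
                        "level": repr(level), "response": repr(resp),
                    }
                )
    pd.DataFrame(rows, columns=_SCHEMA_COLUMNS[schema_name]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Limit lookup
# ---------------------------------------------------------------------------


def resolve_limit(limits: list[LimitEntry], pesticide: str, species: str) -> LimitEntry:
    """Resolve the LOD/LOQ for a pesticide in a species.

    Lookup order: exact species row, then the species' matrix class
    (fish / crustacean / shellfish), then a "default" row.
    """
    by_matrix = {e.matrix: e for e in limits if e.pesticide == pesticide}
    for key in (species, MATRIX_CLASS.get(species, ""), "default"):
        if key in by_matrix:
            return by_matrix[key]
    raise KeyError(f"no LOD/LOQ entry for {pesticide!r} applicable to {species!r}")


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------

_DATA = files("fishres") / "data"


def _data_path(name: str) -> Path:
    return Path(str(_DATA / name))


def load_consumption_table() -> list[ConsumptionRecord]:
    """The packaged KNHANES 2017–2021 per-species intake table (15 species)."""
    return read_table(_data_path("consumption_knhanes.csv"), "consumption")


def load_toxref_table() -> list[ToxRef]:
    """Packaged toxicological references (currently lufenuron only)."""
    return read_table(_data_path("toxref.csv"), "toxref")


def load_method_comparison() -> pd.DataFrame:
    """Per-pesticide mean recoveries (± SD) for the two extraction and two
    clean-up methods compared during method development."""
    return pd.read_csv(_data_path("method_comparison.csv"))


def load_validation_table() -> pd.DataFrame:
    """The full validation summary: linearity, matrix effect, LOD/LOQ,
    recovery and RSD per pesticide x matrix (4 validated matrices)."""
    return pd.read_csv(_data_path("validation_table.csv"))


def load_limits_table() -> list[LimitEntry]:
    """LOD/LOQ entries derived from the validation summary, one per
    pesticide x validated species."""
    df = load_validation_table()
    return [
        LimitEntry(pesticide=r.pesticide, matrix=r.matrix, lod=float(r.lod), loq=float(r.loq))
        for r in df.itertuples(index=False)
    ]
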