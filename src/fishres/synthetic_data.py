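"""Seeded synthetic monitoring, spiked-recovery and calibration data.

The generator emulates the structure of a national residue-monitoring study
so that every pipeline stage is testable with known ground truth:

* monitoring — 15 species x 20 samples x 24 pesticides, detections rare and
  left-censored at the LOQ; detected concentrations follow a log-normal
  (median, geometric SD) truncated below at the LOQ, since residues are
  positive and right-skewed. Exact detections can also be *planted*
  deterministically (the default spec plants lufenuron at 10 ng/g in one
  eel sample).
* spiked recovery — three spike levels (LOQ, 10x, 50x) x five replicates
  per analyte and matrix; noise is multiplicative (CV is relative):
  measured = spike x R*/100 x (1 + N(0, CV*/100)), truncated at 0.
* calibration — paired solvent/matrix series over the level grid matching
  the analyte's LOQ class, with a known matrix/solvent slope factor and
  additive Gaussian response noise (instrument noise is additive).

All draws come from one ``numpy.random.default_rng(seed)`` stream, so a
fixed seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io_model import (
    PESTICIDES,
    SPECIES,
    CalibrationSeries,
    LimitEntry,
    ResidueRecord,
    ValidationRun,
    resolve_limit,
)

#: Calibration level grids (ng/g) keyed by LOQ class.
LEVEL_GRIDS: dict[float, tuple[float, ...]] = {
    3.0: (0.25, 0.75, 1.5, 3.75, 7.5, 12.0, 15.0),
    4.0: (0.3, 1.0, 1.6, 2.0, 5.0, 10.0, 16.0, 20.0),
    5.0: (0.4, 1.25, 2.0, 2.5, 6.25, 12.5, 20.0, 25.0),
    7.0: (0.6, 1.75, 2.8, 3.5, 8.75, 17.5, 28.0, 35.0),
    10.0: (0.8, 2.5, 4.0, 5.0, 12.5, 25.0, 40.0, 50.0),
}

#: Sampling regions rotated across samples of each species.
REGIONS: tuple[str, ...] = (
    "chungcheongbuk-do", "chungcheongnam-do", "jeju-do", "jeollabuk-do",
    "jeollanam-do", "gangwon-do", "gyeonggi-do", "gyeongsangbuk-do",
    "gyeongsangnam-do",
)

VALIDATED_MATRICES: tuple[str, ...] = ("eel", "olive flounder", "abalone", "whiteleg shrimp")

SPIKE_FACTORS: dict[str, float] = {"LOQ": 1.0, "10xLOQ": 10.0, "50xLOQ": 50.0}


class PlantedDetection(BaseModel):
    """A deterministic detection injected into the monitoring output."""

    model_config = ConfigDict(frozen=True)

    species: str
    pesticide: str
    concentration: float = Field(gt=0)  # ng/g
    sample_index: int = Field(default=0, ge=0)


class GeneratorSpec(BaseModel):
    """Ground-truth parameters for one synthetic dataset."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    species: tuple[str, ...] = SPECIES
    pesticides: tuple[str, ...] = PESTICIDES
    n_samples: int = Field(default=20, gt=0)

    # monitoring model
    base_detection_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    detection_prob: dict[tuple[str, str], float] = Field(default_factory=dict)
    conc_median: float = Field(default=10.0, gt=0)  # ng/g
    conc_gsd: float = Field(default=1.5, ge=1.0)  # geometric SD, 1 = degenerate
    planted: tuple[PlantedDetection, ...] = ()
    limits: tuple[LimitEntry, ...] = ()

    # recovery model
    true_recovery: float = Field(default=90.0, gt=0)  # %
    cv_by_level: dict[str, float] = Field(
        default_factory=lambda: {"LOQ": 5.0, "10xLOQ": 2.0, "50xLOQ": 2.0}
    )  # %
    n_replicates: int = Field(default=5, gt=1)

    # calibration model
    solvent_slope: float = Field(default=3.0, gt=0)  # response per ng/g
    matrix_factor: float = Field(default=1.1, gt=0)  # matrix slope / solvent slope
    response_noise_sd: float = Field(default=0.5, ge=0)  # response units
    calibration_matrices: tuple[str, ...] = VALIDATED_MATRICES

    @model_validator(mode="after")
    def _check(self) -> "GeneratorSpec":
        for (sp, pest), p in self.detection_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detection_prob[{sp},{pest}]={p} outside [0,1]")
        for lvl, cv in self.cv_by_level.items():
            if lvl not in SPIKE_FACTORS:
                raise ValueError(f"unknown spike level class {lvl!r}")
            if cv < 0:
                raise ValueError("CV must be non-negative")
        return self


def _default_limits() -> tuple[LimitEntry, ...]:
    """Packaged per-species limits plus a per-pesticide default row (eel values)."""
    from .io_model import load_limits_table

    limits = list(load_limits_table())
    eel = {e.pesticide: e for e in limits if e.matrix == "eel"}
    for pesticide, entry in eel.items():
        limits.append(
            LimitEntry(pesticide=pesticide, matrix="default", lod=entry.lod, loq=entry.loq)
        )
    return tuple(limits)


def default_study_spec(seed: int = 0) -> GeneratorSpec:
    """The packaged study-shaped spec: 15 species x 20 samples x 24 pesticides,
    no random detections, and lufenuron planted at 10 ng/g in one eel sample."""
    return GeneratorSpec(
        seed=seed,
        planted=(PlantedDetection(species="eel", pesticide="lufenuron", concentration=10.0),),
        limits=_default_limits(),
    )


def _spec_limits(spec: GeneratorSpec) -> tuple[LimitEntry, ...]:
    return spec.limits if spec.limits else _default_limits()


def _draw_truncated_lognormal(
    rng: np.random.Generator, median: float, gsd: float, lower: float, max_tries: int = 1000
) -> float:
    """Rejection-sample a log-normal(ln median, ln gsd) draw >= lower."""
    if gsd == 1.0:
        if median < lower:
            raise ValueError(f"degenerate concentration {median} below truncation point {lower}")
        return median
    mu, sigma = np.log(median), np.log(gsd)
    for _ in range(max_tries):
        x = float(rng.lognormal(mu, sigma))
        if x >= lower:
            return x
    # pathological truncation (lower far in the upper tail): fall back to the bound
    return lower


def generate_monitoring(spec: GeneratorSpec) -> list[ResidueRecord]:
    """Simulate the monitoring survey: one record per species x sample x pesticide."""
    rng = np.random.default_rng(spec.seed)
    limits = _spec_limits(spec)
    planted = {(p.species, p.pesticide, p.sample_index): p for p in spec.planted}
    records: list[ResidueRecord] = []
    for species in spec.species:
        for i in range(spec.n_samples):
            sample_id = f"{species.replace(' ', '-')}-{i + 1:03d}"
            region = REGIONS[i % len(REGIONS)]
            for pesticide in spec.pesticides:
                loq = resolve_limit(list(limits), pesticide, species).loq
                plant = planted.get((species, pesticide, i))
                if plant is not None:
                    records.append(
                        ResidueRecord(
                            sample_id=sample_id, species=species, region=region,
                            pesticide=pesticide, concentration=plant.concentration,
                            censored=False,
                        )
                    )
                    continue
                p = spec.detection_prob.get((species, pesticide), spec.base_detection_prob)
                detected = bool(rng.random() < p) if p > 0 else False
                if detected:
                    conc = _draw_truncated_lognormal(rng, spec.conc_median, spec.conc_gsd, loq)
                    records.append(
                        ResidueRecord(
                            sample_id=sample_id, species=species, region=region,
                            pesticide=pesticide, concentration=conc, censored=False,
                        )
                    )
                else:
                    records.append(
                        ResidueRecord(
                            sample_id=sample_id, species=species, region=region,
                            pesticide=pesticide, censored=True,
                        )
                    )
    return records


def generate_validation(
    spec: GeneratorSpec,
    pesticides: Optional[tuple[str, ...]] = None,
    matrices: Optional[tuple[str, ...]] = None,
) -> tuple[list[ValidationRun], int]:
    """Simulate spiked-recovery experiments.

    Returns the runs and the number of replicate draws truncated at zero
    (possible only at extreme CV).
    """
    rng = np.random.default_rng(spec.seed + 1)
    limits = _spec_limits(spec)
    pesticides = pesticides if pesticides is not None else spec.pesticides
    matrices = matrices if matrices is not None else spec.calibration_matrices
    runs: list[ValidationRun] = []
    n_truncated = 0
    for pesticide in pesticides:
        for matrix in matrices:
            loq = resolve_limit(list(limits), pesticide, matrix).loq
            for level, factor in SPIKE_FACTORS.items():
                spike = loq * factor
                cv = spec.cv_by_level.get(level, 0.0)
                noise = rng.normal(0.0, cv / 100.0, size=spec.n_replicates)
                reps = spike * (spec.true_recovery / 100.0) * (1.0 + noise)
                n_truncated += int((reps < 0).sum())
                reps = np.clip(reps, 0.0, None)
                runs.append(
                    ValidationRun(
                        pesticide=pesticide, matrix=matrix, spike_level=spike,
                        level_class=level, replicates=tuple(float(r) for r in reps),
                    )
                )
    return runs, n_truncated


def generate_calibration(
    spec: GeneratorSpec,
    pesticides: Optional[tuple[str, ...]] = None,
    matrices: Optional[tuple[str, ...]] = None,
) -> list[tuple[CalibrationSeries, CalibrationSeries]]:
    """Simulate paired (solvent, matrix) calibration series per analyte x matrix.

    The level grid is selected by the analyte's LOQ class; the true matrix
    effect is (matrix_factor − 1) x 100 %.
    """
    rng = np.random.default_rng(spec.seed + 2)
    limits = _spec_limits(spec)
    pesticides = pesticides if pesticides is not None else spec.pesticides
    matrices = matrices if matrices is not None else spec.calibration_matrices
    pairs: list[tuple[CalibrationSeries, CalibrationSeries]] = []
    for pesticide in pesticides:
        for matrix in matrices:
            loq = resolve_limit(list(limits), pesticide, matrix).loq
            if loq not in LEVEL_GRIDS:
                raise ValueError(f"no calibration level grid for LOQ class {loq} ng/g")
            levels = np.asarray(LEVEL_GRIDS[loq])
            solvent_resp = spec.solvent_slope * levels + rng.normal(
                0.0, spec.response_noise_sd, size=levels.size
            )
            matrix_resp = spec.solvent_slope * spec.matrix_factor * levels + rng.normal(
                0.0, spec.response_noise_sd, size=levels.size
            )
            solvent = CalibrationSeries(
                pesticide=pesticide, matrix_label="solvent",
                points=tuple((float(l), float(r)) for l, r in zip(levels, solvent_resp)),
            )
            in_matrix = CalibrationSeries(
                pesticide=pesticide, matrix_label=f"matrix:{matrix}",
                points=tuple((float(l), float(r)) for l, r in zip(levels, matrix_resp)),
            )
            pairs.append((solvent, in_matrix))
    return pairs


def ground_truth_rows(spec: GeneratorSpec) -> list[dict]:
    """Flat ground-truth manifest rows for a generated dataset."""
    rows = [
        {"quantity": "true_recovery_percent", "key": "", "value": spec.true_recovery},
        {"quantity": "matrix_factor", "key": "", "value": spec.matrix_factor},
        {"quantity": "solvent_slope", "key": "", "value": spec.solvent_slope},
        {"quantity": "conc_median", "key": "", "value": spec.conc_median},
        {"quantity": "conc_gsd", "key": "", "value": spec.conc_gsd},
        {"quantity": "base_detection_prob", "key": "", "value": spec.base_detection_prob},
    ]
    for lvl, cv in spec.cv_by_level.items():
        rows.append({"quantity": "cv_percent", "key": lvl, "value": cv})
    for p in spec.planted:
        rows.append(
            {
                "quantity": "planted_detection",
                "key": f"{p.species}/{p.pesticide}/sample{p.sample_index}",
                "value": p.concentration,
            }
        )
    return rows
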