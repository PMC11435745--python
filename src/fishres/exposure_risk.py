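"""Nine-scenario dietary exposure and hazard-index (%ADI) assessment.

The estimated daily intake of a residue is the product of a daily food
intake (DFI, g/person/day) and a detected pesticide concentration
(DPC, ng/g):

    EDI (ng/person/day) = DFI x DPC

Three intake tiers supply the DFI:

1. mean intake (default: of the species the residue was detected in),
2. 99th-percentile (extreme) intake of the detected species,
3. 99th-percentile intake aggregated over fishery species
   (default: summed over the consumption table).

Three left-censoring treatments supply the DPC from a monitoring summary of
``n_tests`` analyses with ``d`` detections:

A. (Σ detections + LOQ x (n_tests − d)) / n_tests — LOQ substituted for
   every non-detect (upper-bound style mean),
B. Σ detections / d — mean over detections only,
C. max(detections) — worst observed case.

The hazard index expresses the EDI as a percentage of the per-person
acceptable daily intake:

    %ADI = EDI / (ADI x body weight x 10^6 ng/mg) x 100

with ADI in mg/kg bw/day and body weight in kg (default 60). A %ADI below
10 % is conventionally classified as minimal risk (FAO/WHO).

Options B and C are defined only over detections; with zero detections those
scenarios are emitted as not evaluable rather than silently substituting the
LOQ.
"""

from __future__ import annotations

import logging
from collections import Counter

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .io_model import (
    ConsumptionRecord,
    LimitEntry,
    ResidueRecord,
    ScenarioResult,
    ToxRef,
    resolve_limit,
)

logger = logging.getLogger("fishres")

NG_PER_MG = 1e6  # the only unit conversion in the exposure chain

RISK_THRESHOLD_DEFAULT = 10.0  # %ADI below which risk is classified minimal


class ExposureError(ValueError):
    """An exposure quantity is undefined or an input lookup failed."""


class DetectionSummary(BaseModel):
    """Monitoring outcome for one pesticide x species."""

    model_config = ConfigDict(frozen=True)

    pesticide: str
    species: str
    n_tests: int = Field(default=20, ge=1)
    detections: tuple[float, ...] = ()  # concentrations ng/g, >= loq
    loq: float = Field(gt=0)  # ng/g

    @model_validator(mode="after")
    def _check(self) -> "DetectionSummary":
        if len(self.detections) > self.n_tests:
            raise ValueError("more detections than tests")
        if any(c < self.loq for c in self.detections):
            raise ValueError("detected concentrations must be >= LOQ")
        return self


class RiskAssessment(BaseModel):
    """All nine (tier, option) scenarios for one pesticide, classified."""

    model_config = ConfigDict(frozen=True)

    pesticide: str
    species: str
    threshold: float = RISK_THRESHOLD_DEFAULT  # %
    scenarios: tuple[ScenarioResult, ...]
    classification: tuple[str, ...]  # minimal | concern | not evaluable, per scenario

    @model_validator(mode="after")
    def _check(self) -> "RiskAssessment":
        if len(self.scenarios) != 9 or len(self.classification) != 9:
            raise ValueError("exactly 9 scenarios required")
        if [s.scenario_id for s in self.scenarios] != list(range(1, 10)):
            raise ValueError("scenarios must be ordered tier-major, ids 1..9")
        return self

    @property
    def max_percent_adi(self) -> float | None:
        vals = [s.percent_adi for s in self.scenarios if s.evaluable]
        return max(vals) if vals else None


# ---------------------------------------------------------------------------
# DPC estimators (left-censoring treatments)
# ---------------------------------------------------------------------------


def dpc_option_a(s: DetectionSummary) -> float:
    """LOQ-substitution mean: (Σ detections + LOQ x non-detects) / n_tests."""
    return (sum(s.detections) + s.loq * (s.n_tests - len(s.detections))) / s.n_tests


def dpc_option_b(s: DetectionSummary) -> float:
    """Mean over detections only; undefined with zero detections."""
    if not s.detections:
        raise ExposureError(f"{s.pesticide}/{s.species}: option B undefined with no detections")
    return sum(s.detections) / len(s.detections)


def dpc_option_c(s: DetectionSummary) -> float:
    """Maximum detected concentration; undefined with zero detections."""
    if not s.detections:
        raise ExposureError(f"{s.pesticide}/{s.species}: option C undefined with no detections")
    return max(s.detections)


# ---------------------------------------------------------------------------
# Intake tiers
# ---------------------------------------------------------------------------


def intake_for_tier(
    tier: int,
    species_detected: str,
    consumption: list[ConsumptionRecord],
    *,
    tier1_rule: str = "detected_species",
    tier3_rule: str = "sum_all_species",
) -> float:
    """DFI (g/person/day) for an intake tier.

    Tier 2 is fixed: the detected species' extreme (99th percentile) intake.
    Tiers 1 and 3 are aggregation choices: ``detected_species`` reads the
    detected species' own (mean / extreme) intake, ``sum_all_species`` sums
    that column over the whole table.
    """
    by_species = {c.species: c for c in consumption}
    if species_detected not in by_species:
        raise ExposureError(f"species {species_detected!r} not in consumption table")
    if tier == 2:
        return by_species[species_detected].extreme_intake
    if tier == 1:
        column = "mean_intake"
        rule = tier1_rule
    elif tier == 3:
        column = "extreme_intake"
        rule = tier3_rule
    else:
        raise ExposureError(f"tier must be 1, 2 or 3, got {tier}")
    if rule == "detected_species":
        return getattr(by_species[species_detected], column)
    if rule == "sum_all_species":
        return sum(getattr(c, column) for c in consumption)
    raise ExposureError(f"unknown intake rule {rule!r}")


# ---------------------------------------------------------------------------
# Exposure and hazard index
# ---------------------------------------------------------------------------


def compute_edi(dfi: float, dpc: float) -> float:
    """EDI (ng/person/day) = DFI (g/person/day) x DPC (ng/g)."""
    if dfi < 0 or dpc < 0:
        raise ExposureError("DFI and DPC must be non-negative")
    return dfi * dpc


def percent_adi(edi: float, tox: ToxRef) -> float:
    """%ADI = EDI / (ADI x body weight, in ng/person/day) x 100."""
    budget_ng = tox.adi * tox.body_weight * NG_PER_MG
    return edi / budget_ng * 100.0


def format_percent_adi(value: float) -> str:
    """Display rounding for hazard indices: 4 decimal places."""
    return f"{value:.4f}"


def run_scenarios(
    s: DetectionSummary,
    consumption: list[ConsumptionRecord],
    tox: ToxRef,
    *,
    threshold: float = RISK_THRESHOLD_DEFAULT,
    tier1_rule: str = "detected_species",
    tier3_rule: str = "sum_all_species",
) -> RiskAssessment:
    """Evaluate the full 3x3 scenario grid for one detection summary.

    Scenarios are ordered tier-major (1A, 1B, 1C, 2A, ... 3C) with ids 1–9.
    With zero detections options B and C are reported as not evaluable.
    """
    if tox.pesticide != s.pesticide:
        raise ExposureError(
            f"toxicology reference is for {tox.pesticide!r}, summary for {s.pesticide!r}"
        )
    estimators = {"A": dpc_option_a, "B": dpc_option_b, "C": dpc_option_c}
    scenarios: list[ScenarioResult] = []
    classes: list[str] = []
    for tier in (1, 2, 3):
        dfi = intake_for_tier(
            tier, s.species, consumption, tier1_rule=tier1_rule, tier3_rule=tier3_rule
        )
        for option in "ABC":
            sid = 3 * (tier - 1) + "ABC".index(option) + 1
            if option in ("B", "C") and not s.detections:
                scenarios.append(
                    ScenarioResult(
                        intake_tier=tier, dpc_option=option, scenario_id=sid, dfi=dfi,
                        evaluable=False,
                    )
                )
                classes.append("not evaluable")
                continue
            dpc = estimators[option](s)
            edi = compute_edi(dfi, dpc)
            pct = percent_adi(edi, tox)
            scenarios.append(
                ScenarioResult(
                    intake_tier=tier, dpc_option=option, scenario_id=sid,
                    dfi=dfi, dpc=dpc, edi=edi, percent_adi=pct,
                )
            )
            classes.append("minimal" if pct < threshold else "concern")
    return RiskAssessment(
        pesticide=s.pesticide, species=s.species, threshold=threshold,
        scenarios=tuple(scenarios), classification=tuple(classes),
    )


# ---------------------------------------------------------------------------
# Consumption imputation and monitoring summarization
# ---------------------------------------------------------------------------


def impute_consumption(
    table: list[ConsumptionRecord],
    gaps: list[str],
    similarity_groups: dict[str, list[str]],
) -> list[ConsumptionRecord]:
    """Fill missing species with half the minimum intake of similar species.

    For every species in ``gaps``, its similarity group (e.g. fish /
    crustacean / shellfish) must contain at least one observed species; the
    imputed mean and extreme are half the group minima, and the record is
    flagged as imputed.
    """
    observed = {c.species: c for c in table}
    group_of: dict[str, str] = {}
    for group, members in similarity_groups.items():
        for m in members:
            group_of[m] = group
    out = list(table)
    for species in gaps:
        if species in observed:
            continue
        group = group_of.get(species)
        if group is None:
            raise ExposureError(f"no similarity group assigned to {species!r}")
        peers = [
            observed[m] for m in similarity_groups[group] if m in observed and m != species
        ]
        if not peers:
            raise ExposureError(f"similarity group {group!r} has no observed member")
        out.append(
            ConsumptionRecord(
                species=species,
                mean_intake=min(p.mean_intake for p in peers) / 2.0,
                extreme_intake=min(p.extreme_intake for p in peers) / 2.0,
                imputed=True,
            )
        )
    return out


def detection_table(
    records: list[ResidueRecord], limits: list[LimitEntry]
) -> list[DetectionSummary]:
    """Summarize monitoring records per pesticide x species.

    ``n_tests`` is the number of records for the pair, detections are the
    uncensored concentrations, and the LOQ is resolved through the limit
    table (species, then matrix class, then default). Duplicate
    sample x pesticide rows are an integrity error; detections below their
    resolved LOQ are rejected.
    """
    seen = Counter((r.sample_id, r.pesticide) for r in records)
    dups = [k for k, n in seen.items() if n > 1]
    if dups:
        raise ExposureError(f"duplicate sample_id x pesticide record(s): {dups[:5]}")
    grouped: dict[tuple[str, str], list[ResidueRecord]] = {}
    for r in records:
        grouped.setdefault((r.pesticide, r.species), []).append(r)
    summaries = []
    for (pesticide, species), recs in sorted(grouped.items()):
        try:
            limit = resolve_limit(limits, pesticide, species)
        except KeyError as exc:
            raise ExposureError(str(exc)) from exc
        detections = tuple(r.concentration for r in recs if not r.censored)
        low = [c for c in detections if c < limit.loq]
        if low:
            raise ExposureError(
                f"{pesticide}/{species}: detection(s) below LOQ {limit.loq}: {low}"
            )
        summaries.append(
            DetectionSummary(
                pesticide=pesticide, species=species, n_tests=len(recs),
                detections=detections, loq=limit.loq,
            )
        )
    n_det = sum(len(s.detections) for s in summaries)
    logger.info(
        "summarized %d records into %d pesticide x species cells (%d detections)",
        len(records), len(summaries), n_det,
    )
    return summaries
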