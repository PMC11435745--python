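"""Method-validation statistics and Codex acceptance grading.

Implements the accuracy/precision, linearity, matrix-effect and sensitivity
metrics used to validate a multiresidue LC–MS/MS method:

* recovery (measured/spiked x 100) and %RSD from replicate spike experiments,
  using the sample (n−1) standard deviation;
* ordinary least-squares calibration fits and R²;
* matrix effect as the signed percent deviation of the matrix-matched
  calibration slope from the solvent slope (Matuszewski-style slope ratio);
* LOD/LOQ extrapolated from an observed chromatographic signal-to-noise
  ratio assuming S/N scales linearly with concentration near the LOQ;
* pass/fail grading against the Codex windows: recovery 70–120 % (inclusive),
  RSD ≤ 20 %, R² > 0.98.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats

from .io_model import CalibrationSeries, ValidationRun

# Codex acceptance windows for multiresidue methods.
RECOVERY_WINDOW = (70.0, 120.0)  # %, inclusive bounds
RSD_MAX = 20.0  # %
R_SQUARED_MIN = 0.98  # exclusive lower bound

# Matrix-effect interpretation bands (signed %).
ME_MINIMAL = 20.0  # |ME| <= 20  -> minimal interference
ME_STRONG = 50.0  # |ME| > 50  -> strong interference

SN_LOD = 3.0  # minimal signal-to-noise for detection
SN_LOQ = 10.0  # minimal signal-to-noise for quantification


class DomainError(ValueError):
    """A metric is undefined for the given inputs (e.g. zero mean response)."""


class ValidationSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    pesticide: str
    matrix: str
    level_class: str
    spike_level: float
    recovery_mean: float  # %
    recovery_sd: float = Field(ge=0)  # %
    rsd: float = Field(ge=0)  # %
    flags: dict[str, bool] = Field(default_factory=dict)


class LinearityResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    pesticide: str
    matrix_label: str
    slope: float  # response per ng/g
    intercept: float  # response units
    r_squared: float = Field(ge=0.0, le=1.0)


class MatrixEffectResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    pesticide: str
    matrix: str
    me: float  # signed %
    category: str  # minimal | medium | strong


def compute_recovery(run: ValidationRun) -> ValidationSummary:
    """Recovery and precision of one spiked-replicate experiment.

    recovery_mean = mean(replicates) / spike x 100
    recovery_sd   = sd(replicates)   / spike x 100   (sample SD, ddof=1)
    rsd           = sd(replicates)   / mean(replicates) x 100
    """
    reps = np.asarray(run.replicates, dtype=float)
    mean = reps.mean()
    sd = reps.std(ddof=1)
    if mean == 0.0:
        raise DomainError(
            f"{run.pesticide}/{run.matrix} at {run.level_class}: "
            "mean replicate response is zero, %RSD undefined"
        )
    return ValidationSummary(
        pesticide=run.pesticide,
        matrix=run.matrix,
        level_class=run.level_class,
        spike_level=run.spike_level,
        recovery_mean=mean / run.spike_level * 100.0,
        recovery_sd=sd / run.spike_level * 100.0,
        rsd=sd / mean * 100.0,
    )


def fit_calibration(series: CalibrationSeries) -> LinearityResult:
    """Unweighted OLS of response on concentration, with R² = 1 − SSres/SStot.

    A zero-variance response yields R² = 0 by convention (with a warning);
    a design with a single distinct level is rejected as degenerate.
    """
    pts = np.asarray(series.points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise DomainError(f"{series.pesticide}/{series.matrix_label}: degenerate design, all levels equal")
    if np.allclose(y, y[0]):
        warnings.warn(
            f"{series.pesticide}/{series.matrix_label}: constant response, R² set to 0",
            stacklevel=2,
        )
        return LinearityResult(
            pesticide=series.pesticide, matrix_label=series.matrix_label,
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
        )
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    return LinearityResult(
        pesticide=series.pesticide,
        matrix_label=series.matrix_label,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(max(r2, 0.0), 1.0),
    )


def me_category(me: float) -> str:
    """Interpretation band of a signed matrix effect."""
    if abs(me) <= ME_MINIMAL:
        return "minimal"
    if abs(me) > ME_STRONG:
        return "strong"
    return "medium"


def matrix_effect(matrix_fit: LinearityResult, solvent_fit: LinearityResult) -> MatrixEffectResult:
    """ME (%) = (slope_matrix / slope_solvent − 1) x 100.

    Positive values indicate ionization enhancement in matrix, negative
    values suppression.
    """
    if matrix_fit.pesticide != solvent_fit.pesticide:
        raise DomainError(
            f"pesticide mismatch: {matrix_fit.pesticide!r} vs {solvent_fit.pesticide!r}"
        )
    if solvent_fit.slope == 0.0:
        raise DomainError(f"{solvent_fit.pesticide}: solvent slope is zero, ME undefined")
    me = (matrix_fit.slope / solvent_fit.slope - 1.0) * 100.0
    matrix = matrix_fit.matrix_label.removeprefix("matrix:")
    return MatrixEffectResult(
        pesticide=matrix_fit.pesticide, matrix=matrix, me=me, category=me_category(me)
    )


def lod_loq_from_sn(conc: float, sn_observed: float) -> tuple[float, float]:
    """Extrapolate (LOD, LOQ) from one concentration with observed S/N.

    Assumes S/N grows linearly with concentration near the LOQ, so the
    concentration reaching S/N = 3 (LOD) or 10 (LOQ) is conc x target/observed.
    """
    if conc <= 0 or sn_observed <= 0:
        raise DomainError("concentration and S/N must be positive")
    return conc * SN_LOD / sn_observed, conc * SN_LOQ / sn_observed


def codex_flags(
    summary: ValidationSummary, lin: LinearityResult | None = None
) -> ValidationSummary:
    """Grade a validation summary against the Codex windows.

    Returns a copy with ``flags`` populated: ``recovery_pass`` (70–120 %,
    inclusive), ``rsd_pass`` (≤ 20 %) and, when a calibration fit is supplied,
    ``linearity_pass`` (R² > 0.98).
    """
    flags = {
        "recovery_pass": RECOVERY_WINDOW[0] <= summary.recovery_mean <= RECOVERY_WINDOW[1],
        "rsd_pass": summary.rsd <= RSD_MAX,
    }
    if lin is not None:
        flags["linearity_pass"] = lin.r_squared > R_SQUARED_MIN
    return summary.model_copy(update={"flags": flags})


def method_comparison_summary(
    table: pd.DataFrame,
    method_columns: list[str],
    thresholds: tuple[float, ...] = (60.0, 70.0),
) -> dict[str, dict[float, int]]:
    """Count pesticides with mean recovery strictly below each threshold, per method.

    ``table`` holds one row per pesticide with one mean-recovery column per
    method. Duplicate pesticide rows are rejected.
    """
    if table["pesticide"].duplicated().any():
        dups = table.loc[table["pesticide"].duplicated(), "pesticide"].tolist()
        raise DomainError(f"duplicate pesticide row(s): {dups}")
    out: dict[str, dict[float, int]] = {}
    for col in method_columns:
        if col not in table.columns:
            raise DomainError(f"no such method column {col!r}")
        vals = table[col].astype(float)
        out[col] = {thr: int((vals < thr).sum()) for thr in thresholds}
    return out


def validation_table_summary(table: pd.DataFrame) -> dict[str, float]:
    """Headline extrema of a full validation table (one row per pesticide x matrix).

    Reports the overall recovery range across the three spike levels, the
    worst LOQ-level precision, the worst linearity, and the sensitivity range.
    """
    rec = table[["recovery_loq", "recovery_10loq", "recovery_50loq"]].to_numpy(dtype=float)
    return {
        "recovery_min": float(rec.min()),
        "recovery_max": float(rec.max()),
        "rsd_loq_max": float(table["rsd_loq"].astype(float).max()),
        "r_squared_min": float(table["r_squared"].astype(float).min()),
        "lod_max": float(table["lod"].astype(float).max()),
        "lod_min": float(table["lod"].astype(float).min()),
        "loq_max": float(table["loq"].astype(float).max()),
        "loq_min": float(table["loq"].astype(float).min()),
    }
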