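"""TL-to-air-kerma conversion: calibration fits and background handling.

The reader integral ("TL value") of each chip is proportional to the dose it
absorbed; a straight-line calibration against ion-chamber air kerma turns TL
counts into mGy.  A control group kept outside the exposure room estimates
ambient background, which is subtracted from every reading before
conversion.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TLDReading",
    "CalibrationPoint",
    "CalibrationCurve",
    "CalibrationError",
    "fit_calibration",
    "subtract_background",
    "tl_to_kerma",
    "read_readings_csv",
    "write_readings_csv",
    "read_calibration_csv",
    "write_calibration_csv",
]

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class TLDReading:
    """One chip's reader integral plus its placement metadata."""

    chip_id: str
    group_id: str
    slice_index: int
    organ: str
    tl_value: float

    def __post_init__(self) -> None:
        if self.tl_value < 0:
            raise CalibrationError(
                f"chip {self.chip_id}: negative TL value {self.tl_value}"
            )


@dataclass(frozen=True)
class CalibrationPoint:
    tl_value: float
    kerma: float  # mGy
    kerma_sigma: float = 0.0  # mGy

    def __post_init__(self) -> None:
        if self.kerma < 0 or self.kerma_sigma < 0:
            raise CalibrationError("kerma and kerma_sigma must be >= 0")


@dataclass(frozen=True)
class CalibrationCurve:
    """Straight-line kerma(TL) map with parameter standard errors."""

    slope: float  # mGy per count
    intercept: float  # mGy
    slope_sigma: float = 0.0
    intercept_sigma: float = 0.0
    beam_quality: str = ""

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"slope must be positive, got {self.slope}")

    def kerma(self, tl: float) -> float:
        return self.slope * tl + self.intercept

    def tl(self, kerma: float) -> float:
        """Inverse map (used by the synthetic generator)."""
        return (kerma - self.intercept) / self.slope


def fit_calibration(
    points: list[CalibrationPoint],
    force_zero_intercept: bool = False,
    beam_quality: str = "",
) -> CalibrationCurve:
    """Fit kerma = slope*TL (+ intercept) by (weighted) least squares.

    If every point carries a positive ``kerma_sigma`` the fit is
    inverse-variance weighted and the parameter covariance is the exact
    known-sigma expression (X' W X)^-1.  Otherwise ordinary least squares is
    used and the covariance is scaled by the residual variance; with zero
    residual degrees of freedom the parameter sigmas are reported as 0.
    """
    n_min = 1 if force_zero_intercept else 2
    if len(points) < n_min:
        raise CalibrationError(
            f"need at least {n_min} calibration point(s), got {len(points)}"
        )
    tl = np.array([p.tl_value for p in points], dtype=float)
    k = np.array([p.kerma for p in points], dtype=float)
    sig = np.array([p.kerma_sigma for p in points], dtype=float)

    if not force_zero_intercept and np.ptp(tl) == 0:
        raise CalibrationError("all TL values equal: design matrix is singular")

    known_sigma = bool(np.all(sig > 0))
    w = 1.0 / sig**2 if known_sigma else np.ones_like(tl)

    if force_zero_intercept:
        sxx = float(np.sum(w * tl * tl))
        if sxx == 0:
            raise CalibrationError("all TL values are zero: cannot fit slope")
        slope = float(np.sum(w * tl * k) / sxx)
        if known_sigma:
            slope_var = 1.0 / sxx
        else:
            dof = len(points) - 1
            s2 = float(np.sum(w * (k - slope * tl) ** 2) / dof) if dof > 0 else 0.0
            slope_var = s2 / sxx
        intercept, intercept_sigma = 0.0, 0.0
        slope_sigma = float(np.sqrt(slope_var))
    else:
        X = np.column_stack([np.ones_like(tl), tl])
        xtwx = X.T @ (w[:, None] * X)
        xtwy = X.T @ (w * k)
        try:
            beta = np.linalg.solve(xtwx, xtwy)
            cov = np.linalg.inv(xtwx)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise CalibrationError("singular calibration design") from exc
        intercept, slope = float(beta[0]), float(beta[1])
        if not known_sigma:
            dof = len(points) - 2
            resid = k - X @ beta
            s2 = float(np.sum(w * resid**2) / dof) if dof > 0 else 0.0
            cov = cov * s2
        intercept_sigma = float(np.sqrt(max(cov[0, 0], 0.0)))
        slope_sigma = float(np.sqrt(max(cov[1, 1], 0.0)))

    if slope <= 0:
        raise CalibrationError(
            f"fitted slope {slope:.4g} is not positive; calibration data look corrupted"
        )
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        slope_sigma=slope_sigma,
        intercept_sigma=intercept_sigma,
        beam_quality=beam_quality,
    )


def subtract_background(
    readings: list[TLDReading], background_group: list[TLDReading]
) -> list[TLDReading]:
    """Subtract the control group's mean TL from every reading.

    Readings that would go negative are clamped to 0 (and logged): a chip
    cannot have absorbed less than ambient background.
    """
    if not background_group:
        raise CalibrationError("background group is empty")
    bg_mean = float(np.mean([r.tl_value for r in background_group]))
    out: list[TLDReading] = []
    for r in readings:
        corrected = r.tl_value - bg_mean
        if corrected < 0:
            log.warning(
                "chip %s: TL %.3g below background mean %.3g; clamped to 0",
                r.chip_id,
                r.tl_value,
                bg_mean,
            )
            corrected = 0.0
        out.append(dataclasses.replace(r, tl_value=corrected))
    return out


def tl_to_kerma(
    reading: TLDReading | float, curve: CalibrationCurve
) -> tuple[float, float]:
    """Convert one background-subtracted TL value to air kerma.

    Returns ``(kerma_mGy, variance_mGy2)``.  The variance is the first-order
    propagation of the curve's parameter sigmas; the TL value itself is
    treated as exact here (chip-to-chip scatter enters later through the
    group statistics).
    """
    tl = reading.tl_value if isinstance(reading, TLDReading) else float(reading)
    value = curve.kerma(tl)
    variance = (tl * curve.slope_sigma) ** 2 + curve.intercept_sigma**2
    return value, variance


# ---------------------------------------------------------------------------
# CSV I/O

_READING_COLS = ["chip_id", "group_id", "slice", "organ", "tl_value"]
_CAL_COLS = ["tl_value", "kerma_mGy", "kerma_sigma_mGy"]


def read_readings_csv(path: str | Path) -> list[TLDReading]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise CalibrationError(f"{path}: no readings")
    missing = set(_READING_COLS) - set(rows[0])
    if missing:
        raise CalibrationError(f"{path}: missing columns {sorted(missing)}")
    return [
        TLDReading(
            chip_id=row["chip_id"],
            group_id=row["group_id"],
            slice_index=int(row["slice"]),
            organ=row["organ"],
            tl_value=float(row["tl_value"]),
        )
        for row in rows
    ]


def write_readings_csv(readings: list[TLDReading], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_READING_COLS)
        for r in readings:
            writer.writerow(
                [r.chip_id, r.group_id, r.slice_index, r.organ, repr(r.tl_value)]
            )


def read_calibration_csv(path: str | Path) -> list[CalibrationPoint]:
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise CalibrationError(f"{path}: no calibration points")
    missing = {"tl_value", "kerma_mGy"} - set(rows[0])
    if missing:
        raise CalibrationError(f"{path}: missing columns {sorted(missing)}")
    return [
        CalibrationPoint(
            tl_value=float(row["tl_value"]),
            kerma=float(row["kerma_mGy"]),
            kerma_sigma=float(row.get("kerma_sigma_mGy") or 0.0),
        )
        for row in rows
    ]


def write_calibration_csv(points: list[CalibrationPoint], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CAL_COLS)
        for p in points:
            writer.writerow([repr(p.tl_value), repr(p.kerma), repr(p.kerma_sigma)])
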