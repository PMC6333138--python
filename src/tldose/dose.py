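"""Organ dose estimation from per-chip air kerma.

The chain is: per-chip kerma -> per-group mean/variance -> per-slice
inverse-variance weighted kerma -> per-slice organ dose via the
organ-to-air mass-energy absorption coefficient ratio -> whole-organ dose
as the mass-fraction-weighted sum over slices.  Uncertainties are first-order
Gaussian and reported at k=1 (one standard deviation).

Unit convention: group variances are computed from the chip-to-chip scatter
*in kerma units*.  The weighting is invariant under the constant calibration
slope, so this is equivalent to weighting by the scatter of the raw TL
values while keeping every intermediate in mGy.
"""

from __future__ import annotations

import json
import logging
import math
from collections import defaultdict
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .calibration import CalibrationCurve, TLDReading, subtract_background, tl_to_kerma
from .phantom import PhantomLayout, OrganFractionTable

__all__ = [
    "GroupKermaStat",
    "SliceKerma",
    "MassEnergyCoefficientSet",
    "PerSliceDose",
    "OrganDoseResult",
    "PipelineConfig",
    "PipelineResult",
    "DoseError",
    "group_stats",
    "slice_weighted_kerma",
    "slice_dose",
    "organ_dose",
    "run_pipeline",
    "load_coefficients",
    "DEFAULT_VARIANCE_FLOOR_FRAC",
]

log = logging.getLogger(__name__)

#: default fractional floor on group scatter: identical chips are assigned a
#: variance of (1% of the group mean)^2, a typical TLD batch reproducibility
DEFAULT_VARIANCE_FLOOR_FRAC = 0.01

# fallback used when even the floor degenerates (zero-kerma group); keeps the
# inverse-variance weights finite and equal
_EPS_VARIANCE = 1e-30


class DoseError(ValueError):
    pass


@dataclass(frozen=True)
class GroupKermaStat:
    """Mean and scatter of the chips co-located in one TLD group."""

    group_id: str
    slice_index: int
    mean_kerma: float  # mGy
    variance: float  # mGy^2, chip-to-chip scatter (floored if degenerate)
    n_chips: int
    floored: bool = False

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise DoseError(f"group {self.group_id}: negative variance")
        if self.n_chips < 1:
            raise DoseError(f"group {self.group_id}: n_chips < 1")


@dataclass(frozen=True)
class SliceKerma:
    slice_index: int
    kerma: float  # mGy
    variance: float  # mGy^2


@dataclass(frozen=True)
class MassEnergyCoefficientSet:
    """Organ and air mass-energy absorption coefficients at one tube voltage."""

    tube_voltage: str  # kV label, e.g. "120"
    organ: str
    mu_en_rho_organ: float  # cm^2/g
    mu_en_rho_air: float  # cm^2/g

    def __post_init__(self) -> None:
        if self.mu_en_rho_organ <= 0 or self.mu_en_rho_air <= 0:
            raise DoseError("mass-energy absorption coefficients must be positive")

    @property
    def ratio(self) -> float:
        return self.mu_en_rho_organ / self.mu_en_rho_air


@dataclass(frozen=True)
class PerSliceDose:
    slice_index: int
    dose: float
    sigma: float
    fraction: float


@dataclass
class OrganDoseResult:
    organ: str
    dose: float  # mGy
    sigma: float  # mGy, k=1
    per_slice: list[PerSliceDose]

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DoseError("sigma must be >= 0")
        recomputed = math.fsum(p.fraction * p.dose for p in self.per_slice)
        if abs(recomputed - self.dose) > 1e-12 * max(1.0, abs(self.dose)):
            raise DoseError(
                f"{self.organ}: dose {self.dose} inconsistent with per-slice "
                f"records (sum {recomputed})"
            )


def group_stats(
    kermas: list[float],
    group_id: str = "",
    slice_index: int = 0,
    variance_floor_frac: float = DEFAULT_VARIANCE_FLOOR_FRAC,
) -> GroupKermaStat:
    """Mean and unbiased sample variance of one group's chip kermas.

    A single-chip group, or a group of identical chips, has no measurable
    scatter; its variance is replaced by ``(variance_floor_frac * mean)^2``
    so the inverse-variance slice weighting stays finite.
    """
    if not len(kermas):
        raise DoseError(f"group {group_id!r}: no chip values")
    arr = np.asarray(kermas, dtype=float)
    mean = float(arr.mean())
    variance = float(arr.var(ddof=1)) if arr.size > 1 else 0.0
    floored = False
    if variance == 0.0:
        variance = (variance_floor_frac * mean) ** 2
        if variance == 0.0:
            variance = _EPS_VARIANCE
        floored = True
        log.debug(
            "group %s: zero scatter, variance floored to %.3g mGy^2",
            group_id,
            variance,
        )
    return GroupKermaStat(
        group_id=group_id,
        slice_index=slice_index,
        mean_kerma=mean,
        variance=variance,
        n_chips=int(arr.size),
        floored=floored,
    )


def slice_weighted_kerma(groups: list[GroupKermaStat]) -> SliceKerma:
    """Inverse-variance weighted mean kerma over the groups of one slice.

    kerma_i = sum_n(K_n / var_n) / sum_n(1 / var_n); the variance of the
    weighted mean is 1 / sum_n(1 / var_n).
    """
    if not groups:
        raise DoseError("no groups for slice")
    slice_indices = {g.slice_index for g in groups}
    if len(slice_indices) != 1:
        raise DoseError(f"groups span multiple slices: {sorted(slice_indices)}")
    if any(g.variance <= 0 for g in groups):
        raise DoseError("all group variances must be positive (apply the floor first)")
    weights = np.array([1.0 / g.variance for g in groups])
    means = np.array([g.mean_kerma for g in groups])
    kerma = float(np.sum(weights * means) / np.sum(weights))
    variance = float(1.0 / np.sum(weights))
    return SliceKerma(slice_index=groups[0].slice_index, kerma=kerma, variance=variance)


def slice_dose(
    slice_kerma: SliceKerma,
    coeffs: MassEnergyCoefficientSet,
    organ: str | None = None,
    tube_voltage: str | None = None,
) -> tuple[float, float]:
    """Convert slice air kerma to organ absorbed dose in that slice.

    D_i = K_i * (mu_en/rho)_organ / (mu_en/rho)_air.  The coefficient ratio
    is a tabulated constant, so the variance just scales by ratio^2.  If the
    run's organ / tube-voltage metadata is supplied it must match the
    coefficient set.
    """
    if organ is not None and organ != coeffs.organ:
        raise DoseError(
            f"coefficient set is for organ {coeffs.organ!r}, run is {organ!r}"
        )
    if tube_voltage is not None and str(tube_voltage) != str(coeffs.tube_voltage):
        raise DoseError(
            f"coefficient set is for {coeffs.tube_voltage} kV, run is {tube_voltage} kV"
        )
    ratio = coeffs.ratio
    return slice_kerma.kerma * ratio, slice_kerma.variance * ratio**2


def organ_dose(
    per_slice: dict[int, tuple[float, float]],
    fractions: OrganFractionTable,
) -> OrganDoseResult:
    """Mass-fraction weighted sum of slice doses: D = sum_i f_i * D_i.

    ``per_slice`` maps slice index to ``(dose, variance)``.  Every slice in
    the fraction table must be present.  The k=1 sigma is
    sqrt(sum_i f_i^2 * var_i).
    """
    missing = [r.slice_index for r in fractions.rows if r.slice_index not in per_slice]
    if missing:
        raise DoseError(
            f"{fractions.organ}: missing slice dose(s) for slice(s) {missing}"
        )
    records = [
        PerSliceDose(
            slice_index=r.slice_index,
            dose=per_slice[r.slice_index][0],
            sigma=math.sqrt(per_slice[r.slice_index][1]),
            fraction=r.fraction,
        )
        for r in fractions.rows
    ]
    dose = math.fsum(p.fraction * p.dose for p in records)
    variance = math.fsum(p.fraction**2 * p.sigma**2 for p in records)
    return OrganDoseResult(
        organ=fractions.organ,
        dose=dose,
        sigma=math.sqrt(variance),
        per_slice=records,
    )


@dataclass
class PipelineConfig:
    tube_voltage: str = "120"
    variance_floor_frac: float = DEFAULT_VARIANCE_FLOOR_FRAC


@dataclass
class PipelineResult:
    results: dict[str, OrganDoseResult]
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, organ: str) -> OrganDoseResult:
        return self.results[organ]


def run_pipeline(
    readings: list[TLDReading],
    background: list[TLDReading],
    curve: CalibrationCurve,
    layout: PhantomLayout,
    coeffs: dict[str, MassEnergyCoefficientSet],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """End-to-end dose estimation for every organ in the layout.

    Stages: background subtraction -> TL-to-kerma -> per-group statistics ->
    per-slice inverse-variance weighting -> coefficient-ratio conversion ->
    fraction-weighted organ dose.  The calibration-parameter uncertainty is
    attached at the slice level (it is common to all chips of a slice, so
    propagating it per chip and averaging would understate it); the group
    scatter enters through the weighted-mean variance.

    ``coeffs`` maps organ label to its coefficient set.  Returns one
    :class:`OrganDoseResult` per organ plus a provenance record of all
    intermediate values.
    """
    config = config or PipelineConfig()
    corrected = subtract_background(readings, background)
    bg_mean = float(np.mean([r.tl_value for r in background]))

    # group chips: group_id -> readings; track each group's slice/organ
    by_group: dict[str, list[TLDReading]] = defaultdict(list)
    for r in corrected:
        by_group[r.group_id].append(r)

    # organ -> slice -> list[GroupKermaStat]; also remember the mean corrected
    # TL per slice for the calibration-systematics term
    per_organ_slice: dict[str, dict[int, list[GroupKermaStat]]] = defaultdict(
        lambda: defaultdict(list)
    )
    slice_tl: dict[str, dict[int, list[float]]] = defaultdict(lambda: defaultdict(list))
    for group_id, members in sorted(by_group.items()):
        organs = {m.organ for m in members}
        slices = {m.slice_index for m in members}
        if len(organs) != 1 or len(slices) != 1:
            raise DoseError(
                f"group {group_id}: chips disagree on organ/slice "
                f"({sorted(organs)}, {sorted(slices)})"
            )
        organ, slc = members[0].organ, members[0].slice_index
        kermas = [tl_to_kerma(m, curve)[0] for m in members]
        stat = group_stats(
            kermas,
            group_id=group_id,
            slice_index=slc,
            variance_floor_frac=config.variance_floor_frac,
        )
        per_organ_slice[organ][slc].append(stat)
        slice_tl[organ][slc].extend(m.tl_value for m in members)

    results: dict[str, OrganDoseResult] = {}
    provenance: dict = {
        "background_mean_tl": bg_mean,
        "n_readings": len(readings),
        "curve": {
            "slope": curve.slope,
            "intercept": curve.intercept,
            "slope_sigma": curve.slope_sigma,
            "intercept_sigma": curve.intercept_sigma,
            "beam_quality": curve.beam_quality,
        },
        "config": {
            "tube_voltage": config.tube_voltage,
            "variance_floor_frac": config.variance_floor_frac,
        },
        "organs": {},
    }

    for organ, table in layout.tables.items():
        if organ not in coeffs:
            raise DoseError(f"no coefficient set supplied for organ {organ!r}")
        cset = coeffs[organ]
        organ_slices = per_organ_slice.get(organ, {})
        missing = [r.slice_index for r in table.rows if r.slice_index not in organ_slices]
        if missing:
            raise DoseError(f"{organ}: no readings for slice(s) {missing}")

        per_slice: dict[int, tuple[float, float]] = {}
        slice_log = []
        for row in table.rows:
            groups = organ_slices[row.slice_index]
            if len(groups) != row.n_groups:
                log.warning(
                    "%s slice %d: layout expects %d groups, found %d",
                    organ,
                    row.slice_index,
                    row.n_groups,
                    len(groups),
                )
            sk = slice_weighted_kerma(groups)
            # calibration systematics, evaluated at the slice mean TL
            mean_tl = float(np.mean(slice_tl[organ][row.slice_index]))
            cal_var = (mean_tl * curve.slope_sigma) ** 2 + curve.intercept_sigma**2
            sk = SliceKerma(sk.slice_index, sk.kerma, sk.variance + cal_var)
            d_i, var_i = slice_dose(
                sk, cset, organ=organ, tube_voltage=config.tube_voltage
            )
            per_slice[row.slice_index] = (d_i, var_i)
            slice_log.append(
                {
                    "slice": row.slice_index,
                    "kerma_mGy": sk.kerma,
                    "kerma_variance": sk.variance,
                    "calibration_variance": cal_var,
                    "dose_mGy": d_i,
                    "groups": [
                        {
                            "group_id": g.group_id,
                            "mean_kerma": g.mean_kerma,
                            "variance": g.variance,
                            "n_chips": g.n_chips,
                            "floored": g.floored,
                        }
                        for g in groups
                    ],
                }
            )
        result = organ_dose(per_slice, table)
        results[organ] = result
        provenance["organs"][organ] = {
            "dose_mGy": result.dose,
            "sigma_mGy": result.sigma,
            "coefficient_ratio": cset.ratio,
            "slices": slice_log,
        }

    return PipelineResult(results=results, provenance=provenance)


def load_coefficients(
    tube_voltage: int | str, organs: list[str] | None = None
) -> dict[str, MassEnergyCoefficientSet]:
    """Load packaged mass-energy absorption coefficients for one tube voltage.

    Returns a map organ -> coefficient set for the requested organs (default:
    all organs in the table).
    """
    text = (
        resources.files("tldose.data")
        .joinpath("mass_energy_coefficients.json")
        .read_text()
    )
    table = json.loads(text)
    kv = str(tube_voltage)
    if kv not in table:
        available = sorted(k for k in table if k != "comment")
        raise DoseError(f"no coefficients for {kv} kV; available: {available}")
    entry = table[kv]
    air = entry["air"]
    organs = organs or [k for k in entry if k != "air"]
    out = {}
    for organ in organs:
        if organ not in entry:
            raise DoseError(f"no {kv} kV coefficient for organ {organ!r}")
        out[organ] = MassEnergyCoefficientSet(
            tube_voltage=kv,
            organ=organ,
            mu_en_rho_organ=entry[organ],
            mu_en_rho_air=air,
        )
    return out
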