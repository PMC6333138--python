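"""Synthetic inputs with the statistical structure the pipeline assumes.

Given a truth scenario (per-slice organ doses, a calibration curve, and the
coefficient ratio) the generator inverts the dose chain to produce raw TL
readings with multiplicative Gaussian chip noise, a background control
group, and noisy calibration sets.  All randomness flows from the explicit
seed in the noise model; no global state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationCurve, CalibrationPoint, TLDReading
from .dose import MassEnergyCoefficientSet
from .phantom import PhantomLayout
from .protocol import ProtocolConfig

__all__ = [
    "NoiseModel",
    "TruthScenario",
    "TCMProfile",
    "SynthError",
    "generate_readings",
    "generate_calibration_set",
    "generate_tcm_profile",
]

N_CHIPS_PER_GROUP = 3


class SynthError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes for the generator.

    chip_cv: fractional scatter per chip TL value (multiplicative Gaussian);
    background_tl: mean TL of unexposed chips (added to every reading);
    background_cv: fractional scatter of the background chips;
    calib_cv: fractional scatter of calibration kerma measurements.
    """

    chip_cv: float = 0.05
    background_tl: float = 0.0
    background_cv: float = 0.0
    calib_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.chip_cv, self.background_cv, self.calib_cv) < 0:
            raise SynthError("coefficients of variation must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TruthScenario:
    """Ground truth for one synthetic irradiation."""

    layout: PhantomLayout
    protocol: ProtocolConfig
    true_slice_doses: dict[int, float]  # slice -> organ dose in that slice, mGy
    coeffs: dict[str, MassEnergyCoefficientSet]  # organ -> coefficient set
    curve: CalibrationCurve

    def __post_init__(self) -> None:
        for organ, table in self.layout.tables.items():
            missing = [
                r.slice_index
                for r in table.rows
                if r.slice_index not in self.true_slice_doses
            ]
            if missing:
                raise SynthError(f"{organ}: no truth dose for slice(s) {missing}")
            if organ not in self.coeffs:
                raise SynthError(f"no coefficient set for organ {organ!r}")

    @classmethod
    def flat(
        cls,
        layout: PhantomLayout,
        protocol: ProtocolConfig,
        dose: float | dict[str, float],
        coeffs: dict[str, MassEnergyCoefficientSet],
        curve: CalibrationCurve,
    ) -> "TruthScenario":
        """Uniform truth: the same dose in every slice of each organ.

        ``dose`` may be a single value or a per-organ map.  Because the mass
        fractions sum to 1, the resulting whole-organ dose equals the flat
        slice dose.
        """
        doses: dict[int, float] = {}
        for organ, table in layout.tables.items():
            d = dose[organ] if isinstance(dose, dict) else dose
            for row in table.rows:
                doses[row.slice_index] = d
        return cls(
            layout=layout,
            protocol=protocol,
            true_slice_doses=doses,
            coeffs=coeffs,
            curve=curve,
        )

    def organ_truth(self, organ: str) -> float:
        """Whole-organ truth dose implied by the per-slice truths."""
        table = self.layout.tables[organ]
        return math.fsum(
            r.fraction * self.true_slice_doses[r.slice_index] for r in table.rows
        )


def generate_readings(
    scenario: TruthScenario,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> tuple[list[TLDReading], list[TLDReading], dict]:
    """Emit raw TL readings, a background control group, and a truth record.

    For every layout row, exactly ``n_groups`` three-chip groups are placed
    in that slice.  Each chip's TL is the noise-free inversion of the dose
    chain — dose -> air kerma via the coefficient ratio, kerma -> TL via the
    inverse calibration line — perturbed multiplicatively by
    ``Normal(0, chip_cv)`` and shifted by the background TL.  Deterministic
    for a fixed seed.
    """
    rng = rng if rng is not None else noise.rng()
    readings: list[TLDReading] = []
    for organ in sorted(scenario.layout.tables):
        table = scenario.layout.tables[organ]
        ratio = scenario.coeffs[organ].ratio
        for row in table.rows:
            dose = scenario.true_slice_doses[row.slice_index]
            kerma = dose / ratio
            tl_true = scenario.curve.tl(kerma)
            if tl_true < 0:
                raise SynthError(
                    f"{organ} slice {row.slice_index}: truth dose {dose} maps to "
                    f"negative TL under the given curve"
                )
            for g in range(1, row.n_groups + 1):
                group_id = f"{organ[:2].upper()}S{row.slice_index:02d}G{g:02d}"
                eps = rng.normal(0.0, noise.chip_cv, size=N_CHIPS_PER_GROUP)
                for c, e in enumerate(eps, start=1):
                    tl = max(tl_true * (1.0 + e) + noise.background_tl, 0.0)
                    readings.append(
                        TLDReading(
                            chip_id=f"{group_id}C{c}",
                            group_id=group_id,
                            slice_index=row.slice_index,
                            organ=organ,
                            tl_value=float(tl),
                        )
                    )

    background: list[TLDReading] = []
    bg_eps = rng.normal(0.0, noise.background_cv, size=N_CHIPS_PER_GROUP)
    for c, e in enumerate(bg_eps, start=1):
        tl = max(noise.background_tl * (1.0 + e), 0.0)
        background.append(
            TLDReading(
                chip_id=f"BGC{c}",
                group_id="BG",
                slice_index=0,
                organ="background",
                tl_value=float(tl),
            )
        )

    truth = {
        "phantom_id": scenario.layout.phantom_id,
        "protocol": scenario.protocol.name,
        "organ_doses_mGy": {
            organ: scenario.organ_truth(organ) for organ in scenario.layout.tables
        },
        "true_slice_doses_mGy": {
            str(k): v for k, v in sorted(scenario.true_slice_doses.items())
        },
        "noise": {
            "chip_cv": noise.chip_cv,
            "background_tl": noise.background_tl,
            "background_cv": noise.background_cv,
            "seed": noise.seed,
        },
    }
    return readings, background, truth


def generate_calibration_set(
    curve: CalibrationCurve,
    n_points: int,
    noise: NoiseModel,
    tl_range: tuple[float, float] = (100.0, 3000.0),
    rng: np.random.Generator | None = None,
) -> list[CalibrationPoint]:
    """Synthetic calibration exposures along the curve.

    TL values are spaced evenly over ``tl_range``; each kerma is the curve
    value perturbed multiplicatively by ``Normal(0, calib_cv)``, with
    ``kerma_sigma = calib_cv * kerma``.
    """
    if n_points < 2:
        raise SynthError(f"need at least 2 calibration points, got {n_points}")
    rng = rng if rng is not None else noise.rng()
    tls = np.linspace(tl_range[0], tl_range[1], n_points)
    eps = rng.normal(0.0, noise.calib_cv, size=n_points) if noise.calib_cv else 0.0
    points = []
    for i, tl in enumerate(tls):
        k_true = curve.kerma(float(tl))
        k = k_true * (1.0 + (eps[i] if noise.calib_cv else 0.0))
        points.append(
            CalibrationPoint(
                tl_value=float(tl),
                kerma=float(max(k, 0.0)),
                kerma_sigma=float(noise.calib_cv * k_true),
            )
        )
    return points


@dataclass
class TCMProfile:
    positions: np.ndarray  # mm along the couch, neck at 0
    mA: np.ndarray
    mean_mA: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_mA = float(np.mean(self.mA))


def generate_tcm_profile(
    positions: np.ndarray | list[float],
    base_mA: float,
    anatomy: str,
    bounds: tuple[float, float],
) -> TCMProfile:
    """Qualitative longitudinal tube-current modulation profile.

    ``anatomy`` selects the shape: ``patient`` profiles start high at the
    neck (position 0) and fall toward the lungs; ``phantom`` profiles start
    low at the neck and rise toward the lungs; ``constant`` is flat at
    ``base_mA``.  All values are clipped to ``bounds``.  No attenuation
    physics — this is a test stimulus generator.
    """
    lo, hi = bounds
    if lo > hi:
        raise SynthError(f"inverted mA bounds ({lo}, {hi})")
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        raise SynthError("empty position grid")
    span = np.ptp(pos)
    t = (pos - pos.min()) / span if span > 0 else np.zeros_like(pos)
    if anatomy == "constant":
        mA = np.full_like(pos, base_mA)
    elif anatomy == "phantom":
        mA = lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * t))
    elif anatomy == "patient":
        mA = hi - (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * t))
    else:
        raise SynthError(f"unknown anatomy {anatomy!r}")
    return TCMProfile(positions=pos, mA=np.clip(mA, lo, hi))
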