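"""Protocol-level dosimetric metrics.

Normalized dose metrics (dose per mAs and per effective mAs), percent dose
reductions between protocols, scout-scan dose fractions, and the
CTDIvol-coefficient cross-method organ dose estimate.  All uncertainties are
first-order Gaussian with independent inputs, reported at k=1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "ProtocolConfig",
    "OrganCoefficient",
    "ProtocolError",
    "mAs",
    "effective_mAs",
    "dose_per_mAs",
    "percent_decrease",
    "spr_fraction",
    "ctdi_based_dose",
    "relative_difference",
    "load_packaged_protocols",
    "load_packaged_organ_coefficient",
]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition parameters and console dose indices for one protocol."""

    name: str
    tube_voltage: int  # kV
    tube_current: float | tuple[float, float]  # mA, fixed or (min, max) under TCM
    rotation_time: float | None = None  # s
    pitch: float | None = None
    collimation: str | None = None
    ctdi_vol: float | None = None  # mGy
    dlp: float | None = None  # mGy cm
    tcm_mode: str = "none"  # none | longitudinal | longitudinal+angular

    def __post_init__(self) -> None:
        if self.pitch is not None and self.pitch <= 0:
            raise ProtocolError(f"{self.name}: pitch must be > 0")
        if self.rotation_time is not None and self.rotation_time <= 0:
            raise ProtocolError(f"{self.name}: rotation time must be > 0")
        if self.ctdi_vol is not None and self.ctdi_vol < 0:
            raise ProtocolError(f"{self.name}: CTDIvol must be >= 0")
        if self.tcm_mode not in ("none", "longitudinal", "longitudinal+angular"):
            raise ProtocolError(f"{self.name}: unknown tcm_mode {self.tcm_mode!r}")

    @property
    def is_tcm(self) -> bool:
        return self.tcm_mode != "none" or isinstance(self.tube_current, tuple)


@dataclass(frozen=True)
class OrganCoefficient:
    """Organ dose per unit CTDIvol for a reference-size patient."""

    organ: str
    tube_voltage: int
    f_organ: float
    f_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.f_organ <= 0:
            raise ProtocolError("f_organ must be positive")


def mAs(protocol: ProtocolConfig) -> float:
    """Tube current-time product of a fixed-current protocol."""
    if protocol.is_tcm:
        raise ProtocolError(
            f"{protocol.name}: mAs is undefined under TCM; compute an effective "
            "mAs from the modulation profile instead"
        )
    if protocol.rotation_time is None:
        raise ProtocolError(f"{protocol.name}: rotation time not set")
    return float(protocol.tube_current) * protocol.rotation_time


def effective_mAs(mAs_value: float, pitch: float) -> float:
    """Effective tube current-time product for a helical scan: mAs / pitch."""
    if pitch <= 0:
        raise ProtocolError("pitch must be > 0")
    return mAs_value / pitch


def dose_per_mAs(
    dose: float,
    protocol: ProtocolConfig,
    effective: bool = False,
    dose_sigma: float = 0.0,
    mAs_override: float | None = None,
) -> tuple[float, float]:
    """Dose normalized by (effective) mAs, with propagated sigma.

    ``mAs_override`` substitutes an externally reported current-time product
    (e.g. a console-rounded value) for the rotation-time product.
    """
    m = mAs_override if mAs_override is not None else mAs(protocol)
    if effective:
        if protocol.pitch is None:
            raise ProtocolError(f"{protocol.name}: pitch not set")
        m = effective_mAs(m, protocol.pitch)
    return dose / m, dose_sigma / m


def percent_decrease(
    reference_dose: float,
    new_dose: float,
    reference_sigma: float = 0.0,
    new_sigma: float = 0.0,
) -> tuple[float, float]:
    """Percent reduction of ``new_dose`` relative to ``reference_dose``.

    100 * (ref - new) / ref; positive when the new protocol lowers the dose.
    """
    if reference_dose <= 0:
        raise ProtocolError("reference dose must be positive")
    value = (reference_dose - new_dose) / reference_dose * 100.0
    sigma = 100.0 * math.hypot(
        new_dose * reference_sigma / reference_dose**2,
        new_sigma / reference_dose,
    )
    return value, sigma


def spr_fraction(spr_dose: float, protocol_dose: float) -> float:
    """Scout-scan dose as a percentage of the protocol organ dose."""
    if protocol_dose <= 0:
        raise ProtocolError("protocol dose must be positive")
    return spr_dose / protocol_dose * 100.0


def ctdi_based_dose(
    coef: OrganCoefficient, protocol: ProtocolConfig
) -> tuple[float, float]:
    """Organ dose estimated from the console CTDIvol: f_organ * CTDIvol."""
    if coef.tube_voltage != protocol.tube_voltage:
        raise ProtocolError(
            f"coefficient is for {coef.tube_voltage} kV but protocol "
            f"{protocol.name} uses {protocol.tube_voltage} kV"
        )
    if protocol.ctdi_vol is None:
        raise ProtocolError(f"{protocol.name}: CTDIvol not set")
    return coef.f_organ * protocol.ctdi_vol, coef.f_sigma * protocol.ctdi_vol


def relative_difference(
    tld_dose: float,
    ctdi_dose: float,
    tld_sigma: float = 0.0,
    ctdi_sigma: float = 0.0,
) -> tuple[float, float]:
    """Percent difference of the CTDIvol-based estimate from the measured dose.

    100 * (ctdi - tld) / ctdi; positive when the CTDIvol-based estimate is
    the larger of the two.
    """
    if ctdi_dose <= 0:
        raise ProtocolError("CTDIvol-based dose must be positive")
    value = (ctdi_dose - tld_dose) / ctdi_dose * 100.0
    sigma = 100.0 * math.hypot(
        tld_dose * ctdi_sigma / ctdi_dose**2,
        tld_sigma / ctdi_dose,
    )
    return value, sigma


# ---------------------------------------------------------------------------
# packaged fixtures

PACKAGED_PROTOCOL_SETS = ("adult", "pediatric")


def _protocol_from_dict(doc: dict) -> ProtocolConfig:
    current = doc["tube_current"]
    if isinstance(current, list):
        current = tuple(current)
    return ProtocolConfig(
        name=doc["name"],
        tube_voltage=int(doc["tube_voltage"]),
        tube_current=current,
        rotation_time=doc.get("rotation_time"),
        pitch=doc.get("pitch"),
        collimation=doc.get("collimation"),
        ctdi_vol=doc.get("ctdi_vol"),
        dlp=doc.get("dlp"),
        tcm_mode=doc.get("tcm_mode", "none"),
    )


def load_protocols(path: str | Path) -> dict[str, ProtocolConfig]:
    """Load a protocol-set JSON file: {protocols: [{name, tube_voltage, ...}]}."""
    doc = json.loads(Path(path).read_text())
    return {p["name"]: _protocol_from_dict(p) for p in doc["protocols"]}


def load_packaged_protocols(which: str) -> dict[str, ProtocolConfig]:
    """Load the packaged ``adult`` or ``pediatric`` protocol set."""
    if which not in PACKAGED_PROTOCOL_SETS:
        raise ProtocolError(
            f"unknown protocol set {which!r}; have {PACKAGED_PROTOCOL_SETS}"
        )
    text = (
        resources.files("tldose.data").joinpath(f"protocols_{which}.json").read_text()
    )
    doc = json.loads(text)
    return {p["name"]: _protocol_from_dict(p) for p in doc["protocols"]}


def load_packaged_organ_coefficient(organ: str, tube_voltage: int) -> OrganCoefficient:
    """Load the packaged dose-to-CTDIvol coefficient for one organ/voltage."""
    text = (
        resources.files("tldose.data").joinpath("organ_coefficients.json").read_text()
    )
    table = json.loads(text)
    try:
        entry = table[organ][str(tube_voltage)]
    except KeyError as exc:
        raise ProtocolError(
            f"no packaged coefficient for {organ!r} at {tube_voltage} kV"
        ) from exc
    return OrganCoefficient(
        organ=organ,
        tube_voltage=tube_voltage,
        f_organ=entry["f_organ"],
        f_sigma=entry.get("f_sigma", 0.0),
    )
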