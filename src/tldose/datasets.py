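"""Accessors for the packaged study tables (measured doses, references)."""

from __future__ import annotations

import csv
import io
from importlib import resources

from .comparison import DosePair

__all__ = ["load_measured_doses", "load_adult_dose_pairs"]


def _read_packaged_csv(name: str) -> list[dict]:
    text = resources.files("tldose.data").joinpath(name).read_text()
    return list(csv.DictReader(io.StringIO(text)))


def load_measured_doses(which: str) -> dict[tuple[str, str], dict]:
    """Measured organ doses for the ``adult`` or ``pediatric`` study.

    Returns a map ``(protocol, organ) -> record`` with ``dose`` and ``sigma``
    in mGy; adult records also carry the simulated reference ``sim`` (or
    None), pediatric records the console-reported current-time product
    ``mAs`` (or None).
    """
    if which == "adult":
        rows = _read_packaged_csv("adult_doses.csv")
        return {
            (r["protocol"], r["organ"]): {
                "dose": float(r["dose_mGy"]),
                "sigma": float(r["sigma_mGy"]),
                "sim": float(r["sim_mGy"]) if r["sim_mGy"] else None,
            }
            for r in rows
        }
    if which == "pediatric":
        rows = _read_packaged_csv("pediatric_doses.csv")
        return {
            (r["protocol"], r["organ"]): {
                "dose": float(r["dose_mGy"]),
                "sigma": float(r["sigma_mGy"]),
                "mAs": float(r["mAs_printed"]) if r["mAs_printed"] else None,
            }
            for r in rows
        }
    raise ValueError(f"unknown dose table {which!r}")


def load_adult_dose_pairs() -> list[DosePair]:
    """Adult measured/simulated dose pairs (excludes the scout scan, which
    has no simulated reference)."""
    doses = load_measured_doses("adult")
    return [
        DosePair(label=proto, d_exp=rec["dose"], d_sim=rec["sim"], d_exp_sigma=rec["sigma"])
        for (proto, organ), rec in doses.items()
        if rec["sim"] is not None
    ]
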