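"""Agreement between measured and simulated organ doses.

Per-pair percent differences (simulated minus measured, relative to
simulated) and a Bland-Altman analysis of those differences: bias, sample
SD, and bias +/- 1.96 SD limits of agreement, plotted against the pair
means.  Simulated reference doses carry no stated uncertainty and are
treated as exact.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DosePair",
    "AgreementResult",
    "ComparisonError",
    "percent_difference",
    "bland_altman",
    "within_band",
    "plot_bland_altman",
    "read_pairs_csv",
    "write_agreement_csv",
]


class ComparisonError(ValueError):
    pass


@dataclass(frozen=True)
class DosePair:
    """One protocol/organ dose measured two ways."""

    label: str
    d_exp: float  # mGy, measured
    d_sim: float  # mGy, simulated reference
    d_exp_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.d_sim <= 0:
            raise ComparisonError(f"{self.label}: simulated dose must be positive")


@dataclass
class AgreementResult:
    labels: list[str]
    per_pair_delta: list[float]  # percent
    mean_axis: list[float]  # mGy, (d_sim + d_exp) / 2
    bias: float  # percent, mean of deltas
    sd: float  # percent, sample SD of deltas
    loa_low: float
    loa_high: float

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ComparisonError("limits of agreement must bracket the bias")


def percent_difference(pair: DosePair) -> tuple[float, float]:
    """Percent difference of measured from simulated: 100*(sim - exp)/sim.

    Positive when the simulation overestimates the measurement.  The sigma
    propagates the measured dose's uncertainty only.
    """
    delta = (pair.d_sim - pair.d_exp) / pair.d_sim * 100.0
    sigma = pair.d_exp_sigma / pair.d_sim * 100.0
    return delta, sigma


def bland_altman(pairs: list[DosePair]) -> AgreementResult:
    """Bland-Altman agreement over a set of dose pairs.

    Bias is the arithmetic mean of the per-pair percent differences, the SD
    is their sample (n-1) standard deviation, and the 95% limits of
    agreement are bias +/- 1.96*SD.
    """
    if len(pairs) < 2:
        raise ComparisonError("need at least 2 pairs (SD undefined otherwise)")
    deltas = [percent_difference(p)[0] for p in pairs]
    arr = np.asarray(deltas)
    bias = float(arr.mean())
    sd = float(arr.std(ddof=1))
    return AgreementResult(
        labels=[p.label for p in pairs],
        per_pair_delta=deltas,
        mean_axis=[(p.d_sim + p.d_exp) / 2.0 for p in pairs],
        bias=bias,
        sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def within_band(result: AgreementResult, band: float = 20.0) -> dict:
    """Flag each |delta| against a tolerance band (percent)."""
    if band <= 0:
        raise ComparisonError("band must be positive")
    flags = [abs(d) <= band for d in result.per_pair_delta]
    return {
        "band": band,
        "all_within": all(flags),
        "max_abs_delta": max(abs(d) for d in result.per_pair_delta),
        "flags": dict(zip(result.labels, flags)),
    }


def plot_bland_altman(result: AgreementResult, path: str | Path) -> None:
    """Write a Bland-Altman scatter (pair mean vs percent difference) with
    bias and limit lines."""
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 4))
    ax = fig.add_subplot(111)
    ax.scatter(result.mean_axis, result.per_pair_delta, color="k", zorder=3)
    ax.axhline(result.bias, color="tab:blue", label=f"bias {result.bias:.1f}%")
    for limit in (result.loa_low, result.loa_high):
        ax.axhline(limit, color="gray", linestyle="--")
    ax.set_xlabel("mean dose (mGy)")
    ax.set_ylabel("percent difference (%)")
    ax.legend(loc="best")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def read_pairs_csv(path: str | Path) -> list[DosePair]:
    """Read pairs from CSV with columns label,d_exp_mGy,d_exp_sigma,d_sim_mGy."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ComparisonError(f"{path}: no pairs")
    missing = {"label", "d_exp_mGy", "d_sim_mGy"} - set(rows[0])
    if missing:
        raise ComparisonError(f"{path}: missing columns {sorted(missing)}")
    return [
        DosePair(
            label=row["label"],
            d_exp=float(row["d_exp_mGy"]),
            d_sim=float(row["d_sim_mGy"]),
            d_exp_sigma=float(row.get("d_exp_sigma") or 0.0),
        )
        for row in rows
    ]


def write_agreement_csv(result: AgreementResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "mean_mGy", "delta_pct"])
        for label, mean, delta in zip(
            result.labels, result.mean_axis, result.per_pair_delta
        ):
            writer.writerow([label, f"{mean:.4f}", f"{delta:.4f}"])
        writer.writerow([])
        writer.writerow(["bias_pct", f"{result.bias:.4f}"])
        writer.writerow(["sd_pct", f"{result.sd:.4f}"])
        writer.writerow(["loa_low_pct", f"{result.loa_low:.4f}"])
        writer.writerow(["loa_high_pct", f"{result.loa_high:.4f}"])
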