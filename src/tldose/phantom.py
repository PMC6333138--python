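"""Phantom slice layouts: organ mass fractions and TLD group placements.

A layout couples, per organ, the fraction of the organ's mass contained in
each physical phantom slice with the number of three-chip TLD groups placed
in that slice.  Fractions weight per-slice doses into the whole-organ dose,
so they must sum to 1 over the slices that contain the organ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "FractionRow",
    "OrganFractionTable",
    "FractionReport",
    "PhantomLayout",
    "LayoutError",
    "LayoutValidationError",
    "validate_fractions",
    "load_layout",
    "load_packaged_layout",
    "save_layout",
    "PACKAGED_LAYOUTS",
]

#: strict tolerance used for packaged fixtures (tables transcribed exactly)
FRACTION_SUM_TOL = 1e-9
#: softer default for user-supplied files, whose fractions are typically
#: rounded to two decimals
USER_FRACTION_SUM_TOL = 0.005

PACKAGED_LAYOUTS = ("adult_rando", "pediatric_cirs")


class LayoutError(ValueError):
    """Malformed layout document (missing/ill-typed field)."""


class LayoutValidationError(ValueError):
    """Structurally valid layout that violates a physical invariant."""


@dataclass(frozen=True)
class FractionRow:
    """One slice's entry: mass fraction f_i and TLD group count."""

    slice_index: int
    fraction: float
    n_groups: int

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise LayoutValidationError(
                f"slice {self.slice_index}: fraction {self.fraction} not in (0, 1]"
            )
        if self.n_groups < 1:
            raise LayoutValidationError(
                f"slice {self.slice_index}: n_groups {self.n_groups} < 1"
            )


@dataclass
class FractionReport:
    """Outcome of checking an organ fraction table; callers decide severity."""

    passed: bool
    total: float
    offending_rows: list[str] = field(default_factory=list)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        msg = f"{status}: fraction sum {self.total:.6f}"
        if self.offending_rows:
            msg += "; " + "; ".join(self.offending_rows)
        return msg


@dataclass
class OrganFractionTable:
    phantom_id: str
    organ: str
    rows: list[FractionRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise LayoutValidationError(f"{self.organ}: empty fraction table")
        indices = [r.slice_index for r in self.rows]
        if sorted(set(indices)) != indices:
            raise LayoutValidationError(
                f"{self.organ}: slice indices must be unique and strictly "
                f"increasing, got {indices}"
            )

    @property
    def fraction_sum(self) -> float:
        return math.fsum(r.fraction for r in self.rows)

    @property
    def n_groups_total(self) -> int:
        return sum(r.n_groups for r in self.rows)

    @property
    def slice_indices(self) -> list[int]:
        return [r.slice_index for r in self.rows]

    def fraction_of(self, slice_index: int) -> float:
        for r in self.rows:
            if r.slice_index == slice_index:
                return r.fraction
        raise KeyError(slice_index)


def validate_fractions(
    table: OrganFractionTable, tol: float = FRACTION_SUM_TOL
) -> FractionReport:
    """Check that the mass fractions form a proper partition of the organ.

    Passes iff the fractions sum to 1 within ``tol`` and every row is
    positive (row positivity is already enforced at construction; rows that
    slipped through a hand-built table are listed anyway).
    """
    offending = [
        f"slice {r.slice_index}: fraction {r.fraction} not positive"
        for r in table.rows
        if r.fraction <= 0
    ]
    total = table.fraction_sum
    passed = not offending and abs(total - 1.0) <= tol
    if abs(total - 1.0) > tol:
        offending.append(f"fraction sum {total:.6f} differs from 1 by more than {tol}")
    return FractionReport(passed=passed, total=total, offending_rows=offending)


@dataclass
class PhantomLayout:
    """All organ fraction tables for one physical phantom."""

    phantom_id: str
    tables: dict[str, OrganFractionTable]

    @property
    def organs(self) -> list[str]:
        return list(self.tables)

    @property
    def total_groups(self) -> int:
        return sum(t.n_groups_total for t in self.tables.values())

    def validate(self, tol: float = USER_FRACTION_SUM_TOL) -> None:
        """Raise :class:`LayoutValidationError` on the first failing table."""
        for organ, table in self.tables.items():
            report = validate_fractions(table, tol=tol)
            if not report.passed:
                raise LayoutValidationError(f"{self.phantom_id}/{organ}: {report}")

    def to_dict(self) -> dict:
        return {
            "phantom_id": self.phantom_id,
            "organs": [
                {
                    "organ": organ,
                    "rows": [
                        {"slice": r.slice_index, "f": r.fraction, "n_groups": r.n_groups}
                        for r in table.rows
                    ],
                }
                for organ, table in self.tables.items()
            ],
        }


def _layout_from_dict(doc: dict, source: str) -> PhantomLayout:
    try:
        phantom_id = doc["phantom_id"]
        organ_docs = doc["organs"]
    except (KeyError, TypeError) as exc:
        raise LayoutError(f"{source}: missing field {exc}") from exc
    tables: dict[str, OrganFractionTable] = {}
    for odoc in organ_docs:
        try:
            organ = odoc["organ"]
            rows = [
                FractionRow(
                    slice_index=int(row["slice"]),
                    fraction=float(row["f"]),
                    n_groups=int(row["n_groups"]),
                )
                for row in odoc["rows"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise LayoutError(
                f"{source}: malformed organ entry ({exc!r})"
            ) from exc
        if organ in tables:
            raise LayoutError(f"{source}: duplicate organ {organ!r}")
        tables[organ] = OrganFractionTable(phantom_id=phantom_id, organ=organ, rows=rows)
    return PhantomLayout(phantom_id=phantom_id, tables=tables)


def load_layout(
    path: str | Path, fraction_tol: float = USER_FRACTION_SUM_TOL
) -> PhantomLayout:
    """Load and validate a phantom layout JSON document.

    The dialect is ``{phantom_id, organs: [{organ, rows: [{slice, f,
    n_groups}]}]}``.  ``fraction_tol`` bounds how far each organ's fraction
    sum may stray from 1 (printed tables are rounded, so the default is
    looser than the fixture tolerance).
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LayoutError(f"{path}: not valid JSON ({exc})") from exc
    layout = _layout_from_dict(doc, str(path))
    layout.validate(tol=fraction_tol)
    return layout


def load_packaged_layout(name: str) -> PhantomLayout:
    """Load one of the packaged phantom layouts (``adult_rando`` or
    ``pediatric_cirs``), validated at the strict fixture tolerance."""
    if name not in PACKAGED_LAYOUTS:
        raise LayoutError(f"unknown packaged layout {name!r}; have {PACKAGED_LAYOUTS}")
    text = resources.files("tldose.data").joinpath(f"{name}.json").read_text()
    layout = _layout_from_dict(json.loads(text), f"packaged:{name}")
    layout.validate(tol=FRACTION_SUM_TOL)
    return layout


def save_layout(layout: PhantomLayout, path: str | Path) -> None:
    Path(path).write_text(json.dumps(layout.to_dict(), indent=2) + "\n")
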