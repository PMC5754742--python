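"""Regenerate the tumor-size / ctDNA-abundance reference table and audit it.

The package's central artifact is a table running from 27 mm tumors down
to ~1 mm: for each size, the weight, volume, cell count, plasma mutant-DNA
fraction, and expected mutant genome copies per 4 mL plasma draw, plus
literature annotations (chance of progression, mammographic screening
sensitivity) that are carried through verbatim, never computed.

A transcription of the published version of this table ships as a fixture
(:data:`PRINTED_TABLE1`), including its rounding quirks, and
:func:`compare_to_printed` produces a cell-by-cell audit.  The published
rows are keyed by tumor mass: the extrapolated mutant fractions follow the
printed weight column exactly (1 mg -> 1:10,000,000), whereas re-deriving
them from the printed diameters does not reproduce them.  Two printed
cells are internally inconsistent with any spherical-tumor reading (the
16 mg row's cell count and the 1 mg row's volume); the fixture marks them
``known_discrepant`` so the audit reports rather than hides them.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import asdict, dataclass
from typing import Sequence

from .abundance import (
    DEFAULT_ANCHOR,
    DEFAULT_PLASMA,
    PlasmaParams,
    ShedAnchor,
    expected_copies_per_draw,
    mutant_fraction,
)
from .geometry import (
    DEFAULT_ALLOMETRY,
    AllometryConstants,
    burden_from_mass,
)

__all__ = [
    "Table1Row",
    "PrintedRow",
    "GoldenComparison",
    "PRINTED_TABLE1",
    "build_table1",
    "compare_to_printed",
    "render",
    "rows_from_json",
]

#: Expected-copies values below this render as "<0.1", matching the
#: published column's convention.
SMALL_COPIES_THRESHOLD = 0.1


@dataclass(frozen=True)
class Table1Row:
    """One computed row of the reference table.

    ``progression_chance`` and ``mammography_sensitivity`` are literature
    annotations (fractions) or None; everything else is computed from the
    allometry and abundance models.
    """

    diameter_mm: float
    weight_mg: float
    volume_cm3: float
    cells: float
    mutant_fraction: float
    copies_per_draw: float
    progression_chance: float | None = None
    mammography_sensitivity: float | None = None


@dataclass(frozen=True)
class PrintedRow:
    """A published table row as printed, keyed by its weight column.

    ``fraction_denominator`` is x in the printed "1:x"; ``copies`` is a
    number or the literal string "<0.1".  ``known_discrepant`` lists
    fields whose printed value is inconsistent with the spherical-tumor
    model under any keying (documented publication quirks).
    """

    weight_mg: float
    diameter_mm: float
    volume_cm3: float
    cells: float
    fraction_denominator: float
    copies: float | str
    progression_chance: float | None = None
    mammography_sensitivity: float | None = None
    experimental: tuple = ()
    known_discrepant: tuple = ()


PRINTED_TABLE1: tuple[PrintedRow, ...] = (
    PrintedRow(10_000, 27, 10, 1e9, 1_000, 6,
               experimental=("weight_mg", "volume_cm3", "cells", "fraction_denominator")),
    PrintedRow(1_000, 12.5, 1, 1e8, 10_000, 0.6,
               experimental=("weight_mg", "volume_cm3", "cells")),
    PrintedRow(500, 10, 0.5, 5e7, 20_000, 0.3,
               progression_chance=0.50, mammography_sensitivity=0.91),
    PrintedRow(125, 6, 0.12, 1.2e7, 80_000, "<0.1"),
    PrintedRow(62, 5, 0.06, 6e6, 160_000, "<0.1",
               progression_chance=0.06, mammography_sensitivity=0.26),
    PrintedRow(16, 3, 0.015, 1e6, 640_000, "<0.1",
               known_discrepant=("cells",)),
    PrintedRow(4, 2, 0.0035, 4e5, 2_600_000, "<0.1"),
    PrintedRow(1, 1.1, 0.0008, 1e5, 10_000_000, "<0.1",
               progression_chance=0.0005,
               known_discrepant=("volume_cm3",)),
)


@dataclass(frozen=True)
class GoldenComparison:
    """One printed-vs-computed cell of the audit."""

    weight_mg: float
    field: str
    printed: float | str
    computed: float
    relative_deviation: float | None
    passed: bool
    known_discrepant: bool = False


def build_table1(
    masses_mg: Sequence[float] | None = None,
    constants: AllometryConstants = DEFAULT_ALLOMETRY,
    plasma: PlasmaParams = DEFAULT_PLASMA,
    anchor: ShedAnchor = DEFAULT_ANCHOR,
) -> list[Table1Row]:
    """Compute the reference table for the given tumor masses (mg).

    Defaults to the printed weight column; annotation columns are filled
    from the printed fixture where a printed row with the same mass
    carries them.
    """
    annotations = {
        r.weight_mg: (r.progression_chance, r.mammography_sensitivity)
        for r in PRINTED_TABLE1
    }
    if masses_mg is None:
        masses_mg = [r.weight_mg for r in PRINTED_TABLE1]
    rows = []
    for m in masses_mg:
        if m < 0:
            raise ValueError("tumor mass must be nonnegative")
        burden = burden_from_mass(m, constants)
        prog, mammo = annotations.get(m, (None, None))
        rows.append(
            Table1Row(
                diameter_mm=burden.diameter_mm,
                weight_mg=burden.mass_mg,
                volume_cm3=burden.volume_cm3,
                cells=burden.cells,
                mutant_fraction=float(mutant_fraction(m, anchor)),
                copies_per_draw=float(expected_copies_per_draw(m, plasma, anchor)),
                progression_chance=prog,
                mammography_sensitivity=mammo,
            )
        )
    return rows


def compare_to_printed(
    rows: Sequence[Table1Row],
    printed: Sequence[PrintedRow] = PRINTED_TABLE1,
    tolerance: float = 0.15,
) -> list[GoldenComparison]:
    """Cell-by-cell audit of computed rows against the printed fixture.

    Rows are matched on the weight column.  Numeric cells pass when the
    relative deviation is within ``tolerance``; "<0.1" copies cells pass
    when the computed value is below 0.1.  A printed row with no computed
    counterpart yields an explicit failing record for every field.
    """
    by_mass = {round(r.weight_mg, 6): r for r in rows}
    out: list[GoldenComparison] = []
    for p in printed:
        row = by_mass.get(round(p.weight_mg, 6))
        pairs = [
            ("diameter_mm", p.diameter_mm, None if row is None else row.diameter_mm),
            ("volume_cm3", p.volume_cm3, None if row is None else row.volume_cm3),
            ("cells", p.cells, None if row is None else row.cells),
            (
                "mutant_fraction",
                1.0 / p.fraction_denominator,
                None if row is None else row.mutant_fraction,
            ),
            ("copies_per_draw", p.copies, None if row is None else row.copies_per_draw),
        ]
        for field, printed_val, computed in pairs:
            flagged = field in p.known_discrepant
            if computed is None:
                out.append(
                    GoldenComparison(p.weight_mg, field, printed_val, float("nan"),
                                     None, False, flagged)
                )
                continue
            if isinstance(printed_val, str):  # the "<0.1" band
                out.append(
                    GoldenComparison(p.weight_mg, field, printed_val, computed,
                                     None, computed < SMALL_COPIES_THRESHOLD, flagged)
                )
                continue
            rel = abs(computed - printed_val) / abs(printed_val)
            out.append(
                GoldenComparison(p.weight_mg, field, printed_val, computed,
                                 rel, rel <= tolerance, flagged)
            )
    return out


def _fmt_fraction(f: float) -> str:
    if f <= 0:
        return "0"
    return f"1:{round(1.0 / f):,}"


def _fmt_copies(c: float) -> str:
    return "<0.1" if c < SMALL_COPIES_THRESHOLD else f"{c:.1f}"


def _fmt_pct(f: float | None) -> str:
    return "" if f is None else f"{100 * f:g}%"


_TABLE_HEADER = [
    "Tumor diameter, mm",
    "Tumor weight, mg",
    "Tumor volume, cm3",
    "Number of cells",
    "Fraction of mutant DNA",
    "Genomes per 4 mL plasma",
    "Chance of progression",
    "Mammographic screen sensitivity",
]


def _table_cells(row: Table1Row) -> list[str]:
    return [
        f"{row.diameter_mm:.2f}",
        f"{row.weight_mg:g}",
        f"{row.volume_cm3:.4g}",
        f"{row.cells:,.0f}",
        _fmt_fraction(row.mutant_fraction),
        _fmt_copies(row.copies_per_draw),
        _fmt_pct(row.progression_chance),
        _fmt_pct(row.mammography_sensitivity),
    ]


def render(items: Sequence, fmt: str = "markdown") -> str:
    """Render table rows or audit comparisons as csv, markdown, or json.

    JSON is lossless (full float precision); csv and markdown use the
    published table's display conventions ("1:20,000", "<0.1") for
    :class:`Table1Row` items.
    """
    if fmt not in ("csv", "markdown", "json"):
        raise ValueError(f"unknown format: {fmt!r}")
    items = list(items)
    if fmt == "json":
        return json.dumps([asdict(it) for it in items], indent=2)

    if items and isinstance(items[0], GoldenComparison):
        header = ["weight_mg", "field", "printed", "computed",
                  "relative_deviation", "passed", "known_discrepant"]
        table = [
            [str(getattr(c, h)) for h in header]
            for c in items
        ]
    else:
        header = _TABLE_HEADER
        table = [_table_cells(r) for r in items]

    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(header)
        writer.writerows(table)
        return buf.getvalue()

    lines = [
        "| " + " | ".join(header) + " |",
        "| " + " | ".join("---" for _ in header) + " |",
    ]
    lines += ["| " + " | ".join(cells) + " |" for cells in table]
    return "\n".join(lines) + "\n"


def rows_from_json(text: str) -> list[Table1Row]:
    """Inverse of ``render(rows, "json")``."""
    return [Table1Row(**d) for d in json.loads(text)]
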