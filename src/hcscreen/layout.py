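"""Plate-layout handling.

A plate layout maps wells of a multi-well plate to their experimental
metadata: donor, ionising-radiation dose (Gy), fixation time post-IR (h),
seeding density, technical-replicate row and control status.  Rows of the
plate are the unit of technical replication: gating thresholds and
background (secondary-antibody-only) normalization are computed row by row,
so every replicate row that contains experimental wells must also contain
at least one secondary-only control well.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

#: Doses (Gy) and fixation times (hours post-IR) used in the screen design.
STANDARD_DOSES = (0.0, 1.0, 2.0, 5.0)
STANDARD_TIMES = (0.0, 1.0, 2.0, 6.0, 24.0, 48.0)
STANDARD_DENSITIES = (2000, 4000, 8000)
SORT_POPULATIONS = ("unsorted", "CD10", "MUC1", "none")

LAYOUT_COLUMNS = [
    "plate",
    "well",
    "row",
    "column",
    "donor",
    "dose_gy",
    "time_h",
    "seeding_density",
    "replicate_row",
    "is_control",
    "sort_population",
]

_WELL_RE = re.compile(r"^([A-H])(\d{1,2})$")


class LayoutError(ValueError):
    """Raised when a plate layout violates its structural invariants."""


@dataclass
class FieldGrid:
    """Acquisition geometry of one well: an ``nrows`` x ``ncols`` grid of
    fields with fixed centre-to-centre spacing (µm)."""

    nrows: int = 5
    ncols: int = 5
    spacing_um: float = 100.0

    @property
    def n_fields(self) -> int:
        return self.nrows * self.ncols


@dataclass
class PlateLayout:
    """Well-level metadata for one or more plates plus the field grid."""

    wells: pd.DataFrame
    grid: FieldGrid = field(default_factory=FieldGrid)

    def __post_init__(self) -> None:
        missing = [c for c in LAYOUT_COLUMNS if c not in self.wells.columns]
        if missing:
            raise LayoutError(f"layout missing columns: {missing}")
        self.wells = self.wells[LAYOUT_COLUMNS].reset_index(drop=True)

    # -- accessors -------------------------------------------------------
    def experimental_wells(self) -> pd.DataFrame:
        return self.wells[~self.wells["is_control"]]

    def control_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["is_control"]]

    def control_well_for_row(self, plate: str, replicate_row: str) -> str:
        """Well id of the secondary-only control of one replicate row."""
        sel = self.wells[
            (self.wells["plate"] == plate)
            & (self.wells["replicate_row"] == replicate_row)
            & self.wells["is_control"]
        ]
        if sel.empty:
            raise LayoutError(
                f"no secondary-only control well in replicate row "
                f"{replicate_row!r} of plate {plate!r}"
            )
        return str(sel["well"].iloc[0])

    def validate(self, strict_design: bool = True) -> None:
        """Check structural invariants, reporting offending coordinates.

        With ``strict_design`` (default) doses, times and seeding densities
        must come from the declared design sets.
        """
        w = self.wells
        dup = w.duplicated(subset=["plate", "well"])
        if dup.any():
            bad = w.loc[dup, ["plate", "well"]].to_records(index=False).tolist()
            raise LayoutError(f"duplicate well ids: {bad}")
        for _, r in w.iterrows():
            m = _WELL_RE.match(str(r["well"]))
            if not m:
                raise LayoutError(f"malformed well id {r['well']!r}")
            if m.group(1) != r["row"] or int(m.group(2)) != int(r["column"]):
                raise LayoutError(
                    f"well {r['well']!r}: row/column fields disagree with id"
                )
        if strict_design:
            bad_dose = w[~w["dose_gy"].isin(STANDARD_DOSES)]
            if not bad_dose.empty:
                raise LayoutError(
                    "unknown dose(s) "
                    f"{sorted(bad_dose['dose_gy'].unique())} in wells "
                    f"{bad_dose['well'].tolist()} (pass strict_design=False "
                    "to accept)"
                )
            bad_time = w[~w["time_h"].isin(STANDARD_TIMES)]
            if not bad_time.empty:
                raise LayoutError(
                    f"unknown time(s) {sorted(bad_time['time_h'].unique())} "
                    f"in wells {bad_time['well'].tolist()}"
                )
            bad_sort = w[~w["sort_population"].isin(SORT_POPULATIONS)]
            if not bad_sort.empty:
                raise LayoutError(
                    "unknown sort population in wells "
                    f"{bad_sort['well'].tolist()}"
                )
        # every replicate row with experimental wells needs >= 1 control
        for (plate, rrow), grp in w.groupby(["plate", "replicate_row"]):
            if (~grp["is_control"]).any() and not grp["is_control"].any():
                raise LayoutError(
                    f"replicate row {rrow!r} on plate {plate!r} has no "
                    "secondary-only control well"
                )

    def save(self, path) -> None:
        self.wells.to_csv(path, index=False)


def load_layout(path, grid: FieldGrid | None = None,
                strict_design: bool = True) -> PlateLayout:
    """Read a layout CSV, validate it and return a :class:`PlateLayout`."""
    wells = pd.read_csv(
        path,
        dtype={"plate": str, "well": str, "row": str, "donor": str,
               "replicate_row": str, "sort_population": str},
    )
    if "is_control" in wells.columns:
        wells["is_control"] = wells["is_control"].astype(bool)
    layout = PlateLayout(wells, grid or FieldGrid())
    layout.validate(strict_design=strict_design)
    return layout


def make_row_layout(
    n_replicates: int = 5,
    plate: str = "P1",
    rows: list[str] | None = None,
    donor: str = "SIM",
    conditions: list[dict] | None = None,
    seeding_density: int = 2000,
    sort_population: str = "unsorted",
    grid: FieldGrid | None = None,
) -> PlateLayout:
    """Build a row-per-condition layout.

    Each condition occupies one plate row: ``n_replicates`` experimental
    wells in columns 1..n and one secondary-only control well in the next
    column.  ``conditions`` is a list of ``{"dose_gy": ..., "time_h": ...}``
    dicts (default: a single untreated time-zero condition).
    """
    if conditions is None:
        conditions = [{"dose_gy": 0.0, "time_h": 0.0}]
    if rows is None:
        rows = [chr(ord("A") + i) for i in range(len(conditions))]
    if len(rows) < len(conditions):
        raise LayoutError("not enough plate rows for the conditions given")
    records = []
    for row_letter, cond in zip(rows, conditions):
        for col in range(1, n_replicates + 2):
            is_control = col == n_replicates + 1
            records.append(
                {
                    "plate": plate,
                    "well": f"{row_letter}{col}",
                    "row": row_letter,
                    "column": col,
                    "donor": donor,
                    "dose_gy": float(cond["dose_gy"]),
                    "time_h": float(cond["time_h"]),
                    "seeding_density": seeding_density,
                    "replicate_row": f"{plate}-{row_letter}",
                    "is_control": is_control,
                    "sort_population": sort_population,
                }
            )
    layout = PlateLayout(pd.DataFrame(records), grid or FieldGrid())
    layout.validate()
    return layout
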