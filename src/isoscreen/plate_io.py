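"""Plate-screen table I/O and canonical well addressing.

The on-disk form is a long ("tidy") CSV, one well per row, with columns
``plate_id, well, cell_line, compound, dose_um, replicate, luminescence``.
Vehicle (DMSO) control wells are marked by a sentinel in the ``compound``
column and always carry dose 0. Well labels are 1-based for humans ("A1");
row/column indices are 0-based internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

#: rows x columns for the supported microplate formats
PLATE_DIMS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24)}

#: sentinel used in the ``compound`` column for vehicle control wells
DEFAULT_CONTROL_LABEL = "DMSO"

REQUIRED_COLUMNS = [
    "plate_id",
    "well",
    "cell_line",
    "compound",
    "dose_um",
    "replicate",
    "luminescence",
]

_LABEL_RE = re.compile(r"^([A-Za-z])(\d{1,2})$")


class ScreenValidationError(ValueError):
    """Raised when a screen table violates the data contract.

    Validation is total: a malformed input raises, never yields a partial
    dataset. The message names the offending row/plate where applicable.
    """


@dataclass(frozen=True, order=True)
class WellAddress:
    """0-based (row, col) position on a plate; ``label`` renders as e.g. "B3"."""

    row: int
    col: int

    @property
    def label(self) -> str:
        return f"{chr(ord('A') + self.row)}{self.col + 1}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def plate_dims(plate_format: int) -> tuple[int, int]:
    try:
        return PLATE_DIMS[int(plate_format)]
    except KeyError:
        raise ScreenValidationError(
            f"unsupported plate format {plate_format!r}; expected one of {sorted(PLATE_DIMS)}"
        ) from None


def well_from_label(label: str, plate_format: int = 384) -> WellAddress:
    """Parse a human well label like "A1" into a :class:`WellAddress`.

    The address is validated against the plate format (8x12 for 96-well,
    16x24 for 384-well); labels round-trip through ``WellAddress.label``.
    """
    n_rows, n_cols = plate_dims(plate_format)
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ScreenValidationError(f"malformed well label {label!r}")
    row = ord(m.group(1).upper()) - ord("A")
    col = int(m.group(2)) - 1
    if col < 0:
        raise ScreenValidationError(f"malformed well label {label!r}")
    if row >= n_rows or col >= n_cols:
        raise ScreenValidationError(
            f"well {label!r} out of range for {plate_format}-well format "
            f"({n_rows} rows x {n_cols} columns)"
        )
    return WellAddress(row, col)


@dataclass
class ScreenDataset:
    """A validated collection of plate-well records plus panel metadata.

    ``records`` is a DataFrame with :data:`REQUIRED_COLUMNS`; ``panel`` is the
    ordered list of cell-line ids in the screen; ``provenance`` carries
    generator config / seed metadata and the control sentinel in use.
    """

    records: pd.DataFrame
    panel: list[str]
    provenance: dict[str, Any] = field(default_factory=dict)
    plate_format: int = 384
    control_label: str = DEFAULT_CONTROL_LABEL

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ScreenValidationError(f"missing required column(s): {missing}")
        if df.empty:
            return
        for i, lab in zip(df.index, df["well"]):
            well_from_label(str(lab), self.plate_format)  # raises if invalid
            del i
        lum = pd.to_numeric(df["luminescence"], errors="coerce")
        bad = df.index[~np.isfinite(lum) | (lum < 0)]
        if len(bad):
            raise ScreenValidationError(
                f"negative or non-finite luminescence at row {bad[0]}"
            )
        dose = pd.to_numeric(df["dose_um"], errors="coerce")
        bad = df.index[~np.isfinite(dose) | (dose < 0)]
        if len(bad):
            raise ScreenValidationError(f"negative or non-numeric dose at row {bad[0]}")
        dup = df.duplicated(subset=["plate_id", "well"])
        if dup.any():
            r = df.index[dup][0]
            raise ScreenValidationError(
                f"duplicate (plate, well) at row {r}: "
                f"{df.loc[r, 'plate_id']}/{df.loc[r, 'well']}"
            )
        is_ctrl = df["compound"] == self.control_label
        if (dose[is_ctrl] != 0).any():
            r = df.index[is_ctrl & (dose != 0)][0]
            raise ScreenValidationError(f"control well with nonzero dose at row {r}")
        for plate, grp in df.groupby("plate_id", sort=False):
            ctrl = grp["compound"] == self.control_label
            if not ctrl.any():
                raise ScreenValidationError(f"no controls on plate {plate!r}")
            treated_lines = set(grp.loc[~ctrl, "cell_line"])
            control_lines = set(grp.loc[ctrl, "cell_line"])
            if treated_lines and not treated_lines <= control_lines:
                raise ScreenValidationError(
                    f"plate {plate!r}: treated cell line(s) "
                    f"{sorted(treated_lines - control_lines)} lack same-line controls"
                )

    # -- convenience ------------------------------------------------------
    @property
    def n_records(self) -> int:
        return len(self.records)

    def controls(self) -> pd.DataFrame:
        return self.records[self.records["compound"] == self.control_label]

    def treated(self) -> pd.DataFrame:
        return self.records[self.records["compound"] != self.control_label]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenDataset):
            return NotImplemented
        a = _canonical_frame(self)
        b = _canonical_frame(other)
        return (
            self.panel == other.panel
            and self.plate_format == other.plate_format
            and a.equals(b)
        )


def _canonical_frame(ds: ScreenDataset) -> pd.DataFrame:
    df = ds.records.copy()
    addr = [well_from_label(str(w), ds.plate_format) for w in df["well"]]
    df["_row"] = [a.row for a in addr]
    df["_col"] = [a.col for a in addr]
    df = df.sort_values(["plate_id", "_row", "_col"], kind="mergesort")
    df = df[REQUIRED_COLUMNS].reset_index(drop=True)
    df["dose_um"] = df["dose_um"].astype(float)
    df["luminescence"] = df["luminescence"].astype(float)
    df["replicate"] = df["replicate"].astype(int)
    for c in ("plate_id", "well", "cell_line", "compound"):
        df[c] = df[c].astype(str)
    return df


def read_screen(
    path: str | Path,
    plate_format: int = 384,
    control_label: str = DEFAULT_CONTROL_LABEL,
) -> ScreenDataset:
    """Read and fully validate a long-format screen CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        dtype={"plate_id": str, "well": str, "cell_line": str, "compound": str},
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenValidationError(f"{path.name}: missing required column(s): {missing}")
    panel = list(dict.fromkeys(df.loc[df["compound"] != control_label, "cell_line"]))
    if not panel:
        panel = list(dict.fromkeys(df["cell_line"].dropna()))
    return ScreenDataset(
        records=df,
        panel=panel,
        provenance={"source": str(path)},
        plate_format=plate_format,
        control_label=control_label,
    )


def write_screen(dataset: ScreenDataset, path: str | Path) -> None:
    """Write a dataset as CSV with deterministic column order and row sort.

    Rows are ordered by (plate_id, row, col); output is UTF-8 with "."
    decimals, so two writes of the same dataset are byte-identical and
    ``read_screen(write_screen(ds)) == ds``.
    """
    df = _canonical_frame(dataset)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")
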