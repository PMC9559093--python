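"""Superpixel grid conventions and long-table input/output.

Macular thickness exports arrive as an 8x8 array of 3deg x 3deg superpixels.
Rows are numbered 1..8 from superior to inferior, columns 1..8 from temporal
to nasal (right-eye orientation); a superpixel is written "row.col", e.g. the
four parafoveal cells are 4.4, 4.5, 5.4 and 5.5.  The analysis keeps the 7x7
subarray obtained by omitting the most inferior row and the nasal-most
column.

Left-eye (OS) measurements can be mirrored left-right into the canonical
right-eye orientation with :func:`mirror_left_eyes`; this is *not* done
implicitly on read so that write-then-read round-trips are exact.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SuperpixelLabel",
    "LongTableError",
    "LabelError",
    "GridMap",
    "parse_label",
    "format_label",
    "analysis_labels",
    "label_index",
    "select_analysis_grid",
    "mirror_left_eyes",
    "validate_long_table",
    "read_long_table",
    "write_long_table",
    "LONG_COLUMNS",
]

#: Column order of the long-format measurement table.
LONG_COLUMNS = ["subject_id", "eye", "time_years", "superpixel", "thickness_um"]

#: Grid size of the raw export and of the analysis subgrid.
EXPORT_SIZE = 8
GRID_SIZE = 7

#: Fovea centre, between rows 4-5 and columns 4-5 (plot annotation only).
FOVEA_CENTER = (4.5, 4.5)

_LABEL_RE = re.compile(r"^([1-8])\.([1-8])$")


class LabelError(ValueError):
    """A superpixel label could not be parsed."""


class LongTableError(ValueError):
    """A long-format table violates its invariants."""


class SuperpixelLabel(NamedTuple):
    """Grid position of one superpixel (row 1 = superior, col 1 = temporal)."""

    row: int
    col: int

    @property
    def text(self) -> str:
        return f"{self.row}.{self.col}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def parse_label(text: str) -> SuperpixelLabel:
    """Parse a "row.col" superpixel label with both digits in 1..8."""
    m = _LABEL_RE.match(str(text).strip())
    if m is None:
        raise LabelError(
            f"invalid superpixel label {text!r}: expected '<digit>.<digit>' "
            "with both digits in 1..8"
        )
    return SuperpixelLabel(int(m.group(1)), int(m.group(2)))


def format_label(label: SuperpixelLabel | tuple[int, int]) -> str:
    row, col = label
    return f"{int(row)}.{int(col)}"


def analysis_labels() -> list[str]:
    """The 49 labels of the 7x7 analysis grid in row-major order."""
    return [f"{r}.{c}" for r in range(1, GRID_SIZE + 1) for c in range(1, GRID_SIZE + 1)]


def label_index(labels: Iterable[str] | None = None) -> dict[str, int]:
    """Map label text -> column index in the canonical ordering."""
    if labels is None:
        labels = analysis_labels()
    return {lab: i for i, lab in enumerate(labels)}


def select_analysis_grid(table: pd.DataFrame) -> pd.DataFrame:
    """Drop records in the most inferior row (8) or nasal-most column (8).

    All other records are preserved unchanged.
    """
    parsed = table["superpixel"].map(parse_label)
    keep = parsed.map(lambda l: l.row <= GRID_SIZE and l.col <= GRID_SIZE)
    return table.loc[keep].reset_index(drop=True)


def mirror_left_eyes(table: pd.DataFrame) -> pd.DataFrame:
    """Mirror OS records left-right (col -> 9 - col) into OD orientation.

    After mirroring, "temporal" is always column 1 and "nasal" column 8
    regardless of laterality.  Must be applied to 8x8-labelled data, before
    :func:`select_analysis_grid`.
    """
    out = table.copy()
    is_os = out["eye"] == "OS"

    def _flip(text: str) -> str:
        lab = parse_label(text)
        return format_label((lab.row, EXPORT_SIZE + 1 - lab.col))

    out.loc[is_os, "superpixel"] = out.loc[is_os, "superpixel"].map(_flip)
    return out


def validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate invariants and return a canonically sorted copy.

    Raises :class:`LongTableError` listing offending keys on duplicate
    (subject, time, superpixel) triples, non-finite values or bad labels.
    """
    missing = [c for c in LONG_COLUMNS if c not in table.columns]
    if missing:
        raise LongTableError(f"missing columns: {missing}")
    out = table.loc[:, LONG_COLUMNS].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    out["superpixel"] = out["superpixel"].astype(str)

    bad_eye = ~out["eye"].isin(["OD", "OS"])
    if bad_eye.any():
        raise LongTableError(
            f"eye must be OD or OS; found {sorted(out.loc[bad_eye, 'eye'].unique())}"
        )
    for lab in out["superpixel"].unique():
        parse_label(lab)  # raises LabelError

    t = pd.to_numeric(out["time_years"], errors="coerce")
    y = pd.to_numeric(out["thickness_um"], errors="coerce")
    if t.isna().any() or not np.isfinite(t).all() or (t < 0).any():
        raise LongTableError("time_years must be finite and >= 0")
    if y.isna().any() or not np.isfinite(y).all() or (y < 0).any():
        raise LongTableError("thickness_um must be finite, numeric and >= 0")
    out["time_years"] = t.astype(float)
    out["thickness_um"] = y.astype(float)

    key = ["subject_id", "time_years", "superpixel"]
    dup = out.duplicated(subset=key, keep=False)
    if dup.any():
        offenders = (
            out.loc[dup, key].drop_duplicates().head(10).to_records(index=False).tolist()
        )
        raise LongTableError(
            f"duplicate (subject, time, superpixel) keys, e.g. {offenders}"
        )
    out = out.sort_values(key, kind="mergesort").reset_index(drop=True)
    return out


def read_long_table(path, canonicalize_os: bool = False) -> pd.DataFrame:
    """Read and validate a long-format CSV.

    Parameters
    ----------
    canonicalize_os
        If True, mirror OS eyes into the canonical OD orientation
        (only valid for 8x8-labelled exports).
    """
    raw = pd.read_csv(path, dtype={"subject_id": str, "superpixel": str})
    table = validate_long_table(raw)
    if canonicalize_os:
        table = validate_long_table(mirror_left_eyes(table))
    return table


def write_long_table(table: pd.DataFrame, path) -> None:
    validate_long_table(table).to_csv(path, index=False)


@dataclass
class GridMap:
    """A scalar value per superpixel of the 7x7 analysis grid."""

    values: np.ndarray  # (7, 7), [row-1, col-1]
    name: str = ""
    fovea: tuple[float, float] = field(default=FOVEA_CENTER)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (GRID_SIZE, GRID_SIZE):
            raise ValueError(f"GridMap needs a 7x7 array, got {self.values.shape}")

    @classmethod
    def from_dict(cls, mapping: dict[str, float], name: str = "") -> "GridMap":
        values = np.full((GRID_SIZE, GRID_SIZE), np.nan)
        for text, v in mapping.items():
            lab = parse_label(text)
            if lab.row > GRID_SIZE or lab.col > GRID_SIZE:
                raise LabelError(f"label {text} outside the 7x7 analysis grid")
            values[lab.row - 1, lab.col - 1] = v
        if np.isnan(values).any():
            raise ValueError("GridMap.from_dict requires all 49 labels")
        return cls(values, name=name)

    def to_dict(self) -> dict[str, float]:
        return {
            f"{r}.{c}": float(self.values[r - 1, c - 1])
            for r in range(1, GRID_SIZE + 1)
            for c in range(1, GRID_SIZE + 1)
        }

    def __getitem__(self, label: str | SuperpixelLabel) -> float:
        lab = parse_label(label) if isinstance(label, str) else label
        return float(self.values[lab.row - 1, lab.col - 1])

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values,
            index=[f"row{r}" for r in range(1, GRID_SIZE + 1)],
            columns=[f"col{c}" for c in range(1, GRID_SIZE + 1)],
        )
        df.to_csv(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"name": self.name, "values": self.to_dict()}, fh, indent=1)
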