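"""Cell tables and study designs.

The universal input is a tidy per-cell table — the standard export of a
segmented and phenotyped multiplex image (CODEX, IMC, Vectra, MIBI): one row
per cell with planar coordinates, a cell-type label, and identifiers tying
the cell to an image, the image to a subject, and the subject to a clinical
group.  Coordinates are continuous in whatever length unit the platform
exports (pixels or µm); no unit conversion is attempted and the radius grid
downstream is interpreted in the same unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ParseError, SchemaError
from .geometry import PointPattern, Window

__all__ = [
    "CellTable",
    "StudyDesign",
    "read_cell_table",
    "write_cell_table",
    "summarize_design",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = ("x", "y", "cell_type", "image_id", "subject_id", "group")


def _first_appearance_levels(values: pd.Series) -> list:
    return list(dict.fromkeys(values.tolist()))


@dataclass
class CellTable:
    """Validated per-cell table with a fixed image -> subject -> group hierarchy.

    Categorical levels (cell types, groups) are recorded in first-appearance
    order so that downstream heatmap axes are deterministic; an explicit
    ordering may be supplied.
    """

    df: pd.DataFrame
    cell_types: list = field(default_factory=list)
    groups: list = field(default_factory=list)
    windows: dict = field(default_factory=dict)  # image_id -> Window override

    def __post_init__(self) -> None:
        df = self.df
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        if len(df) == 0:
            raise SchemaError("cell table has no rows")
        for col in ("x", "y"):
            vals = df[col].to_numpy()
            if not np.issubdtype(vals.dtype, np.number):
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                raise ParseError(
                    f"non-numeric coordinate in column {col!r} at row(s) {list(bad[:5])}"
                )
            if not np.all(np.isfinite(vals)):
                bad = df.index[~np.isfinite(vals)]
                raise ParseError(f"non-finite coordinate in column {col!r} at row(s) {list(bad[:5])}")
        # hierarchy: image -> exactly one subject, subject -> exactly one group
        img_sub = df.groupby("image_id", sort=False)["subject_id"].nunique()
        if (img_sub > 1).any():
            offenders = img_sub.index[img_sub > 1].tolist()
            raise ConsistencyError(f"image(s) {offenders} assigned to more than one subject")
        sub_grp = df.groupby("subject_id", sort=False)["group"].nunique()
        if (sub_grp > 1).any():
            offenders = sub_grp.index[sub_grp > 1].tolist()
            raise ConsistencyError(f"subject(s) {offenders} assigned to more than one group")
        if not self.cell_types:
            self.cell_types = _first_appearance_levels(df["cell_type"])
        if not self.groups:
            self.groups = _first_appearance_levels(df["group"])

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        allow_duplicates: bool = False,
        cell_types: Sequence | None = None,
        groups: Sequence | None = None,
        windows: Mapping | None = None,
    ) -> "CellTable":
        table = cls(
            df.reset_index(drop=True),
            cell_types=list(cell_types or []),
            groups=list(groups or []),
            windows=dict(windows or {}),
        )
        if not allow_duplicates:
            dup = df.duplicated(subset=["image_id", "x", "y", "cell_type"])
            if dup.any():
                raise ConsistencyError(
                    f"{int(dup.sum())} duplicated (image_id, x, y, cell_type) rows; "
                    "pass allow_duplicates=True if cell centroids may coincide"
                )
        return table

    @property
    def n_images(self) -> int:
        return self.df["image_id"].nunique()

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def image_ids(self) -> list:
        return _first_appearance_levels(self.df["image_id"])

    def pattern(self, image_id) -> PointPattern:
        """One image as a typed point pattern with its observation window.

        The window is an explicit per-image override if supplied, else the
        axis-aligned bounding rectangle of the image's cells.
        """
        sub = self.df[self.df["image_id"] == image_id]
        if len(sub) == 0:
            raise KeyError(f"unknown image_id {image_id!r}")
        x = sub["x"].to_numpy(dtype=float)
        y = sub["y"].to_numpy(dtype=float)
        window = self.windows.get(image_id) or Window.bounding(x, y)
        return PointPattern(x, y, sub["cell_type"].to_numpy(), window, str(image_id))

    def image_meta(self) -> pd.DataFrame:
        """One row per image: image_id, subject_id, group (first-appearance order)."""
        return (
            self.df[["image_id", "subject_id", "group"]]
            .drop_duplicates("image_id")
            .reset_index(drop=True)
        )


@dataclass
class StudyDesign:
    """Nested bookkeeping of a study: groups, subjects, images, cell counts."""

    groups: list
    subjects_by_group: dict  # group -> ordered subject list
    images_by_subject: dict  # subject -> ordered image list
    counts: pd.DataFrame  # image_id x cell_type counts (l_m per image)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_subjects(self) -> int:
        return sum(len(s) for s in self.subjects_by_group.values())

    @property
    def n_images(self) -> int:
        return sum(len(v) for v in self.images_by_subject.values())


def summarize_design(table: CellTable) -> StudyDesign:
    """Tabulate the study hierarchy and per-image cell-type counts."""
    df = table.df
    meta = table.image_meta()
    groups = table.groups
    subjects_by_group = {
        g: _first_appearance_levels(meta.loc[meta["group"] == g, "subject_id"])
        for g in groups
    }
    images_by_subject = {
        s: _first_appearance_levels(meta.loc[meta["subject_id"] == s, "image_id"])
        for g in groups
        for s in subjects_by_group[g]
    }
    counts = (
        df.groupby(["image_id", "cell_type"], sort=False)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=table.cell_types, fill_value=0)
        .reindex(index=table.image_ids)
    )
    return StudyDesign(groups, subjects_by_group, images_by_subject, counts)


def read_cell_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
    allow_duplicates: bool = False,
) -> CellTable:
    """Read a CSV/TSV per-cell export into a validated :class:`CellTable`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    column_map
        Mapping from required names (x, y, cell_type, image_id, subject_id,
        group) to the column names actually present in the file.
    sep
        Field separator; inferred from the extension when omitted
        (``.tsv``/``.txt`` -> tab, else comma).
    allow_duplicates
        Permit rows with identical (image_id, x, y, cell_type); some
        platforms export coincident centroids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    colmap = dict(column_map or {})
    rename = {}
    for needed in REQUIRED_COLUMNS:
        source = colmap.get(needed, needed)
        if source not in df.columns:
            raise SchemaError(f"{path}: missing required column {source!r} (for {needed!r})")
        rename[source] = needed
    df = df.rename(columns=rename)[list(REQUIRED_COLUMNS)]
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric {col!r} at row(s) {list(bad[:5])}")
        df[col] = coerced
    return CellTable.from_dataframe(df, allow_duplicates=allow_duplicates)


def write_cell_table(table: CellTable, path: str | Path, sep: str = ",") -> None:
    """Write the table in the same dialect :func:`read_cell_table` accepts."""
    table.df.to_csv(path, sep=sep, index=False)
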