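"""Reading, validation and windowing of FTIR spectral tables.

Data model
----------
A :class:`SpectrumSet` bundles a strictly ascending wavenumber axis (cm^-1),
an ``n_samples x n_variables`` absorbance matrix and a per-sample metadata
table (``sample_id``, ``botanical``, ``year``, ``region``).  FTIR instruments
commonly export descending axes; those are reversed (together with their
columns) at the boundary so that everything downstream can assume one axis
convention.

Two on-disk dialects are supported:

* ``wide_csv`` — first column ``sample_id``, remaining headers numeric
  wavenumbers, cells absorbance; an optional sidecar metadata CSV keyed by
  ``sample_id`` supplies the class labels.
* a read-only JCAMP-DX 4.24 subset (``##XYDATA=(X++(Y..Y))``) for single
  spectra exported by bench instruments.

Axes are never resampled silently: combining sets with different grids is the
caller's problem, by design.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectraFormatError",
    "SpectraValidationError",
    "WindowError",
    "SampleMetadata",
    "SpectrumSet",
    "BOTANICAL_LEVELS",
    "YEAR_LEVELS",
    "REGION_LEVELS",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_metadata",
    "write_metadata",
    "read_jcamp",
    "trim_window",
]


class SpectraFormatError(ValueError):
    """A file could not be parsed as the declared dialect."""


class SpectraValidationError(ValueError):
    """Parsed data violate a SpectrumSet invariant."""


class WindowError(ValueError):
    """A spectral window selects no variables."""


BOTANICAL_LEVELS = ("acacia", "colza", "honeydew", "linden")
YEAR_LEVELS = ("2020", "2021")
REGION_LEVELS = ("Others", "Transylvania")

_META_COLUMNS = ("sample_id", "botanical", "year", "region")


@dataclass(frozen=True)
class SampleMetadata:
    """Labels attached to one sample; any factor may be absent (None)."""

    sample_id: str
    botanical: str | None = None
    year: str | None = None
    region: str | None = None


def _normalize_meta(meta: pd.DataFrame) -> pd.DataFrame:
    out = meta.copy()
    for col in _META_COLUMNS:
        if col not in out.columns:
            out[col] = None
    out = out.loc[:, list(_META_COLUMNS)].reset_index(drop=True)
    for col in _META_COLUMNS:
        out[col] = out[col].astype("object")
        mask = out[col].isna()
        # years may arrive as ints/floats from CSV readers
        out.loc[~mask, col] = out.loc[~mask, col].map(
            lambda v: str(int(v)) if isinstance(v, float) and float(v).is_integer() else str(v)
        )
        out.loc[mask, col] = None
    return out


@dataclass
class SpectrumSet:
    """Wavenumber axis + absorbance matrix + per-sample metadata."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.wavenumbers.ndim != 1:
            raise SpectraValidationError("wavenumber axis must be one-dimensional")
        if np.any(self.wavenumbers <= 0):
            raise SpectraValidationError("wavenumbers must be strictly positive")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise SpectraValidationError("wavenumber axis must be strictly ascending")
        if self.absorbance.shape[1] != self.wavenumbers.size:
            raise SpectraValidationError(
                f"absorbance has {self.absorbance.shape[1]} columns but the axis "
                f"has {self.wavenumbers.size} wavenumbers"
            )
        if not np.all(np.isfinite(self.absorbance)):
            bad = np.argwhere(~np.isfinite(self.absorbance))[0]
            raise SpectraValidationError(
                f"non-finite absorbance at sample row {bad[0]}, variable column {bad[1]}"
            )
        self.meta = _normalize_meta(self.meta)
        if len(self.meta) != self.absorbance.shape[0]:
            raise SpectraValidationError(
                f"metadata has {len(self.meta)} rows but the matrix has "
                f"{self.absorbance.shape[0]} samples"
            )
        ids = self.meta["sample_id"]
        if ids.isna().any():
            raise SpectraValidationError("every sample needs a sample_id")
        dup = ids[ids.duplicated()]
        if len(dup):
            raise SpectraValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_variables(self) -> int:
        return self.absorbance.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.meta["sample_id"].to_numpy()

    def labels(self, factor: str) -> np.ndarray:
        """Return the label column for a factor, failing on missing values."""
        if factor not in ("botanical", "year", "region"):
            raise ValueError(f"unknown factor {factor!r}")
        col = self.meta[factor]
        if col.isna().any():
            missing = self.meta.loc[col.isna(), "sample_id"].iloc[0]
            raise SpectraValidationError(
                f"sample {missing!r} lacks a {factor!r} label required for this task"
            )
        return col.to_numpy(dtype=object)

    def subset_samples(self, rows: np.ndarray) -> "SpectrumSet":
        rows = np.asarray(rows)
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            absorbance=self.absorbance[rows],
            meta=self.meta.iloc[rows].reset_index(drop=True),
        )

    def select_variables(self, cols: np.ndarray) -> "SpectrumSet":
        cols = np.asarray(cols)
        return SpectrumSet(
            wavenumbers=self.wavenumbers[cols],
            absorbance=self.absorbance[:, cols],
            meta=self.meta.copy(),
        )

    def sample_metadata(self) -> list[SampleMetadata]:
        return [
            SampleMetadata(
                sample_id=row.sample_id,
                botanical=row.botanical,
                year=row.year,
                region=row.region,
            )
            for row in self.meta.itertuples(index=False)
        ]


# ---------------------------------------------------------------------------
# wide_csv dialect
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sidecar metadata CSV (sample_id, botanical, year, region)."""
    meta = pd.read_csv(path, dtype=object)
    if "sample_id" not in meta.columns:
        raise SpectraFormatError(f"{path}: metadata CSV must have a sample_id column")
    return _normalize_meta(meta)


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    _normalize_meta(meta).to_csv(path, index=False)


def read_spectrum_table(
    path: str | Path,
    metadata: str | Path | pd.DataFrame | None = None,
    dialect: str = "wide_csv",
) -> SpectrumSet:
    """Read a wide-format spectral table into a validated SpectrumSet.

    The header row (all columns after ``sample_id``) must parse as numeric
    wavenumbers.  Descending axes are reversed together with their columns.
    Rows with missing cells are rejected with the offending row and column
    named.
    """
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        table = pd.read_csv(path, header=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise SpectraFormatError(f"{path}: {exc}") from exc
    if table.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need a sample_id column plus wavenumber columns")
    header = list(table.columns[1:])
    try:
        axis = np.array([float(h) for h in header], dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric wavenumber header: {exc}") from exc

    ids = table.iloc[:, 0].astype(str)
    values = table.iloc[:, 1:]
    na = values.isna()
    if na.to_numpy().any():
        r, c = np.argwhere(na.to_numpy())[0]
        raise SpectraValidationError(
            f"{path}: missing value for sample {ids.iloc[r]!r} at wavenumber column {header[c]}"
        )
    try:
        matrix = values.to_numpy(dtype=float)
    except ValueError as exc:
        raise SpectraFormatError(f"{path}: non-numeric absorbance cell: {exc}") from exc

    if axis.size > 1 and axis[0] > axis[-1]:
        axis = axis[::-1].copy()
        matrix = matrix[:, ::-1].copy()

    if metadata is None:
        meta = pd.DataFrame({"sample_id": ids})
    else:
        lookup = read_metadata(metadata) if not isinstance(metadata, pd.DataFrame) else _normalize_meta(metadata)
        dup = lookup["sample_id"][lookup["sample_id"].duplicated()]
        if len(dup):
            raise SpectraValidationError(f"duplicate sample_id in metadata: {dup.iloc[0]!r}")
        meta = pd.DataFrame({"sample_id": ids}).merge(lookup, on="sample_id", how="left")
    return SpectrumSet(wavenumbers=axis, absorbance=matrix, meta=meta)


def write_spectrum_table(
    s: SpectrumSet,
    path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write the wide_csv dialect; absorbances use shortest round-trip floats."""
    frame = pd.DataFrame(s.absorbance, columns=[repr(float(v)) for v in s.wavenumbers])
    frame.insert(0, "sample_id", s.sample_ids)
    frame.to_csv(path, index=False)
    if metadata_path is not None:
        write_metadata(s.meta, metadata_path)


# ---------------------------------------------------------------------------
# JCAMP-DX subset (read-only)
# ---------------------------------------------------------------------------

_LDR = re.compile(r"^##\s*([^=]+?)\s*=\s*(.*)\s*$")


def read_jcamp(path: str | Path) -> SpectrumSet:
    """Read one spectrum from a JCAMP-DX 4.24 ``(X++(Y..Y))`` data block.

    Supports FIRSTX/LASTX/NPOINTS with XFACTOR/YFACTOR scaling; the X value
    starting each data line is informational, Y values are laid out on the
    implied affine grid.  NPOINTS inconsistent with the data is a format
    error.  Descending files come out as ascending SpectrumSets.
    """
    text = Path(path).read_text()
    records: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        m = _LDR.match(line)
        if m:
            key = m.group(1).upper().replace(" ", "")
            val = m.group(2)
            if key in ("XYDATA", "XYPOINTS"):
                in_data = True
                records[key] = val
                continue
            if key == "END":
                in_data = False
                continue
            in_data = False
            records[key] = val
        elif in_data:
            data_lines.append(line)

    if "XYDATA" not in records and "XYPOINTS" not in records:
        raise SpectraFormatError(f"{path}: no XYDATA/XYPOINTS block")

    def fnum(key: str, default: float | None = None) -> float:
        if key not in records:
            if default is None:
                raise SpectraFormatError(f"{path}: missing ##{key}")
            return default
        try:
            return float(records[key])
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: bad ##{key}={records[key]!r}") from exc

    firstx = fnum("FIRSTX")
    lastx = fnum("LASTX")
    npoints = int(fnum("NPOINTS"))
    xfactor = fnum("XFACTOR", 1.0)
    yfactor = fnum("YFACTOR", 1.0)

    ys: list[float] = []
    for line in data_lines:
        parts = line.replace(",", " ").split()
        if not parts:
            continue
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise SpectraFormatError(f"{path}: bad data line {line!r}") from exc
        ys.extend(vals[1:])  # first token is the line's X start
    if len(ys) != npoints:
        raise SpectraFormatError(
            f"{path}: NPOINTS={npoints} but {len(ys)} Y values present"
        )
    if npoints < 2:
        raise SpectraFormatError(f"{path}: need at least two points")

    x = np.linspace(firstx * xfactor, lastx * xfactor, npoints)
    y = np.asarray(ys, dtype=float) * yfactor
    if x[0] > x[-1]:
        x = x[::-1].copy()
        y = y[::-1].copy()
    title = records.get("TITLE", Path(path).stem) or Path(path).stem
    meta = pd.DataFrame({"sample_id": [title]})
    return SpectrumSet(wavenumbers=x, absorbance=y[np.newaxis, :], meta=meta)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

#: absolute slack for closed-interval window comparisons; covers float error
#: accumulated when an axis is built as start + j*spacing.
_WINDOW_ATOL = 1e-8


def trim_window(s: SpectrumSet, low: float, high: float) -> SpectrumSet:
    """Keep exactly the variables with low <= nu <= high (closed interval)."""
    if not low < high:
        raise ValueError(f"window low ({low}) must be below high ({high})")
    keep = (s.wavenumbers >= low - _WINDOW_ATOL) & (s.wavenumbers <= high + _WINDOW_ATOL)
    if not keep.any():
        raise WindowError(
            f"window [{low}, {high}] cm^-1 selects no variables on an axis spanning "
            f"[{s.wavenumbers[0]:.1f}, {s.wavenumbers[-1]:.1f}]"
        )
    return s.select_variables(np.flatnonzero(keep))
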