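"""Spectral dataset containers and I/O.

The central container is :class:`SpectraSet`: a matrix of absorbance spectra
on a shared wavenumber grid plus one :class:`SpectrumMeta` per spectrum.
Spectra are near-infrared transflectance measurements over 12,000-4,000 cm^-1,
stored high-to-low along the wavenumber axis (FTIR plotting convention).

Supported on-disk formats:

* wide CSV — first column ``wavenumber_cm-1``, one column per spectrum named
  ``<sample_id>_r<replicate>``, with a companion metadata CSV holding columns
  ``sample_id, replicate, prep_class, label`` (one row per spectrum column);
* single-block JCAMP-DX files with an AFFN ``##XYDATA=(X++(Y..Y))`` table
  (read only).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyIntervalError,
    EmptySelectionError,
    FormatError,
    GridError,
    ParameterError,
    ParseError,
    ShapeError,
)

WAVENUMBER_MAX = 12_000.0
WAVENUMBER_MIN = 4_000.0

#: Column header for the wavenumber axis in wide CSV files.
WAVENUMBER_COLUMN = "wavenumber_cm-1"


class PrepClass(str, enum.Enum):
    """Tissue-section preparation, which decides the interference signature."""

    PARAFFIN_EMBEDDED = "paraffin_embedded"
    DEPARAFFINIZED = "deparaffinized"
    STAINED = "stained"


class Label(str, enum.Enum):
    """Reference BRAF V600E mutation status of a sample."""

    MUTANT = "mutant"
    WILD_TYPE = "wild_type"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly decreasing wavenumber axis in cm^-1 within [4000, 12000]."""

    values: np.ndarray
    spacing: float = field(init=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise GridError("wavenumber grid must be a 1-D array of length >= 2")
        if np.any(np.diff(values) >= 0):
            raise GridError("wavenumber grid must be strictly decreasing")
        if values.max() > WAVENUMBER_MAX or values.min() < WAVENUMBER_MIN:
            raise GridError(
                f"wavenumbers must lie within [{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}] cm^-1"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", float(np.median(-np.diff(values))))

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SpectrumMeta:
    """Per-spectrum metadata: sample identity, replicate, prep, reference label."""

    sample_id: str
    replicate: int
    prep_class: PrepClass
    label: Label

    def __post_init__(self) -> None:
        if self.replicate not in (1, 2, 3):
            raise FormatError(f"replicate must be 1, 2 or 3, got {self.replicate}")
        object.__setattr__(self, "prep_class", PrepClass(self.prep_class))
        object.__setattr__(self, "label", Label(self.label))

    @property
    def column_name(self) -> str:
        return f"{self.sample_id}_r{self.replicate}"


@dataclass
class SpectraSet:
    """Absorbance spectra (n_spectra x n_points) on a shared grid, with metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: list[SpectrumMeta]

    def __post_init__(self) -> None:
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.absorbance.shape[1] != len(self.grid):
            raise ShapeError(
                f"absorbance has {self.absorbance.shape[1]} columns but grid has "
                f"{len(self.grid)} points"
            )
        if len(self.meta) != self.absorbance.shape[0]:
            raise FormatError(
                f"{len(self.meta)} metadata rows for {self.absorbance.shape[0]} spectra"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ParseError("absorbance matrix contains missing/non-finite values")
        labels_by_sample: dict[str, Label] = {}
        for m in self.meta:
            if m.label is Label.UNKNOWN:
                continue
            previous = labels_by_sample.setdefault(m.sample_id, m.label)
            if previous is not m.label:
                raise FormatError(
                    f"sample {m.sample_id!r} carries inconsistent labels "
                    f"({previous.value} vs {m.label.value})"
                )

    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def labels(self) -> list[Label]:
        return [m.label for m in self.meta]

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.meta]

    def select(self, indices: Sequence[int]) -> "SpectraSet":
        """Row subset, preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(self.grid, self.absorbance[idx], [self.meta[i] for i in idx])


@dataclass(frozen=True)
class SubrangeSpec:
    """Closed wavenumber intervals (high, low), non-overlapping, high-to-low."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        intervals = tuple((float(h), float(lo)) for h, lo in self.intervals)
        if not intervals:
            raise ParameterError("subrange spec needs at least one interval")
        for high, low in intervals:
            if high <= low:
                raise GridError(f"interval ({high:g}, {low:g}) must satisfy high > low")
        for (h1, l1), (h2, l2) in zip(intervals, intervals[1:]):
            if l1 <= h2:
                raise GridError("intervals must be non-overlapping and listed high-to-low")
        object.__setattr__(self, "intervals", intervals)


#: The two modeling subranges carrying the C-H / O-H overtone and combination
#: bands that separate mutant from wild-type tissue.
TWO_SUBRANGES = SubrangeSpec(((9000.0, 6800.0), (6500.0, 4000.0)))

#: Single-interval alternative covering the same region without the gap.
ONE_SUBRANGE = SubrangeSpec(((9000.0, 4000.0),))

FULL_RANGE = SubrangeSpec(((12000.0, 4000.0),))


# ---------------------------------------------------------------------------
# reading / writing


def _read_meta(meta_path: str | Path) -> list[SpectrumMeta]:
    df = pd.read_csv(meta_path, comment="#")
    required = {"sample_id", "replicate", "prep_class", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"metadata file missing columns: {sorted(missing)}")
    return [
        SpectrumMeta(
            sample_id=str(row.sample_id),
            replicate=int(row.replicate),
            prep_class=PrepClass(row.prep_class),
            label=Label(row.label),
        )
        for row in df.itertuples()
    ]


def _validate_grid_column(values: np.ndarray) -> np.ndarray:
    if np.unique(values).size != values.size:
        raise GridError("wavenumber grid contains duplicated values")
    return values


def read_spectra(
    path: str | Path,
    format: str = "csv_wide",
    meta_path: str | Path | None = None,
) -> SpectraSet:
    """Read a validated :class:`SpectraSet` from disk.

    Parameters
    ----------
    path
        Spectra file (wide CSV or JCAMP-DX, see module docstring).
    format
        ``"csv_wide"`` or ``"jcamp_dx"``.
    meta_path
        Metadata CSV with one row per spectrum.

    The wavenumber axis is re-ordered to strictly decreasing if the file
    stores it ascending; duplicated wavenumbers raise :class:`GridError`.
    """
    if format not in ("csv_wide", "jcamp_dx"):
        raise ParameterError(f"unknown format {format!r}")
    if meta_path is None:
        raise FormatError("meta_path is required")
    meta = _read_meta(meta_path)

    if format == "jcamp_dx":
        wavenumbers, ys = _read_jcamp(path)
        matrix = ys[np.newaxis, :]
    else:
        try:
            df = pd.read_csv(path, comment="#")
        except ValueError as exc:  # pragma: no cover - pandas message passthrough
            raise ParseError(str(exc)) from exc
        if df.shape[1] < 2:
            raise FormatError("wide CSV needs a wavenumber column plus >= 1 spectrum")
        try:
            data = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-numeric cell in {path}: {exc}") from exc
        wavenumbers = data[:, 0]
        matrix = data[:, 1:].T
        if matrix.shape[0] != len(meta):
            raise FormatError(
                f"{len(meta)} metadata rows for {matrix.shape[0]} spectrum columns"
            )
        expected = [m.column_name for m in meta]
        got = list(df.columns[1:])
        if got != expected:
            raise FormatError(
                f"spectrum columns {got} do not match metadata-derived names {expected}"
            )

    if len(meta) != matrix.shape[0]:
        raise FormatError(f"{len(meta)} metadata rows for {matrix.shape[0]} spectra")
    _validate_grid_column(wavenumbers)
    order = np.argsort(wavenumbers)[::-1]
    return SpectraSet(WavenumberGrid(wavenumbers[order]), matrix[:, order], meta)


def write_spectra(
    sset: SpectraSet,
    path: str | Path,
    meta_path: str | Path,
    header_comment: str | None = None,
) -> None:
    """Write a :class:`SpectraSet` as wide CSV + metadata CSV (round-trippable)."""
    cols = {WAVENUMBER_COLUMN: sset.grid.values}
    for m, row in zip(sset.meta, sset.absorbance):
        cols[m.column_name] = row
    frame = pd.DataFrame(cols)
    meta_frame = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in sset.meta],
            "replicate": [m.replicate for m in sset.meta],
            "prep_class": [m.prep_class.value for m in sset.meta],
            "label": [m.label.value for m in sset.meta],
        }
    )
    prefix = f"# {header_comment}\n" if header_comment else ""
    with open(path, "w") as fh:
        fh.write(prefix)
        frame.to_csv(fh, index=False)
    with open(meta_path, "w") as fh:
        fh.write(prefix)
        meta_frame.to_csv(fh, index=False)


_JCAMP_NUM = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?")


def _read_jcamp(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a single-block AFFN ``##XYDATA=(X++(Y..Y))`` JCAMP-DX file.

    The x axis is reconstructed from FIRSTX/LASTX/NPOINTS (falling back to
    the per-line abscissas when those records are absent); y values are
    scaled by YFACTOR.
    """
    headers: dict[str, str] = {}
    line_starts: list[float] = []
    ys: list[float] = []
    in_table = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("$$"):
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            headers[key] = value.strip()
            if key == "XYDATA":
                if "(X++(Y..Y))" not in value.replace(" ", ""):
                    raise FormatError(f"unsupported XYDATA form {value.strip()!r}")
                in_table = True
            elif key == "END":
                in_table = False
            continue
        if in_table:
            numbers = _JCAMP_NUM.findall(line)
            if len(numbers) < 2:
                raise ParseError(f"unparseable JCAMP data line: {raw!r}")
            line_starts.append(float(numbers[0]))
            ys.extend(float(tok) for tok in numbers[1:])
    if not ys:
        raise FormatError(f"no XYDATA table found in {path}")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    n = len(ys)
    if "FIRSTX" in headers and "LASTX" in headers:
        first = float(headers["FIRSTX"])
        last = float(headers["LASTX"])
        npoints = int(float(headers.get("NPOINTS", n)))
        if npoints != n:
            raise FormatError(f"NPOINTS={npoints} but table holds {n} y values")
        x = np.linspace(first, last, n)
    else:
        starts = np.asarray(line_starts) * xfactor
        if len(starts) > 1:
            step = (starts[-1] - starts[0]) / (n - n // len(starts))
        else:
            step = 1.0
        x = starts[0] + step * np.arange(n)
    return x, np.asarray(ys, dtype=float) * yfactor


# ---------------------------------------------------------------------------
# slicing and summaries


def extract_subranges(sset: SpectraSet, spec: SubrangeSpec) -> SpectraSet:
    """Restrict a set to the grid points inside the given closed intervals.

    Boundaries are inclusive on both ends; original (high-to-low) point order
    is preserved and intervals are concatenated in their listed order.
    """
    masks = []
    values = sset.grid.values
    for high, low in spec.intervals:
        mask = (values <= high) & (values >= low)
        if not mask.any():
            raise EmptyIntervalError(
                f"interval ({high:g}, {low:g}) cm^-1 contains no grid points"
            )
        masks.append(np.flatnonzero(mask))
    idx = np.concatenate(masks)
    return SpectraSet(WavenumberGrid(values[idx]), sset.absorbance[:, idx], list(sset.meta))


def mean_spectrum(sset: SpectraSet, label: Label) -> np.ndarray:
    """Pointwise mean over all spectra carrying ``label``."""
    label = Label(label)
    rows = [i for i, m in enumerate(sset.meta) if m.label is label]
    if not rows:
        raise EmptySelectionError(f"no spectra with label {label.value!r}")
    selected = sset.absorbance[rows]
    # anchored mean: exact when all selected spectra are identical
    return selected[0] + (selected - selected[0]).mean(axis=0)


def difference_spectrum(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Elementwise ``mean_a - mean_b`` (e.g. mutant minus wild-type mean)."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b
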