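"""Time-course metabolomic tables and their smooth interpolation.

The input is a rectangular CSV: one axis metabolite identifiers, the other
numeric time points (either orientation; auto-detected).  Identifiers are
matched against the map's BiGG ids, optionally tolerating a missing/extra
compartment suffix (``_c``, ``_e`` ...).  Each series is then interpolated —
by default with a natural cubic spline through its non-missing knots — and
sampled at animation frame times.

Interpolation contract:

* the interpolant passes through every non-missing knot (relative error
  below 1e-9);
* no extrapolation: queries outside the measured span return the boundary
  values;
* evaluated values are clamped from below (default floor 0 — concentrations
  cannot be negative), applied after evaluation rather than constraining
  the fit.
"""
from __future__ import annotations

import gzip
import io
import logging
import re
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import BinaryIO, Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

from .maps import MetabolicMap

__all__ = [
    "TimeSeriesTable",
    "MatchReport",
    "InterpolantSet",
    "read_timecourse_csv",
    "match_identifiers",
    "build_interpolants",
    "sample_frames",
    "TimecourseFormatError",
]

log = logging.getLogger(__name__)

GZIP_MAGIC = b"\x1f\x8b"
ZIP_MAGIC = b"PK"

#: One- or two-character compartment suffixes as used by BiGG identifiers.
_COMPARTMENT_RE = re.compile(r"_[a-z][a-z0-9]?$")


class TimecourseFormatError(ValueError):
    """The CSV is not a valid time-course table."""


@dataclass
class TimeSeriesTable:
    """Measured values on a strictly increasing time axis.

    ``series`` maps metabolite id to a value vector aligned with ``times``;
    missing measurements are NaN and flagged in ``missing``.
    """

    times: np.ndarray
    series: dict[str, np.ndarray]
    missing: dict[str, np.ndarray] = field(default_factory=dict)
    time_label: str = "time"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) == 0:
            raise TimecourseFormatError("time axis must be a non-empty 1-D vector")
        if np.any(np.diff(self.times) <= 0):
            raise TimecourseFormatError("time points must be strictly increasing")
        for mid, vals in self.series.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != self.times.shape:
                raise TimecourseFormatError(
                    f"series {mid!r} has {len(vals)} values for {len(self.times)} time points"
                )
            self.series[mid] = vals
            if mid not in self.missing:
                self.missing[mid] = np.isnan(vals)
        for mid, vals in self.series.items():
            ok = ~self.missing[mid]
            if not np.all(np.isfinite(vals[ok])):
                raise TimecourseFormatError(f"series {mid!r} has non-finite values")

    @property
    def n_times(self) -> int:
        return len(self.times)

    def ids(self) -> list[str]:
        return list(self.series)


@dataclass
class MatchReport:
    """Which table identifiers found a node on the map, and which did not."""

    matched: set[str] = field(default_factory=set)
    data_only: set[str] = field(default_factory=set)
    map_only: set[str] = field(default_factory=set)
    #: table id -> map bigg_id, for matches made via compartment-suffix fallback
    aliases: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{len(self.matched)} matched, {len(self.data_only)} in data only, "
            f"{len(self.map_only)} map metabolites without data"
        )


# ---------------------------------------------------------------------------
# CSV reading


def _decode_payload(raw: bytes) -> bytes:
    if raw[:2] == GZIP_MAGIC:
        return gzip.decompress(raw)
    if raw[:2] == ZIP_MAGIC:
        with zipfile.ZipFile(io.BytesIO(raw)) as zf:
            names = [n for n in zf.namelist() if n.lower().endswith(".csv")]
            if not names:
                raise TimecourseFormatError("ZIP archive contains no .csv member")
            return zf.read(names[0])
    return raw


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    counts = {d: first.count(d) for d in (",", ";", "\t")}
    return max(counts, key=counts.get) if max(counts.values()) else ","


def read_timecourse_csv(
    source: Union[str, Path, bytes, BinaryIO],
    delimiter: Optional[str] = None,
    decimal: str = ".",
    orientation: str = "auto",
) -> TimeSeriesTable:
    """Load a time-course table from CSV (plain, gzip or zip-wrapped).

    ``orientation``: ``rows`` = one row per metabolite with numeric time
    headers (the layout used for blood-cell storage time courses),
    ``columns`` = transposed, ``auto`` = detect which axis is all-numeric.
    Empty cells are missing values.
    """
    if isinstance(source, (str, Path)):
        raw = Path(source).read_bytes()
    elif isinstance(source, bytes):
        raw = source
    else:
        raw = source.read()
    text = _decode_payload(raw).decode("utf-8-sig")
    if delimiter is None:
        delimiter = _sniff_delimiter(text)

    try:
        df = pd.read_csv(
            io.StringIO(text), sep=delimiter, decimal=decimal, header=0, index_col=0,
            skip_blank_lines=True,
        )
    except pd.errors.ParserError as exc:
        raise TimecourseFormatError(f"ragged or malformed CSV: {exc}") from exc

    def numeric(labels) -> Optional[np.ndarray]:
        try:
            vals = np.array([float(str(x).strip()) for x in labels])
        except ValueError:
            return None
        return vals if len(vals) else None

    col_times = numeric(df.columns)
    row_times = numeric(df.index)

    if orientation == "auto":
        if col_times is not None:
            orientation = "rows"
        elif row_times is not None:
            orientation = "columns"
        else:
            bad = next(
                str(x) for x in list(df.columns) + list(df.index)
                if numeric([x]) is None
            )
            raise TimecourseFormatError(
                f"neither axis is fully numeric; offending label: {bad!r}"
            )

    if orientation == "rows":
        if col_times is None:
            bad = next(str(x) for x in df.columns if numeric([x]) is None)
            raise TimecourseFormatError(f"non-numeric time label: {bad!r}")
        times, frame = col_times, df
        ids = [str(i) for i in df.index]
        time_label = str(df.index.name or "time")
    elif orientation == "columns":
        if row_times is None:
            bad = next(str(x) for x in df.index if numeric([x]) is None)
            raise TimecourseFormatError(f"non-numeric time label: {bad!r}")
        times, frame = row_times, df.T
        ids = [str(c) for c in df.columns]
        time_label = str(df.columns.name or df.index.name or "time")
    else:
        raise ValueError(f"unknown orientation {orientation!r}")

    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise TimecourseFormatError(f"duplicate metabolite identifiers: {dupes}")

    values = frame.to_numpy(dtype=float)
    order = np.argsort(times, kind="stable")
    times = times[order]
    if np.any(np.diff(times) <= 0):
        raise TimecourseFormatError("duplicate time points in table")
    values = values[:, order]

    series = {mid: values[k] for k, mid in enumerate(ids)}
    return TimeSeriesTable(times=times, series=series, time_label=time_label)


# ---------------------------------------------------------------------------
# identifier matching


def match_identifiers(
    table: TimeSeriesTable,
    metabolic_map: MetabolicMap,
    strip_compartment: bool = True,
) -> MatchReport:
    """Match table identifiers to the map's metabolite BiGG ids.

    Exact matches first; with ``strip_compartment``, an id that fails to
    match retries with the trailing compartment suffix stripped from either
    side (so ``glc__D`` in the data finds ``glc__D_c`` on the map).
    An empty match set is reported with a warning, never an error.
    """
    map_ids = metabolic_map.bigg_ids()
    stripped_map: dict[str, str] = {}
    for mid in sorted(map_ids):
        stripped_map.setdefault(_COMPARTMENT_RE.sub("", mid), mid)

    report = MatchReport()
    for tid in table.ids():
        if tid in map_ids:
            report.matched.add(tid)
            continue
        if strip_compartment:
            t_stripped = _COMPARTMENT_RE.sub("", tid)
            hit = stripped_map.get(tid) or stripped_map.get(t_stripped)
            if hit is None and t_stripped in map_ids:
                hit = t_stripped
            if hit is not None:
                report.matched.add(tid)
                report.aliases[tid] = hit
                continue
        report.data_only.add(tid)

    consumed = set(report.matched) | set(report.aliases.values())
    report.map_only = {
        n.node_id
        for n in metabolic_map.metabolite_nodes()
        if n.bigg_id not in consumed
    }
    if not report.matched:
        log.warning("no table identifier matched any map metabolite")
    return report


# ---------------------------------------------------------------------------
# interpolation


@dataclass
class InterpolantSet:
    """Per-metabolite interpolants over the measured time span."""

    interpolants: dict[str, Callable[[np.ndarray], np.ndarray]]
    t_first: float
    t_last: float
    method: str = "cubic-spline"
    clamp_floor: Optional[float] = 0.0

    def ids(self) -> list[str]:
        return list(self.interpolants)

    def __call__(self, metabolite_id: str, t: Union[float, np.ndarray]) -> np.ndarray:
        """Evaluate one series at time(s) ``t`` (clamped to the data span)."""
        t = np.clip(np.asarray(t, dtype=float), self.t_first, self.t_last)
        v = np.asarray(self.interpolants[metabolite_id](t), dtype=float)
        if self.clamp_floor is not None:
            v = np.maximum(v, self.clamp_floor)
        return v


def _fit_one(t: np.ndarray, v: np.ndarray, method: str) -> Callable:
    n = len(t)
    if n == 1:
        c = float(v[0])
        return lambda x: np.full_like(np.asarray(x, dtype=float), c)
    if method == "pchip":
        return PchipInterpolator(t, v)
    if method == "linear" or n == 2:
        return lambda x, _t=t, _v=v: np.interp(np.asarray(x, dtype=float), _t, _v)
    if n == 3:
        # the unique interpolating quadratic
        coeffs = np.polyfit(t, v, 2)
        return np.poly1d(coeffs)
    return CubicSpline(t, v, bc_type="natural")


def build_interpolants(
    table: TimeSeriesTable,
    method: str = "cubic-spline",
    clamp_floor: Optional[float] = 0.0,
) -> InterpolantSet:
    """Fit one interpolant per series through its non-missing knots.

    ``method``: ``cubic-spline`` (natural boundary; degrades to the unique
    quadratic/linear interpolant for 3/2 knots), ``pchip`` (monotone,
    overshoot-free), or ``linear``.  Series with a single non-missing point
    are held constant with a warning; all-missing series are excluded.
    """
    if method not in ("cubic-spline", "pchip", "linear"):
        raise ValueError(f"unknown interpolation method {method!r}")
    interpolants: dict[str, Callable] = {}
    for mid, vals in table.series.items():
        ok = ~table.missing[mid]
        if not np.any(ok):
            log.warning("series %r is entirely missing; excluded", mid)
            continue
        t, v = table.times[ok], vals[ok]
        if len(t) < 2:
            log.warning("series %r has <2 points; held constant", mid)
        interpolants[mid] = _fit_one(t, v, method)
    return InterpolantSet(
        interpolants=interpolants,
        t_first=float(table.times[0]),
        t_last=float(table.times[-1]),
        method=method,
        clamp_floor=clamp_floor,
    )


def sample_frames(
    interpolants: InterpolantSet, duration_s: float, fps: float
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Evaluate every interpolant on the animation's frame grid.

    Frame ``i`` of ``n = round(duration_s * fps)`` maps affinely onto data
    time ``t_first + i/(n-1) * (t_last - t_first)``; the first and last
    frames therefore carry the measured boundary values exactly.

    Returns ``(frame_times, metabolite_ids, matrix)`` with ``matrix`` of
    shape ``(n_frames, n_metabolites)``.
    """
    if duration_s <= 0 or fps <= 0:
        raise ValueError("duration_s and fps must be positive")
    n_frames = int(round(duration_s * fps))
    n_frames = max(n_frames, 1)
    if interpolants.t_last == interpolants.t_first:
        log.warning("single time point: all frames identical")
    if n_frames == 1:
        frame_times = np.array([interpolants.t_first])
    else:
        u = np.arange(n_frames) / (n_frames - 1)
        frame_times = interpolants.t_first + u * (interpolants.t_last - interpolants.t_first)
    ids = interpolants.ids()
    matrix = np.empty((n_frames, len(ids)))
    for j, mid in enumerate(ids):
        matrix[:, j] = interpolants(mid, frame_times)
    return frame_times, ids, matrix
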