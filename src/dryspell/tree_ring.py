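"""Ring-width series, spline detrending, and robust plot chronologies.

The detrending model is the classical dendrochronological one: each tree's
ring-width series is fitted with a cubic smoothing spline whose amplitude
frequency response is 50% at a chosen wavelength (30 years by default), and
the tree-ring index (TRI) is the ratio of observed to fitted width, so the
index is dimensionless with long-run mean near 1.  Plot chronologies are the
per-year Tukey biweight robust mean of the tree indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import make_smoothing_spline


@dataclass
class RingWidthSeries:
    """Annual ring widths (mm) for one tree; NaN marks a missing ring."""

    tree_id: str
    plot_id: str
    first_year: int
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.widths = np.asarray(self.widths, dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(self.widths[~np.isnan(self.widths)] <= 0):
                raise ValueError(f"{self.tree_id}: non-positive ring width")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + len(self.widths))


@dataclass
class DetrendedSeries:
    tree_id: str
    plot_id: str
    years: np.ndarray
    tri: np.ndarray
    fitted: np.ndarray


@dataclass
class Chronology:
    plot_id: str
    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray
    meta: dict = field(default_factory=dict)


def spline_stiffness(wavelength_years: float) -> float:
    """Penalty weight giving a 50% amplitude response at the wavelength.

    For a cubic smoothing spline on unit-spaced data the frequency response
    is approximately 1 / (1 + lam * omega**4), so a 0.5 response at
    omega = 2*pi/P requires lam = (P / 2*pi)**4.
    """
    return (wavelength_years / (2.0 * math.pi)) ** 4


def spline_detrend(series: RingWidthSeries, wavelength_years: int = 30) -> DetrendedSeries:
    """Fit the 50%-cutoff smoothing spline and return TRI = width / fitted.

    Missing rings (NaN) are excluded from the fit; their TRI stays NaN.
    Raises if the series is shorter than half the cutoff wavelength or if
    the fitted curve is non-positive anywhere.
    """
    w = series.widths
    ok = ~np.isnan(w)
    if ok.sum() < wavelength_years / 2:
        raise ValueError(
            f"{series.tree_id}: {int(ok.sum())} rings < half the "
            f"{wavelength_years}-year cutoff")
    t = np.arange(len(w), dtype=float)
    lam = spline_stiffness(wavelength_years)
    fitted = np.full_like(w, np.nan)
    fitted[ok] = make_smoothing_spline(t[ok], w[ok], lam=lam)(t[ok])
    if np.any(fitted[ok] <= 0):
        raise ValueError(f"{series.tree_id}: fitted spline non-positive")
    tri = np.where(ok, w / fitted, np.nan)
    return DetrendedSeries(series.tree_id, series.plot_id, series.years, tri, fitted)


def tukey_biweight_mean(values: Sequence[float], c: float = 9.0,
                        max_iter: int = 10, rtol: float = 1e-6) -> float:
    """Tukey biweight robust mean with tuning constant ``c`` x MAD.

    Iterates the weighted mean from the median; if the MAD is zero the
    median is returned (degenerate scale).
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("no values")
    m = float(np.median(x))
    mad = float(np.median(np.abs(x - m)))
    if mad == 0.0:
        return m
    s = c * mad
    for _ in range(max_iter):
        u = (x - m) / s
        w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
        if w.sum() == 0.0:
            return m
        new = float(np.sum(w * x) / w.sum())
        if abs(new - m) <= rtol * max(abs(m), 1.0):
            m = new
            break
        m = new
    return m


def build_chronology(detrended: Iterable[DetrendedSeries], plot_id: str,
                     min_depth: int = 5) -> Chronology:
    """Biweight-average tree indices into a plot chronology.

    Years with fewer than ``min_depth`` contributing trees are dropped.
    """
    detrended = [d for d in detrended]
    if not detrended:
        raise ValueError("no detrended series")
    y0 = min(int(d.years[0]) for d in detrended)
    y1 = max(int(d.years[-1]) for d in detrended)
    years = np.arange(y0, y1 + 1)
    mat = np.full((len(detrended), len(years)), np.nan)
    for i, d in enumerate(detrended):
        mat[i, d.years[0] - y0: d.years[-1] - y0 + 1] = d.tri
    depth = np.sum(~np.isnan(mat), axis=0)
    keep = depth >= min_depth
    if not keep.any():
        raise ValueError(f"{plot_id}: no year reaches sample depth {min_depth}")
    index = np.array([tukey_biweight_mean(mat[:, j]) for j in np.nonzero(keep)[0]])
    return Chronology(plot_id, years[keep], index, depth[keep])


# ---------------------------------------------------------------------------
# Tucson RWL interchange
# ---------------------------------------------------------------------------
# One line per decade: series id (<=8 chars), decade start year, then the
# values for consecutive years.  Dialects: stop marker 999 with values in
# 0.01 mm, or -9999 with values in 0.001 mm.  Missing rings are commonly
# coded -999 (0.01 mm dialect) or 0 is NOT used here; we write/read gaps as
# the sentinel -999 in either dialect.

_MISSING = -999


def write_rwl(collection: Iterable[RingWidthSeries], path: str | Path,
              precision: float = 0.01) -> None:
    """Write Tucson RWL; precision 0.01 mm (stop 999) or 0.001 mm (-9999)."""
    if precision not in (0.01, 0.001):
        raise ValueError("precision must be 0.01 or 0.001")
    stop = 999 if precision == 0.01 else -9999
    lines = []
    for s in collection:
        if len(s.tree_id) > 8:
            raise ValueError(f"series id {s.tree_id!r} exceeds the 8-character "
                             "Tucson field")
        vals = [(_MISSING if np.isnan(w) else int(round(w / precision)))
                for w in s.widths]
        vals.append(stop)
        year = s.first_year
        i = 0
        while i < len(vals):
            decade_end = (year // 10) * 10 + 10
            n = min(decade_end - year, len(vals) - i)
            chunk = vals[i:i + n]
            lines.append(f"{s.tree_id:<8.8s}{year:4d}" +
                         "".join(f"{v:6d}" for v in chunk))
            year += n
            i += n
    Path(path).write_text("\n".join(lines) + "\n")


def read_rwl(path: str | Path, precision: float | None = None) -> list[RingWidthSeries]:
    """Read Tucson RWL into ring-width series.

    The unit dialect is auto-detected from the stop marker (999 -> 0.01 mm,
    -9999 -> 0.001 mm) unless ``precision`` is forced.  Plot id defaults to
    the file stem; year gaps inside a series become NaN widths.
    """
    path = Path(path)
    plot_id = path.stem
    per_series: dict[str, dict[int, int]] = {}
    done: set[str] = set()
    stops: dict[str, int] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        sid = line[:8].strip()
        rest = line[8:].split()
        if len(rest) < 2:
            raise ValueError(f"{path}:{lineno}: malformed line")
        try:
            year = int(rest[0])
            vals = [int(v) for v in rest[1:]]
        except ValueError as e:
            raise ValueError(f"{path}:{lineno}: non-numeric field") from e
        if sid in done:
            raise ValueError(f"{path}:{lineno}: duplicate series id {sid!r}")
        store = per_series.setdefault(sid, {})
        for k, v in enumerate(vals):
            if v in (999, -9999) and k == len(vals) - 1:
                stops[sid] = v
                done.add(sid)
                break
            y = year + k
            if y in store:
                raise ValueError(f"{path}:{lineno}: year {y} repeated in {sid!r}")
            store[y] = v
    out = []
    for sid, store in per_series.items():
        stop = stops.get(sid, 999)
        prec = precision if precision is not None else (0.01 if stop == 999 else 0.001)
        years = sorted(store)
        first, last = years[0], years[-1]
        w = np.full(last - first + 1, np.nan)
        for y, v in store.items():
            if v != _MISSING:
                w[y - first] = v * prec
        out.append(RingWidthSeries(sid, plot_id, first, w))
    return out
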