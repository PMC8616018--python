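"""Spectral containers and FTIR preprocessing.

All grids are wavenumbers in cm^-1, strictly ascending; wavelength is
derived on demand as lambda[um] = 1e4 / nu[cm^-1].  Unreliable points are
carried as an explicit boolean ``valid`` mask parallel to the values -- they
are never dropped, so masked regions survive every pipeline stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "ReplicateSet",
    "SpectrumFormatError",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "average_replicates",
    "baseline_correct",
    "remove_co2_band",
    "normalize_at",
]

KINDS = ("absorbance", "k", "n", "d_eff")

#: default CO2 asymmetric-stretch artifact interval, cm^-1
CO2_BAND = (2280.0, 2400.0)


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file cannot be parsed."""


@dataclass
class Spectrum:
    """A sampled scalar function of wavenumber.

    Parameters
    ----------
    wavenumbers : array, cm^-1, strictly increasing, all > 0.
    values : array, same length; absorbance / k / n (unitless) or d_eff (um).
    kind : one of ``{"absorbance", "k", "n", "d_eff"}``.
    meta : free-form provenance record (sample id, haematocrit, replicate...).
    valid : boolean reliability mask, parallel to ``values``.
    """

    wavenumbers: np.ndarray
    values: np.ndarray
    kind: str = "absorbance"
    meta: dict = field(default_factory=dict)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.wavenumbers.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.kind not in KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {KINDS}")
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size < 2:
            raise ValueError("a spectrum needs a 1-d grid with at least 2 points")
        if self.values.shape != self.wavenumbers.shape or self.valid.shape != self.wavenumbers.shape:
            raise ValueError("wavenumbers, values and valid must have identical length")
        if np.any(self.wavenumbers <= 0):
            raise ValueError("wavenumbers must all be > 0")
        d = np.diff(self.wavenumbers)
        if np.any(d == 0):
            raise ValueError("duplicate wavenumbers in grid")
        if np.any(d < 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite everywhere (use the valid mask, not NaN)")

    # -- convenience -------------------------------------------------------

    @property
    def wavelengths_um(self) -> np.ndarray:
        return 1e4 / self.wavenumbers

    def value_at(self, wavenumber: float) -> float:
        """Linearly interpolated value at an (possibly off-grid) wavenumber."""
        lo, hi = self.wavenumbers[0], self.wavenumbers[-1]
        if not (lo - 1e-9 <= wavenumber <= hi + 1e-9):
            raise ValueError(f"wavenumber {wavenumber} outside grid range [{lo}, {hi}]")
        return float(np.interp(wavenumber, self.wavenumbers, self.values))

    def with_values(self, values: np.ndarray, **meta_updates) -> "Spectrum":
        meta = dict(self.meta, **meta_updates)
        return Spectrum(self.wavenumbers.copy(), np.asarray(values, float),
                        self.kind, meta, self.valid.copy())

    def copy(self) -> "Spectrum":
        return replace(self, wavenumbers=self.wavenumbers.copy(),
                       values=self.values.copy(), meta=dict(self.meta),
                       valid=self.valid.copy())


@dataclass
class ReplicateSet:
    """Replicate measurements of one sample, all of the same kind."""

    members: list
    grid_policy: str = "first"

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty replicate set")
        kinds = {m.kind for m in self.members}
        if len(kinds) != 1:
            raise ValueError(f"replicates mix kinds: {sorted(kinds)}")

    def aligned(self) -> "ReplicateSet":
        """Resample every member onto a shared grid (clipped common overlap)."""
        if self.grid_policy != "first":
            raise ValueError(f"unknown grid policy {self.grid_policy!r}")
        lo = max(m.wavenumbers[0] for m in self.members)
        hi = min(m.wavenumbers[-1] for m in self.members)
        if lo >= hi:
            raise ValueError("replicate grids do not overlap")
        base = self.members[0].wavenumbers
        grid = base[(base >= lo - 1e-9) & (base <= hi + 1e-9)]
        out = [m if np.array_equal(m.wavenumbers, grid) else resample(m, grid)
               for m in self.members]
        return ReplicateSet(out, self.grid_policy)


# -- file I/O --------------------------------------------------------------

def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".dx", ".jdx", ".jcm", ".jcamp"):
        return "jcampdx"
    return "csv"


def read_spectrum(path, format: str | None = None, kind: str | None = None) -> Spectrum:
    """Read a two-column wavenumber/value spectrum from CSV or JCAMP-DX.

    Files stored in descending wavenumber order (the instrument convention)
    are reversed, not rejected.  Duplicate wavenumbers raise a validation
    error; unparseable content raises :class:`SpectrumFormatError` naming the
    offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"spectrum file not found: {path}")
    fmt = format or _sniff_format(path)
    if fmt == "csv":
        spec = _read_csv(path, kind)
    elif fmt == "jcampdx":
        spec = _read_jcampdx(path, kind)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return spec


def _finalize(wn, vals, valid, kind, meta, path) -> Spectrum:
    wn = np.asarray(wn, float)
    vals = np.asarray(vals, float)
    valid = np.asarray(valid, bool)
    if wn.size and wn.size > 1 and wn[0] > wn[-1]:
        wn, vals, valid = wn[::-1], vals[::-1], valid[::-1]
    if np.unique(wn).size != wn.size:
        raise ValueError(f"duplicate wavenumbers in {path}")
    meta = dict(meta, source=str(path))
    return Spectrum(wn, vals, kind, meta, valid)


def _read_csv(path: Path, kind: str | None) -> Spectrum:
    wn, vals, valid = [], [], []
    header_kind = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.split(",")]
            try:
                x = float(fields[0])
            except ValueError:
                # tolerate exactly one header line
                if header_kind is None and wn == []:
                    header_kind = fields[1] if len(fields) > 1 else None
                    continue
                raise SpectrumFormatError(
                    f"{path}:{lineno}: cannot parse {line!r}") from None
            if len(fields) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: missing value column")
            try:
                y = float(fields[1])
            except ValueError:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: cannot parse value {fields[1]!r}") from None
            v = True
            if len(fields) >= 3 and fields[2] != "":
                v = bool(int(float(fields[2])))
            wn.append(x)
            vals.append(y)
            valid.append(v)
    if len(wn) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data rows")
    k = kind or (header_kind if header_kind in KINDS else "absorbance")
    return _finalize(wn, vals, valid, k, {}, path)


_JCAMP_YUNITS = {"absorbance": "ABSORBANCE", "k": "K", "n": "N", "d_eff": "D_EFF"}
_JCAMP_YUNITS_INV = {v: k for k, v in _JCAMP_YUNITS.items()}


def _read_jcampdx(path: Path, kind: str | None) -> Spectrum:
    records: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    mode = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                name, _, value = line[2:].partition("=")
                name = name.strip().upper().replace(" ", "")
                value = value.strip()
                if name in ("XYPOINTS", "XYDATA"):
                    mode = name
                    records[name] = value
                elif name == "END":
                    mode = None
                else:
                    records[name] = value
                continue
            if mode in ("XYPOINTS", "XYDATA"):
                data_lines.append((lineno, line))
    if mode is None and "XYPOINTS" not in records and "XYDATA" not in records:
        raise SpectrumFormatError(f"{path}: no XYPOINTS/XYDATA block found")
    xfac = float(records.get("XFACTOR", 1.0))
    yfac = float(records.get("YFACTOR", 1.0))
    wn, vals = [], []
    if "XYPOINTS" in records:
        for lineno, line in data_lines:
            for pair in line.replace(";", " ;").split(";"):
                pair = pair.strip()
                if not pair:
                    continue
                parts = pair.replace(",", " ").split()
                if len(parts) != 2:
                    raise SpectrumFormatError(f"{path}:{lineno}: bad XY pair {pair!r}")
                try:
                    wn.append(float(parts[0]) * xfac)
                    vals.append(float(parts[1]) * yfac)
                except ValueError:
                    raise SpectrumFormatError(
                        f"{path}:{lineno}: bad XY pair {pair!r}") from None
    else:  # XYDATA (X++(Y..Y)), plain AFFN only
        for lineno, line in data_lines:
            if any(c.isalpha() for c in line.replace("E", "").replace("e", "")):
                raise SpectrumFormatError(
                    f"{path}:{lineno}: compressed JCAMP (SQZ/DIF) not supported")
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(f"{path}:{lineno}: bad XYDATA line")
            try:
                x0 = float(parts[0]) * xfac
                ys = [float(p) * yfac for p in parts[1:]]
            except ValueError:
                raise SpectrumFormatError(f"{path}:{lineno}: bad XYDATA line") from None
            npts = int(float(records.get("NPOINTS", 0)))
            firstx = float(records.get("FIRSTX", x0))
            lastx = float(records.get("LASTX", x0))
            dx = (lastx - firstx) / (npts - 1) if npts > 1 else 0.0
            for j, y in enumerate(ys):
                wn.append(x0 + j * dx)
                vals.append(y)
    if len(wn) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")
    yunits = records.get("YUNITS", "").upper()
    k = kind or _JCAMP_YUNITS_INV.get(yunits, "absorbance")
    meta = {"title": records.get("TITLE", "")}
    return _finalize(wn, vals, np.ones(len(wn), bool), k, meta, path)


def write_spectrum(spec: Spectrum, path, format: str | None = None) -> Path:
    """Write a spectrum as CSV or JCAMP-DX (XYPOINTS), with provenance header."""
    from . import __version__

    path = Path(path)
    fmt = format or _sniff_format(path)
    ops = spec.meta.get("operations", [])
    prov = f"bloodmir {__version__}; operations: {json.dumps(ops)}"
    if fmt == "csv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# {prov}\n")
            for key in ("sample", "haematocrit", "replicate", "config_hash"):
                if key in spec.meta:
                    fh.write(f"# {key}: {spec.meta[key]}\n")
            all_valid = bool(np.all(spec.valid))
            fh.write(f"wavenumber_cm-1,{spec.kind}" + ("" if all_valid else ",valid") + "\n")
            for x, y, v in zip(spec.wavenumbers, spec.values, spec.valid):
                row = f"{x:.10g},{y:.10g}"
                if not all_valid:
                    row += f",{int(v)}"
                fh.write(row + "\n")
    elif fmt == "jcampdx":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"##TITLE={spec.meta.get('sample', path.stem)}\n")
            fh.write("##JCAMP-DX=4.24\n##DATA TYPE=INFRARED SPECTRUM\n")
            fh.write(f"##ORIGIN={prov}\n##OWNER=\n")
            fh.write("##XUNITS=1/CM\n")
            fh.write(f"##YUNITS={_JCAMP_YUNITS[spec.kind]}\n")
            fh.write("##XFACTOR=1\n##YFACTOR=1\n")
            fh.write(f"##FIRSTX={spec.wavenumbers[0]:.10g}\n")
            fh.write(f"##LASTX={spec.wavenumbers[-1]:.10g}\n")
            fh.write(f"##NPOINTS={spec.wavenumbers.size}\n")
            fh.write("##XYPOINTS=(XY..XY)\n")
            for x, y in zip(spec.wavenumbers, spec.values):
                fh.write(f"{x:.10g}, {y:.10g}\n")
            fh.write("##END=\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


# -- grid operations -------------------------------------------------------

def resample(spec: Spectrum, grid) -> Spectrum:
    """Linear interpolation onto ``grid``; extrapolation is refused.

    A target point bracketed by any invalid source point is marked invalid.
    """
    grid = np.asarray(grid, dtype=float)
    if grid[0] < spec.wavenumbers[0] - 1e-9 or grid[-1] > spec.wavenumbers[-1] + 1e-9:
        raise ValueError(
            f"resample target [{grid[0]}, {grid[-1]}] exceeds source range "
            f"[{spec.wavenumbers[0]}, {spec.wavenumbers[-1]}]; no silent extrapolation")
    vals = np.interp(grid, spec.wavenumbers, spec.values)
    vfrac = np.interp(grid, spec.wavenumbers, spec.valid.astype(float))
    valid = vfrac > 1.0 - 1e-9
    meta = dict(spec.meta)
    meta["operations"] = list(meta.get("operations", [])) + ["resample"]
    return Spectrum(grid, vals, spec.kind, meta, valid)


def average_replicates(reps) -> Spectrum:
    """Pointwise arithmetic mean of an aligned replicate set."""
    if isinstance(reps, (list, tuple)):
        reps = ReplicateSet(list(reps))
    reps = reps.aligned()
    stack = np.vstack([m.values for m in reps.members])
    valid = np.logical_and.reduce([m.valid for m in reps.members])
    mean = stack.mean(axis=0)
    first = reps.members[0]
    meta = dict(first.meta, n_replicates=len(reps.members))
    meta["operations"] = list(meta.get("operations", [])) + ["average_replicates"]
    return Spectrum(first.wavenumbers.copy(), mean, first.kind, meta, valid)


def _lower_convex_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of (x, y), left to right."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            cross = (x[i1] - x[i0]) * (y[i] - y[i0]) - (y[i1] - y[i0]) * (x[i] - x[i0])
            if cross <= 0:  # i1 is above or on the chord i0->i: drop it
                hull.pop()
            else:
                break
        hull.append(i)
    return np.asarray(hull, dtype=int)


def baseline_correct(spec: Spectrum, method: str = "linear_endpoints") -> Spectrum:
    """Subtract a baseline from an absorbance spectrum.

    ``linear_endpoints`` removes the straight line through the first and last
    samples (exact for linear instrumental drift on spectra whose endpoints
    carry no signal).  ``rubberband`` subtracts the lower convex hull, the
    classic FTIR rubberband correction.  Both are idempotent.
    """
    if spec.kind != "absorbance":
        raise ValueError(f"baseline correction applies to absorbance, not {spec.kind!r}")
    x, y = spec.wavenumbers, spec.values
    if method == "linear_endpoints":
        baseline = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
    elif method == "rubberband":
        hull = _lower_convex_hull(x, y)
        baseline = np.interp(x, x[hull], y[hull])
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    out = spec.with_values(y - baseline, baseline_method=method)
    out.meta["operations"] = list(spec.meta.get("operations", [])) + [f"baseline:{method}"]
    return out


def remove_co2_band(spec: Spectrum, band: tuple[float, float] = CO2_BAND) -> Spectrum:
    """Replace values inside the CO2 artifact band by the straight chord
    between the band-edge samples; all points outside the band are untouched."""
    lo, hi = band
    if lo >= hi:
        raise ValueError("band must be (low, high) with low < high")
    x = spec.wavenumbers
    if lo < x[0] or hi > x[-1]:
        raise ValueError(f"CO2 band [{lo}, {hi}] outside grid range [{x[0]}, {x[-1]}]")
    i_left = int(np.searchsorted(x, lo, side="right") - 1)   # last point <= lo
    i_right = int(np.searchsorted(x, hi, side="left"))       # first point >= hi
    vals = spec.values.copy()
    inside = slice(i_left + 1, i_right)
    x0, x1 = x[i_left], x[i_right]
    y0, y1 = vals[i_left], vals[i_right]
    vals[inside] = y0 + (y1 - y0) * (x[inside] - x0) / (x1 - x0)
    out = spec.with_values(vals)
    out.meta["operations"] = list(spec.meta.get("operations", [])) + [
        f"remove_co2:{lo}-{hi}"]
    return out


def normalize_at(spec: Spectrum, anchor: float = 3300.0) -> Spectrum:
    """Divide the spectrum by its (interpolated) value at ``anchor``.

    Used for display-style normalisation at the O-H stretch peak; idempotent
    and scale invariant.  A near-zero anchor value signals a wrong anchor or
    an empty measurement cell and is refused.
    """
    c = spec.value_at(anchor)
    if abs(c) <= 1e-6:
        raise ValueError(
            f"value at anchor {anchor} cm^-1 is {c:.2e}; refusing to normalize")
    out = spec.with_values(spec.values / c, normalized_at=anchor)
    out.meta["operations"] = list(spec.meta.get("operations", [])) + [
        f"normalize_at:{anchor}"]
    return out
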