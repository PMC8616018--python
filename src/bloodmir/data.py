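"""Bundled water optical constants.

The d_eff calibration and the Kramers-Kronig anchor both need liquid-water
n and k over (at least) 400-5200 cm^-1.  The packaged table,
``data/water_nk_synthetic.csv``, is a SYNTHETIC stand-in: a small
oscillator model (libration, O-H bend at ~1643 cm^-1, association band at
~2127 cm^-1, two O-H stretch components near 3300 cm^-1) whose band
positions and magnitudes track published liquid-water tables (Downing &
Williams 1975; Hale & Querry 1973), with the real index generated from k by
this package's own Kramers-Kronig transform on a wide grid and anchored to
n = 1.306 at 5000 cm^-1 (2 um).  It is internally KK-consistent, which is
what the round-trip validation of the pipeline requires; it is not a
measured dataset.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = ["WATER_OSCILLATORS", "WATER_ANCHOR", "build_water_table",
           "load_water_table", "water_table_path"]

#: (center cm^-1, peak k amplitude, HWHM cm^-1, shape) for the water model
WATER_OSCILLATORS = (
    (590.0, 0.360, 180.0, "lorentzian"),   # libration
    (1643.0, 0.105, 70.0, "gaussian"),     # O-H bend
    (2127.0, 0.015, 160.0, "gaussian"),    # association band
    (3280.0, 0.210, 180.0, "gaussian"),    # O-H stretch (low component)
    (3450.0, 0.170, 160.0, "gaussian"),    # O-H stretch (high component)
)

#: anchor: n of water at 2 um (5000 cm^-1), a low-loss window
WATER_ANCHOR = (5000.0, 1.306)


def _oscillator_k(nu: np.ndarray, center: float, amplitude: float,
                  width: float, shape: str) -> np.ndarray:
    if shape == "lorentzian":
        return amplitude * width**2 / ((nu - center) ** 2 + width**2)
    if shape == "gaussian":
        return amplitude * np.exp(-np.log(2.0) * ((nu - center) / width) ** 2)
    raise ValueError(f"unknown oscillator shape {shape!r}")


def build_water_table(lo: float = 400.0, hi: float = 5200.0, step: float = 4.0):
    """Regenerate the synthetic water n,k table from the oscillator model.

    k is evaluated on a wide internal grid (300-5600 cm^-1 at 2 cm^-1) so
    that the finite-range KK truncation error inside [lo, hi] is negligible,
    then both n and k are cropped/resampled to the requested grid.
    """
    from .optics import ComplexIndexSpectrum, _maclaurin_hilbert

    wide = np.arange(300.0, 5600.0 + 1.0, 2.0)
    k_wide = np.zeros_like(wide)
    for center, amp, width, shape in WATER_OSCILLATORS:
        k_wide += _oscillator_k(wide, center, amp, width, shape)
    dn = _maclaurin_hilbert(wide, k_wide)
    anchor_nu, anchor_n = WATER_ANCHOR
    n_wide = dn + (anchor_n - float(np.interp(anchor_nu, wide, dn)))
    grid = np.arange(lo, hi + step / 2.0, step)
    n = np.interp(grid, wide, n_wide)
    k = np.interp(grid, wide, k_wide)
    return ComplexIndexSpectrum(grid, n, k, meta={"source": "synthetic water model"})


def write_water_table(path) -> Path:
    """Write the synthetic table to CSV (used to regenerate the fixture)."""
    table = build_water_table()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# SYNTHETIC water optical constants: oscillator-model emulation of\n"
                 "# published liquid-water n,k tables (Downing & Williams 1975;\n"
                 "# Hale & Querry 1973). Generated by bloodmir.data.write_water_table;\n"
                 "# n from k via Maclaurin Kramers-Kronig on a 300-5600 cm-1 grid,\n"
                 "# anchored n(5000 cm-1) = 1.306.\n")
        fh.write("wavenumber_cm-1,n,k\n")
        for x, n, k in zip(table.wavenumbers, table.n, table.k):
            fh.write(f"{x:.6g},{n:.8g},{k:.8g}\n")
    return path


def water_table_path() -> Path:
    return Path(resources.files("bloodmir") / "data" / "water_nk_synthetic.csv")


@lru_cache(maxsize=1)
def load_water_table():
    """Load the packaged water n,k table as a ComplexIndexSpectrum."""
    from .optics import ComplexIndexSpectrum

    path = water_table_path()
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line[0].isalpha() or line.startswith("wave"):
                continue
            rows.append([float(f) for f in line.split(",")])
    arr = np.asarray(rows, float)
    return ComplexIndexSpectrum(arr[:, 0], arr[:, 1], arr[:, 2],
                                meta={"source": str(path)})
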