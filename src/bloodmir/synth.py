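"""Synthetic whole-blood ATR-FTIR spectra with known ground truth.

The generative model is a water background (the bundled optical-constants
table) plus Lorentzian/Gaussian oscillators: plasma protein bands (amide I
near 1640 cm^-1, amide II near 1545 cm^-1) that are present at every
haematocrit, and red-cell bands concentrated in 1370-1620 cm^-1 whose
contribution scales as coupling * haematocrit.  The coupling gamma in [0, 1]
encodes the fraction of the cellular material that reaches the evanescent
field (cells partially, not fully, excluded).  Because the cell term is
additive and linear in haematocrit, the ground-truth error slope that the
analysis must recover is known exactly.

Instrument-like absorbance spectra are produced by the forward ATR model
plus seeded Gaussian noise, a small linear baseline drift and a CO2 artifact
band; everything is deterministic for a fixed (seed, haematocrit,
replicate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data import load_water_table, _oscillator_k
from .optics import ATRConfig, ComplexIndexSpectrum, forward_atr_absorbance, kk_n_from_k
from .spectra import Spectrum, write_spectrum

__all__ = ["Oscillator", "BiofluidModel", "water_nk", "synth_nk",
           "synth_absorbance", "synth_water_absorbance", "make_study",
           "load_manifest", "true_error_slope"]


@dataclass(frozen=True)
class Oscillator:
    """One absorption band: peak k contribution at ``center`` with HWHM ``width``."""

    center: float
    amplitude: float
    width: float
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.width <= 0 or self.center <= 0:
            raise ValueError("oscillator needs amplitude >= 0, width > 0, center > 0")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown shape {self.shape!r}")

    def k_profile(self, nu: np.ndarray) -> np.ndarray:
        return _oscillator_k(np.asarray(nu, float), self.center,
                             self.amplitude, self.width, self.shape)

    def dispersion(self, nu: np.ndarray) -> np.ndarray:
        """Closed-form Kramers-Kronig partner dn(nu) of a Lorentzian k line.

        dn = a w [ (nu+c)/((nu+c)^2+w^2) - (nu-c)/((nu-c)^2+w^2) ],
        the exact Hilbert pair of the odd-symmetrised Lorentzian.  Used as an
        independent analytic oracle; not defined for Gaussian lines.
        """
        if self.shape != "lorentzian":
            raise NotImplementedError("closed-form dispersion only for Lorentzian lines")
        nu = np.asarray(nu, float)
        a, c, w = self.amplitude, self.center, self.width
        return a * w * ((nu + c) / ((nu + c) ** 2 + w**2)
                        - (nu - c) / ((nu - c) ** 2 + w**2))

    def symmetrized_k(self, nu: np.ndarray) -> np.ndarray:
        """Odd-symmetrised Lorentzian k (the exact partner of ``dispersion``)."""
        if self.shape != "lorentzian":
            raise NotImplementedError
        nu = np.asarray(nu, float)
        a, c, w = self.amplitude, self.center, self.width
        return a * w**2 / ((nu - c) ** 2 + w**2) - a * w**2 / ((nu + c) ** 2 + w**2)


# realistic defaults: plasma protein bands well below the water bend peak,
# cell bands concentrated in the 1370-1620 cm^-1 window where whole blood
# departs most strongly from plasma
DEFAULT_PLASMA_OSCILLATORS = (
    Oscillator(1642.0, 0.012, 36.0),   # amide I
    Oscillator(1547.0, 0.009, 30.0),   # amide II
)
DEFAULT_CELL_OSCILLATORS = (
    Oscillator(1541.0, 0.040, 28.0),   # amide II (cell-surface protein)
    Oscillator(1450.0, 0.010, 32.0),   # CH2 bending
    Oscillator(1396.0, 0.008, 26.0),   # COO- symmetric stretch
)


def default_grid() -> np.ndarray:
    """Instrument grid: 600-4000 cm^-1 at 4 cm^-1 resolution."""
    return np.arange(600.0, 4000.0 + 2.0, 4.0)


@dataclass
class BiofluidModel:
    """Generative description of water + plasma + haematocrit-scaled cells.

    noise_sd is additive Gaussian noise on absorbance (per point, per
    replicate); baseline_drift is the maximum absolute endpoint value of a
    random linear drift; co2_artifact is the amplitude of an injected
    2280-2400 cm^-1 band.
    """

    grid: np.ndarray = field(default_factory=default_grid)
    plasma_oscillators: tuple = DEFAULT_PLASMA_OSCILLATORS
    cell_oscillators: tuple = DEFAULT_CELL_OSCILLATORS
    coupling: float = 0.3
    noise_sd: float = 0.001
    baseline_drift: float = 0.0005
    co2_artifact: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, float)
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return {
            "grid": [float(self.grid[0]), float(self.grid[-1]),
                     float(self.grid[1] - self.grid[0])],
            "plasma_oscillators": [vars(o) for o in self.plasma_oscillators],
            "cell_oscillators": [vars(o) for o in self.cell_oscillators],
            "coupling": self.coupling,
            "noise_sd": self.noise_sd,
            "baseline_drift": self.baseline_drift,
            "co2_artifact": self.co2_artifact,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiofluidModel":
        lo, hi, step = d["grid"]
        return cls(
            grid=np.arange(lo, hi + step / 2.0, step),
            plasma_oscillators=tuple(Oscillator(**o) for o in d["plasma_oscillators"]),
            cell_oscillators=tuple(Oscillator(**o) for o in d["cell_oscillators"]),
            coupling=d["coupling"],
            noise_sd=d["noise_sd"],
            baseline_drift=d["baseline_drift"],
            co2_artifact=d["co2_artifact"],
            seed=d["seed"],
        )


def water_nk(grid) -> ComplexIndexSpectrum:
    """The bundled water table resampled onto ``grid`` (no extrapolation)."""
    return load_water_table().resampled(np.asarray(grid, float))


def _component_k(model: BiofluidModel):
    nu = model.grid
    water = water_nk(nu)
    plasma_k = np.zeros_like(nu)
    for osc in model.plasma_oscillators:
        plasma_k += osc.k_profile(nu)
    cell_k_unit = np.zeros_like(nu)  # per unit (coupling * hct)
    for osc in model.cell_oscillators:
        cell_k_unit += osc.k_profile(nu)
    return water, plasma_k, cell_k_unit


def synth_nk(model: BiofluidModel, hct: float) -> ComplexIndexSpectrum:
    """Ground-truth complex index at haematocrit ``hct``.

    k = water k + plasma bands + coupling * hct * cell bands.  n is the
    water-table n plus the module's own KK transform of the added (oscillator)
    k, so the (n, k) pair is self-consistent by construction.  The additive
    components are retained in ``meta['components']`` for oracle tests.
    """
    if not (0.0 <= hct <= 1.0):
        raise ValueError("haematocrit must be a fraction in [0, 1]")
    nu = model.grid
    water, plasma_k, cell_k_unit = _component_k(model)
    added_k = plasma_k + model.coupling * hct * cell_k_unit
    k = water.k + added_k
    # KK of the additive part only: the water table n already carries the
    # wide-grid KK of the water k, and the transform is linear.
    added_spec = Spectrum(nu, added_k, "k")
    dn = kk_n_from_k(added_spec, anchor_wavenumber=float(nu[-1]), anchor_n=0.0)
    n = water.n + dn.values
    components = {
        "water_k": water.k.copy(),
        "plasma_k": plasma_k,
        "cell_k_per_unit_hct": model.coupling * cell_k_unit,
        "added_dn": dn.values.copy(),
    }
    return ComplexIndexSpectrum(nu.copy(), n, k, water.valid.copy(),
                                {"haematocrit": hct, "components": components})


def _artifacts(model: BiofluidModel, rng: np.random.Generator) -> np.ndarray:
    nu = model.grid
    t = (nu - nu[0]) / (nu[-1] - nu[0])
    u1, u2, u3 = rng.uniform(-1.0, 1.0, size=3)
    drift = model.baseline_drift * (u1 * (1.0 - t) + u2 * t)
    co2 = model.co2_artifact * (1.0 + 0.25 * u3) * np.exp(
        -np.log(2.0) * ((nu - 2350.0) / 25.0) ** 2)
    noise = rng.normal(0.0, model.noise_sd, size=nu.size)
    return drift + co2 + noise


def _rng_for(model: BiofluidModel, tag: int, hct: float, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(model.seed), int(tag), int(round(hct * 1e6)), int(replicate)])


def synth_absorbance(model: BiofluidModel, hct: float,
                     atr: ATRConfig = ATRConfig(), replicate: int = 1) -> Spectrum:
    """Instrument-like absorbance of blood at ``hct`` (one replicate)."""
    if replicate < 1:
        raise ValueError("replicate index starts at 1")
    clean = forward_atr_absorbance(synth_nk(model, hct), atr)
    rng = _rng_for(model, 1, hct, replicate)
    vals = clean.values + _artifacts(model, rng)
    meta = dict(clean.meta, sample=f"hct_{hct:.2f}", haematocrit=hct,
                replicate=replicate)
    meta.pop("components", None)
    return Spectrum(clean.wavenumbers, vals, "absorbance", meta, clean.valid)


def synth_water_absorbance(model: BiofluidModel, atr: ATRConfig = ATRConfig(),
                           replicate: int = 1) -> Spectrum:
    """Instrument-like absorbance of the water calibration reference."""
    if replicate < 1:
        raise ValueError("replicate index starts at 1")
    water = water_nk(model.grid)
    clean = forward_atr_absorbance(water, atr)
    rng = _rng_for(model, 2, 0.0, replicate)
    vals = clean.values + _artifacts(model, rng)
    meta = dict(sample="water", replicate=replicate)
    return Spectrum(clean.wavenumbers, vals, "absorbance", meta, clean.valid)


def true_error_slope(model: BiofluidModel, wavenumber: float,
                     component: str = "k") -> float:
    """Generator-truth slope of the percentage error vs haematocrit fraction.

    For k the error at the cell band is exactly linear in haematocrit:
    error% = 100 * hct * coupling * A_cell(nu) / k_plasma(nu), so the slope
    is 100 * coupling * A_cell / k_plasma (% per haematocrit fraction).  For
    n the analogous expression uses the closed-form Lorentzian dispersion of
    the cell bands over the plasma n.
    """
    nu = model.grid
    j = int(np.argmin(np.abs(nu - wavenumber)))
    water, plasma_k, cell_k_unit = _component_k(model)
    if component == "k":
        k_plasma = water.k[j] + plasma_k[j]
        return 100.0 * model.coupling * cell_k_unit[j] / k_plasma
    if component == "n":
        plasma = synth_nk(model, 0.0)
        dn_cell = np.zeros_like(nu)
        for osc in model.cell_oscillators:
            dn_cell += osc.dispersion(nu)
        return 100.0 * model.coupling * dn_cell[j] / plasma.n[j]
    raise ValueError("component must be 'n' or 'k'")


def make_study(model: BiofluidModel, hct_list, replicates: int = 3,
               out_dir=None, atr: ATRConfig = ATRConfig()) -> dict:
    """Generate a complete study: water reference, plasma, haematocrit series.

    Every sample -- water and plasma included -- is written in ``replicates``
    replicate files (the study protocol characterises each sample in
    triplicate), giving replicates * (2 + len(hct_list)) spectra plus a JSON
    manifest recording the full model and the ground truth needed by oracle
    tests.  With ``out_dir=None`` the spectra are returned in memory.
    """
    hct_list = [float(h) for h in hct_list]
    if not hct_list:
        raise ValueError("hct_list must be non-empty")
    for h in hct_list:
        if not (0.0 < h <= 1.0):
            raise ValueError(f"haematocrit {h} outside (0, 1]")
    if len(set(hct_list)) != len(hct_list):
        raise ValueError("haematocrit values must be unique")

    water_reps = [synth_water_absorbance(model, atr, r)
                  for r in range(1, replicates + 1)]
    plasma_reps = [synth_absorbance(model, 0.0, atr, r)
                   for r in range(1, replicates + 1)]
    sample_reps = {h: [synth_absorbance(model, h, atr, r)
                       for r in range(1, replicates + 1)]
                   for h in hct_list}

    main_cell = max(model.cell_oscillators, key=lambda o: o.amplitude)
    manifest = {
        "format": "bloodmir-study/1",
        "model": model.to_dict(),
        "atr": vars(atr),
        "hct_list": hct_list,
        "replicates": replicates,
        "truth": {
            "cell_center_cm-1": main_cell.center,
            "true_k_error_slope_pct_per_hct": true_error_slope(model, main_cell.center, "k"),
        },
    }

    if out_dir is None:
        manifest["spectra"] = {"water": water_reps, "plasma": plasma_reps,
                               "samples": sample_reps}
        return manifest

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"study directory {out_dir} is not writable: {exc}") from exc

    files: dict = {"water": [], "plasma": [], "samples": {}}
    for r, spec in enumerate(water_reps, start=1):
        name = f"water_rep{r}.csv"
        write_spectrum(spec, out_dir / name)
        files["water"].append(name)
    for r, spec in enumerate(plasma_reps, start=1):
        name = f"plasma_rep{r}.csv"
        write_spectrum(spec, out_dir / name)
        files["plasma"].append(name)
    for h, reps in sample_reps.items():
        key = f"{h:.4g}"
        files["samples"][key] = []
        for r, spec in enumerate(reps, start=1):
            name = f"blood_hct{100 * h:.0f}_rep{r}.csv"
            write_spectrum(spec, out_dir / name)
            files["samples"][key].append(name)
    manifest["files"] = files
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(study_dir) -> dict:
    path = Path(study_dir) / "manifest.json"
    if not path.exists():
        raise FileNotFoundError(f"no manifest.json in {study_dir}")
    with open(path, encoding="utf-8") as fh:
        manifest = json.load(fh)
    if manifest.get("format") != "bloodmir-study/1":
        raise ValueError(f"{path}: unrecognised manifest format")
    return manifest
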