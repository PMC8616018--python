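"""Haematocrit error analysis.

Quantifies the error that the cellular content of whole blood introduces
into effective plasma optical constants measured evanescently: signed
percentage-error spectra relative to plasma, localisation of the peak error
in the 1370-1620 cm^-1 window, ordinary-least-squares regression of the
error against haematocrit, and extrapolation to the healthy adult range.
Also implements the plasma volume-exchange plan used to prepare samples at
a target haematocrit (red-cell volume is conserved: H_t (v + dv) = H_i v).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .optics import (ATRConfig, ComplexIndexSpectrum, PenetrationDepthCurve,
                     absorbance_to_k, compute_deff, kk_n_from_k)
from .spectra import (Spectrum, average_replicates, baseline_correct,
                      read_spectrum, remove_co2_band, write_spectrum)

__all__ = [
    "VolumePlan", "plasma_volume_delta",
    "HaematocritSeries", "ErrorSpectra", "ErrorRegression",
    "percent_error_spectra", "peak_error", "fit_error_vs_hct",
    "extrapolate_error", "StudyConfig", "StudyReport",
    "run_haematocrit_study", "run_synthetic_study",
]

#: window where whole blood departs most strongly from plasma
ANALYSIS_BAND = (1370.0, 1620.0)

#: healthy adult haematocrit range (volume fraction)
HEALTHY_RANGE = (0.35, 0.48)


# -- sample preparation ----------------------------------------------------

@dataclass(frozen=True)
class VolumePlan:
    """Plasma volume change needed to move a sample to a target haematocrit."""

    delta_volume: float
    action: str  # add_plasma | remove_plasma | none

    def __post_init__(self):
        expect = ("add_plasma" if self.delta_volume > 0
                  else "remove_plasma" if self.delta_volume < 0 else "none")
        if self.action != expect:
            raise ValueError(f"action {self.action!r} inconsistent with "
                             f"delta_volume {self.delta_volume}")


def plasma_volume_delta(h_initial: float, h_target: float,
                        v_sample: float) -> VolumePlan:
    """Plasma volume to add (positive) or remove (negative).

    dv = (H_initial / H_target - 1) * v_sample, which conserves red-cell
    volume exactly: H_target (v + dv) = H_initial v.
    """
    if not (0.0 < h_initial <= 1.0) or not (0.0 < h_target <= 1.0):
        raise ValueError("haematocrits must be fractions in (0, 1]")
    if v_sample <= 0:
        raise ValueError("sample volume must be positive")
    dv = (h_initial / h_target - 1.0) * v_sample
    action = "add_plasma" if dv > 0 else "remove_plasma" if dv < 0 else "none"
    return VolumePlan(dv, action)


# -- error spectra ---------------------------------------------------------

@dataclass
class HaematocritSeries:
    """A plasma reference plus whole-blood spectra at known haematocrits."""

    plasma: ComplexIndexSpectrum
    samples: list  # of (hct fraction in (0, 1], ComplexIndexSpectrum)

    def __post_init__(self) -> None:
        hcts = [h for h, _ in self.samples]
        if len(set(hcts)) != len(hcts):
            raise ValueError("haematocrit values must be unique")
        for h in hcts:
            if not (0.0 < h <= 1.0):
                raise ValueError(f"haematocrit {h} outside (0, 1]")
        grid = self.plasma.wavenumbers
        self.samples = [
            (float(h), s if np.array_equal(s.wavenumbers, grid) else s.resampled(grid))
            for h, s in self.samples]


@dataclass
class ErrorSpectra:
    """Signed percentage errors of n and k relative to plasma, per sample."""

    wavenumbers: np.ndarray
    hcts: np.ndarray
    err_n: np.ndarray   # (n_samples, n_points), percent
    err_k: np.ndarray
    valid_n: np.ndarray
    valid_k: np.ndarray

    def row(self, hct: float) -> int:
        i = int(np.argmin(np.abs(self.hcts - hct)))
        if abs(self.hcts[i] - hct) > 1e-9:
            raise KeyError(f"no sample at haematocrit {hct}")
        return i


def percent_error_spectra(series: HaematocritSeries) -> ErrorSpectra:
    """error% = 100 (x_hct - x_plasma) / x_plasma for x in {n, k}.

    Points where the plasma value magnitude is below 1e-6 are masked invalid
    rather than producing huge ratios.
    """
    if series.plasma is None:
        raise ValueError("missing plasma reference")
    grid = series.plasma.wavenumbers
    pn, pk = series.plasma.n, series.plasma.k
    ok_n = np.abs(pn) >= 1e-6
    ok_k = np.abs(pk) >= 1e-6
    hcts, rows_n, rows_k, val_n, val_k = [], [], [], [], []
    for h, s in series.samples:
        hcts.append(h)
        with np.errstate(divide="ignore", invalid="ignore"):
            en = 100.0 * (s.n - pn) / np.where(ok_n, pn, 1.0)
            ek = 100.0 * (s.k - pk) / np.where(ok_k, pk, 1.0)
        en[~ok_n] = 0.0
        ek[~ok_k] = 0.0
        rows_n.append(en)
        rows_k.append(ek)
        val_n.append(ok_n & series.plasma.valid & s.valid)
        val_k.append(ok_k & series.plasma.valid & s.valid)
    return ErrorSpectra(grid.copy(), np.asarray(hcts), np.vstack(rows_n),
                        np.vstack(rows_k), np.vstack(val_n), np.vstack(val_k))


def peak_error(errors: ErrorSpectra, component: str,
               band: tuple[float, float] = ANALYSIS_BAND,
               sample: float | None = None) -> tuple[float, float]:
    """Location and signed value of the largest |error| inside ``band``.

    Ties break toward the lower wavenumber.  ``sample`` selects the
    haematocrit; default is the highest one (largest contrast).
    """
    if component not in ("n", "k"):
        raise ValueError("component must be 'n' or 'k'")
    nu = errors.wavenumbers
    if band[0] < nu[0] or band[1] > nu[-1]:
        raise ValueError(f"band {band} outside grid range [{nu[0]}, {nu[-1]}]")
    i = errors.row(sample if sample is not None else float(errors.hcts.max()))
    err = errors.err_n[i] if component == "n" else errors.err_k[i]
    ok = errors.valid_n[i] if component == "n" else errors.valid_k[i]
    in_band = (nu >= band[0]) & (nu <= band[1]) & ok
    if not np.any(in_band):
        raise ValueError(f"no valid points in band {band}")
    idx = np.flatnonzero(in_band)
    j = idx[int(np.argmax(np.abs(err[idx])))]  # argmax -> first -> lowest nu
    return float(nu[j]), float(err[j])


@dataclass(frozen=True)
class ErrorRegression:
    """OLS fit of error% on haematocrit fraction at one wavenumber."""

    wavenumber: float          # grid point actually used, cm^-1
    slope: float               # % per haematocrit fraction
    intercept: float           # %
    r_squared: float
    n_points: int
    requested_wavenumber: float = None
    grid_distance: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < 2:
            raise ValueError("a regression needs at least 2 points")


def fit_error_vs_hct(errors: ErrorSpectra, component: str,
                     wavenumber: float) -> ErrorRegression:
    """OLS of error% on haematocrit, free intercept, at the nearest grid point.

    The plasma reference itself (haematocrit 0, error 0 by construction) is
    not part of ``errors`` and so is not fitted.
    """
    if component not in ("n", "k"):
        raise ValueError("component must be 'n' or 'k'")
    nu = errors.wavenumbers
    j = int(np.argmin(np.abs(nu - wavenumber)))
    err = (errors.err_n if component == "n" else errors.err_k)[:, j]
    ok = (errors.valid_n if component == "n" else errors.valid_k)[:, j]
    x = errors.hcts[ok]
    y = err[ok]
    if x.size < 2:
        raise ValueError(f"fewer than 2 valid samples at {nu[j]:.1f} cm^-1")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # zero-variance y: perfect horizontal fit
        r2 = 1.0
    return ErrorRegression(float(nu[j]), float(res.slope), float(res.intercept),
                           min(r2, 1.0), int(x.size),
                           requested_wavenumber=float(wavenumber),
                           grid_distance=float(abs(nu[j] - wavenumber)))


def extrapolate_error(reg: ErrorRegression, hct_lo: float,
                      hct_hi: float) -> tuple[float, float]:
    """Evaluate the fitted line at both ends of a haematocrit range."""
    if not (0.0 < hct_lo < hct_hi <= 1.0):
        raise ValueError("need 0 < hct_lo < hct_hi <= 1")
    return (reg.intercept + reg.slope * hct_lo,
            reg.intercept + reg.slope * hct_hi)


# -- end-to-end study ------------------------------------------------------

@dataclass
class StudyConfig:
    """Declarative configuration for a full haematocrit study.

    Input spectra come either from ``study_dir`` (a directory written by
    ``synth.make_study``, located via its manifest) or are handed over in
    memory by :func:`run_synthetic_study`.
    """

    study_dir: str | None = None
    out_dir: str | None = None
    min_abs: float = 0.005
    min_k: float = 0.005
    co2_band: tuple = (2280.0, 2400.0)
    analysis_band: tuple = ANALYSIS_BAND
    anchor_wavenumber: float = 5000.0
    anchor_n: float | None = None          # None -> water table value
    baseline_method: str = "none"          # none | linear_endpoints | rubberband
    regression_wavenumbers: dict | None = None   # {'n': nu, 'k': nu}; None -> peaks
    extrapolation_range: tuple = HEALTHY_RANGE

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        """Read a YAML/JSON key-value config file."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("co2_band", "analysis_band", "extrapolation_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the scientific configuration (paths excluded)."""
        payload = json.dumps(
            {k: list(v) if isinstance(v, tuple) else v
             for k, v in vars(self).items()
             if k not in ("study_dir", "out_dir")}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    """Everything the pipeline computed, plus machine-readable summaries."""

    deff: PenetrationDepthCurve
    plasma: ComplexIndexSpectrum
    samples: list                       # of (hct, ComplexIndexSpectrum)
    errors: ErrorSpectra
    peaks: dict                         # component -> (wavenumber, error%)
    regressions: dict                   # component -> ErrorRegression
    extrapolations: dict                # component -> (error_lo%, error_hi%)
    config: StudyConfig = field(default_factory=StudyConfig)

    def summary_rows(self) -> list:
        lo, hi = self.config.extrapolation_range
        rows = []
        for comp in ("n", "k"):
            reg = self.regressions[comp]
            e_lo, e_hi = self.extrapolations[comp]
            rows.append({
                "component": comp,
                "peak_wavenumber_cm-1": self.peaks[comp][0],
                "slope": reg.slope,
                "intercept": reg.intercept,
                "r2": reg.r_squared,
                f"error_at_{100 * lo:.0f}pct": e_lo,
                f"error_at_{100 * hi:.0f}pct": e_hi,
            })
        return rows

    def write(self, out_dir) -> None:
        import pandas as pd

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.deff.to_csv(out_dir / "deff.csv")
        write_spectrum(self.plasma.k_spectrum(), out_dir / "plasma_k.csv")
        write_spectrum(self.plasma.n_spectrum(), out_dir / "plasma_n.csv")
        for h, s in self.samples:
            tag = f"hct{100 * h:.0f}"
            write_spectrum(s.k_spectrum(), out_dir / f"{tag}_k.csv")
            write_spectrum(s.n_spectrum(), out_dir / f"{tag}_n.csv")
        rows = self.summary_rows()
        pd.DataFrame(rows).to_csv(out_dir / "summary.csv", index=False)
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump({"config_hash": self.config.digest(), "summary": rows},
                      fh, indent=2)


class StudyStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input provenance."""

    def __init__(self, stage: str, provenance: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {provenance}: {cause}")
        self.stage = stage
        self.provenance = provenance
        self.__cause__ = cause


def _preprocess(reps: list, config: StudyConfig, label: str) -> Spectrum:
    try:
        spec = average_replicates(reps)
        if config.baseline_method != "none":
            spec = baseline_correct(spec, config.baseline_method)
        spec = remove_co2_band(spec, config.co2_band)
    except Exception as exc:
        raise StudyStageError("preprocess", label, exc) from exc
    spec.meta["sample"] = label
    return spec


def _run_pipeline(water_reps: list, water_k: Spectrum, plasma_reps: list,
                  sample_reps: dict, config: StudyConfig) -> StudyReport:
    water_abs = _preprocess(water_reps, config, "water")
    try:
        deff = compute_deff(water_abs, water_k, config.min_abs, config.min_k)
        if not np.any(deff.valid):
            raise ValueError("no valid points in the d_eff calibration")
    except StudyStageError:
        raise
    except Exception as exc:
        raise StudyStageError("compute_deff", "water reference", exc) from exc

    def to_nk(label: str, reps: list) -> ComplexIndexSpectrum:
        spec = _preprocess(reps, config, label)
        try:
            k = absorbance_to_k(spec, deff)
            n = kk_n_from_k(k, config.anchor_wavenumber, config.anchor_n)
        except Exception as exc:
            raise StudyStageError("absorbance_to_nk", label, exc) from exc
        return ComplexIndexSpectrum(k.wavenumbers, n.values, k.values,
                                    k.valid & n.valid, {"sample": label})

    plasma = to_nk("plasma", plasma_reps)
    samples = [(h, to_nk(f"hct_{h:.2f}", reps))
               for h, reps in sorted(sample_reps.items())]

    try:
        series = HaematocritSeries(plasma, samples)
        errors = percent_error_spectra(series)
        peaks = {c: peak_error(errors, c, config.analysis_band) for c in ("n", "k")}
        reg_nu = config.regression_wavenumbers or {c: peaks[c][0] for c in ("n", "k")}
        regressions = {c: fit_error_vs_hct(errors, c, reg_nu[c]) for c in ("n", "k")}
        lo, hi = config.extrapolation_range
        extrapolations = {c: extrapolate_error(regressions[c], lo, hi)
                          for c in ("n", "k")}
    except StudyStageError:
        raise
    except Exception as exc:
        raise StudyStageError("error_analysis", "haematocrit series", exc) from exc

    report = StudyReport(deff, plasma, samples, errors, peaks, regressions,
                         extrapolations, config)
    if config.out_dir:
        report.write(config.out_dir)
    return report


def run_haematocrit_study(config: StudyConfig) -> StudyReport:
    """Execute the full pipeline on a study directory.

    preprocess -> compute_deff -> absorbance_to_k -> kk_n_from_k ->
    percent_error_spectra -> peak_error -> fit_error_vs_hct ->
    extrapolate_error; intermediate spectra and a CSV+JSON summary are
    written to ``config.out_dir`` when set.  Any stage failure aborts with
    the stage name and the offending input.
    """
    from .data import load_water_table
    from .synth import load_manifest

    if not config.study_dir:
        raise ValueError("config.study_dir is required (or use run_synthetic_study)")
    study_dir = Path(config.study_dir)
    manifest = load_manifest(study_dir)
    files = manifest["files"]

    def load_all(names):
        return [read_spectrum(study_dir / name) for name in names]

    water_reps = load_all(files["water"])
    plasma_reps = load_all(files["plasma"])
    sample_reps = {float(h): load_all(names)
                   for h, names in files["samples"].items()}
    grid = water_reps[0].wavenumbers
    table = load_water_table().resampled(grid)
    water_k = Spectrum(grid, table.k, "k", {"sample": "water literature k"},
                       table.valid)
    return _run_pipeline(water_reps, water_k, plasma_reps, sample_reps, config)


def run_synthetic_study(model, hct_list=(0.2, 0.3, 0.4, 0.5, 0.6, 0.7),
                        replicates: int = 3,
                        config: StudyConfig | None = None,
                        atr: ATRConfig = ATRConfig()) -> StudyReport:
    """Run the pipeline on an in-memory synthetic study (no files)."""
    from .synth import make_study, water_nk

    config = config or StudyConfig()
    manifest = make_study(model, list(hct_list), replicates, out_dir=None, atr=atr)
    spectra = manifest["spectra"]
    grid = model.grid
    table = water_nk(grid)
    water_k = Spectrum(grid, table.k, "k", {"sample": "water literature k"},
                       table.valid)
    return _run_pipeline(spectra["water"], water_k, spectra["plasma"],
                         spectra["samples"], config)
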