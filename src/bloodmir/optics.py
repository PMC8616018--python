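"""Complex refractive index from evanescent ATR-FTIR absorbance.

The chain implemented here is the empirical-penetration-depth method for
non-polarised ATR spectroscopy:

1.  Calibrate an effective penetration depth from a reference liquid of
    known optical constants (water):  d_eff(nu) = lambda * a / (4 pi k log10 e),
    i.e. the equivalent transmission path length that reproduces the
    measured evanescent absorbance.
2.  Convert sample absorbance to the imaginary index with the same relation
    rearranged:  k = lambda * a / (4 pi d_eff log10 e).
3.  Reconstruct the real index n from k with a finite-range Kramers-Kronig
    transform (Maclaurin alternating-point quadrature), anchored to the
    refractive index of water in the low-loss region near 2 um.

A forward weak-absorption ATR model (Harrick effective thicknesses,
unpolarised = mean of s and p) closes the loop so the whole chain can be
exercised and validated on synthetic samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra import Spectrum, resample

__all__ = [
    "ComplexIndexSpectrum",
    "PenetrationDepthCurve",
    "ATRConfig",
    "compute_deff",
    "absorbance_to_k",
    "kk_n_from_k",
    "forward_atr_absorbance",
    "theoretical_penetration_depth",
]

LOG10E = math.log10(math.e)
FOUR_PI = 4.0 * math.pi

#: fraction of the grid at each end flagged reduced-confidence after a
#: finite-range Kramers-Kronig transform
KK_EDGE_FRACTION = 0.05

#: default ill-conditioning thresholds for the d_eff calibration ratio
MIN_ABS_DEFAULT = 0.005
MIN_K_DEFAULT = 0.005


@dataclass
class ComplexIndexSpectrum:
    """Real and imaginary refractive index on a shared wavenumber grid."""

    wavenumbers: np.ndarray
    n: np.ndarray
    k: np.ndarray
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        self.n = np.asarray(self.n, float)
        self.k = np.asarray(self.k, float)
        if self.valid is None:
            self.valid = np.ones(self.wavenumbers.shape, bool)
        else:
            self.valid = np.asarray(self.valid, bool)
        if not (self.n.shape == self.k.shape == self.wavenumbers.shape == self.valid.shape):
            raise ValueError("wavenumbers, n, k and valid must share one grid")
        if np.any(np.diff(self.wavenumbers) <= 0) or np.any(self.wavenumbers <= 0):
            raise ValueError("wavenumbers must be positive and strictly increasing")
        if np.any(self.k[self.valid] < -1e-12):
            raise ValueError("k must be >= 0 wherever valid")
        if np.any(self.n[self.valid] <= 0):
            raise ValueError("n must be > 0 wherever valid")

    @property
    def wavelengths_um(self) -> np.ndarray:
        return 1e4 / self.wavenumbers

    def n_spectrum(self) -> Spectrum:
        return Spectrum(self.wavenumbers.copy(), self.n.copy(), "n",
                        dict(self.meta), self.valid.copy())

    def k_spectrum(self) -> Spectrum:
        return Spectrum(self.wavenumbers.copy(), self.k.copy(), "k",
                        dict(self.meta), self.valid.copy())

    def resampled(self, grid) -> "ComplexIndexSpectrum":
        ns = resample(self.n_spectrum(), grid)
        ks = resample(self.k_spectrum(), grid)
        return ComplexIndexSpectrum(np.asarray(grid, float), ns.values, ks.values,
                                    ns.valid & ks.valid, dict(self.meta))

    def n_at(self, wavenumber: float) -> float:
        return float(np.interp(wavenumber, self.wavenumbers, self.n))


@dataclass
class PenetrationDepthCurve:
    """Empirical effective path length vs wavenumber, in um, with a mask for
    the ill-conditioned region where the calibration ratio ~ 0/0."""

    wavenumbers: np.ndarray
    d_eff: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, float)
        self.d_eff = np.asarray(self.d_eff, float)
        self.valid = np.asarray(self.valid, bool)
        if not (self.d_eff.shape == self.wavenumbers.shape == self.valid.shape):
            raise ValueError("wavenumbers, d_eff and valid must share one grid")
        if np.any(self.d_eff[self.valid] <= 0):
            raise ValueError("d_eff must be > 0 wherever valid")

    def to_csv(self, path) -> Path:
        from . import __version__

        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# bloodmir {__version__}; empirical effective penetration depth\n")
            fh.write("wavenumber_cm-1,d_eff_um,valid\n")
            for x, d, v in zip(self.wavenumbers, self.d_eff, self.valid):
                fh.write(f"{x:.10g},{d:.10g},{int(v)}\n")
        return path

    @classmethod
    def from_csv(cls, path) -> "PenetrationDepthCurve":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line[0].isalpha():
                    continue
                rows.append([float(f) for f in line.split(",")])
        arr = np.asarray(rows, float)
        if arr.ndim != 2 or arr.shape[1] < 3:
            raise ValueError(f"{path}: expected wavenumber,d_eff,valid columns")
        return cls(arr[:, 0], arr[:, 1], arr[:, 2] > 0.5)


@dataclass(frozen=True)
class ATRConfig:
    """Internal-reflection element geometry (single-reflection diamond)."""

    crystal_index: float = 2.4
    incidence_angle_deg: float = 45.0
    reflections: int = 1
    # polarization is fixed at unpolarized (mean of s and p)


def _align(a: Spectrum, b: Spectrum) -> tuple[Spectrum, Spectrum]:
    """Resample ``b`` onto ``a``'s grid if their grids differ."""
    if np.array_equal(a.wavenumbers, b.wavenumbers):
        return a, b
    lo = max(a.wavenumbers[0], b.wavenumbers[0])
    hi = min(a.wavenumbers[-1], b.wavenumbers[-1])
    if lo >= hi:
        raise ValueError("spectra grids do not overlap; cannot align")
    grid = a.wavenumbers[(a.wavenumbers >= lo - 1e-9) & (a.wavenumbers <= hi + 1e-9)]
    return resample(a, grid), resample(b, grid)


def compute_deff(reference_absorbance: Spectrum, reference_k: Spectrum,
                 min_abs: float = MIN_ABS_DEFAULT,
                 min_k: float = MIN_K_DEFAULT) -> PenetrationDepthCurve:
    """Empirical effective penetration depth from a known-index reference.

    d_eff = lambda * a / (4 pi k log10 e), pointwise, in um.  Points where
    either the measured absorbance or the literature k drops below its
    threshold are flagged invalid (the ratio approaches 0/0 there, as above
    ~3700 cm^-1 for water) but are kept on the grid.
    """
    a_spec, k_spec = _align(reference_absorbance, reference_k)
    lam = 1e4 / a_spec.wavenumbers
    a = a_spec.values
    k = k_spec.values
    valid = (a >= min_abs) & (k >= min_k) & a_spec.valid & k_spec.valid
    k_safe = np.where(np.abs(k) > 1e-30, k, 1e-30)
    d = lam * a / (FOUR_PI * k_safe * LOG10E)
    # keep values finite (and meaningless) in the masked region
    d = np.where(valid, d, np.abs(d))
    return PenetrationDepthCurve(a_spec.wavenumbers.copy(), d, valid,
                                 {"min_abs": min_abs, "min_k": min_k})


def absorbance_to_k(sample_absorbance: Spectrum,
                    deff: PenetrationDepthCurve,
                    negative_floor: float = -0.005) -> Spectrum:
    """Imaginary refractive index from absorbance and the calibrated d_eff.

    k = lambda * a / (4 pi d_eff log10 e).  Zero absorbance maps to k = 0.
    Small negative excursions (detector noise about zero in dead spectral
    regions) are clipped to zero; absorbance below ``negative_floor`` inside
    the calibration-valid region signals a missing baseline/preprocessing
    step and raises.  Invalid d_eff points produce invalid k points.
    """
    deff_spec = Spectrum(deff.wavenumbers, deff.d_eff, "d_eff",
                         dict(deff.meta), deff.valid)
    a_spec, d_spec = _align(sample_absorbance, deff_spec)
    a = a_spec.values
    gross = (a < negative_floor) & d_spec.valid
    if np.any(gross):
        bad = a_spec.wavenumbers[gross][0]
        raise ValueError(
            f"negative absorbance ({a[gross].min():.3g}) at {bad:.1f} cm^-1; "
            "baseline-correct the spectrum first")
    a = np.clip(a, 0.0, None)
    lam = 1e4 / a_spec.wavenumbers
    k = lam * a / (FOUR_PI * d_spec.values * LOG10E)
    valid = a_spec.valid & d_spec.valid
    meta = dict(sample_absorbance.meta)
    meta["operations"] = list(meta.get("operations", [])) + ["absorbance_to_k"]
    return Spectrum(a_spec.wavenumbers.copy(), k, "k", meta, valid)


def _maclaurin_hilbert(nu: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Finite-range principal-value KK integral by Maclaurin's formula.

    dn(nu_i) = (2/pi) P int nu' k(nu') / (nu'^2 - nu_i^2) dnu', evaluated by
    summing only grid points of opposite parity to i with weight 2h, which
    sidesteps the singular point without special-casing it.  Requires a
    uniform grid.
    """
    h = np.diff(nu)
    if (h.max() - h.min()) > 1e-6 * h.mean():
        raise ValueError("Kramers-Kronig quadrature requires a uniform wavenumber grid")
    step = float(h.mean())
    nu2 = nu * nu
    numer = nu * k
    denom = nu2[None, :] - nu2[:, None]
    idx = np.arange(nu.size)
    odd = ((idx[None, :] + idx[:, None]) % 2) == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(odd, numer[None, :] / denom, 0.0)
    return (2.0 / math.pi) * 2.0 * step * terms.sum(axis=1)


def _default_water_table():
    from .data import load_water_table

    return load_water_table()


def kk_n_from_k(k_spec: Spectrum, anchor_wavenumber: float = 5000.0,
                anchor_n: float | None = None,
                water_table: "ComplexIndexSpectrum | None" = None) -> Spectrum:
    """Real refractive index from k by anchored Kramers-Kronig transform.

    The susceptibility-like output of the finite-range transform is offset so
    that n equals ``anchor_n`` at ``anchor_wavenumber``.  The conventional
    anchor -- water in the low-loss window at 2 um (5000 cm^-1) -- lies
    outside a 600-4000 cm^-1 measurement grid; in that case the offset is
    chosen so that n at the nearest grid edge matches the literature water
    dispersion between the edge and the anchor, without extrapolating the
    sample's k.  The outer 5% of the grid at each end is flagged
    reduced-confidence (truncation error concentrates there).
    """
    if k_spec.kind != "k":
        raise ValueError(f"expected a k spectrum, got kind {k_spec.kind!r}")
    nu = k_spec.wavenumbers
    k = k_spec.values.copy()
    if not np.all(k_spec.valid):
        if not np.any(k_spec.valid):
            raise ValueError("k spectrum has no valid points")
        # pre-fill unreliable points by interpolation across valid neighbours;
        # they stay flagged in the output mask
        good = k_spec.valid
        k[~good] = np.interp(nu[~good], nu[good], k[good])
    dn = _maclaurin_hilbert(nu, k)

    if anchor_n is None or not (nu[0] <= anchor_wavenumber <= nu[-1]):
        water = water_table if water_table is not None else _default_water_table()
    if anchor_n is None:
        if not (water.wavenumbers[0] <= anchor_wavenumber <= water.wavenumbers[-1]):
            raise ValueError(
                f"anchor {anchor_wavenumber} cm^-1 outside the water table range "
                "and no anchor_n given")
        anchor_n = water.n_at(anchor_wavenumber)

    if nu[0] <= anchor_wavenumber <= nu[-1]:
        offset = anchor_n - float(np.interp(anchor_wavenumber, nu, dn))
    else:
        wlo, whi = water.wavenumbers[0], water.wavenumbers[-1]
        if not (wlo <= anchor_wavenumber <= whi):
            raise ValueError(
                f"anchor {anchor_wavenumber} cm^-1 outside both the measured grid "
                "and the water table; no literature fallback available")
        edge = nu[-1] if abs(anchor_wavenumber - nu[-1]) <= abs(anchor_wavenumber - nu[0]) else nu[0]
        if not (wlo <= edge <= whi):
            raise ValueError("water table does not cover the grid edge needed for anchoring")
        water_delta = water.n_at(edge) - water.n_at(anchor_wavenumber)
        target_edge_n = anchor_n + water_delta
        offset = target_edge_n - float(np.interp(edge, nu, dn))

    n = dn + offset
    valid = k_spec.valid.copy()
    m = max(1, int(math.ceil(KK_EDGE_FRACTION * nu.size)))
    valid[:m] = False
    valid[-m:] = False
    meta = dict(k_spec.meta)
    meta["operations"] = list(meta.get("operations", [])) + ["kk_n_from_k"]
    meta["kk_anchor"] = (anchor_wavenumber, anchor_n)
    return Spectrum(nu.copy(), n, "n", meta, valid)


def _effective_thicknesses(lam_um, n1, n2, theta_rad):
    """Harrick weak-absorption effective thicknesses (s, p) for a bulk sample."""
    n21 = n2 / n1
    s2 = math.sin(theta_rad) ** 2
    under = s2 - n21 * n21
    if np.any(under <= 0):
        nu_bad = None
        return None, None, under
    root = np.sqrt(under)
    dp = lam_um / (2.0 * math.pi * n1 * root)
    cos_t = math.cos(theta_rad)
    de_s = n21 * dp * cos_t / (1.0 - n21 * n21)
    de_p = (n21 * dp * cos_t * (2.0 * s2 - n21 * n21)
            / ((1.0 - n21 * n21) * ((1.0 + n21 * n21) * s2 - n21 * n21)))
    return de_s, de_p, under


def forward_atr_absorbance(sample: ComplexIndexSpectrum,
                           config: ATRConfig = ATRConfig()) -> Spectrum:
    """Weak-absorption ATR absorbance of a bulk sample.

    a(nu) = reflections * alpha(nu) * de(nu) * log10 e, with
    alpha = 4 pi k / lambda and de the unpolarised (mean of s and p) Harrick
    effective thickness computed from the crystal index, sample n and the
    incidence angle.  Refuses sub-critical incidence, naming the offending
    wavenumber.
    """
    theta = math.radians(config.incidence_angle_deg)
    lam = sample.wavelengths_um
    n1 = config.crystal_index
    de_s, de_p, under = _effective_thicknesses(lam, n1, sample.n, theta)
    if de_s is None:
        bad = sample.wavenumbers[int(np.argmin(under))]
        raise ValueError(
            f"incidence angle {config.incidence_angle_deg} deg is below the "
            f"critical angle at {bad:.1f} cm^-1 (sample n = {sample.n_at(bad):.3f}); "
            "total internal reflection is lost")
    ratio = np.max(sample.k / sample.n)
    if ratio > 0.5:
        warnings.warn(
            f"max k/n = {ratio:.2f} > 0.5: outside the weak-absorption regime, "
            "the effective-thickness model loses accuracy", stacklevel=2)
    de = 0.5 * (de_s + de_p)
    alpha = FOUR_PI * sample.k / lam
    a = config.reflections * alpha * de * LOG10E
    return Spectrum(sample.wavenumbers.copy(), a, "absorbance",
                    dict(sample.meta), sample.valid.copy())


def theoretical_penetration_depth(sample_n: Spectrum,
                                  config: ATRConfig = ATRConfig()) -> PenetrationDepthCurve:
    """Classical evanescent-field 1/e penetration depth (diagnostic only).

    dp = lambda / (2 pi n1 sqrt(sin^2 theta - (n2/n1)^2)), in um.
    """
    theta = math.radians(config.incidence_angle_deg)
    n1 = config.crystal_index
    n21 = sample_n.values / n1
    under = math.sin(theta) ** 2 - n21 * n21
    if np.any(under <= 0):
        bad = sample_n.wavenumbers[int(np.argmin(under))]
        raise ValueError(f"sub-critical incidence at {bad:.1f} cm^-1")
    lam = sample_n.wavelengths_um
    dp = lam / (2.0 * math.pi * n1 * np.sqrt(under))
    return PenetrationDepthCurve(sample_n.wavenumbers.copy(), dp,
                                 sample_n.valid.copy(), {"model": "classical_dp"})
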