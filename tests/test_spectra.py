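"""Spectral container, file round trips and preprocessing operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bloodmir import (ReplicateSet, Spectrum, SpectrumFormatError,
                      average_replicates, baseline_correct, normalize_at,
                      read_spectrum, remove_co2_band, resample,
                      write_spectrum)
from bloodmir.synth import BiofluidModel, synth_absorbance


# -- container invariants --------------------------------------------------

@pytest.mark.parametrize("wn,vals,err", [
    ([1000.0, 1000.0, 1100.0], [1, 2, 3], "duplicate"),
    ([1100.0, 1000.0, 1200.0], [1, 2, 3], "increasing"),
    ([-5.0, 1000.0], [1, 2], "> 0"),
    ([1000.0], [1.0], "at least 2"),
    ([1000.0, 1100.0], [1.0, np.nan], "finite"),
])
def test_spectrum_validation_rejects_bad_grids(wn, vals, err):
    with pytest.raises(ValueError, match=err):
        Spectrum(np.asarray(wn), np.asarray(vals), "absorbance")


# -- file I/O --------------------------------------------------------------

def test_csv_parse_and_order_invariance(tmp_path):
    asc = tmp_path / "asc.csv"
    desc = tmp_path / "desc.csv"
    asc.write_text("1000,0.5\n2000,0.3\n")
    desc.write_text("2000,0.3\n1000,0.5\n")
    s1 = read_spectrum(asc)
    s2 = read_spectrum(desc)
    assert s1.wavenumbers.tolist() == [1000.0, 2000.0]
    np.testing.assert_array_equal(s1.values, s2.values)
    np.testing.assert_array_equal(s1.wavenumbers, s2.wavenumbers)


def test_csv_duplicate_wavenumbers_rejected(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text("1000,0.5\n1000,0.6\n2000,0.3\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_spectrum(p)


def test_csv_bad_line_names_location(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("1000,0.5\n1100,oops\n")
    with pytest.raises(SpectrumFormatError, match="bad.csv:2"):
        read_spectrum(p)


@pytest.mark.parametrize("fmt,suffix", [("csv", ".csv"), ("jcampdx", ".jdx")])
def test_write_read_round_trip(tmp_path, fmt, suffix, toy_spectrum):
    path = tmp_path / f"roundtrip{suffix}"
    write_spectrum(toy_spectrum, path, format=fmt)
    back = read_spectrum(path, format=fmt)
    assert back.kind == toy_spectrum.kind
    np.testing.assert_allclose(back.wavenumbers, toy_spectrum.wavenumbers, atol=1e-9)
    np.testing.assert_allclose(back.values, toy_spectrum.values, atol=1e-9)


def test_jcamp_xydata_affn_block(tmp_path):
    p = tmp_path / "xydata.jdx"
    p.write_text(
        "##TITLE=t\n##JCAMP-DX=4.24\n##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n"
        "##XFACTOR=1\n##YFACTOR=0.001\n##FIRSTX=1000\n##LASTX=1006\n"
        "##NPOINTS=4\n##XYDATA=(X++(Y..Y))\n1000 100 200\n1004 300 400\n##END=\n")
    s = read_spectrum(p)
    np.testing.assert_allclose(s.wavenumbers, [1000, 1002, 1004, 1006])
    np.testing.assert_allclose(s.values, [0.1, 0.2, 0.3, 0.4])


def test_jcamp_compressed_rejected(tmp_path):
    p = tmp_path / "sqz.jdx"
    p.write_text("##TITLE=t\n##NPOINTS=3\n##FIRSTX=1000\n##LASTX=1002\n"
                 "##XYDATA=(X++(Y..Y))\n1000A12J34\n##END=\n")
    with pytest.raises(SpectrumFormatError, match="not supported"):
        read_spectrum(p)


# -- resample --------------------------------------------------------------

def test_resample_identity_and_midpoints(toy_spectrum):
    same = resample(toy_spectrum, toy_spectrum.wavenumbers)
    np.testing.assert_array_equal(same.values, toy_spectrum.values)

    nu = np.array([1000.0, 1100.0, 1200.0])
    ramp = Spectrum(nu, np.array([0.0, 2.0, 4.0]), "absorbance")
    mid = resample(ramp, np.array([1050.0, 1150.0]))
    np.testing.assert_allclose(mid.values, [1.0, 3.0], atol=1e-12)


def test_resample_refuses_extrapolation(toy_spectrum):
    with pytest.raises(ValueError, match="extrapolation"):
        resample(toy_spectrum, np.array([900.0, 1500.0]))


@given(a=st.floats(-2, 2), b=st.floats(-5, 5))
@settings(max_examples=25, deadline=None)
def test_resample_exact_on_affine_functions(a, b):
    nu = np.linspace(800.0, 1800.0, 51)
    spec = Spectrum(nu, a * nu + b, "absorbance")
    target = np.linspace(850.0, 1750.0, 37)
    out = resample(spec, target)
    np.testing.assert_allclose(out.values, a * target + b, atol=1e-8)


def test_resample_marks_points_near_invalid_sources():
    nu = np.linspace(1000.0, 1100.0, 11)
    valid = np.ones(11, bool)
    valid[5] = False
    spec = Spectrum(nu, np.ones(11), "absorbance", valid=valid)
    out = resample(spec, np.array([1025.0, 1047.0, 1075.0]))
    assert out.valid.tolist() == [True, False, True]


# -- replicate averaging ---------------------------------------------------

def test_average_of_identical_and_constant_replicates(toy_spectrum):
    mean = average_replicates([toy_spectrum] * 3)
    np.testing.assert_allclose(mean.values, toy_spectrum.values)
    assert mean.meta["n_replicates"] == 3

    nu = np.linspace(1000.0, 1100.0, 5)
    members = [Spectrum(nu, np.full(5, c), "absorbance") for c in (1.0, 2.0, 3.0)]
    np.testing.assert_allclose(average_replicates(members).values, 2.0)


def test_average_rejects_empty_and_mixed_kinds(toy_spectrum):
    with pytest.raises(ValueError, match="empty"):
        ReplicateSet([])
    other = Spectrum(toy_spectrum.wavenumbers, toy_spectrum.values, "k")
    with pytest.raises(ValueError, match="kinds"):
        average_replicates([toy_spectrum, other])


def test_replicate_averaging_shrinks_noise_like_sqrt_m():
    """RMS deviation of the replicate mean from truth drops ~ 1/sqrt(m)."""
    model = BiofluidModel(seed=11, baseline_drift=0.0, co2_artifact=0.0,
                          noise_sd=0.005)
    truth = BiofluidModel(seed=11, noise_sd=0.0, baseline_drift=0.0,
                          co2_artifact=0.0)
    clean = synth_absorbance(truth, 0.4, replicate=1)
    rms = {}
    for m in (1, 4, 16):
        reps = [synth_absorbance(model, 0.4, replicate=r) for r in range(1, m + 1)]
        mean = average_replicates(reps)
        rms[m] = np.sqrt(np.mean((mean.values - clean.values) ** 2))
    assert 0.55 < rms[1] / (2 * rms[4]) < 1.8
    assert 0.55 < rms[4] / (2 * rms[16]) < 1.8


# -- baseline correction ---------------------------------------------------

def test_linear_endpoints_recovers_added_line(toy_spectrum):
    nu = toy_spectrum.wavenumbers
    # endpoints of the toy Gaussian are ~0, so it is its own baseline-free form
    zeroed = toy_spectrum.with_values(toy_spectrum.values - np.interp(
        nu, [nu[0], nu[-1]], [toy_spectrum.values[0], toy_spectrum.values[-1]]))
    tilted = zeroed.with_values(zeroed.values + 0.01 * (nu - nu[0]) + 0.3)
    corrected = baseline_correct(tilted, "linear_endpoints")
    np.testing.assert_allclose(corrected.values, zeroed.values, atol=1e-9)
    # already-zero endpoints: unchanged
    again = baseline_correct(corrected, "linear_endpoints")
    np.testing.assert_allclose(again.values, corrected.values, atol=1e-9)


@pytest.mark.parametrize("method", ["linear_endpoints", "rubberband"])
def test_baseline_idempotence(method, toy_spectrum):
    once = baseline_correct(toy_spectrum, method)
    twice = baseline_correct(once, method)
    np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


def test_rubberband_matches_brute_force_hull():
    """Convex-hull baseline equals the max over all all-below chords."""
    rng = np.random.default_rng(3)
    nu = np.linspace(1000.0, 1500.0, 40)
    vals = 0.2 + 0.3 * np.exp(-((nu - 1250.0) / 40.0) ** 2) + 0.05 * rng.random(40)
    spec = Spectrum(nu, vals, "absorbance")
    out = baseline_correct(spec, "rubberband")

    # brute force: for every x, the lower hull is the largest value attained
    # by any chord between two data points that stays <= the data everywhere
    baseline = np.full(nu.size, -np.inf)
    for i in range(nu.size):
        for j in range(i + 1, nu.size):
            chord = vals[i] + (vals[j] - vals[i]) * (nu - nu[i]) / (nu[j] - nu[i])
            if np.all(chord <= vals + 1e-12):
                baseline = np.maximum(baseline, chord)
    np.testing.assert_allclose(out.values, vals - baseline, atol=1e-9)
    assert np.all(out.values >= -1e-9)


def test_rubberband_flattens_single_peak_on_constant_offset():
    nu = np.linspace(1000.0, 1200.0, 41)
    peak = 0.4 * np.exp(-((nu - 1100.0) / 20.0) ** 2)
    spec = Spectrum(nu, peak + 0.7, "absorbance")
    out = baseline_correct(spec, "rubberband")
    np.testing.assert_allclose(out.values, peak, atol=1e-9)


def test_baseline_rejects_non_absorbance(toy_spectrum):
    k = Spectrum(toy_spectrum.wavenumbers, toy_spectrum.values, "k")
    with pytest.raises(ValueError, match="absorbance"):
        baseline_correct(k)


# -- CO2 band removal ------------------------------------------------------

def test_co2_removal_constant_and_linear_unchanged():
    nu = np.arange(2000.0, 2800.0, 4.0)
    const = Spectrum(nu, np.full(nu.size, 0.2), "absorbance")
    np.testing.assert_allclose(remove_co2_band(const).values, 0.2, atol=1e-12)
    lin = Spectrum(nu, 0.001 * nu, "absorbance")
    np.testing.assert_allclose(remove_co2_band(lin).values, lin.values, atol=1e-12)


def test_co2_removal_replaces_injected_peak_with_chord():
    nu = np.arange(2000.0, 2800.0, 4.0)
    base = 0.1 + 0.0001 * (nu - 2000.0)
    peak = 0.5 * np.exp(-((nu - 2350.0) / 12.0) ** 2)   # wholly inside the band
    spec = Spectrum(nu, base + peak, "absorbance")
    out = remove_co2_band(spec, (2280.0, 2400.0))
    outside = (nu < 2280.0) | (nu > 2400.0)
    np.testing.assert_array_equal(out.values[outside], spec.values[outside])
    inside = ~outside
    np.testing.assert_allclose(out.values[inside], base[inside], atol=1e-6)


def test_co2_band_outside_grid_rejected(toy_spectrum):
    with pytest.raises(ValueError, match="outside grid"):
        remove_co2_band(toy_spectrum, (2280.0, 2400.0))


@given(lo=st.floats(2100, 2400), width=st.floats(10, 300))
@settings(max_examples=25, deadline=None)
def test_co2_removal_changes_nothing_outside_band(lo, width):
    nu = np.arange(2000.0, 2800.0, 4.0)
    rng = np.random.default_rng(0)
    spec = Spectrum(nu, rng.random(nu.size), "absorbance")
    hi = min(lo + width, 2796.0)
    out = remove_co2_band(spec, (lo, hi))
    outside = (nu <= lo) | (nu >= hi)
    np.testing.assert_array_equal(out.values[outside], spec.values[outside])


# -- normalization ---------------------------------------------------------

def test_normalize_halves_and_anchors_to_one(grid):
    vals = np.full(grid.size, 2.0)
    spec = Spectrum(grid, vals, "absorbance")
    out = normalize_at(spec, 3300.0)
    np.testing.assert_allclose(out.values, 1.0)
    assert out.value_at(3300.0) == pytest.approx(1.0, abs=1e-15)


@given(scale=st.floats(1e-3, 1e3))
@settings(max_examples=25, deadline=None)
def test_normalize_idempotent_and_scale_invariant(scale):
    nu = np.linspace(1000.0, 2000.0, 101)
    spec = Spectrum(nu, 0.1 + 0.5 * np.exp(-((nu - 1500.0) / 60.0) ** 2),
                    "absorbance")
    ref = normalize_at(spec, 1500.0)
    scaled = normalize_at(spec.with_values(spec.values * scale), 1500.0)
    np.testing.assert_allclose(scaled.values, ref.values, rtol=1e-12)
    again = normalize_at(ref, 1500.0)
    np.testing.assert_allclose(again.values, ref.values, rtol=1e-12)


def test_normalize_near_zero_anchor_rejected():
    nu = np.linspace(3200.0, 3400.0, 11)
    spec = Spectrum(nu, np.full(11, 1e-8), "absorbance")
    with pytest.raises(ValueError, match="refusing"):
        normalize_at(spec, 3300.0)
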