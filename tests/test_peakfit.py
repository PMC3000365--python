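import numpy as np
import pytest

from repeatdyn import (
    PeakFitError,
    Trace,
    decompose,
    fit_single_gaussian,
    peak_resolvability,
    peak_table,
    render_model,
)
from repeatdyn.peakfit import GaussianPeak, PeakDecomposition


def test_gaussian_peak_properties():
    p = GaussianPeak(443.0, 6.0, 100.0)
    assert p.area == pytest.approx(100.0 * 6.0 * np.sqrt(2 * np.pi))
    assert p.mean_repeats == pytest.approx(119.0)
    assert p.sigma_repeats == pytest.approx(2.0)
    with pytest.raises(ValueError):
        GaussianPeak(443.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        GaussianPeak(443.0, 1.0, 0.0)


def test_decomposition_validation():
    a = GaussianPeak(443.0, 6.0, 10.0)
    b = GaussianPeak(440.0, 6.0, 10.0)
    with pytest.raises(ValueError):
        PeakDecomposition([], 1.0)
    with pytest.raises(ValueError):
        PeakDecomposition([a, b], 1.0)  # means must increase


def test_single_gaussian_exact(make_trace):
    tr, comps = make_trace([(443.0, 5.94, 120.0)])
    fit = fit_single_gaussian(tr)
    assert fit.mean_bp == pytest.approx(443.0, abs=1e-3)
    assert fit.sigma_bp == pytest.approx(5.94, abs=1e-3)
    assert fit.amplitude == pytest.approx(120.0, rel=1e-3)


def test_single_gaussian_noisy(make_trace):
    tr, _ = make_trace([(443.0, 5.94, 120.0)])
    rng = np.random.default_rng(3)
    noisy = Trace(tr.size_bp, np.clip(tr.intensity + rng.normal(0, 1, tr.size_bp.size), 0, None))
    fit = fit_single_gaussian(noisy)
    assert fit.mean_bp == pytest.approx(443.0, abs=0.2)
    assert fit.sigma_bp == pytest.approx(5.94, abs=0.2)


def test_single_gaussian_failure_carries_best():
    x = np.arange(400.0, 500.0, 0.5)
    flat = Trace(x, np.full(x.size, 10.0))
    with pytest.raises(PeakFitError):
        fit_single_gaussian(flat)


def test_decompose_two_overlapping_peaks(make_trace):
    tr, comps = make_trace([(443.0, 5.94, 100.0), (464.0, 5.94, 60.0)])
    dec = decompose(tr)
    assert dec.n_peaks == 2
    for got, want in zip(dec.peaks, comps):
        assert got.mean_bp == pytest.approx(want.mean_bp, abs=0.05)
        assert got.sigma_bp == pytest.approx(want.sigma_bp, abs=0.05)
        assert got.area == pytest.approx(want.area, rel=0.01)


def test_decompose_six_peak_oracle(make_trace):
    layout = [(443.0 + 21.0 * k, 6.0, a) for k, a in enumerate([100, 80, 55, 30, 14, 6])]
    tr, comps = make_trace(layout)
    dec = decompose(tr)
    assert dec.n_peaks == 6
    assert dec.converged
    assert dec.explained_fraction >= 0.98
    for got, want in zip(dec.peaks, comps):
        assert got.mean_bp == pytest.approx(want.mean_bp, abs=0.02)
        assert got.sigma_bp == pytest.approx(want.sigma_bp, abs=0.02)
        assert got.area == pytest.approx(want.area, rel=0.005)


def test_decompose_prunes_small_peaks(make_trace):
    # the third component holds ~0.2% of the area: below the 1% floor
    tr, _ = make_trace([(443.0, 6.0, 100.0), (464.0, 6.0, 50.0), (506.0, 6.0, 0.3)])
    dec = decompose(tr)
    assert dec.n_peaks == 2


def test_decompose_deterministic(make_trace):
    tr, _ = make_trace([(443.0, 6.0, 100.0), (464.0, 6.0, 50.0)])
    a = decompose(tr)
    b = decompose(tr)
    assert [(p.mean_bp, p.sigma_bp, p.amplitude) for p in a.peaks] == [
        (p.mean_bp, p.sigma_bp, p.amplitude) for p in b.peaks
    ]


def test_decompose_errors(make_trace):
    tr, _ = make_trace([(443.0, 6.0, 100.0)])
    with pytest.raises(ValueError):
        decompose(tr, min_explained=0.0)
    with pytest.raises(ValueError):
        decompose(tr, min_explained=1.5)
    x = np.arange(400.0, 420.0, 0.5)
    with pytest.raises(ValueError):
        decompose(Trace(x, np.zeros(x.size)))


def test_decompose_budget_flags_nonconvergence(make_trace):
    layout = [(443.0 + 21.0 * k, 6.0, 50.0) for k in range(6)]
    tr, _ = make_trace(layout)
    with pytest.warns(UserWarning):
        dec = decompose(tr, max_peaks=3)
    assert not dec.converged
    assert dec.n_peaks <= 3


def test_render_model_roundtrip(make_trace):
    tr, comps = make_trace([(443.0, 6.0, 100.0)])
    dec = decompose(tr)
    out = render_model(dec, tr.size_bp)
    np.testing.assert_allclose(out.intensity, tr.intensity, atol=0.01)
    with pytest.raises(ValueError):
        render_model(dec, np.array([1.0, 1.0, 2.0]))


def test_peak_table(make_trace):
    tr, _ = make_trace([(443.0, 6.0, 100.0), (464.0, 6.0, 50.0)])
    table = peak_table(decompose(tr))
    assert list(table.columns) == [
        "mean_bp", "sigma_bp", "amplitude", "area", "mean_repeats", "area_fraction",
    ]
    assert table.area_fraction.sum() == pytest.approx(1.0)
    assert table.mean_bp.is_monotonic_increasing


def test_peak_resolvability_extremes():
    narrow = [GaussianPeak(443.0 + 21 * k, 3.0, 10.0) for k in range(4)]
    assert peak_resolvability(PeakDecomposition(narrow, 1.0)) == 1.0
    broad = [GaussianPeak(443.0 + 21 * k, 15.0, 10.0) for k in range(4)]
    assert peak_resolvability(PeakDecomposition(broad, 1.0)) == 0.0
    single = PeakDecomposition([GaussianPeak(443.0, 6.0, 10.0)], 1.0)
    assert peak_resolvability(single) == 0.0
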