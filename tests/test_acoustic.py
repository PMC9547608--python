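"""k-space acoustic forward model, bandwidth filter, noise injection."""

import numpy as np
import pytest

from oaflux import acoustic as ac
from oaflux.errors import (ConfigurationError, DegenerateInputError,
                           GeometryError, StabilityError)


def test_paper2d_sinogram_dimensioning():
    """256 detectors x 2048 time steps = 524,288 samples."""
    pre = ac.paper2d_preset()
    s = ac.empty_sinogram(pre.detectors, pre.forward_grid)
    assert s.data.shape == (256, 2048)
    assert s.n_samples == 524_288


def test_paper3d_sinogram_dimensioning():
    """4096 planar elements x 2391 steps = 9,793,536 samples."""
    pre = ac.paper3d_preset()
    s = ac.empty_sinogram(pre.detectors, pre.forward_grid)
    assert s.data.shape == (4096, 2391)
    assert s.n_samples == 9_793_536


def test_zero_p0_zero_sinogram(desk):
    s = ac.forward_propagate(np.zeros((64, 64)), desk.c, desk.forward_grid,
                             desk.detectors)
    assert np.all(s.data == 0)


def test_time_of_flight_peak():
    """Tight central source, 19 mm ring, dt 50 ns -> peak near sample 247."""
    grid = ac.AcousticGrid((256, 256), 0.2, 50e-9, 300, pml_width=8)
    det = ac.circular_array(19.0, 16)
    yy, xx = np.mgrid[0:256, 0:256]
    p0 = np.exp(-(((yy - 127.5) ** 2 + (xx - 127.5) ** 2) * 0.2 ** 2) / (2 * 0.1 ** 2))
    s = ac.forward_propagate(p0, 1540.0, grid, det)
    peaks = np.abs(s.data).argmax(axis=1)
    expected = round(0.019 / 1540.0 / 50e-9)
    assert np.all(np.abs(peaks - expected) <= 2)


def test_mirror_symmetry():
    """Mirror-symmetric sources give a sinogram symmetric under the
    corresponding detector permutation."""
    grid = ac.AcousticGrid((128, 128), 0.2, 50e-9, 200, pml_width=8)
    det = ac.circular_array(9.0, 32)
    yy, xx = np.mgrid[0:128, 0:128]
    blob = lambda cy, cx: np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) * 0.04) / (2 * 0.3 ** 2))
    p0 = blob(63.5, 43.5) + blob(63.5, 83.5)  # mirror pair about the x-centre
    s = ac.forward_propagate(p0, 1540.0, grid, det)
    # theta -> pi - theta detector permutation: index k -> (N/2 - k) % N
    perm = (16 - np.arange(32)) % 32
    rel = (np.abs(s.data - s.data[perm]).max()
           / np.abs(s.data).max())
    assert rel <= 1e-6


def test_linearity_superposition():
    grid = ac.AcousticGrid((128, 128), 0.2, 50e-9, 150, pml_width=8)
    det = ac.circular_array(9.0, 8)
    rng = np.random.default_rng(0)
    a = np.zeros((128, 128))
    b = np.zeros((128, 128))
    a[60:68, 50:58] = rng.random((8, 8))
    b[40:46, 70:76] = rng.random((6, 6))
    sa = ac.forward_propagate(a, 1540.0, grid, det).data
    sb = ac.forward_propagate(b, 1540.0, grid, det).data
    sab = ac.forward_propagate(a + 2 * b, 1540.0, grid, det).data
    rel = np.abs(sab - (sa + 2 * sb)).max() / np.abs(sab).max()
    assert rel <= 1e-6


def test_pml_reflection_below_one_percent():
    """Outgoing pulse returns with < 1% amplitude after hitting a 20-cell PML."""
    grid = ac.AcousticGrid((256, 256), 0.2, 50e-9, 450, pml_width=20)
    yy, xx = np.mgrid[0:256, 0:256]
    p0 = np.exp(-(((yy - 127.5) ** 2 + (xx - 127.5) ** 2) * 0.2 ** 2) / (2 * 0.5 ** 2))
    det = ac.DetectorArray(np.array([[0.0, 0.0]]))  # grid centre
    trace = ac.forward_propagate(p0, 1540.0, grid, det).data[0]
    incident = np.abs(trace[:60]).max()
    reflected = np.abs(trace[250:]).max()
    assert reflected / incident < 0.01


def test_cfl_violation_raises():
    grid = ac.AcousticGrid((64, 64), 0.05, 50e-9, 10, pml_width=8)
    with pytest.raises(StabilityError):
        ac.forward_propagate(np.zeros((64, 64)), 1540.0, grid,
                             ac.circular_array(0.5, 4))


def test_detector_outside_interior_raises(desk):
    det = ac.DetectorArray(np.array([[0.0, 40.0]]))  # beyond the grid
    with pytest.raises(GeometryError):
        det.to_cells(desk.forward_grid)


# --- bandwidth filter -------------------------------------------------------


def _tone_sinogram(freq, dt=30e-9, n=2048):
    t = np.arange(n) * dt
    data = np.sin(2 * np.pi * freq * t)[None, :]
    det = ac.DetectorArray(np.array([[0.0, 0.0]]))
    return ac.Sinogram(data, dt, 1540.0, det)


def test_bandwidth_preserves_center_frequency():
    s = _tone_sinogram(5e6)
    out = ac.apply_bandwidth(s, 5e6, 0.9)
    # ignore windowing edges
    sl = slice(200, -200)
    ratio = np.abs(out.data[0, sl]).max() / np.abs(s.data[0, sl]).max()
    assert ratio == pytest.approx(1.0, abs=0.01)
    assert out.bandlimited


def test_bandwidth_rejects_dc():
    det = ac.DetectorArray(np.array([[0.0, 0.0]]))
    s = ac.Sinogram(np.ones((1, 1024)), 30e-9, 1540.0, det)
    out = ac.apply_bandwidth(s, 5e6, 0.9)
    assert np.mean(out.data ** 2) < 1e-3 * np.mean(s.data ** 2)


def test_bandwidth_idempotent_squares_response():
    """Filtering twice equals one pass with the squared response."""
    rng = np.random.default_rng(3)
    det = ac.DetectorArray(np.array([[0.0, 0.0]]))
    s = ac.Sinogram(rng.standard_normal((1, 4096)), 30e-9, 1540.0, det)
    twice = ac.apply_bandwidth(ac.apply_bandwidth(s, 5e6, 0.9), 5e6, 0.9)
    freqs = np.fft.rfftfreq(4096, 30e-9)
    sigma = 0.9 * 5e6 / (2 * np.sqrt(2 * np.log(2)))
    resp = np.exp(-((freqs - 5e6) ** 2) / (2 * sigma ** 2))
    resp[0] = 0.0
    once_sq = np.fft.irfft(np.fft.rfft(s.data, axis=1) * resp ** 2, n=4096, axis=1)
    np.testing.assert_allclose(twice.data, once_sq, atol=1e-10)


def test_bandwidth_above_nyquist_rejected():
    s = _tone_sinogram(1e6, dt=30e-9)
    with pytest.raises(ConfigurationError):
        ac.apply_bandwidth(s, 20e6, 0.9)


# --- noise ------------------------------------------------------------------


def test_add_noise_realized_snr(desk_sinogram):
    noisy = ac.add_noise(desk_sinogram, 40.0, seed=1)
    p_sig = np.mean(desk_sinogram.data ** 2)
    p_noise = np.mean((noisy.data - desk_sinogram.data) ** 2)
    realized = 10 * np.log10(p_sig / p_noise)
    assert 39.5 <= realized <= 40.5
    assert noisy.noise_snr_db == 40.0


def test_add_noise_infinite_snr_identity(desk_sinogram):
    out = ac.add_noise(desk_sinogram, np.inf, seed=1)
    np.testing.assert_array_equal(out.data, desk_sinogram.data)


def test_add_noise_seeds_independent(desk_sinogram):
    n1 = ac.add_noise(desk_sinogram, 30.0, seed=1).data - desk_sinogram.data
    n2 = ac.add_noise(desk_sinogram, 30.0, seed=2).data - desk_sinogram.data
    rho = np.corrcoef(n1.ravel(), n2.ravel())[0, 1]
    assert abs(rho) < 0.05


def test_add_noise_zero_sinogram_rejected():
    det = ac.DetectorArray(np.array([[0.0, 0.0]]))
    s = ac.Sinogram(np.zeros((1, 64)), 30e-9, 1540.0, det)
    with pytest.raises(DegenerateInputError):
        ac.add_noise(s, 40.0, seed=0)


def test_energy_conservation_before_pml():
    """Acoustic energy surrogate constant within 1% before the wavefront
    reaches the PML."""
    grid = ac.AcousticGrid((256, 256), 0.2, 50e-9, 120, pml_width=8)
    yy, xx = np.mgrid[0:256, 0:256]
    p0 = np.exp(-(((yy - 127.5) ** 2 + (xx - 127.5) ** 2) * 0.2 ** 2) / (2 * 0.5 ** 2))
    solver = ac.KSpaceSolver(grid, 1540.0)
    solver.set_initial_pressure(p0)
    energies = []
    rho_c2 = 1540.0 ** 2
    for _ in range(120):  # wavefront reaches the PML at ~160 steps
        solver.step()
        p = solver.pressure
        kinetic = sum(np.sum(u ** 2) for u in solver.u) * rho_c2
        energies.append(np.sum(p ** 2) + kinetic)
    energies = np.array(energies[10:])  # skip start-up transient
    assert energies.max() / energies.min() - 1 < 0.01
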