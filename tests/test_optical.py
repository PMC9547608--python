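"""Diffusion-equation fluence solver."""

import numpy as np
import pytest
from scipy import sparse

from oaflux import optical as op
from oaflux.errors import ConfigurationError, ShapeError
from oaflux.phantom import AbsorptionMap


def _homog_medium_2d(n=64, mu_a=0.005, mu_sp=0.1, h=0.2):
    return op.OpticalMedium(mu_a=np.full((n, n), mu_a), mu_s_prime=mu_sp,
                            spacing_mm=h)


def test_zero_source_zero_fluence():
    """q = 0 -> phi = 0 (homogeneous equation with decaying boundaries)."""
    med = _homog_medium_2d()
    empty = op.SourceSet(np.empty((0, 2)), np.empty(0))
    fl = op.solve_diffusion(med, empty, tol=1e-8)
    assert np.all(fl.phi == 0)


def test_greens_function_3d_oracle():
    """Homogeneous 3-D solution matches exp(-mu_eff r)/(4 pi D r) within 10%
    for r between 2 and 10 transport mean free paths."""
    n, mu_a, mu_sp, h = 61, 0.02, 2.0, 0.25
    med = op.OpticalMedium(mu_a=np.full((n, n, n), mu_a), mu_s_prime=mu_sp,
                           spacing_mm=h)
    src = op.SourceSet([[n // 2, n // 2, n // 2]], [1.0])
    fl = op.solve_diffusion(med, src, tol=1e-8)
    D = 1 / (3 * (mu_a + mu_sp))
    mu_eff = np.sqrt(mu_a / D)
    mfp = 1 / (mu_a + mu_sp)
    c = n // 2
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    r = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) * h
    border = np.minimum.reduce([zz, yy, xx, n - 1 - zz, n - 1 - yy, n - 1 - xx])
    sel = (r >= 2 * mfp) & (r <= 10 * mfp) & (border >= 5)
    phi_true = np.exp(-mu_eff * r[sel]) / (4 * np.pi * D * r[sel])
    rel = np.abs(fl.phi[sel] - phi_true) / phi_true
    assert rel.max() <= 0.10


def test_linearity_in_source():
    med = _homog_medium_2d()
    src1 = op.top_edge_sources((64, 64), 0.1, spacing_mm=0.2, amplitude=1.0)
    src2 = op.top_edge_sources((64, 64), 0.1, spacing_mm=0.2, amplitude=2.0)
    f1 = op.solve_diffusion(med, src1, tol=1e-10)
    f2 = op.solve_diffusion(med, src2, tol=1e-10)
    np.testing.assert_allclose(f2.phi, 2 * f1.phi, rtol=1e-6, atol=1e-12)


def test_positivity_and_depth_decay():
    med = _homog_medium_2d()
    src = op.top_edge_sources((64, 64), 0.1, spacing_mm=0.2)
    fl = op.solve_diffusion(med, src)
    assert fl.phi.min() >= 0
    col = fl.phi.mean(axis=1)
    peak = int(np.argmax(col))
    assert np.all(np.diff(col[peak:]) <= 1e-12)


def test_energy_balance():
    """Absorbed power + boundary outflow = source power within 2%."""
    med = _homog_medium_2d(mu_a=0.01)
    src = op.top_edge_sources((64, 64), 0.1, spacing_mm=0.2)
    fl = op.solve_diffusion(med, src, tol=1e-10)
    absorbed = float((med.mu_a * fl.phi).sum()) * 0.2 ** 2
    outflow = op.boundary_outflow(med, fl.phi)
    total = float(src.amplitudes.sum())
    assert abs(absorbed + outflow - total) / total <= 0.02


def test_cg_matches_dense_solve():
    """Iterative solution equals a dense direct solve on a 31x31 grid."""
    rng = np.random.default_rng(1)
    mu_a = 0.002 + 0.004 * rng.random((31, 31))
    med = op.OpticalMedium(mu_a=mu_a, mu_s_prime=0.1, spacing_mm=0.2)
    src = op.top_edge_sources((31, 31), 0.1, n_sources=4, spacing_mm=0.2)
    fl = op.solve_diffusion(med, src, tol=1e-12)
    mat = op._assemble_system(med)
    q = op._source_field(src, (31, 31), 0.2)
    direct = np.linalg.solve(mat.toarray(), q.ravel()).reshape(31, 31)
    assert np.linalg.norm(fl.phi - direct) / np.linalg.norm(direct) <= 1e-8


def test_wavelength_identity_and_depth_trend():
    """700 nm reproduces the base solve; 600 nm is dimmer and 800 nm brighter
    in the deepest quartile."""
    amap = AbsorptionMap(values=np.full((64, 64), 0.003), spacing_mm=0.2)
    base_medium = op.OpticalMedium(mu_a=amap.values, mu_s_prime=0.1, spacing_mm=0.2)
    src = op.top_edge_sources((64, 64), 0.1, spacing_mm=0.2)
    direct = op.solve_diffusion(base_medium, src, tol=1e-8)
    via_lut = op.fluence_for_wavelength(amap, 700.0, tol=1e-8)
    np.testing.assert_allclose(via_lut.phi, direct.phi, rtol=1e-8, atol=1e-14)

    deep = slice(48, 64)
    f600 = op.fluence_for_wavelength(amap, 600.0, tol=1e-8)
    f800 = op.fluence_for_wavelength(amap, 800.0, tol=1e-8)
    assert f600.phi[deep].mean() < via_lut.phi[deep].mean()
    assert f800.phi[deep].mean() > via_lut.phi[deep].mean()


def test_wavelength_missing_from_lut():
    amap = AbsorptionMap(values=np.full((64, 64), 0.003), spacing_mm=0.2)
    with pytest.raises(ConfigurationError):
        op.fluence_for_wavelength(amap, 650.0)


def test_absorbed_energy_definitions():
    med = _homog_medium_2d(mu_a=2.0, h=1.0)
    phi = op.FluenceMap(np.full((64, 64), 3.0), 1.0)
    e = op.absorbed_energy(med, phi, gamma=1.0)
    assert e.H[0, 0] == pytest.approx(6.0)
    assert e.P0[0, 0] == pytest.approx(6.0)
    e2 = op.absorbed_energy(med, phi, gamma=0.5)
    assert e2.P0[0, 0] == pytest.approx(3.0)
    # mu_a = 0 -> H = 0
    med0 = op.OpticalMedium(mu_a=np.zeros((64, 64)), mu_s_prime=0.1, spacing_mm=1.0)
    assert np.all(op.absorbed_energy(med0, phi).H == 0)


def test_absorbed_energy_grid_mismatch():
    med = _homog_medium_2d()
    phi = op.FluenceMap(np.zeros((32, 32)), 0.2)
    with pytest.raises(ShapeError):
        op.absorbed_energy(med, phi)


def test_medium_invariants():
    with pytest.raises(ConfigurationError):
        op.OpticalMedium(mu_a=np.zeros((8, 8)), mu_s_prime=0.0)
    with pytest.raises(ConfigurationError):
        op.OpticalMedium(mu_a=np.full((8, 8), 0.01), refractive_index=0.5)
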