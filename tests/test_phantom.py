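"""Vessel and breast phantom generation."""

import numpy as np
import pytest

from oaflux import phantom as ph
from oaflux.errors import ConfigurationError, DegenerateInputError


def test_isodata_toy_threshold():
    """Hand-iterated recurrence: mean 5 -> class means 0 and 10 -> t = 5."""
    assert ph.isodata_threshold(np.array([0, 0, 0, 10, 10, 10.0])) == pytest.approx(5.0)


def test_isodata_constant_input_rejected():
    with pytest.raises(DegenerateInputError):
        ph.isodata_threshold(np.full(10, 3.0))


def test_vessel_gray_deterministic_and_seed_sensitive():
    cfg = ph.PhantomConfig(shape=(64, 64), seed=5)
    a = ph.generate_vessel_gray(cfg)
    b = ph.generate_vessel_gray(cfg)
    np.testing.assert_array_equal(a, b)
    c = ph.generate_vessel_gray(cfg.with_seed(6))
    assert np.mean(a != c) >= 0.01


def test_vessel_gray_fill_fraction_and_range():
    for seed in range(5):
        cfg = ph.PhantomConfig(shape=(128, 128), seed=seed)
        g = ph.generate_vessel_gray(cfg)
        assert g.min() >= 0 and g.max() <= 1
        dark = (g < 0.45).mean()  # vessel (dark) pixel fraction
        assert 0.03 <= dark <= 0.25


def test_zero_branches_gives_vessel_free_image():
    cfg = ph.PhantomConfig(shape=(64, 64), seed=0, n_branches=0)
    g = ph.generate_vessel_gray(cfg)
    assert (g < 0.45).sum() == 0
    # downstream stage rejects a mask with no foreground
    with pytest.raises(DegenerateInputError):
        ph.assign_absorption(np.zeros((64, 64), dtype=bool), cfg)


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        ph.PhantomConfig(shape=(16, 16))
    with pytest.raises(ConfigurationError):
        ph.PhantomConfig(mu_fore_cm=(0.05, 0.01))


def test_mask_single_dominant_component():
    """Default-config masks form one dominant connected network."""
    for seed in range(5):
        cfg = ph.PhantomConfig(seed=seed)  # 256x256 reference scale
        mask = ph.extract_mask(ph.generate_vessel_gray(cfg), cfg)
        assert ph.largest_component_fraction(mask) >= 0.8


def test_huge_min_object_empties_mask():
    """Area opening removes every component below the size threshold."""
    cfg = ph.PhantomConfig(shape=(64, 64), seed=1, min_object_px=10 ** 6)
    mask = ph.extract_mask(ph.generate_vessel_gray(cfg), cfg)
    assert mask.sum() == 0


def test_assign_absorption_ranges_and_units():
    """Foreground in [0.03, 0.0438] cm^-1, background in [0, 0.001] cm^-1,
    stored in mm^-1."""
    cfg = ph.PhantomConfig(shape=(256, 256), seed=2)
    mask = ph.extract_mask(ph.generate_vessel_gray(cfg), cfg)
    amap = ph.assign_absorption(mask, cfg)
    fg = amap.values[mask]
    bg = amap.values[~mask]
    assert fg.min() >= 0.003 and fg.max() <= 0.00438
    assert bg.min() >= 0.0 and bg.max() <= 0.0001
    assert fg.min() > bg.max()  # class separation


def test_assign_absorption_zero_width_range():
    cfg = ph.PhantomConfig(shape=(64, 64), seed=1, mu_fore_cm=(0.04, 0.04))
    mask = np.zeros((64, 64), dtype=bool)
    mask[10:20, 10:20] = True
    amap = ph.assign_absorption(mask, cfg)
    np.testing.assert_allclose(amap.values[mask], 0.004)


def test_assign_absorption_foreground_mean():
    """Empirical mean within 3 standard errors of the uniform mean."""
    cfg = ph.PhantomConfig(shape=(256, 256), seed=7)
    mask = np.zeros((256, 256), dtype=bool)
    mask[:128] = True
    amap = ph.assign_absorption(mask, cfg)
    fg = amap.values[mask]
    lo, hi = cfg.mu_fore_mm
    expect = (lo + hi) / 2
    se = (hi - lo) / np.sqrt(12 * fg.size)
    assert abs(fg.mean() - expect) <= 3 * se


def test_assign_absorption_deterministic():
    cfg = ph.PhantomConfig(shape=(64, 64), seed=3)
    mask = ph.extract_mask(ph.generate_vessel_gray(cfg), cfg)
    a = ph.assign_absorption(mask, cfg)
    b = ph.assign_absorption(mask, cfg)
    np.testing.assert_array_equal(a.values, b.values)


def test_pipeline_closure_many_seeds():
    """Full 2-D chain yields valid absorption maps across seeds."""
    for seed in range(25):
        cfg = ph.PhantomConfig(shape=(64, 64), seed=seed)
        amap = ph.generate_vessel_phantom(cfg)
        assert np.all(np.isfinite(amap.values))
        assert amap.values.min() >= 0
        assert amap.values.max() <= 0.00438 + 1e-12


def test_extract_mask_constant_image_rejected():
    cfg = ph.PhantomConfig(shape=(64, 64), seed=0)
    with pytest.raises(DegenerateInputError):
        ph.extract_mask(np.full((64, 64), 0.5), cfg)


# --- 3-D breast phantom -----------------------------------------------------


@pytest.fixture(scope="module")
def breast():
    cfg = ph.PhantomConfig(shape=(64, 64, 64), spacing_mm=0.38, seed=4)
    return ph.generate_breast_3d(cfg)


def test_breast_value_support(breast):
    """Voxel histogram support is exactly the five tissue-class values."""
    np.testing.assert_array_equal(np.unique(breast.values),
                                  [0.0, 0.016, 0.024, 0.032, 0.04])
    # every class present
    assert set(np.unique(breast.labels)) == {0, 1, 2, 3, 4}


def test_breast_no_enclosed_background(breast):
    from scipy import ndimage
    holes = ndimage.binary_fill_holes(breast.labels > 0) & (breast.labels == 0)
    assert holes.sum() == 0


def test_breast_skin_shell_encloses_interior(breast):
    """Ray-casting oracle: every axis-aligned ray from an interior voxel to
    the volume boundary crosses at least one skin voxel."""
    labels = breast.labels
    skin = labels == ph.BREAST_LABELS["skin"]
    interior = (labels > 0) & ~skin
    pts = np.argwhere(interior)
    rng = np.random.default_rng(0)
    for p in pts[rng.choice(len(pts), size=200, replace=False)]:
        z, y, x = p
        rays = [skin[:z, y, x], skin[z + 1:, y, x], skin[z, :y, x],
                skin[z, y + 1:, x], skin[z, y, :x], skin[z, y, x + 1:]]
        assert all(r.any() for r in rays)


def test_breast_too_small_shape_rejected():
    with pytest.raises(ConfigurationError):
        ph.generate_breast_3d(ph.PhantomConfig(shape=(34, 34, 34), seed=0,
                                               skin_voxels=6))
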