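"""Synthetic absorption phantoms for optoacoustic simulation.

Two families are produced:

* 2-D vessel-network phantoms: a procedural branching vessel tree is drawn as
  a grayscale image, passed through an enhancement / thresholding /
  morphological-cleaning chain (CLAHE, mean filtering, isodata threshold on
  the difference image, small-object removal), and the resulting binary
  vessel mask is converted to an absorption map by drawing per-pixel
  absorption values uniformly from a foreground range (vessels) and a
  background range (tissue).

* 3-D layered breast phantoms: a hemispherical volume with a skin shell,
  interior fat, embedded fibroglandular lobes and tube-like vessels, each
  tissue class carrying its literature absorption value.

All absorption values are stored in the canonical unit mm^-1.  The 2-D
vessel ranges are conventionally quoted in cm^-1 and are converted on
configuration load.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import exposure, measure, morphology

from .errors import ConfigurationError, DegenerateInputError

# 2-D vessel phantom absorption ranges, quoted in cm^-1
MU_A_FORE_CM = (0.03, 0.0438)
MU_A_BACK_CM = (0.0, 0.001)

# 3-D breast tissue classes, mm^-1
BREAST_MU_A = {
    "background": 0.0,
    "fibroglandular": 0.016,
    "fat": 0.024,
    "skin": 0.032,
    "vessel": 0.04,
}
BREAST_LABELS = {
    "background": 0,
    "fibroglandular": 1,
    "fat": 2,
    "skin": 3,
    "vessel": 4,
}


@dataclass
class PhantomConfig:
    """Parameters of the procedural phantom generators.

    ``mu_fore`` / ``mu_back`` are the 2-D vessel/background absorption ranges
    in cm^-1 (converted to mm^-1 internally); ``class_mu_a`` holds the 3-D
    per-tissue values in mm^-1.
    """

    shape: tuple = (256, 256)
    spacing_mm: float = 0.1
    seed: int = 0
    wavelength_nm: float = 700.0
    # 2-D absorption ranges (cm^-1, as conventionally quoted)
    mu_fore_cm: tuple = MU_A_FORE_CM
    mu_back_cm: tuple = MU_A_BACK_CM
    # 3-D per-class values (mm^-1)
    class_mu_a: dict = field(default_factory=lambda: dict(BREAST_MU_A))
    # vessel-tree generator
    n_branches: int = 9
    step_px: float = 2.0
    width_px: tuple = (1.0, 6.0)
    curvature: float = 0.25
    background_texture: float = 0.12
    target_fill: tuple = (0.03, 0.25)
    # mask extraction
    clahe_tiles: int = 8
    clahe_clip: float = 0.01
    mean_filter_px: int = 25
    min_object_px: int = 30
    # 3-D geometry
    skin_voxels: int = 2
    n_lobes: tuple = (3, 6)
    n_vessels_3d: tuple = (2, 5)

    def __post_init__(self):
        if len(self.shape) not in (2, 3) or min(self.shape) < 32:
            raise ConfigurationError(f"shape must be >= 32 per axis, got {self.shape}")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ConfigurationError(f"seed must be a non-negative integer, got {self.seed!r}")
        for lo, hi, name in [(*self.mu_fore_cm, "mu_fore_cm"), (*self.mu_back_cm, "mu_back_cm")]:
            if lo < 0 or lo > hi:
                raise ConfigurationError(f"{name} must satisfy 0 <= min <= max, got ({lo}, {hi})")

    @property
    def mu_fore_mm(self) -> tuple:
        return (self.mu_fore_cm[0] / 10.0, self.mu_fore_cm[1] / 10.0)

    @property
    def mu_back_mm(self) -> tuple:
        return (self.mu_back_cm[0] / 10.0, self.mu_back_cm[1] / 10.0)

    def with_seed(self, seed: int) -> "PhantomConfig":
        return replace(self, seed=int(seed))


@dataclass
class AbsorptionMap:
    """Per-cell optical absorption coefficient on a regular grid (mm^-1)."""

    values: np.ndarray
    spacing_mm: float
    wavelength_nm: float = 700.0
    labels: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or self.values.min() < 0:
            raise ValueError("absorption values must be finite and non-negative")

    @property
    def shape(self):
        return self.values.shape


def _validate_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"grayscale image must be 2-D, got ndim={img.ndim}")
    if not np.all(np.isfinite(img)) or img.min() < -1e-12 or img.max() > 1 + 1e-12:
        raise ValueError("grayscale image values must be finite and in [0, 1]")
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# vessel-tree grayscale generator
# ---------------------------------------------------------------------------

def _stamp_gaussian(canvas: np.ndarray, y: float, x: float, sigma: float, amp: float):
    """Add a small Gaussian blob centred at (y, x) in place."""
    h, w = canvas.shape
    r = max(1, int(np.ceil(3 * sigma)))
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - y) ** 2 + (xx - x) ** 2
    np.maximum(canvas[y0:y1, x0:x1],
               amp * np.exp(-d2 / (2 * sigma ** 2)),
               out=canvas[y0:y1, x0:x1])


def generate_vessel_gray(config: PhantomConfig) -> np.ndarray:
    """Draw a connected branching vessel network as a grayscale image.

    A random-walk tree is grown from a root near one image edge; each branch
    is rendered as a chain of Gaussian cross-section stamps whose width
    tapers with branch generation.  Vessels are dark on a bright smoothly
    textured background, as in retinal imagery, so the downstream
    enhancement/threshold chain sees the contrast polarity it expects.
    Deterministic for a fixed config/seed.
    """
    if len(config.shape) != 2:
        raise ConfigurationError("generate_vessel_gray requires a 2-D shape")
    h, w = config.shape
    rng = np.random.default_rng([config.seed, 101])
    canvas = np.zeros((h, w), dtype=np.float64)

    if config.n_branches <= 0:
        fg = canvas
    else:
        # grow the tree: queue of (position, direction, width, generation)
        root = np.array([rng.uniform(0.1, 0.3) * h, rng.uniform(0.2, 0.8) * w])
        direction = rng.uniform(0.25 * np.pi, 0.75 * np.pi)  # pointing downward
        w_lo, w_hi = config.width_px
        queue = [(root, direction, rng.uniform(0.7 * w_hi, w_hi), 0)]
        n_spawned = 1
        target_lo, target_hi = config.target_fill
        max_rounds = 6
        for _ in range(max_rounds):
            while queue:
                pos, ang, width, gen = queue.pop(0)
                n_steps = int(rng.integers(max(h, w) // 4, max(h, w) // 2))
                pos = pos.copy()
                for _ in range(n_steps):
                    ang += rng.normal(0.0, config.curvature)
                    pos += config.step_px * np.array([np.sin(ang), np.cos(ang)])
                    if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                        break
                    width = max(w_lo, width * 0.997)
                    _stamp_gaussian(canvas, pos[0], pos[1], max(0.6, width / 2.0), 1.0)
                    if (n_spawned < config.n_branches
                            and rng.random() < 0.02 and width > 1.5 * w_lo):
                        side = 1.0 if rng.random() < 0.5 else -1.0
                        queue.append((pos.copy(),
                                      ang + side * rng.uniform(0.4, 1.1),
                                      width * rng.uniform(0.55, 0.8),
                                      gen + 1))
                        n_spawned += 1
            fill = np.mean(canvas > 0.5)
            if fill >= target_lo:
                break
            # grow another primary branch from a point already on the tree
            on = np.argwhere(canvas > 0.8)
            if len(on) == 0:
                queue = [(root.copy(), rng.uniform(0, 2 * np.pi),
                          rng.uniform(0.7 * w_hi, w_hi), 0)]
            else:
                p = on[rng.integers(len(on))].astype(float)
                queue = [(p, rng.uniform(0, 2 * np.pi),
                          rng.uniform(0.5 * w_hi, w_hi), 0)]
            n_spawned += 1
        fg = canvas

    # bright textured background with dark vessels, as in retinal imagery
    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=6.0)
    tmin, tmax = texture.min(), texture.max()
    if tmax > tmin:
        texture = (texture - tmin) / (tmax - tmin)
    background = 0.75 + config.background_texture * (texture - 0.5)
    img = background - 0.55 * fg
    return _validate_gray(img)


# ---------------------------------------------------------------------------
# mask extraction chain
# ---------------------------------------------------------------------------

def isodata_threshold(values: np.ndarray, tol: float = 1e-6, max_iter: int = 500) -> float:
    """Isodata (Ridler-Calvard) automatic threshold.

    Iterates ``t <- (mean(values <= t) + mean(values > t)) / 2`` from the
    global mean until |dt| < tol.  Raises on constant input, for which the
    two-class split is undefined.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0 or v.max() == v.min():
        raise DegenerateInputError("isodata threshold undefined for constant input")
    t = float(v.mean())
    for _ in range(max_iter):
        lo = v[v <= t]
        hi = v[v > t]
        if hi.size == 0 or lo.size == 0:
            raise DegenerateInputError("isodata iteration produced an empty class")
        t_new = 0.5 * (lo.mean() + hi.mean())
        if abs(t_new - t) < tol:
            return float(t_new)
        t = t_new
    return float(t)


def extract_mask(img: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Binarize a grayscale vessel image via the enhancement/threshold chain.

    Steps, in order: CLAHE contrast enhancement; mean-filter smoothing of the
    enhanced image (the window is wide relative to a vessel, so it estimates
    the local background); absolute difference between the enhanced image
    and its smoothed background; isodata threshold of the difference image;
    removal of connected components smaller than ``min_object_px``; removal
    of isolated single pixels.
    """
    img = _validate_gray(img)
    if img.max() == img.min():
        raise DegenerateInputError("cannot threshold an all-constant image")
    h, w = img.shape
    kernel = (max(8, h // config.clahe_tiles), max(8, w // config.clahe_tiles))
    enhanced = exposure.equalize_adapthist(img, kernel_size=kernel,
                                           clip_limit=config.clahe_clip)
    smoothed = ndimage.uniform_filter(enhanced, size=config.mean_filter_px)
    diff = np.abs(enhanced - smoothed)
    t = isodata_threshold(diff)
    mask = diff > t
    # close 1-px threshold gaps so the network stays connected
    mask = morphology.closing(mask, morphology.footprint_rectangle((3, 3)))
    # scale the minimum object size with image area (reference: 256x256)
    min_px = max(1, int(round(config.min_object_px * (h * w) / (256 * 256))))
    mask = morphology.remove_small_objects(mask, max_size=min_px - 1)
    # morphological 'clean': drop pixels with no 8-connected neighbour
    neighbours = ndimage.convolve(mask.astype(np.uint8), np.ones((3, 3)),
                                  mode="constant") - mask
    mask &= neighbours > 0
    return mask.astype(bool)


def assign_absorption(mask: np.ndarray, config: PhantomConfig) -> AbsorptionMap:
    """Convert a binary vessel mask into a heterogeneous absorption map.

    Foreground pixels draw i.i.d. uniform values from the vessel range and
    background pixels from the background range; the two random fields are
    masked and summed.  Ranges are quoted in cm^-1 in the config and the
    result is stored in mm^-1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any() or mask.all():
        raise DegenerateInputError("mask must contain both foreground and background")
    rng = np.random.default_rng([config.seed, 202])
    f_lo, f_hi = config.mu_fore_mm
    b_lo, b_hi = config.mu_back_mm
    fore = f_lo + (f_hi - f_lo) * rng.random(mask.shape)
    back = b_lo + (b_hi - b_lo) * rng.random(mask.shape)
    values = fore * mask + back * ~mask
    return AbsorptionMap(
        values=values,
        spacing_mm=config.spacing_mm,
        wavelength_nm=config.wavelength_nm,
        meta={
            "mu_fore_mm": config.mu_fore_mm,
            "mu_back_mm": config.mu_back_mm,
            "seed": config.seed,
            "mask_fraction": float(mask.mean()),
        },
    )


def generate_vessel_phantom(config: PhantomConfig) -> AbsorptionMap:
    """Full 2-D chain: draw vessels, extract the mask, assign absorption."""
    gray = generate_vessel_gray(config)
    mask = extract_mask(gray, config)
    return assign_absorption(mask, config)


# ---------------------------------------------------------------------------
# 3-D layered breast phantom
# ---------------------------------------------------------------------------

def _ellipsoid_mask(shape, center, radii):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) ** 2 / radii[0] ** 2
            + (yy - center[1]) ** 2 / radii[1] ** 2
            + (xx - center[2]) ** 2 / radii[2] ** 2) <= 1.0


def generate_breast_3d(config: PhantomConfig) -> AbsorptionMap:
    """Hemispherical layered breast phantom with skin, fat, lobes, vessels.

    The dome rests on the first z-plane; a closed skin shell (dome surface
    plus base plate) encloses a fat interior with randomly placed
    fibroglandular lobes and random-walk vessel tubes.  Each class region is
    hole-filled before the literature absorption value is assigned.
    """
    if len(config.shape) != 3:
        raise ConfigurationError("generate_breast_3d requires a 3-D shape")
    nz, ny, nx = config.shape
    rng = np.random.default_rng([config.seed, 303])
    radius = min(nz - 2, ny // 2 - 2, nx // 2 - 2)
    if radius <= 3 * config.skin_voxels:
        raise ConfigurationError(
            f"shape {config.shape} too small to hold a {config.skin_voxels}-voxel skin shell")
    center = np.array([0.0, ny / 2.0, nx / 2.0])

    zz, yy, xx = np.ogrid[:nz, :ny, :nx]
    r2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    breast = (r2 <= radius ** 2)
    breast = ndimage.binary_fill_holes(breast)

    interior = ndimage.binary_erosion(breast, iterations=config.skin_voxels)
    interior[: config.skin_voxels] = False  # base plate of skin at z < skin_voxels
    skin = breast & ~interior

    # fibroglandular lobes: random ellipsoids inside the interior
    lobes = np.zeros_like(breast)
    n_lobes = int(rng.integers(config.n_lobes[0], config.n_lobes[1] + 1))
    core = np.argwhere(ndimage.binary_erosion(interior, iterations=2))
    for _ in range(n_lobes):
        c = core[rng.integers(len(core))]
        radii = rng.uniform(radius * 0.08, radius * 0.25, size=3)
        lobes |= _ellipsoid_mask((nz, ny, nx), c, radii)
    lobes &= interior
    lobes = ndimage.binary_fill_holes(lobes)
    lobes &= interior

    # vessels: random-walk tubes
    vessels = np.zeros_like(breast)
    n_ves = int(rng.integers(config.n_vessels_3d[0], config.n_vessels_3d[1] + 1))
    for _ in range(n_ves):
        p = core[rng.integers(len(core))].astype(float)
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        tube_r = rng.uniform(1.0, max(1.5, radius * 0.05))
        for _ in range(int(4 * radius)):
            d += 0.3 * rng.standard_normal(3)
            d /= np.linalg.norm(d)
            p += d
            lo = np.maximum(np.floor(p - tube_r).astype(int), 0)
            hi = np.minimum(np.ceil(p + tube_r).astype(int) + 1, [nz, ny, nx])
            if np.any(lo >= hi):
                break
            sz, sy, sx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
            ball = ((sz - p[0]) ** 2 + (sy - p[1]) ** 2 + (sx - p[2]) ** 2) <= tube_r ** 2
            vessels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball
            if not interior[tuple(np.clip(np.round(p).astype(int), 0, [nz - 1, ny - 1, nx - 1]))]:
                break
    vessels &= interior
    vessels = ndimage.binary_fill_holes(vessels)
    vessels &= interior

    labels = np.zeros((nz, ny, nx), dtype=np.int8)
    labels[interior] = BREAST_LABELS["fat"]
    labels[lobes] = BREAST_LABELS["fibroglandular"]
    labels[vessels] = BREAST_LABELS["vessel"]
    labels[skin] = BREAST_LABELS["skin"]

    # enclosed background voxels inside the breast become fat
    holes = ndimage.binary_fill_holes(labels > 0) & (labels == 0)
    labels[holes] = BREAST_LABELS["fat"]

    mu = config.class_mu_a
    lut = np.array([mu["background"], mu["fibroglandular"], mu["fat"],
                    mu["skin"], mu["vessel"]])
    values = lut[labels]
    return AbsorptionMap(values=values, spacing_mm=config.spacing_mm,
                         wavelength_nm=config.wavelength_nm, labels=labels,
                         meta={"seed": config.seed, "radius_voxels": int(radius)})


def largest_component_fraction(mask: np.ndarray) -> float:
    """Fraction of foreground pixels in the largest connected component."""
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        return 0.0
    sizes = np.bincount(lab.ravel())[1:]
    return float(sizes.max() / sizes.sum())
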