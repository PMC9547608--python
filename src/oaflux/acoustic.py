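"""Acoustic forward model: k-space pseudospectral wave propagation.

The lossless homogeneous wave equation with initial conditions
``p(0) = P0``, ``dp/dt(0) = 0`` is integrated with the first-order
pressure/velocity split scheme on a staggered spatial grid:

    u_i^{n+1/2} = pml_i [ pml_i u_i^{n-1/2} - dt/rho d_i p^n ]
    p_i^{n+1}   = pml_i [ pml_i p_i^n - dt rho c^2 d_i u_i^{n+1/2} ]
    p = sum_i p_i

Spatial derivatives are evaluated spectrally with the exact k-space
dispersion correction kappa = sinc(c k dt / 2), which makes the scheme exact
for homogeneous media; a split-field perfectly matched layer (PML) with a
quartic absorption ramp absorbs outgoing waves at the grid edges.

Detection: point detectors sampled by multilinear interpolation each time
step, an optional Gaussian amplitude bandwidth filter (zero phase), and
additive white Gaussian noise at a prescribed sinogram SNR.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (ConfigurationError, DegenerateInputError, GeometryError,
                     ShapeError, StabilityError)

DEFAULT_SOUND_SPEED = 1540.0  # m/s
DEFAULT_CENTER_FREQ = 5e6     # Hz
DEFAULT_FRAC_BW = 0.9


@dataclass
class AcousticGrid:
    """Computational grid for wave propagation (PML included in ``shape``)."""

    shape: tuple
    spacing_mm: float
    dt: float              # s
    n_steps: int
    pml_width: int = 20
    pml_alpha: float = 2.0  # Nepers per grid point at the outer PML edge

    def __post_init__(self):
        if self.pml_width < 1:
            raise ConfigurationError("pml_width must be >= 1")
        if min(self.shape) <= 2 * self.pml_width + 2:
            raise ConfigurationError("grid too small for the PML")

    @property
    def dx_m(self) -> float:
        return self.spacing_mm * 1e-3

    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=np.float64) - 1) / 2.0

    def check_cfl(self, c: float, cfl_max: float = 1.0):
        cfl = c * self.dt / self.dx_m
        if cfl > cfl_max:
            raise StabilityError(
                f"CFL number {cfl:.3f} exceeds {cfl_max} (dt={self.dt}, dx={self.dx_m})")


@dataclass
class DetectorArray:
    """Point detectors; positions in mm relative to the grid centre."""

    positions_mm: np.ndarray  # (n_det, ndim)
    geometry: str = "circle"
    center_freq: float = DEFAULT_CENTER_FREQ
    frac_bandwidth: float = DEFAULT_FRAC_BW

    def __post_init__(self):
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=np.float64))
        if len(self.positions_mm) < 1:
            raise ConfigurationError("at least one detector required")

    @property
    def n_detectors(self) -> int:
        return len(self.positions_mm)

    def to_cells(self, grid: AcousticGrid) -> np.ndarray:
        """Fractional cell coordinates of the detectors on a given grid."""
        pos = self.positions_mm / grid.spacing_mm + grid.center
        lo = np.asarray([grid.pml_width] * pos.shape[1])
        hi = np.asarray(grid.shape) - grid.pml_width - 1
        if np.any(pos < lo) or np.any(pos > hi):
            raise GeometryError("detector positions fall inside the PML or outside the grid")
        return pos


def circular_array(radius_mm: float, n_detectors: int = 256,
                   center_freq: float = DEFAULT_CENTER_FREQ,
                   frac_bandwidth: float = DEFAULT_FRAC_BW) -> DetectorArray:
    """Detectors equispaced on a circle around the grid centre (2-D)."""
    theta = 2 * np.pi * np.arange(n_detectors) / n_detectors
    pos = radius_mm * np.stack([np.sin(theta), np.cos(theta)], axis=1)
    return DetectorArray(pos, "circle", center_freq, frac_bandwidth)


def planar_array(extent_mm: float, n_per_side: int = 64, offset_mm: float = 0.0,
                 center_freq: float = DEFAULT_CENTER_FREQ,
                 frac_bandwidth: float = DEFAULT_FRAC_BW) -> DetectorArray:
    """n x n detectors on a single z-plane (3-D), offset from the centre."""
    coords = (np.arange(n_per_side) + 0.5) / n_per_side - 0.5
    yy, xx = np.meshgrid(coords * extent_mm, coords * extent_mm, indexing="ij")
    pos = np.stack([np.full(yy.size, offset_mm), yy.ravel(), xx.ravel()], axis=1)
    return DetectorArray(pos, "plane", center_freq, frac_bandwidth)


@dataclass
class Sinogram:
    """Detector x time pressure record with acquisition metadata."""

    data: np.ndarray          # (n_detectors, n_steps)
    dt: float
    c: float
    detectors: DetectorArray
    bandlimited: bool = False
    noise_snr_db: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ShapeError("sinogram data must be (n_detectors, n_steps)")

    @property
    def n_samples(self) -> int:
        return self.data.size


def empty_sinogram(det: DetectorArray, grid: AcousticGrid,
                   c: float = DEFAULT_SOUND_SPEED) -> Sinogram:
    """Allocate a zero sinogram for a given acquisition geometry."""
    return Sinogram(np.zeros((det.n_detectors, grid.n_steps)), grid.dt, c, det)


# ---------------------------------------------------------------------------
# k-space solver
# ---------------------------------------------------------------------------

class KSpaceSolver:
    """First-order k-space pseudospectral stepper with split-field PML.

    Works in 2-D and 3-D; density is set to 1 (pressure in arbitrary units).
    """

    def __init__(self, grid: AcousticGrid, c: float):
        grid.check_cfl(c)
        self.grid = grid
        self.c = c
        shape = grid.shape
        self.ndim = len(shape)
        self._axes = tuple(range(self.ndim))
        dx = grid.dx_m
        dt = grid.dt

        # wavenumber grids on the rfft layout (last axis halved)
        ks = [2 * np.pi * np.fft.fftfreq(n, dx) for n in shape[:-1]]
        ks.append(2 * np.pi * np.fft.rfftfreq(shape[-1], dx))
        self.k_axes = []
        for ax, k in enumerate(ks):
            sh = [1] * self.ndim
            sh[ax] = len(k)
            self.k_axes.append(k.reshape(sh))
        k2 = sum(k ** 2 for k in self.k_axes)
        kmag = np.sqrt(k2)
        self.kappa = np.sinc(c * kmag * dt / (2 * np.pi))  # np.sinc(x)=sin(pi x)/(pi x)
        # staggered-grid shift operators
        self.shift_pos = [np.exp(1j * k * dx / 2) for k in self.k_axes]
        self.shift_neg = [np.exp(-1j * k * dx / 2) for k in self.k_axes]

        # PML absorption profiles (one per axis, broadcastable); the
        # velocity profile is sampled at the staggered (x + dx/2) positions
        # so left- and right-going waves see identical absorption ramps
        self.pml = []
        self.pml_stag = []
        sigma_max = grid.pml_alpha * c / dx
        w = grid.pml_width

        def profile(x, n):
            d = np.zeros_like(x)
            left = x < w
            d[left] = (w - x[left]) / w
            right = x > n - 1 - w
            d[right] = (x[right] - (n - 1 - w)) / w
            return np.exp(-sigma_max * np.clip(d, 0, 1) ** 4 * dt / 2)

        for ax, n in enumerate(shape):
            x = np.arange(n, dtype=np.float64)
            sh = [1] * self.ndim
            sh[ax] = n
            self.pml.append(profile(x, n).reshape(sh))
            self.pml_stag.append(profile(x + 0.5, n).reshape(sh))

        self.p_split = None
        self.u = None

    # -- state management --------------------------------------------------
    def set_initial_pressure(self, p0: np.ndarray):
        if p0.shape != self.grid.shape:
            raise ShapeError(f"p0 shape {p0.shape} != grid {self.grid.shape}")
        self.p_split = [p0.astype(np.float64) / self.ndim for _ in range(self.ndim)]
        # half-step velocity so that dp/dt(0) ~ 0 in the leapfrog sense
        P = np.fft.rfftn(p0)
        self.u = []
        for ax in range(self.ndim):
            grad = np.fft.irfftn(1j * self.k_axes[ax] * self.kappa
                                 * self.shift_pos[ax] * P, s=self.grid.shape,
                                 axes=self._axes)
            self.u.append(self.pml_stag[ax] * (-self.grid.dt / 2 * grad))

    def zero_state(self):
        self.p_split = [np.zeros(self.grid.shape) for _ in range(self.ndim)]
        self.u = [np.zeros(self.grid.shape) for _ in range(self.ndim)]

    @property
    def pressure(self) -> np.ndarray:
        return sum(self.p_split)

    def step(self):
        """Advance the field by one dt."""
        dt = self.grid.dt
        c2 = self.c ** 2
        P = np.fft.rfftn(self.pressure)
        for ax in range(self.ndim):
            grad = np.fft.irfftn(1j * self.k_axes[ax] * self.kappa
                                 * self.shift_pos[ax] * P, s=self.grid.shape,
                                 axes=self._axes)
            self.u[ax] = self.pml_stag[ax] * (self.pml_stag[ax] * self.u[ax]
                                              - dt * grad)
        for ax in range(self.ndim):
            U = np.fft.rfftn(self.u[ax])
            div = np.fft.irfftn(1j * self.k_axes[ax] * self.kappa
                                * self.shift_neg[ax] * U, s=self.grid.shape,
                                axes=self._axes)
            self.p_split[ax] = self.pml[ax] * (self.pml[ax] * self.p_split[ax]
                                               - dt * c2 * div)


def _interp_weights(positions_cells: np.ndarray, shape):
    """Multilinear gather indices/weights for fractional cell positions."""
    ndim = positions_cells.shape[1]
    base = np.floor(positions_cells).astype(int)
    frac = positions_cells - base
    idx_list, w_list = [], []
    strides = np.cumprod((1,) + tuple(shape[::-1][:-1]))[::-1]
    for corner in np.ndindex(*(2,) * ndim):
        corner = np.asarray(corner)
        idx = np.minimum(base + corner, np.asarray(shape) - 1)
        flat = (idx * strides).sum(axis=1)
        w = np.prod(np.where(corner, frac, 1 - frac), axis=1)
        idx_list.append(flat)
        w_list.append(w)
    return np.stack(idx_list, axis=1), np.stack(w_list, axis=1)


def embed_p0(p0: np.ndarray, grid: AcousticGrid, scale: int = 1) -> np.ndarray:
    """Embed (optionally upsampled) initial pressure at the grid centre.

    ``scale`` > 1 bilinearly refines p0 by an integer factor before
    embedding, used to place a coarse phantom on the finer forward grid.
    """
    from scipy import ndimage
    arr = np.asarray(p0, dtype=np.float64)
    if scale > 1:
        arr = ndimage.zoom(arr, scale, order=1, grid_mode=True, mode="nearest")
    if any(a > g for a, g in zip(arr.shape, grid.shape)):
        raise ShapeError(f"p0 {arr.shape} does not fit in grid {grid.shape}")
    out = np.zeros(grid.shape)
    starts = [(g - a) // 2 for g, a in zip(grid.shape, arr.shape)]
    sl = tuple(slice(s, s + a) for s, a in zip(starts, arr.shape))
    out[sl] = arr
    return out


def forward_propagate(p0, c: float, grid: AcousticGrid,
                      det: DetectorArray) -> Sinogram:
    """Propagate an initial pressure field and record the detector traces.

    ``p0`` may be a raw array matching the grid, or an
    :class:`~oaflux.optical.AbsorbedEnergyMap` whose P0 is embedded centred
    on the grid (upsampled if its spacing is an integer multiple of the
    grid's).
    """
    if hasattr(p0, "P0"):
        ratio = p0.spacing_mm / grid.spacing_mm
        scale = int(round(ratio))
        if abs(ratio - scale) > 1e-9 or scale < 1:
            raise ShapeError(f"p0 spacing {p0.spacing_mm} incompatible with grid "
                             f"spacing {grid.spacing_mm}")
        field_p0 = embed_p0(p0.P0, grid, scale=scale)
    else:
        field_p0 = np.asarray(p0, dtype=np.float64)
        if field_p0.shape != grid.shape:
            field_p0 = embed_p0(field_p0, grid)
    solver = KSpaceSolver(grid, c)
    solver.set_initial_pressure(field_p0)
    cells = det.to_cells(grid)
    idx, w = _interp_weights(cells, grid.shape)
    data = np.empty((det.n_detectors, grid.n_steps))
    p = solver.pressure
    data[:, 0] = (p.ravel()[idx] * w).sum(axis=1)
    for n in range(1, grid.n_steps):
        solver.step()
        p = solver.pressure
        data[:, n] = (p.ravel()[idx] * w).sum(axis=1)
    return Sinogram(data, grid.dt, c, det, meta={"grid_shape": tuple(grid.shape),
                                                 "spacing_mm": grid.spacing_mm})


# ---------------------------------------------------------------------------
# detection chain
# ---------------------------------------------------------------------------

def apply_bandwidth(s: Sinogram, center_freq: float | None = None,
                    frac_bw: float | None = None) -> Sinogram:
    """Apply the transducer's Gaussian amplitude response (zero phase).

    The Gaussian is centred at ``center_freq`` with a -6 dB full width of
    ``frac_bw * center_freq``; the DC bin is zeroed (AC-coupled detector).
    """
    f0 = s.detectors.center_freq if center_freq is None else center_freq
    bw = s.detectors.frac_bandwidth if frac_bw is None else frac_bw
    nyquist = 0.5 / s.dt
    if f0 >= nyquist:
        raise ConfigurationError(f"center frequency {f0:.3g} Hz >= Nyquist {nyquist:.3g} Hz")
    n_t = s.data.shape[1]
    freqs = np.fft.rfftfreq(n_t, s.dt)
    sigma = bw * f0 / (2 * np.sqrt(2 * np.log(2)))
    response = np.exp(-((freqs - f0) ** 2) / (2 * sigma ** 2))
    response[0] = 0.0
    spec = np.fft.rfft(s.data, axis=1) * response
    out = np.fft.irfft(spec, n=n_t, axis=1)
    return replace(s, data=out, bandlimited=True)


def add_noise(s: Sinogram, snr_db: float, seed: int = 0) -> Sinogram:
    """Add white Gaussian noise at a prescribed sinogram-global SNR (dB).

    Signal power is the mean square over the whole sinogram; ``snr_db`` of
    +inf returns the input unchanged.
    """
    if np.isinf(snr_db):
        return s
    power = float(np.mean(s.data ** 2))
    if power == 0:
        raise DegenerateInputError("cannot set an SNR on an all-zero sinogram")
    noise_var = power / 10 ** (snr_db / 10)
    rng = np.random.default_rng([int(seed), 404])
    noisy = s.data + rng.normal(0.0, np.sqrt(noise_var), size=s.data.shape)
    return replace(s, data=noisy, noise_snr_db=float(snr_db))


# ---------------------------------------------------------------------------
# acquisition presets
# ---------------------------------------------------------------------------

@dataclass
class AcquisitionPreset:
    """A forward/reconstruction grid pair with its detector geometry.

    The forward grid is twice as fine as the reconstruction grid so the
    inverse problem never sees data generated on its own discretization.
    """

    name: str
    forward_grid: AcousticGrid
    recon_grid: AcousticGrid
    detectors: DetectorArray
    c: float = DEFAULT_SOUND_SPEED
    phantom_shape: tuple = (64, 64)
    phantom_spacing_mm: float = 0.2


def desk2d_preset() -> AcquisitionPreset:
    """Scaled-down 2-D acquisition that runs in seconds on one CPU.

    64x64 phantom at 0.2 mm circumscribed by a 9.6 mm ring of 64 detectors;
    forward grid 224x224 at 0.1 mm, reconstruction grid 128x128 at 0.2 mm.
    """
    return AcquisitionPreset(
        name="desk2d",
        forward_grid=AcousticGrid((224, 224), 0.1, 30e-9, 448, pml_width=8),
        recon_grid=AcousticGrid((128, 128), 0.2, 30e-9, 448, pml_width=8),
        detectors=circular_array(9.6, 64),
        phantom_shape=(64, 64),
        phantom_spacing_mm=0.2,
    )


def default2d_preset() -> AcquisitionPreset:
    """Mid-size 2-D test acquisition (200x200 forward grid, 64 detectors)."""
    return AcquisitionPreset(
        name="default2d",
        forward_grid=AcousticGrid((200, 200), 0.2, 40e-9, 512, pml_width=10),
        recon_grid=AcousticGrid((100, 100), 0.4, 40e-9, 512, pml_width=5),
        detectors=circular_array(14.4, 64),
        phantom_shape=(48, 48),
        phantom_spacing_mm=0.4,
    )


def paper2d_preset() -> AcquisitionPreset:
    """Full-scale 2-D acquisition: 801x801 at 0.05 mm forward grid, 256
    detectors on a 19 mm ring, dt 50 ns, 2048 steps, 20-cell PML."""
    return AcquisitionPreset(
        name="paper2d",
        forward_grid=AcousticGrid((801, 801), 0.05, 50e-9, 2048, pml_width=20),
        recon_grid=AcousticGrid((401, 401), 0.1, 50e-9, 2048, pml_width=20),
        detectors=circular_array(19.0, 256),
        phantom_shape=(256, 256),
        phantom_spacing_mm=0.1,
    )


def paper3d_preset() -> AcquisitionPreset:
    """Full-scale 3-D acquisition: 131^3 at 0.19 mm, 64x64-element planar
    array, dt 50 ns, 2391 steps, 20-cell PML."""
    grid = AcousticGrid((131, 131, 131), 0.19, 50e-9, 2391, pml_width=20)
    # plane just inside the PML on the first axis
    offset = -(131 / 2 - 22) * 0.19
    det = planar_array(extent_mm=131 * 0.19 * 0.6, n_per_side=64, offset_mm=offset)
    return AcquisitionPreset(
        name="paper3d",
        forward_grid=grid,
        recon_grid=AcousticGrid((66, 66, 66), 0.38, 50e-9, 2391, pml_width=10),
        detectors=det,
        phantom_shape=(64, 64, 64),
        phantom_spacing_mm=0.38,
    )


PRESETS = {
    "desk2d": desk2d_preset,
    "default2d": default2d_preset,
    "paper2d": paper2d_preset,
    "paper3d": paper3d_preset,
}


def get_preset(name: str) -> AcquisitionPreset:
    try:
        return PRESETS[name]()
    except KeyError:
        raise ConfigurationError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
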