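"""Image reconstruction from sinograms.

Two estimators of the initial pressure are provided:

* time reversal: the k-space propagator is run backwards in time on the
  (coarser) reconstruction grid, the recorded pressures being imposed as
  Dirichlet values at the detector cells at every reversed step; the field
  after the final step is the P0 estimate.

* delay-and-sum backprojection in the universal-backprojection style: each
  pixel accumulates, over detectors, the filtered trace value
  ``q(t) = p(t) - t dp/dt`` at its time of flight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .acoustic import AcousticGrid, DetectorArray, KSpaceSolver, Sinogram
from .errors import ConfigurationError


@dataclass
class ReconImage:
    """Estimated initial pressure on the reconstruction grid."""

    values: np.ndarray
    spacing_mm: float
    method: str
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.values.shape


def _nearest_detector_cells(det: DetectorArray, grid: AcousticGrid) -> tuple:
    cells = np.round(det.to_cells(grid)).astype(int)
    return tuple(cells[:, ax] for ax in range(cells.shape[1]))


def time_reversal(s: Sinogram, grid: AcousticGrid, det: DetectorArray,
                  crop: tuple | None = None) -> ReconImage:
    """Time-reversal reconstruction with Dirichlet enforcement at detectors.

    The propagator starts from a zero field and replays the recorded traces
    in reversed order, replacing the field value at each detector's nearest
    grid cell before every step.  ``crop`` optionally extracts a centred
    sub-image (the phantom region) from the reconstruction grid.
    """
    if abs(s.dt - grid.dt) > 1e-15:
        raise ConfigurationError(f"sinogram dt {s.dt} != reconstruction grid dt {grid.dt}")
    if s.data.shape[0] != det.n_detectors:
        raise ConfigurationError("sinogram detector count does not match the array")
    solver = KSpaceSolver(grid, s.c)
    solver.zero_state()
    cells = _nearest_detector_cells(det, grid)
    ndim = len(grid.shape)
    n_steps = s.data.shape[1]
    for n in range(n_steps - 1, -1, -1):
        value = s.data[:, n] / ndim
        for comp in solver.p_split:
            comp[cells] = value
        if n > 0:
            solver.step()
    img = solver.pressure
    if crop is not None:
        starts = [(g - c) // 2 for g, c in zip(grid.shape, crop)]
        img = img[tuple(slice(st, st + c) for st, c in zip(starts, crop))]
    return ReconImage(img, grid.spacing_mm, "time_reversal",
                      meta={"n_steps": n_steps, "c": s.c})


def backproject(s: Sinogram, grid: AcousticGrid, det: DetectorArray,
                c: float | None = None, crop: tuple | None = None) -> ReconImage:
    """Delay-and-sum backprojection (2-D).

    Each pixel accumulates ``p(t) - t dp/dt`` evaluated at its time of
    flight to every detector (linear interpolation in time).  Flight times
    beyond the recorded window contribute zero, with a warning.
    """
    c = s.c if c is None else c
    if len(grid.shape) != 2:
        raise ConfigurationError("backproject is implemented for 2-D grids")
    n_det, n_t = s.data.shape
    dt = s.dt
    t = np.arange(n_t) * dt
    dpdt = np.gradient(s.data, dt, axis=1)
    q = s.data - t[None, :] * dpdt

    det_cells = det.to_cells(grid)
    h, w = grid.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    img = np.zeros((h, w))
    dx_m = grid.dx_m
    truncated = False
    for d in range(n_det):
        dist = np.sqrt((yy - det_cells[d, 0]) ** 2 + (xx - det_cells[d, 1]) ** 2) * dx_m
        tau = dist / c / dt
        i0 = np.floor(tau).astype(int)
        frac = tau - i0
        valid = i0 < n_t - 1
        if not valid.all():
            truncated = True
        i0c = np.clip(i0, 0, n_t - 2)
        vals = (1 - frac) * q[d, i0c] + frac * q[d, i0c + 1]
        img += np.where(valid, vals, 0.0)
    if truncated:
        warnings.warn("some pixel flight times exceed the recorded window; "
                      "their contributions were zeroed", stacklevel=2)
    img /= n_det
    if crop is not None:
        starts = [(g - cc) // 2 for g, cc in zip(grid.shape, crop)]
        img = img[tuple(slice(st, st + cc) for st, cc in zip(starts, crop))]
    return ReconImage(img, grid.spacing_mm, "backprojection", meta={"c": c})
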