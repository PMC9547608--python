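"""Image-quality metrics: PSNR, SSIM, gCNR, CNR, NRMSE.

Conventions: PSNR uses a configurable maximum intensity (1.0 on normalized
images); SSIM defaults to the global single-window statistics form with
population variances (a sliding-window variant is available behind a flag);
gCNR builds both ROI histograms on shared bin edges spanning the pooled
value range; CNR uses population variances with the root-of-summed-variances
denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, ShapeError
from .models import nrmse_loss


@dataclass
class ROIPair:
    """Disjoint target and background masks on the image grid."""

    target_mask: np.ndarray
    background_mask: np.ndarray

    def __post_init__(self):
        self.target_mask = np.asarray(self.target_mask, dtype=bool)
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        if self.target_mask.shape != self.background_mask.shape:
            raise ShapeError("ROI masks must share a shape")
        if not self.target_mask.any() or not self.background_mask.any():
            raise DegenerateInputError("both ROIs must be nonempty")
        if (self.target_mask & self.background_mask).any():
            raise DegenerateInputError("ROIs must be disjoint")


@dataclass
class MetricsReport:
    psnr: float
    ssim: float
    nrmse: float
    gcnr: float | None = None
    cnr: float | None = None
    n_bins: int = 256
    meta: dict = field(default_factory=dict)


def psnr(ref: np.ndarray, est: np.ndarray, max_i: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 20 log10(max_i / sqrt(MSE)), in dB."""
    ref = np.asarray(ref, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    if ref.shape != est.shape:
        raise ShapeError(f"shapes {ref.shape} and {est.shape} differ")
    mse = float(np.mean((ref - est) ** 2))
    if mse == 0:
        return np.inf
    return float(20.0 * np.log10(max_i / np.sqrt(mse)))


def ssim(ref: np.ndarray, est: np.ndarray, k1: float = 0.01, k2: float = 0.03,
         L: float = 1.0, sliding: bool = False) -> float:
    """Structural similarity.

    Default: the global formula evaluated once with whole-image means,
    population variances and covariance.  ``sliding=True`` switches to the
    conventional 11x11 Gaussian-window average.
    """
    ref = np.asarray(ref, dtype=np.float64)
    est = np.asarray(est, dtype=np.float64)
    if ref.shape != est.shape:
        raise ShapeError(f"shapes {ref.shape} and {est.shape} differ")
    if ref.size == 0:
        raise DegenerateInputError("empty image")
    if sliding:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(
            ref, est, data_range=L, gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, K1=k1, K2=k2))
    c1 = (k1 * L) ** 2
    c2 = (k2 * L) ** 2
    mu_r, mu_e = ref.mean(), est.mean()
    var_r, var_e = ref.var(), est.var()
    cov = ((ref - mu_r) * (est - mu_e)).mean()
    return float(((2 * mu_r * mu_e + c1) * (2 * cov + c2))
                 / ((mu_r ** 2 + mu_e ** 2 + c1) * (var_r + var_e + c2)))


def gcnr(img: np.ndarray, rois: ROIPair, n_bins: int = 256) -> float:
    """Generalized contrast-to-noise ratio, 1 - histogram overlap in [0, 1].

    Normalized histograms of the two ROIs are built on ``n_bins`` shared
    bins spanning the pooled min-max range of both ROIs.
    """
    if n_bins < 2:
        raise DegenerateInputError("n_bins must be >= 2")
    img = np.asarray(img, dtype=np.float64)
    ti = img[rois.target_mask]
    bo = img[rois.background_mask]
    lo = min(ti.min(), bo.min())
    hi = max(ti.max(), bo.max())
    if hi == lo:
        raise DegenerateInputError("both ROIs constant; histogram range is empty")
    edges = np.linspace(lo, hi, n_bins + 1)
    hi_hist = np.histogram(ti, bins=edges)[0] / ti.size
    ho_hist = np.histogram(bo, bins=edges)[0] / bo.size
    ovl = float(np.minimum(hi_hist, ho_hist).sum())
    return 1.0 - ovl


def cnr(img: np.ndarray, rois: ROIPair) -> float:
    """Contrast-to-noise ratio |mu_t - mu_b| / sqrt(var_t + var_b)."""
    img = np.asarray(img, dtype=np.float64)
    t = img[rois.target_mask]
    b = img[rois.background_mask]
    num = abs(t.mean() - b.mean())
    denom = np.sqrt(t.var() + b.var())
    if denom == 0:
        return np.inf if num > 0 else 0.0
    return float(num / denom)


def nrmse(ref: np.ndarray, est: np.ndarray) -> float:
    """Root-mean-square error normalized by the reference RMS."""
    return nrmse_loss(ref, est)


def deep_region_rois(shape, margin: float = 0.1, box: float = 0.25) -> ROIPair:
    """Default ROI boxes for vessel phantoms: a deep-region target box and a
    background box near the illuminated (top) edge corner."""
    h, w = shape
    bh, bw = int(box * h), int(box * w)
    target = np.zeros(shape, dtype=bool)
    background = np.zeros(shape, dtype=bool)
    m = int(margin * h)
    target[h - m - bh:h - m, (w - bw) // 2:(w + bw) // 2] = True
    background[m:m + bh, m:m + bw] = True
    background &= ~target
    return ROIPair(target, background)


def evaluate_pair(ref: np.ndarray, est: np.ndarray, rois: ROIPair | None = None,
                  max_i: float = 1.0, L: float = 1.0,
                  n_bins: int = 256, sliding_ssim: bool = False) -> MetricsReport:
    """All metrics of an estimate against a reference in one report."""
    report = MetricsReport(
        psnr=psnr(ref, est, max_i=max_i),
        ssim=ssim(ref, est, L=L, sliding=sliding_ssim),
        nrmse=nrmse(ref, est),
        n_bins=n_bins,
        meta={"ssim_mode": "sliding" if sliding_ssim else "global"},
    )
    if rois is not None:
        report.gcnr = gcnr(est, rois, n_bins=n_bins)
        report.cnr = cnr(est, rois)
    return report
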