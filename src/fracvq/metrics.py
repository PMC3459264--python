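"""Quality metrics: MSE, PSNR, NCC, and single-window (global) SSIM.

The partition optimizer scores candidate quadtree layouts with the global
SSIM form — one mean, variance, and covariance over the whole image:

    SSIM(x, y) = (2 u_x u_y + C1)(2 cov_xy + C2)
                 / ((u_x^2 + u_y^2 + C1)(var_x + var_y + C2))

with C1 = (0.01 * peak)^2 and C2 = (0.03 * peak)^2.  A windowed mean-SSIM
variant is exposed for evaluation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _skimage_ssim

from .exceptions import DegenerateInputError, SizeError

__all__ = ["QualityReport", "mse", "psnr", "ncc", "ssim_global", "ssim_windowed", "quality_report"]


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise SizeError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise SizeError("empty images")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, peak: int = 255) -> float:
    e = mse(x, y)
    if e == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / e)


def ncc(x: np.ndarray, y: np.ndarray) -> float:
    """Normalized cross-correlation over raw intensities (not mean-removed)."""
    x, y = _check_pair(x, y)
    ex = float(np.sum(x * x))
    ey = float(np.sum(y * y))
    if ex == 0 or ey == 0:
        raise DegenerateInputError("ncc undefined for a zero-energy operand")
    return float(np.sum(x * y) / math.sqrt(ex * ey))


def ssim_global(x: np.ndarray, y: np.ndarray, peak: int = 255) -> float:
    x, y = _check_pair(x, y)
    c1 = (0.01 * peak) ** 2
    c2 = (0.03 * peak) ** 2
    ux = float(x.mean())
    uy = float(y.mean())
    vx = float(x.var())
    vy = float(y.var())
    cov = float(((x - ux) * (y - uy)).mean())
    return ((2 * ux * uy + c1) * (2 * cov + c2)) / ((ux * ux + uy * uy + c1) * (vx + vy + c2))


def ssim_windowed(x: np.ndarray, y: np.ndarray, peak: int = 255) -> float:
    """Mean local SSIM (7x7 sliding windows); evaluation convenience only."""
    x, y = _check_pair(x, y)
    return float(_skimage_ssim(x, y, data_range=peak))


@dataclass
class QualityReport:
    mse: float
    psnr: float
    ncc: float
    ssim: float
    peak: int


def quality_report(x: np.ndarray, y: np.ndarray, peak: int = 255, windowed: bool = False) -> QualityReport:
    e = mse(x, y)
    p = psnr(x, y, peak)
    if e > 0:
        assert abs(p - 10.0 * math.log10(peak * peak / e)) < 1e-9
    s = ssim_windowed(x, y, peak) if windowed else ssim_global(x, y, peak)
    return QualityReport(mse=e, psnr=p, ncc=ncc(x, y), ssim=s, peak=peak)
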