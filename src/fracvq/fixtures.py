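"""Synthetic CT-like phantoms and fractal test surfaces.

The codec is evaluated on grayscale tomography-style images that mix three
kinds of local structure: smooth organ-scale regions, sharp anatomical
boundaries, and rough texture.  ``make_phantom`` composes exactly that triad
deterministically from a seed, so every pipeline stage can be exercised
without any external image data.  ``make_fbm_surface`` synthesizes fractional
Brownian motion surfaces with a known theoretical fractal dimension
``3 - H``, which is what validates the blanket-method estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ConfigurationError

__all__ = ["PhantomSpec", "make_phantom", "make_fbm_surface"]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic CT-like phantom.

    size
        Pixels per side; must be >= 64 and divisible by 4.
    bit_depth
        8, 12 or 16 bits per pixel.
    n_ellipses
        Number of smooth elliptical "organs" with sharp anti-aliased rims.
        With ``n_ellipses == 0`` the scene is empty and the background is a
        flat field (no gradient).
    texture_hurst
        Hurst exponent of the fBm texture patch in (0, 1); ``None`` disables
        the texture region.
    noise_sigma
        Standard deviation of additive Gaussian pixel noise, in gray levels
        of the target bit depth.
    seed
        Seed for all randomness; a fixed seed gives bit-identical output.
    """

    size: int = 512
    bit_depth: int = 8
    n_ellipses: int = 4
    texture_hurst: float | None = 0.4
    noise_sigma: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.size < 64 or self.size % 4 != 0:
            raise ConfigurationError(
                f"phantom size must be >= 64 and divisible by 4, got {self.size}"
            )
        if self.bit_depth not in (8, 12, 16):
            raise ConfigurationError(f"unsupported bit depth {self.bit_depth}")
        if self.n_ellipses < 0:
            raise ConfigurationError("n_ellipses must be non-negative")
        if self.texture_hurst is not None and not 0.0 < self.texture_hurst < 1.0:
            raise ConfigurationError(
                f"texture_hurst must lie in (0, 1), got {self.texture_hurst}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")


def make_fbm_surface(hurst: float, size: int, seed: int, oversample: int = 2) -> np.ndarray:
    """Zero-mean fractional Brownian motion surface by spectral synthesis.

    Complex Gaussian white noise is shaped with a power-law amplitude
    ``|f|^-(H+1)`` (power spectrum exponent ``2H + 2``), which yields a
    self-affine surface of theoretical fractal dimension ``3 - H``.  The field
    is synthesized on an ``oversample``-times finer grid and decimated, so the
    returned lattice carries the aliased high-frequency power a point-sampled
    fBm surface would have; without this, small-lag increments are too smooth
    at low H.  The DC component is zeroed, so the mean is ~0 up to round-off.
    """
    if not 0.0 < hurst < 1.0:
        raise ConfigurationError(f"hurst must lie in (0, 1), got {hurst}")
    if size < 4:
        raise ConfigurationError("surface size must be >= 4")
    if oversample < 1:
        raise ConfigurationError("oversample must be >= 1")
    n = size * oversample
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(n)
    f = np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-(hurst + 1.0))
    noise = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
    surface = np.fft.ifft2(amp * noise).real[::oversample, ::oversample]
    return surface - surface.mean()


def _ellipse_indicator(
    yy: np.ndarray,
    xx: np.ndarray,
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
    n: int,
) -> np.ndarray:
    """Anti-aliased ellipse membership in [0, 1] with a ~1-pixel soft rim."""
    cy, cx = center
    a, b = axes
    dy = yy - cy
    dx = xx - cx
    xr = np.cos(angle) * dx + np.sin(angle) * dy
    yr = -np.sin(angle) * dx + np.cos(angle) * dy
    s = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    # transition width ~1 pixel in image units
    return np.clip((1.0 - s) * (min(a, b) * n), 0.0, 1.0)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render a deterministic CT-like phantom per `spec`.

    The scene is composed in normalized units: a Gaussian-smoothed background
    gradient, anti-aliased ellipses of random contrast, an fBm texture patch
    masked to a fixed disc, then an affine stretch so the image spans ~92% of
    the dynamic range, plus optional clipped Gaussian noise.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    maxv = float(2**spec.bit_depth - 1)
    yy, xx = np.mgrid[0:n, 0:n] / float(n)

    field = np.full((n, n), 0.4)
    if spec.n_ellipses > 0:
        bg = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 6.0)
        sd = bg.std()
        if sd > 0:
            field = field + 0.08 * (bg - bg.mean()) / sd
        for _ in range(spec.n_ellipses):
            center = (rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8))
            axes = (rng.uniform(0.08, 0.3), rng.uniform(0.08, 0.3))
            angle = rng.uniform(0.0, np.pi)
            amp = rng.uniform(0.2, 0.5) * rng.choice([-1.0, 1.0])
            field = field + amp * _ellipse_indicator(yy, xx, center, axes, angle, n)

    if spec.texture_hurst is not None:
        tex = make_fbm_surface(spec.texture_hurst, n, spec.seed + 10007)
        sd = tex.std()
        if sd > 0:
            tex = tex / sd
        mask = _ellipse_indicator(yy, xx, (0.65, 0.35), (0.18, 0.18), 0.0, n)
        field = field + 0.08 * tex * mask

    lo, hi = float(field.min()), float(field.max())
    if hi - lo < 1e-12:
        img = np.full((n, n), field[0, 0] * maxv)
    else:
        img = 0.04 * maxv + (field - lo) * (0.92 * maxv / (hi - lo))

    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=(n, n))

    img = np.clip(np.rint(img), 0, maxv)
    return img.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)
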