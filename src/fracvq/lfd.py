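"""Blanket-method fractal dimension and local-FD maps of wavelet bands.

A coefficient band is read as a terrain surface whose height is proportional
to the coefficient magnitude.  The blanket estimator grows an upper surface
``u`` and lower surface ``b`` around it, one gray level per scale step:

    u_e(i,j) = max( u_{e-1}(i,j) + 1,  max over 4-neighbors of u_{e-1} )
    b_e(i,j) = min( b_{e-1}(i,j) - 1,  min over 4-neighbors of b_{e-1} )

with u_0 = b_0 = surface.  The blanket volume is v_e = sum(u_e - b_e) and the
surface area at scale e is A(e) = (v_e - v_{e-1}) / 2.  For a fractal surface
A(e) ~ F * e**(2 - D), so D = 2 - slope of the least-squares fit of log A(e)
on log e over e = 1..eps_max, clamped to [2, 3].  A flat surface gives
constant A and hence D = 2 exactly.

``lfd_map`` applies the estimator to every pixel's window (mirror-padded at
the borders, each window rescaled to the 8-bit range), producing the
complexity map that drives variable-block-size partitioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigurationError, SizeError

__all__ = ["LFDMap", "normalize_band", "blanket_fd", "lfd_map", "rescale_surface"]


@dataclass
class LFDMap:
    values: np.ndarray  # per-pixel fractal dimension in [2, 3]
    window: int
    eps_max: int


def normalize_band(band: np.ndarray) -> np.ndarray:
    """Affinely rescale |coefficients| to [0, 255]; constant bands map to 0."""
    band = np.asarray(band, dtype=np.float64)
    if band.size == 0:
        raise SizeError("band is empty")
    a = np.abs(band)
    mn = a.min()
    mx = a.max()
    if mx == mn:
        return np.zeros_like(a)
    return (a - mn) * (255.0 / (mx - mn))


def rescale_surface(surface: np.ndarray, peak: float = 255.0) -> np.ndarray:
    """Affine rescale of a signed surface to [0, peak] (no magnitude fold)."""
    surface = np.asarray(surface, dtype=np.float64)
    mn = surface.min()
    mx = surface.max()
    if mx == mn:
        return np.zeros_like(surface)
    return (surface - mn) * (peak / (mx - mn))


def _neighbor_max(a: np.ndarray) -> np.ndarray:
    pad = [(0, 0)] * (a.ndim - 2) + [(1, 1), (1, 1)]
    p = np.pad(a, pad, mode="constant", constant_values=-np.inf)
    return np.maximum(
        np.maximum(p[..., :-2, 1:-1], p[..., 2:, 1:-1]),
        np.maximum(p[..., 1:-1, :-2], p[..., 1:-1, 2:]),
    )


def _neighbor_min(a: np.ndarray) -> np.ndarray:
    pad = [(0, 0)] * (a.ndim - 2) + [(1, 1), (1, 1)]
    p = np.pad(a, pad, mode="constant", constant_values=np.inf)
    return np.minimum(
        np.minimum(p[..., :-2, 1:-1], p[..., 2:, 1:-1]),
        np.minimum(p[..., 1:-1, :-2], p[..., 1:-1, 2:]),
    )


def blanket_areas(surface: np.ndarray, eps_max: int) -> np.ndarray:
    """Blanket surface areas A(1..eps_max); last axis indexes the scale.

    Accepts a single surface ``(h, w)`` or a stack ``(..., h, w)``.
    """
    u = np.asarray(surface, dtype=np.float64).copy()
    b = u.copy()
    v_prev = np.zeros(u.shape[:-2])
    areas = []
    for _ in range(eps_max):
        u = np.maximum(u + 1.0, _neighbor_max(u))
        b = np.minimum(b - 1.0, _neighbor_min(b))
        v = (u - b).sum(axis=(-2, -1))
        areas.append((v - v_prev) / 2.0)
        v_prev = v
    return np.stack(areas, axis=-1)


def _fit_dimension(areas: np.ndarray) -> np.ndarray:
    """D = 2 - slope of log A(e) on log e; clamped to [2, 3]."""
    eps_max = areas.shape[-1]
    x = np.log(np.arange(1, eps_max + 1, dtype=np.float64))
    y = np.log(areas)
    xc = x - x.mean()
    slope = (y * xc).sum(axis=-1) / (xc * xc).sum()
    d = 2.0 - slope
    d = np.where(np.isfinite(d), d, 2.0)
    return np.clip(d, 2.0, 3.0)


def blanket_fd(surface: np.ndarray, eps_max: int = 5) -> float:
    """Fractal dimension of one surface by the blanket method."""
    surface = np.asarray(surface, dtype=np.float64)
    if surface.ndim != 2 or surface.shape[0] < 2 or surface.shape[1] < 2:
        raise SizeError("surface must be at least 2x2")
    if eps_max < 2:
        raise ConfigurationError("eps_max must be >= 2 (the log-log fit needs >= 2 points)")
    areas = blanket_areas(surface, eps_max)
    return float(_fit_dimension(areas))


def lfd_map(band: np.ndarray, window: int = 5, eps_max: int = 5) -> LFDMap:
    """Per-pixel blanket FD over mirror-padded windows of a band.

    Each window is normalized like ``normalize_band`` (magnitude, affine to
    [0, 255]; constant windows to zero) before estimation, so the map reflects
    local roughness shape rather than local amplitude.
    """
    band = np.asarray(band, dtype=np.float64)
    if window < 3 or window % 2 == 0:
        raise ConfigurationError(f"window must be an odd integer >= 3, got {window}")
    if eps_max < 2:
        raise ConfigurationError("eps_max must be >= 2")
    if band.ndim != 2 or band.shape[0] < window or band.shape[1] < window:
        raise SizeError(f"band must be at least {window}x{window}")
    h, w = band.shape
    half = window // 2
    padded = np.pad(band, half, mode="reflect")
    wins = sliding_window_view(padded, (window, window)).reshape(h * w, window, window)
    a = np.abs(wins)
    mn = a.min(axis=(-2, -1), keepdims=True)
    mx = a.max(axis=(-2, -1), keepdims=True)
    scale = np.where(mx > mn, 255.0 / np.maximum(mx - mn, 1e-300), 0.0)
    norm = (a - mn) * scale
    areas = blanket_areas(norm, eps_max)
    values = _fit_dimension(areas).reshape(h, w)
    return LFDMap(values=values, window=window, eps_max=eps_max)
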