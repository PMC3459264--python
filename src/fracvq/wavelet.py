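"""Two-level separable DWT and subband bookkeeping.

Uses periodized boundaries so that, for sides divisible by ``2**levels``,
every band shape is an exact power-of-two fraction of the input and the LL
band holds exactly ``4**-levels`` of the coefficients — the fraction the
compression-ratio accounting relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .exceptions import ContainerError, SizeError

__all__ = ["DetailBand", "SubbandSet", "forward_dwt2", "inverse_dwt2", "pad_to_multiple"]

ORIENTATIONS = ("HL", "LH", "HH")  # pywt (cH, cV, cD) order


@dataclass
class DetailBand:
    level: int  # 1 = finest
    orientation: str  # "HL" | "LH" | "HH"
    coeffs: np.ndarray


@dataclass
class SubbandSet:
    ll: np.ndarray
    details: list[DetailBand]
    levels: int
    basis_name: str
    original_size: tuple[int, int]
    boundary_mode: str = "periodization"
    bit_depth: int = 8
    _extra: dict = field(default_factory=dict, repr=False)

    def band(self, level: int, orientation: str) -> np.ndarray:
        for d in self.details:
            if d.level == level and d.orientation == orientation:
                return d.coeffs
        raise KeyError((level, orientation))


def pad_to_multiple(image: np.ndarray, multiple: int) -> np.ndarray:
    """Edge-replicate the bottom/right so both sides divide `multiple`."""
    rows, cols = image.shape
    pr = (-rows) % multiple
    pc = (-cols) % multiple
    if pr == 0 and pc == 0:
        return image
    return np.pad(image, ((0, pr), (0, pc)), mode="edge")


def forward_dwt2(
    image: np.ndarray,
    levels: int = 2,
    basis: str = "bior4.4",
    bit_depth: int | None = None,
) -> SubbandSet:
    """Decompose a grayscale image into LL + 3*levels oriented detail bands."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise SizeError("expected a 2-D grayscale image")
    if levels < 1:
        raise SizeError("levels must be >= 1")
    rows, cols = image.shape
    m = 2**levels
    if rows % m or cols % m:
        raise SizeError(
            f"image sides must be divisible by {m}; pad {rows}x{cols} to "
            f"{rows + (-rows) % m}x{cols + (-cols) % m} first (pad_to_multiple)"
        )
    if bit_depth is None:
        bit_depth = 16 if image.dtype.itemsize > 1 else 8
    coeffs = pywt.wavedec2(image.astype(np.float64), basis, mode="periodization", level=levels)
    details: list[DetailBand] = []
    for i, triple in enumerate(coeffs[1:]):
        level = levels - i  # wavedec2 lists coarsest first
        for orient, band in zip(ORIENTATIONS, triple):
            details.append(DetailBand(level, orient, np.asarray(band)))
    return SubbandSet(
        ll=np.asarray(coeffs[0]),
        details=details,
        levels=levels,
        basis_name=basis,
        original_size=(rows, cols),
        bit_depth=bit_depth,
    )


def _reconstruct(bands: SubbandSet) -> np.ndarray:
    """Inverse transform to a real-valued image (no rounding/clipping)."""
    by_level: dict[int, dict[str, np.ndarray]] = {}
    for d in bands.details:
        by_level.setdefault(d.level, {})[d.orientation] = d.coeffs
    if sorted(by_level) != list(range(1, bands.levels + 1)):
        raise ContainerError("detail bands do not cover levels 1..L")
    coeffs: list = [bands.ll]
    for level in range(bands.levels, 0, -1):
        triple = by_level[level]
        if set(triple) != set(ORIENTATIONS):
            raise ContainerError(f"level {level} is missing an orientation band")
        shapes = {triple[o].shape for o in ORIENTATIONS}
        if len(shapes) != 1:
            raise ContainerError(f"level {level} bands have mismatched shapes")
        coeffs.append(tuple(triple[o] for o in ORIENTATIONS))
    try:
        rec = pywt.waverec2(coeffs, bands.basis_name, mode=bands.boundary_mode)
    except ValueError as exc:
        raise ContainerError(f"inconsistent subband shapes: {exc}") from exc
    rows, cols = bands.original_size
    if rec.shape[0] < rows or rec.shape[1] < cols:
        raise ContainerError("reconstruction smaller than recorded original size")
    return rec[:rows, :cols]


def inverse_dwt2(bands: SubbandSet) -> np.ndarray:
    """Reconstruct, crop to the recorded size, and quantize to the bit depth."""
    rec = _reconstruct(bands)
    maxv = 2**bands.bit_depth - 1
    out = np.clip(np.rint(rec), 0, maxv)
    return out.astype(np.uint8 if bands.bit_depth == 8 else np.uint16)
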