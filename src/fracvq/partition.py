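"""Complexity-driven variable-block-size partitioning of a band.

The local-FD map is reduced to three classes (0 = smoothest) by multilevel
discriminant (Otsu) thresholding, then tiled by a quadtree whose root grid
may be shifted: for an initial block size ``l0`` there are ``2*l0 - 1``
candidate shift positions (row shifts with column 0, then column shifts with
row 0).  Before splitting, the class map is edge-replicated so the shifted
grid covers it exactly (a row shift of k pads k rows on top and ``l0 - k``
below, likewise for columns).  An ``l0 x l0`` cell stays whole iff every
contained label is 0; otherwise it splits into four, and a quarter cell stays
whole iff every label is <= 1, else it splits into four smallest leaves.

Each candidate shift i is scored by

    SUM_i = N_i + 1e5 * SSIM_i

where N_i counts smallest-size leaves and SSIM_i is the global SSIM between
the class map and the "division image" implied by the leaf sizes (both mapped
to gray levels {0, 128, 255}).  The argmax shift (first on ties) wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .bitio import BitReader, BitWriter
from .exceptions import ConfigurationError, ContainerError, DegenerateInputError
from .metrics import ssim_global

__all__ = [
    "ClassMap",
    "Partition",
    "discriminant_thresholds",
    "classify",
    "quadtree_divide",
    "division_image",
    "select_initial_position",
    "partition_bits",
    "partition_from_bits",
]


@dataclass
class ClassMap:
    labels: np.ndarray  # int grid, values in {0..C-1}, 0 = smoothest
    thresholds: np.ndarray  # ascending, length C-1


@dataclass
class Partition:
    offset: tuple[int, int]  # (row_shift, col_shift) of the root grid
    extended_size: tuple[int, int]
    blocks: list[tuple[int, int, int]]  # (row, col, size) in extended coords
    l0: int
    source_shape: tuple[int, int]


def discriminant_thresholds(values: np.ndarray, n_classes: int = 3, bins: int = 64) -> np.ndarray:
    """Multilevel Otsu thresholds by exhaustive search over histogram bins.

    Maximizes the between-class variance of the binned value distribution
    over all combinations of ``n_classes - 1`` bin boundaries; thresholds are
    returned ascending, each the upper edge of the last bin of its class.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise DegenerateInputError("no values to threshold")
    if n_classes < 2:
        raise ConfigurationError("n_classes must be >= 2")
    vmin = float(values.min())
    vmax = float(values.max())
    if vmax == vmin:
        raise DegenerateInputError("all values identical; thresholding is degenerate")
    hist, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    p = hist / hist.sum()
    w_cum = np.concatenate([[0.0], np.cumsum(p)])
    m_cum = np.concatenate([[0.0], np.cumsum(p * centers)])
    mu = m_cum[-1]

    best = -1.0
    best_combo: tuple[int, ...] | None = None
    for combo in itertools.combinations(range(bins - 1), n_classes - 1):
        bounds = (-1,) + combo + (bins - 1,)
        var_b = 0.0
        ok = True
        for c in range(n_classes):
            lo, hi = bounds[c] + 1, bounds[c + 1] + 1
            w = w_cum[hi] - w_cum[lo]
            if w <= 0.0:
                ok = False
                break
            m = m_cum[hi] - m_cum[lo]
            var_b += (m - w * mu) ** 2 / w
        if ok and var_b > best:
            best = var_b
            best_combo = combo
    if best_combo is None:
        raise DegenerateInputError("no threshold combination yields populated classes")
    return np.array([edges[i + 1] for i in best_combo])


def classify(lfd_values: np.ndarray, thresholds: np.ndarray) -> ClassMap:
    """Per-pixel class by threshold interval; values at a threshold go low."""
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if thresholds.size and np.any(np.diff(thresholds) < 0):
        raise ConfigurationError("thresholds must be ascending")
    values = np.asarray(lfd_values, dtype=np.float64)
    labels = np.searchsorted(thresholds, values, side="left").astype(np.int8)
    return ClassMap(labels=labels, thresholds=thresholds)


def _extend_labels(labels: np.ndarray, offset: tuple[int, int], l0: int) -> np.ndarray:
    kr, kc = offset
    rows, cols = labels.shape
    pad_r = (-(rows + kr)) % l0
    pad_c = (-(cols + kc)) % l0
    return np.pad(labels, ((kr, pad_r), (kc, pad_c)), mode="edge")


def _check_offset(offset: tuple[int, int], l0: int) -> None:
    if l0 < 4 or l0 & (l0 - 1):
        raise ConfigurationError(f"l0 must be a power of two >= 4, got {l0}")
    kr, kc = offset
    if not (0 <= kr < l0 and 0 <= kc < l0):
        raise ConfigurationError(f"offset {offset} out of range [0, {l0})")


def _cell_maxima(ext: np.ndarray, l0: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-quarter-cell and per-root-cell label maxima of an extended map."""
    r, c = ext.shape
    q = l0 // 2
    m4 = ext.reshape(r // q, q, c // q, q).max(axis=(1, 3))
    m8 = m4.reshape(r // l0, 2, c // l0, 2).max(axis=(1, 3))
    return m4, m8


def quadtree_divide(classes: ClassMap | np.ndarray, offset: tuple[int, int] = (0, 0), l0: int = 8) -> Partition:
    """Tile the (edge-replicated) class map into l0 / l0/2 / l0/4 blocks."""
    labels = classes.labels if isinstance(classes, ClassMap) else np.asarray(classes)
    _check_offset(offset, l0)
    ext = _extend_labels(labels, offset, l0)
    m4, m8 = _cell_maxima(ext, l0)
    q = l0 // 2
    e = l0 // 4
    blocks: list[tuple[int, int, int]] = []
    for i in range(m8.shape[0]):
        for j in range(m8.shape[1]):
            if m8[i, j] == 0:
                blocks.append((i * l0, j * l0, l0))
                continue
            for di in (0, 1):
                for dj in (0, 1):
                    qi, qj = 2 * i + di, 2 * j + dj
                    if m4[qi, qj] <= 1:
                        blocks.append((qi * q, qj * q, q))
                    else:
                        for si in (0, 1):
                            for sj in (0, 1):
                                blocks.append((qi * q + si * e, qj * q + sj * e, e))
    return Partition(
        offset=offset,
        extended_size=ext.shape,
        blocks=blocks,
        l0=l0,
        source_shape=labels.shape,
    )


def division_image(p: Partition) -> np.ndarray:
    """Label grid implied by leaf sizes (l0->0, l0/2->1, l0/4->2), cropped."""
    size_label = {p.l0: 0, p.l0 // 2: 1, p.l0 // 4: 2}
    canvas = np.empty(p.extended_size, dtype=np.int8)
    for r, c, s in p.blocks:
        canvas[r : r + s, c : c + s] = size_label[s]
    kr, kc = p.offset
    rows, cols = p.source_shape
    return canvas[kr : kr + rows, kc : kc + cols]


def _labels_to_gray(labels: np.ndarray) -> np.ndarray:
    return np.rint(np.asarray(labels, dtype=np.float64) * 127.5)


def select_initial_position(
    classes: ClassMap | np.ndarray, l0: int = 8
) -> tuple[tuple[int, int], Partition, list[float]]:
    """Pick the quadtree root shift maximizing SUM_i = N_i + 1e5 * SSIM_i.

    Candidates are row shifts 0..l0-1 at column 0, then column shifts
    1..l0-1 at row 0 (2*l0 - 1 total); ties keep the earliest candidate.
    """
    labels = classes.labels if isinstance(classes, ClassMap) else np.asarray(classes)
    if l0 < 4 or l0 & (l0 - 1):
        raise ConfigurationError(f"l0 must be a power of two >= 4, got {l0}")
    candidates = [(r, 0) for r in range(l0)] + [(0, c) for c in range(1, l0)]
    gray_ref = _labels_to_gray(labels)
    q = l0 // 2
    sums: list[float] = []
    best_score = -np.inf
    best_offset = candidates[0]
    for offset in candidates:
        ext = _extend_labels(labels, offset, l0)
        m4, m8 = _cell_maxima(ext, l0)
        n2 = 4 * int(np.count_nonzero(m4 >= 2))
        root_split = np.repeat(np.repeat(m8 > 0, 2, axis=0), 2, axis=1)
        qlab = np.where(root_split, np.where(m4 >= 2, 2, 1), 0)
        div_ext = np.repeat(np.repeat(qlab, q, axis=0), q, axis=1)
        kr, kc = offset
        div = div_ext[kr : kr + labels.shape[0], kc : kc + labels.shape[1]]
        score = n2 + 1e5 * ssim_global(gray_ref, _labels_to_gray(div), peak=255)
        sums.append(score)
        if score > best_score:
            best_score = score
            best_offset = offset
    return best_offset, quadtree_divide(labels, best_offset, l0), sums


def partition_bits(p: Partition) -> tuple[bytes, int]:
    """Depth-first split bitstring (1 = split, 0 = leaf), root cells in raster
    order; smallest leaves are implicit (no bit at maximum depth)."""
    writer = BitWriter()
    blocks = p.blocks
    pos = 0
    rows, cols = p.extended_size
    n_cells = (rows // p.l0) * (cols // p.l0)
    q = p.l0 // 2
    for _ in range(n_cells):
        if blocks[pos][2] == p.l0:
            writer.write_bit(0)
            pos += 1
            continue
        writer.write_bit(1)
        for _ in range(4):
            if blocks[pos][2] == q:
                writer.write_bit(0)
                pos += 1
            else:
                writer.write_bit(1)
                pos += 4
    if pos != len(blocks):
        raise ContainerError("partition blocks inconsistent with the cell grid")
    return writer.getvalue(), writer.bit_length


def partition_from_bits(
    data: bytes,
    bit_length: int,
    offset: tuple[int, int],
    source_shape: tuple[int, int],
    l0: int,
) -> Partition:
    """Rebuild a Partition from its serialized split bitstring."""
    _check_offset(offset, l0)
    kr, kc = offset
    rows = source_shape[0] + kr + ((-(source_shape[0] + kr)) % l0)
    cols = source_shape[1] + kc + ((-(source_shape[1] + kc)) % l0)
    reader = BitReader(data, bit_length)
    q = l0 // 2
    e = l0 // 4
    blocks: list[tuple[int, int, int]] = []
    for i in range(rows // l0):
        for j in range(cols // l0):
            if reader.read_bit() == 0:
                blocks.append((i * l0, j * l0, l0))
                continue
            for di in (0, 1):
                for dj in (0, 1):
                    qi, qj = 2 * i + di, 2 * j + dj
                    if reader.read_bit() == 0:
                        blocks.append((qi * q, qj * q, q))
                    else:
                        for si in (0, 1):
                            for sj in (0, 1):
                                blocks.append((qi * q + si * e, qj * q + sj * e, e))
    if reader.remaining:
        raise ContainerError("trailing bits after quadtree traversal")
    return Partition(
        offset=offset,
        extended_size=(rows, cols),
        blocks=blocks,
        l0=l0,
        source_shape=source_shape,
    )
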