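"""Vector quantization of band blocks with energy-ordered K-means seeding.

Blocks of one size from one band are flattened row-major into training
vectors.  The codebook is trained by Lloyd's algorithm (squared-Euclidean
nearest assignment, centroid update).  Initialization is either

* ``energy``: vectors are stably sorted by block energy (sum of squared
  entries) and the k seeds are taken at equal intervals along that order —
  seed j is the vector at sorted position floor((j + 0.5) * N / k).  This
  pathway is fully deterministic.
* ``random``: Forgy seeding — k distinct vectors drawn uniformly without
  replacement under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ContainerError, InfeasibleCodebookError, SizeError
from .partition import Partition

__all__ = [
    "BlockSet",
    "Codebook",
    "block_energy",
    "extract_blocks",
    "energy_init",
    "random_init",
    "kmeans_train",
    "vq_encode",
    "vq_decode",
]


@dataclass
class BlockSet:
    vectors: np.ndarray  # (N, size*size), row-major flattened blocks
    block_size: int
    origin: str = ""  # band identifier, bookkeeping only

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


@dataclass
class Codebook:
    block_size: int
    codewords: np.ndarray  # (K, size*size)
    init_mode: str = "energy"
    iterations: int = 0
    final_distortion: float = 0.0
    distortion_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.codewords.shape[0]


def block_energy(v: np.ndarray) -> float:
    """Energy of one flattened block: the sum of squared entries."""
    v = np.asarray(v, dtype=np.float64)
    if v.size == 0:
        raise SizeError("empty block")
    return float(np.sum(v * v))


def extract_blocks(band_ext: np.ndarray, p: Partition) -> dict[int, BlockSet]:
    """Gather the partition's blocks from the extended band, grouped by size.

    Within each size, vectors appear in partition (depth-first raster) order —
    the same order ``vq_decode`` consumes indices in.
    """
    if band_ext.shape != p.extended_size:
        raise SizeError(
            f"extended band shape {band_ext.shape} != partition {p.extended_size}"
        )
    grouped: dict[int, list[np.ndarray]] = {}
    for r, c, s in p.blocks:
        grouped.setdefault(s, []).append(band_ext[r : r + s, c : c + s].reshape(-1))
    return {
        s: BlockSet(vectors=np.array(vecs, dtype=np.float64), block_size=s)
        for s, vecs in grouped.items()
    }


def energy_init(blocks: BlockSet, k: int) -> np.ndarray:
    """Equal-interval picks along the energy-sorted block list (stable sort)."""
    n = blocks.n
    if k > n:
        raise InfeasibleCodebookError(f"k={k} exceeds the {n} available blocks")
    if k < 1:
        raise InfeasibleCodebookError("k must be >= 1")
    energies = np.einsum("ij,ij->i", blocks.vectors, blocks.vectors)
    order = np.argsort(energies, kind="stable")
    positions = ((2 * np.arange(k) + 1) * n) // (2 * k)  # floor((j+0.5)*N/k)
    return blocks.vectors[order[positions]].copy()


def random_init(blocks: BlockSet, k: int, seed: int) -> np.ndarray:
    """Forgy seeding: k distinct blocks, uniform without replacement."""
    n = blocks.n
    if k > n:
        raise InfeasibleCodebookError(f"k={k} exceeds the {n} available blocks")
    if k < 1:
        raise InfeasibleCodebookError("k must be >= 1")
    rng = np.random.default_rng(seed)
    sel = rng.choice(n, size=k, replace=False)
    return blocks.vectors[sel].copy()


def _nearest(vectors: np.ndarray, codewords: np.ndarray, chunk: int = 8192) -> tuple[np.ndarray, np.ndarray]:
    """Nearest codeword per vector (squared Euclidean, ties to lowest index)."""
    n = vectors.shape[0]
    c2 = np.einsum("ij,ij->i", codewords, codewords)
    idx = np.empty(n, dtype=np.int64)
    d2 = np.empty(n, dtype=np.float64)
    for s in range(0, n, chunk):
        x = vectors[s : s + chunk]
        d = x @ codewords.T
        d *= -2.0
        d += np.einsum("ij,ij->i", x, x)[:, None]
        d += c2[None, :]
        i = np.argmin(d, axis=1)
        idx[s : s + x.shape[0]] = i
        d2[s : s + x.shape[0]] = np.take_along_axis(d, i[:, None], axis=1)[:, 0]
    np.maximum(d2, 0.0, out=d2)
    return idx, d2


def kmeans_train(
    blocks: BlockSet,
    k: int,
    init: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-4,
    init_mode: str = "energy",
) -> Codebook:
    """Lloyd iterations until the relative distortion drop falls below tol.

    Distortion is the total squared distance of every vector to its codeword,
    recorded once per iteration after assignment; the sequence is
    non-increasing.  Empty clusters are reseeded with the assigned vector
    farthest from its codeword (preferring vectors whose cluster keeps at
    least one member), which can only lower distortion.
    """
    init = np.asarray(init, dtype=np.float64)
    if init.shape != (k, blocks.vectors.shape[1]):
        raise InfeasibleCodebookError(
            f"init shape {init.shape} != ({k}, {blocks.vectors.shape[1]})"
        )
    vectors = blocks.vectors
    cw = init.copy()
    history: list[float] = []
    prev = None
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        idx, d2 = _nearest(vectors, cw)
        counts = np.bincount(idx, minlength=k)
        empty = np.flatnonzero(counts == 0)
        if empty.size:
            order = np.argsort(d2)[::-1]
            ptr = 0
            for c in empty:
                while ptr < order.size and counts[idx[order[ptr]]] <= 1:
                    ptr += 1
                j = order[ptr] if ptr < order.size else order[0]
                ptr += 1
                counts[idx[j]] -= 1
                idx[j] = c
                counts[c] += 1
                cw[c] = vectors[j]
                d2[j] = 0.0
        dist = float(d2.sum())
        history.append(dist)
        if dist == 0.0 or (prev is not None and prev - dist <= tol * max(prev, 1e-300)):
            break
        prev = dist
        sums = np.zeros_like(cw)
        np.add.at(sums, idx, vectors)
        nz = counts > 0
        cw[nz] = sums[nz] / counts[nz, None]
    return Codebook(
        block_size=blocks.block_size,
        codewords=cw,
        init_mode=init_mode,
        iterations=iterations,
        final_distortion=history[-1],
        distortion_history=history,
    )


def vq_encode(blocks: BlockSet, cb: Codebook) -> np.ndarray:
    """Index of the nearest codeword per block (ties to the lowest index)."""
    if blocks.vectors.shape[1] != cb.codewords.shape[1]:
        raise ContainerError(
            f"block dimension {blocks.vectors.shape[1]} != codebook "
            f"dimension {cb.codewords.shape[1]}"
        )
    idx, _ = _nearest(blocks.vectors, cb.codewords)
    return idx


def vq_decode(
    indices,
    codebooks,
    p: Partition,
    band_shape: tuple[int, int],
) -> np.ndarray:
    """Write codewords back into block positions, then crop the extension.

    ``codebooks`` may be a single Codebook or a mapping ``size -> Codebook``;
    ``indices`` correspondingly a sequence or a mapping ``size -> sequence``.
    Blocks of sizes with no codebook decode to zero.
    """
    if isinstance(codebooks, Codebook):
        codebooks = {codebooks.block_size: codebooks}
        indices = {next(iter(codebooks)): indices}
    out = np.zeros(p.extended_size, dtype=np.float64)
    cursors = {s: 0 for s in codebooks}
    for r, c, s in p.blocks:
        if s not in codebooks:
            continue
        cb = codebooks[s]
        pos = cursors[s]
        seq = indices[s]
        if pos >= len(seq):
            raise ContainerError(f"too few indices for {s}x{s} blocks")
        i = int(seq[pos])
        cursors[s] = pos + 1
        if not 0 <= i < cb.k:
            raise ContainerError(f"codeword index {i} out of range for K={cb.k}")
        out[r : r + s, c : c + s] = cb.codewords[i].reshape(s, s)
    for s, pos in cursors.items():
        if pos != len(indices[s]):
            raise ContainerError(f"unconsumed indices for {s}x{s} blocks")
    kr, kc = p.offset
    return out[kr : kr + band_shape[0], kc : kc + band_shape[1]]
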