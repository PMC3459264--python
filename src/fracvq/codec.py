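"""End-to-end encoder/decoder and compression-ratio accounting.

Encode pipeline: edge-pad the image to a multiple of ``2**levels``; 2-level
biorthogonal DWT (periodized); Huffman-code the rounded LL band; for each
detail band build a local-fractal-dimension complexity map, reduce it to
three classes by discriminant thresholding, choose the best quadtree root
shift, tile the band into 8x8/4x4/2x2 blocks, train one energy- or
randomly-initialized K-means codebook per block size, and store the nearest
codeword index per block at fixed width ``ceil(log2 K)``.

Container layout (all integers little-endian): a header holding everything
global (size, bit depth, basis, levels, l0, class count, LL step, init mode,
codebook-embed flag); the LL Huffman table + payload; then one segment per
band — in level-coarse-to-fine, HL/LH/HH order — holding the root-grid
offset, the depth-first quadtree split bitstring, and per present block size
the codebook size K, the (optional) float32 codewords, and the packed index
payload.  Band shapes, per-size block counts, and index bit widths are all
derivable and never stored.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field

import numpy as np

from .bitio import BitReader, BitWriter
from .exceptions import ContainerError, DegenerateInputError, SizeError
from .lfd import lfd_map, normalize_band
from .lossless import HuffmanTable, dequantize_ll, huffman_decode, huffman_encode, quantize_ll
from .partition import (
    Partition,
    classify,
    discriminant_thresholds,
    partition_bits,
    partition_from_bits,
    select_initial_position,
)
from .vq import Codebook, energy_init, extract_blocks, kmeans_train, random_init, vq_decode, vq_encode
from .wavelet import DetailBand, SubbandSet, forward_dwt2, inverse_dwt2, pad_to_multiple

__all__ = ["CodecConfig", "EncodedImage", "RatioReport", "encode", "decode", "ratio_report", "combine_ratios"]

_MAGIC = b"FVQ1"
_VERSION = 1
_INIT_MODES = ("energy", "random")


@dataclass(frozen=True)
class CodecConfig:
    """Tunable codec parameters; defaults follow the reference settings
    (bior4.4 basis, two decomposition levels, three complexity classes,
    8x8/4x4/2x2 blocks, unit LL quantization step)."""

    basis: str = "bior4.4"
    levels: int = 2
    l0: int = 8
    n_classes: int = 3
    ll_step: float = 1.0
    lfd_window: int = 5
    eps_max: int = 5
    k_by_size: dict = field(default_factory=lambda: {2: 256, 4: 256, 8: 128})
    init: str = "energy"
    seed: int = 0
    max_iter: int = 50
    tol: float = 1e-4
    embed_codebooks: bool = True


@dataclass
class BandCode:
    size: int
    k: int
    codewords: np.ndarray | None  # (K, size*size) float32, None if not embedded
    index_payload: bytes
    index_bits: int


@dataclass
class EncodedBand:
    level: int
    orientation: str
    band_shape: tuple[int, int]
    offset: tuple[int, int]
    qt_payload: bytes
    qt_bits: int
    codes: list[BandCode]  # ordered by descending size, only sizes present


@dataclass
class EncodedImage:
    original_size: tuple[int, int]
    bit_depth: int
    basis: str
    levels: int
    l0: int
    n_classes: int
    ll_step: float
    init_mode: str
    embed_codebooks: bool
    ll_table: HuffmanTable
    ll_payload: bytes
    ll_bits: int
    bands: list[EncodedBand]
    section_bits: dict = field(default_factory=dict, repr=False)
    _cached: bytes | None = field(default=None, repr=False)

    # -- derived geometry -------------------------------------------------
    @property
    def padded_size(self) -> tuple[int, int]:
        m = 2**self.levels
        r, c = self.original_size
        return (r + (-r) % m, c + (-c) % m)

    @property
    def ll_shape(self) -> tuple[int, int]:
        pr, pc = self.padded_size
        return (pr >> self.levels, pc >> self.levels)

    def band_shape(self, level: int) -> tuple[int, int]:
        pr, pc = self.padded_size
        return (pr >> level, pc >> level)

    # -- serialization -----------------------------------------------------
    def to_bytes(self) -> bytes:
        if self._cached is not None:
            return self._cached
        sections: dict[str, int] = {}
        parts: list[bytes] = []

        def emit(name: str, chunk: bytes) -> None:
            sections[name] = sections.get(name, 0) + len(chunk) * 8
            parts.append(chunk)

        basis_b = self.basis.encode("ascii")
        header = b"".join(
            [
                _MAGIC,
                struct.pack("<B", _VERSION),
                struct.pack("<IIB", *self.original_size, self.bit_depth),
                struct.pack("<B", len(basis_b)),
                basis_b,
                struct.pack(
                    "<BBB", self.levels, self.l0, self.n_classes
                ),
                struct.pack("<d", self.ll_step),
                struct.pack(
                    "<BB",
                    _INIT_MODES.index(self.init_mode),
                    1 if self.embed_codebooks else 0,
                ),
            ]
        )
        emit("header", header)
        emit("ll_table", self.ll_table.to_bytes())
        emit("ll_payload", struct.pack("<I", self.ll_bits) + self.ll_payload)
        for i, band in enumerate(self.bands):
            tag = f"band{i}"
            emit(
                f"{tag}_meta",
                struct.pack("<BB", band.offset[0], band.offset[1])
                + struct.pack("<I", band.qt_bits),
            )
            emit(f"{tag}_quadtree", band.qt_payload)
            for code in band.codes:
                emit(f"{tag}_meta", struct.pack("<H", code.k))
                if self.embed_codebooks and code.k > 0:
                    cw = np.ascontiguousarray(code.codewords, dtype="<f4")
                    emit(f"{tag}_codebooks", cw.tobytes())
                emit(f"{tag}_indices", code.index_payload)
        data = b"".join(parts)
        self.section_bits = sections
        self._cached = data
        return data

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            fh.write(self.to_bytes())

    @property
    def total_bits(self) -> int:
        return len(self.to_bytes()) * 8

    @classmethod
    def from_bytes(cls, data: bytes) -> "EncodedImage":
        r = _Reader(data)
        if r.read(4) != _MAGIC:
            raise ContainerError("bad magic; not a fracvq container")
        version = r.u8()
        if version != _VERSION:
            raise ContainerError(f"unsupported container version {version}")
        rows, cols, bit_depth = r.unpack("<IIB", 9)
        basis = r.read(r.u8()).decode("ascii")
        levels, l0, n_classes = r.unpack("<BBB", 3)
        (ll_step,) = r.unpack("<d", 8)
        init_idx, embed = r.unpack("<BB", 2)
        if init_idx >= len(_INIT_MODES):
            raise ContainerError("unknown init mode")
        ll_table, r.pos = HuffmanTable.from_stream(data, r.pos)
        (ll_bits,) = r.unpack("<I", 4)
        ll_payload = r.read((ll_bits + 7) // 8)

        enc = cls(
            original_size=(rows, cols),
            bit_depth=bit_depth,
            basis=basis,
            levels=levels,
            l0=l0,
            n_classes=n_classes,
            ll_step=ll_step,
            init_mode=_INIT_MODES[init_idx],
            embed_codebooks=bool(embed),
            ll_table=ll_table,
            ll_payload=ll_payload,
            ll_bits=ll_bits,
            bands=[],
        )
        for level in range(levels, 0, -1):
            for orient in ("HL", "LH", "HH"):
                shape = enc.band_shape(level)
                kr, kc = r.unpack("<BB", 2)
                (qt_bits,) = r.unpack("<I", 4)
                qt_payload = r.read((qt_bits + 7) // 8)
                part = partition_from_bits(qt_payload, qt_bits, (kr, kc), shape, l0)
                counts: dict[int, int] = {}
                for _, _, s in part.blocks:
                    counts[s] = counts.get(s, 0) + 1
                codes: list[BandCode] = []
                for s in sorted(counts, reverse=True):
                    (k,) = r.unpack("<H", 2)
                    if k < 1 or k > counts[s]:
                        raise ContainerError(f"invalid codebook size K={k}")
                    cw = None
                    if embed:
                        raw = r.read(k * s * s * 4)
                        cw = np.frombuffer(raw, dtype="<f4").reshape(k, s * s).astype(np.float64)
                    width = max(1, math.ceil(math.log2(k))) if k > 1 else 0
                    nbits = counts[s] * width
                    payload = r.read((nbits + 7) // 8)
                    codes.append(BandCode(s, k, cw, payload, nbits))
                enc.bands.append(
                    EncodedBand(level, orient, shape, (kr, kc), qt_payload, qt_bits, codes)
                )
        if r.pos != len(data):
            raise ContainerError(f"{len(data) - r.pos} trailing bytes in container")
        return enc

    @classmethod
    def load(cls, path) -> "EncodedImage":
        with open(path, "rb") as fh:
            return cls.from_bytes(fh.read())


class _Reader:
    def __init__(self, data: bytes) -> None:
        self.data = data
        self.pos = 0

    def read(self, n: int) -> bytes:
        if self.pos + n > len(self.data):
            raise ContainerError("truncated container")
        out = self.data[self.pos : self.pos + n]
        self.pos += n
        return out

    def u8(self) -> int:
        return self.read(1)[0]

    def unpack(self, fmt: str, n: int):
        return struct.unpack(fmt, self.read(n))


def _index_width(k: int) -> int:
    if k <= 1:
        return 0
    return max(1, math.ceil(math.log2(k)))


def _extend_band(band: np.ndarray, p: Partition) -> np.ndarray:
    kr, kc = p.offset
    rows, cols = band.shape
    er, ec = p.extended_size
    return np.pad(band, ((kr, er - rows - kr), (kc, ec - cols - kc)), mode="edge")


def _band_seed(base: int, band_index: int, size: int) -> int:
    return (base * 2654435761 + band_index * 97 + size) % (2**31)


def encode(image: np.ndarray, config: CodecConfig | None = None) -> EncodedImage:
    """Compress a grayscale image into a self-contained container."""
    config = config or CodecConfig()
    image = np.asarray(image)
    if image.ndim != 2:
        raise SizeError("expected a 2-D grayscale image")
    min_side = 2 * config.l0 * 2**config.levels
    if min(image.shape) < min_side:
        raise SizeError(f"image sides must be >= {min_side} pixels")
    if config.init not in _INIT_MODES:
        raise ValueError(f"init must be one of {_INIT_MODES}")
    bit_depth = 16 if image.dtype.itemsize > 1 else 8
    padded = pad_to_multiple(image, 2**config.levels)
    bands = forward_dwt2(padded, config.levels, config.basis, bit_depth)

    ll_q = quantize_ll(bands.ll, config.ll_step)
    ll_table, ll_payload, ll_bits = huffman_encode(ll_q)

    enc_bands: list[EncodedBand] = []
    for band_index, detail in enumerate(bands.details):
        coeffs = detail.coeffs
        surface = normalize_band(coeffs)
        lmap = lfd_map(surface, config.lfd_window, config.eps_max)
        try:
            thresholds = discriminant_thresholds(lmap.values, config.n_classes)
            cmap = classify(lmap.values, thresholds)
        except DegenerateInputError:
            cmap = classify(lmap.values, np.array([]))
            cmap.labels[:] = 0
        offset, part, _sums = select_initial_position(cmap, config.l0)
        qt_payload, qt_bits = partition_bits(part)

        band_ext = _extend_band(coeffs, part)
        blocksets = extract_blocks(band_ext, part)
        codes: list[BandCode] = []
        for s in sorted(blocksets, reverse=True):
            bs = blocksets[s]
            n_distinct = np.unique(bs.vectors, axis=0).shape[0]
            k = min(config.k_by_size.get(s, 256), bs.n, n_distinct)
            if config.init == "energy":
                init = energy_init(bs, k)
            else:
                init = random_init(bs, k, _band_seed(config.seed, band_index, s))
            cb = kmeans_train(bs, k, init, config.max_iter, config.tol, config.init)
            indices = vq_encode(bs, cb)
            width = _index_width(k)
            writer = BitWriter()
            for i in indices:
                writer.write_bits(int(i), width)
            codes.append(
                BandCode(
                    size=s,
                    k=k,
                    codewords=cb.codewords.astype(np.float32),
                    index_payload=writer.getvalue(),
                    index_bits=writer.bit_length,
                )
            )
        enc_bands.append(
            EncodedBand(
                level=detail.level,
                orientation=detail.orientation,
                band_shape=coeffs.shape,
                offset=offset,
                qt_payload=qt_payload,
                qt_bits=qt_bits,
                codes=codes,
            )
        )

    enc = EncodedImage(
        original_size=image.shape,
        bit_depth=bit_depth,
        basis=config.basis,
        levels=config.levels,
        l0=config.l0,
        n_classes=config.n_classes,
        ll_step=config.ll_step,
        init_mode=config.init,
        embed_codebooks=config.embed_codebooks,
        ll_table=ll_table,
        ll_payload=ll_payload,
        ll_bits=ll_bits,
        bands=enc_bands,
    )
    enc.to_bytes()  # populate section accounting
    return enc


def decode(enc: EncodedImage) -> np.ndarray:
    """Reconstruct the image from a container (inverse of ``encode``)."""
    if not enc.embed_codebooks:
        raise ContainerError("container has no embedded codebooks; decode needs them")
    ll_q = huffman_decode(enc.ll_table, enc.ll_payload, enc.ll_bits, enc.ll_shape)
    ll = dequantize_ll(ll_q, enc.ll_step)

    details: list[DetailBand] = []
    for band in enc.bands:
        part = partition_from_bits(
            band.qt_payload, band.qt_bits, band.offset, band.band_shape, enc.l0
        )
        counts: dict[int, int] = {}
        for _, _, s in part.blocks:
            counts[s] = counts.get(s, 0) + 1
        codebooks: dict[int, Codebook] = {}
        indices: dict[int, list[int]] = {}
        for code in band.codes:
            if code.codewords is None:
                raise ContainerError("missing codewords for a band segment")
            codebooks[code.size] = Codebook(
                block_size=code.size,
                codewords=np.asarray(code.codewords, dtype=np.float64),
                init_mode=enc.init_mode,
            )
            width = _index_width(code.k)
            n = counts.get(code.size, 0)
            reader = BitReader(code.index_payload, code.index_bits)
            indices[code.size] = [reader.read_bits(width) if width else 0 for _ in range(n)]
        coeffs = vq_decode(indices, codebooks, part, band.band_shape)
        details.append(DetailBand(band.level, band.orientation, coeffs))

    bands = SubbandSet(
        ll=ll,
        details=details,
        levels=enc.levels,
        basis_name=enc.basis,
        original_size=enc.padded_size,
        bit_depth=enc.bit_depth,
    )
    rec = inverse_dwt2(bands)
    rows, cols = enc.original_size
    return rec[:rows, :cols]


@dataclass
class RatioReport:
    cr_lossless: float
    cr_lossy: float
    cr_overall: float
    raw_bits: dict
    coded_bits: dict
    include_codebooks: bool

    def check_identity(self) -> float:
        """Overall ratio as the LL-fraction-weighted harmonic mean of parts."""
        f = self.raw_bits["ll"] / self.raw_bits["total"]
        return combine_ratios(self.cr_lossless, self.cr_lossy, f)


def combine_ratios(cr_ll: float, cr_hf: float, f: float) -> float:
    """Combine per-part compression ratios with LL coefficient fraction f."""
    return 1.0 / (f / cr_ll + (1.0 - f) / cr_hf)


def ratio_report(
    enc: EncodedImage, image: np.ndarray, include_codebooks: bool | None = None
) -> RatioReport:
    """Bit accounting: raw bits split 4**-levels : rest between LL and detail
    parts; coded bits from the serialized segment lengths.  With
    ``include_codebooks=False`` the codeword bytes are excluded from the lossy
    part (shared-codebook accounting)."""
    if include_codebooks is None:
        include_codebooks = enc.embed_codebooks
    image = np.asarray(image)
    if image.shape != enc.original_size:
        raise SizeError("image does not match the container's recorded size")
    data = enc.to_bytes()
    sections = enc.section_bits
    total_bits = len(data) * 8
    assert total_bits == sum(sections.values())
    coded_ll = sections["ll_table"] + sections["ll_payload"]
    codebook_bits = sum(v for k, v in sections.items() if k.endswith("_codebooks"))
    coded_hf = total_bits - coded_ll
    if not include_codebooks:
        coded_hf -= codebook_bits
    raw_total = image.shape[0] * image.shape[1] * enc.bit_depth
    f = 4.0 ** (-enc.levels)
    raw_ll = raw_total * f
    raw_hf = raw_total - raw_ll
    return RatioReport(
        cr_lossless=raw_ll / coded_ll,
        cr_lossy=raw_hf / coded_hf,
        cr_overall=raw_total / (coded_ll + coded_hf),
        raw_bits={"ll": raw_ll, "hf": raw_hf, "total": raw_total},
        coded_bits={
            "ll": coded_ll,
            "hf": coded_hf,
            "codebooks": codebook_bits,
            "total": coded_ll + coded_hf,
            "container": total_bits,
        },
        include_codebooks=include_codebooks,
    )
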