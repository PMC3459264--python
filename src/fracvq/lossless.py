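"""Canonical Huffman coding of the quantized LL band.

The LL coefficients are real-valued after a biorthogonal transform, so they
are first rounded to integer symbols (``round(ll / step)``).  The symbol
stream is then entropy-coded with a canonical Huffman code: tree-building
ties are broken by smallest contained symbol, and codes are assigned in
(length, symbol) order, so identical frequency tables always produce
bit-identical streams.  A single-symbol alphabet is coded at 1 bit/value.
"""

from __future__ import annotations

import heapq
import struct
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .bitio import BitReader, BitWriter
from .exceptions import ContainerError, SizeError

__all__ = [
    "HuffmanTable",
    "quantize_ll",
    "dequantize_ll",
    "huffman_encode",
    "huffman_decode",
]


def quantize_ll(ll: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Uniform scalar quantization: round(ll / step), ties to even."""
    if step <= 0:
        raise ValueError("step must be positive")
    return np.rint(np.asarray(ll, dtype=np.float64) / step).astype(np.int64)


def dequantize_ll(q: np.ndarray, step: float = 1.0) -> np.ndarray:
    return np.asarray(q, dtype=np.float64) * step


def _code_lengths(freqs: dict[int, int]) -> dict[int, int]:
    if len(freqs) == 1:
        return {next(iter(freqs)): 1}
    lengths = {s: 0 for s in freqs}
    heap: list[tuple[int, int, list[int]]] = [(f, s, [s]) for s, f in freqs.items()]
    heapq.heapify(heap)
    while len(heap) > 1:
        f1, s1, l1 = heapq.heappop(heap)
        f2, s2, l2 = heapq.heappop(heap)
        merged = l1 + l2
        for s in merged:
            lengths[s] += 1
        heapq.heappush(heap, (f1 + f2, min(s1, s2), merged))
    return lengths


@dataclass
class HuffmanTable:
    symbols: np.ndarray  # int32, in canonical (length, symbol) order
    lengths: np.ndarray  # uint8, same order

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int32)
        self.lengths = np.asarray(self.lengths, dtype=np.uint8)

    def codes(self) -> dict[int, tuple[int, int]]:
        """symbol -> (code, length), canonical assignment."""
        out: dict[int, tuple[int, int]] = {}
        code = 0
        prev_len = 0
        for s, ln in zip(self.symbols.tolist(), self.lengths.tolist()):
            code <<= ln - prev_len
            out[int(s)] = (code, int(ln))
            code += 1
            prev_len = ln
        return out

    def kraft_sum(self) -> float:
        return float(np.sum(2.0 ** (-self.lengths.astype(np.float64))))

    @classmethod
    def from_frequencies(cls, freqs: dict[int, int]) -> "HuffmanTable":
        lengths = _code_lengths(freqs)
        order = sorted(lengths.items(), key=lambda kv: (kv[1], kv[0]))
        return cls(
            symbols=np.array([s for s, _ in order], dtype=np.int32),
            lengths=np.array([ln for _, ln in order], dtype=np.uint8),
        )

    def to_bytes(self) -> bytes:
        parts = [struct.pack("<I", len(self.symbols))]
        for s, ln in zip(self.symbols.tolist(), self.lengths.tolist()):
            parts.append(struct.pack("<iB", int(s), int(ln)))
        return b"".join(parts)

    @classmethod
    def from_stream(cls, data: bytes, pos: int) -> tuple["HuffmanTable", int]:
        if pos + 4 > len(data):
            raise ContainerError("truncated Huffman table header")
        (count,) = struct.unpack_from("<I", data, pos)
        pos += 4
        need = count * 5
        if pos + need > len(data):
            raise ContainerError("truncated Huffman table entries")
        symbols = np.empty(count, dtype=np.int32)
        lengths = np.empty(count, dtype=np.uint8)
        for i in range(count):
            s, ln = struct.unpack_from("<iB", data, pos)
            symbols[i] = s
            lengths[i] = ln
            pos += 5
        return cls(symbols=symbols, lengths=lengths), pos


def huffman_encode(values: np.ndarray) -> tuple[HuffmanTable, bytes, int]:
    """Encode an integer grid; returns (table, payload bytes, payload bits)."""
    values = np.asarray(values)
    if values.size == 0:
        raise SizeError("nothing to encode")
    flat = values.ravel().tolist()
    table = HuffmanTable.from_frequencies(Counter(flat))
    codes = table.codes()
    writer = BitWriter()
    for v in flat:
        code, ln = codes[int(v)]
        writer.write_bits(code, ln)
    return table, writer.getvalue(), writer.bit_length


def huffman_decode(
    table: HuffmanTable, payload: bytes, bit_length: int, shape: tuple[int, ...]
) -> np.ndarray:
    """Exact inverse of ``huffman_encode`` for a matching (table, payload)."""
    n = int(np.prod(shape))
    lookup = {(ln, code): s for s, (code, ln) in table.codes().items()}
    max_len = int(table.lengths.max()) if table.lengths.size else 0
    reader = BitReader(payload, bit_length)
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        acc = 0
        ln = 0
        while True:
            acc = (acc << 1) | reader.read_bit()
            ln += 1
            sym = lookup.get((ln, acc))
            if sym is not None:
                out[i] = sym
                break
            if ln > max_len:
                raise ContainerError("invalid Huffman payload (no matching code)")
    if reader.remaining:
        raise ContainerError(
            f"payload has {reader.remaining} leftover bits for shape {shape}"
        )
    return out.reshape(shape)
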