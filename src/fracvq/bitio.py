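"""Minimal MSB-first bit stream writer/reader.

Bit order: the first bit written is the most significant bit of the first
byte.  The final partial byte is zero-padded on the right; exact bit lengths
are carried out-of-band by the container format.
"""

from __future__ import annotations

from .exceptions import ContainerError


class BitWriter:
    def __init__(self) -> None:
        self._bytes = bytearray()
        self._acc = 0
        self._nacc = 0
        self.bit_length = 0

    def write_bit(self, bit: int) -> None:
        self.write_bits(bit & 1, 1)

    def write_bits(self, value: int, n: int) -> None:
        if n < 0 or (n and not 0 <= value < (1 << n)):
            raise ValueError(f"value {value} does not fit in {n} bits")
        self._acc = (self._acc << n) | value
        self._nacc += n
        self.bit_length += n
        while self._nacc >= 8:
            self._nacc -= 8
            self._bytes.append((self._acc >> self._nacc) & 0xFF)
            self._acc &= (1 << self._nacc) - 1

    def getvalue(self) -> bytes:
        out = bytes(self._bytes)
        if self._nacc:
            out += bytes([(self._acc << (8 - self._nacc)) & 0xFF])
        return out


class BitReader:
    def __init__(self, data: bytes, bit_length: int | None = None) -> None:
        self._data = data
        self.bit_length = len(data) * 8 if bit_length is None else bit_length
        if self.bit_length > len(data) * 8:
            raise ContainerError("bit length exceeds available payload bytes")
        self.pos = 0

    @property
    def remaining(self) -> int:
        return self.bit_length - self.pos

    def read_bit(self) -> int:
        if self.pos >= self.bit_length:
            raise ContainerError("bit stream exhausted")
        byte = self._data[self.pos >> 3]
        bit = (byte >> (7 - (self.pos & 7))) & 1
        self.pos += 1
        return bit

    def read_bits(self, n: int) -> int:
        if self.pos + n > self.bit_length:
            raise ContainerError("bit stream exhausted")
        value = 0
        pos = self.pos
        data = self._data
        for _ in range(n):
            value = (value << 1) | ((data[pos >> 3] >> (7 - (pos & 7))) & 1)
            pos += 1
        self.pos = pos
        return value
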