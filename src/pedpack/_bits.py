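"""MSB-first bit-stream reader/writer for variable-width integer fields.

Payloads are sequences of fixed-width unsigned fields that are not byte
aligned; the stream is padded with zero bits to a whole number of bytes.
The first bit written lands in the most-significant bit of the first byte.
"""

from __future__ import annotations


class BitWriter:
    """Accumulates unsigned integer fields into a zero-padded byte string."""

    __slots__ = ("_buf", "_acc", "_nbits")

    def __init__(self) -> None:
        self._buf = bytearray()
        self._acc = 0
        self._nbits = 0

    def write(self, value: int, width: int) -> None:
        if width <= 0:
            raise ValueError("field width must be positive")
        if value < 0 or value >> width:
            raise ValueError(f"value {value} does not fit in {width} bits")
        self._acc = (self._acc << width) | value
        self._nbits += width
        while self._nbits >= 8:
            self._nbits -= 8
            self._buf.append((self._acc >> self._nbits) & 0xFF)
        self._acc &= (1 << self._nbits) - 1

    def write_bytes(self, data: bytes, nbits: int) -> None:
        """Append the leading ``nbits`` bits of ``data`` (MSB-first)."""
        if nbits > 8 * len(data):
            raise ValueError("nbits exceeds data length")
        full, rem = divmod(nbits, 8)
        for b in data[:full]:
            self.write(b, 8)
        if rem:
            self.write(data[full] >> (8 - rem), rem)

    @property
    def bit_length(self) -> int:
        return 8 * len(self._buf) + self._nbits

    def getvalue(self) -> bytes:
        """Return the stream so far, zero-padded to a whole byte."""
        out = bytes(self._buf)
        if self._nbits:
            out += bytes([(self._acc << (8 - self._nbits)) & 0xFF])
        return out


class BitReader:
    """Reads fixed-width unsigned fields from a byte string, MSB-first."""

    __slots__ = ("_data", "_pos")

    def __init__(self, data: bytes) -> None:
        self._data = data
        self._pos = 0  # bit position

    @property
    def bits_remaining(self) -> int:
        return 8 * len(self._data) - self._pos

    def read(self, width: int) -> int:
        if width <= 0:
            raise ValueError("field width must be positive")
        if width > self.bits_remaining:
            raise ValueError("bit stream exhausted: payload shorter than its declared fields")
        value = 0
        pos = self._pos
        data = self._data
        need = width
        while need:
            byte_idx, bit_off = divmod(pos, 8)
            take = min(8 - bit_off, need)
            chunk = (data[byte_idx] >> (8 - bit_off - take)) & ((1 << take) - 1)
            value = (value << take) | chunk
            pos += take
            need -= take
        self._pos = pos
        return value

    def read_bytes(self, nbits: int) -> bytes:
        """Read ``nbits`` bits and return them packed MSB-first, zero-padded."""
        full, rem = divmod(nbits, 8)
        out = bytearray(self.read(8) for _ in range(full))
        if rem:
            out.append(self.read(rem) << (8 - rem))
        return bytes(out)
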