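"""Per-marker genotype codecs and size-driven method selection.

Three encodings of one marker's dosage vector (n subjects, codes in
{0,1,2,3}, 3 = missing) are supported:

* ``SUB1`` — dense 2-bit packing, four genotypes per byte. Size is
  ``ceil(2n/8)`` bytes regardless of allele frequency.
* ``SUB2`` — carrier indices. Only the subjects holding the rare-homozygous,
  heterozygous or missing genotype are listed by index; everyone else
  defaults to the common-homozygous genotype. Each index and each of the
  three count fields occupies ``w = ceil(log2(n+1))`` bits, giving
  ``ceil(w * (#Homo + #Heter + #Missing + 3) / 8)`` bytes. Wins for rare
  variants, where carriers are few.
* ``SUB3`` — hybrid: rare-homozygous and missing subjects by index as in
  ``SUB2``, but heterozygotes as an n-bit presence bit-vector, giving
  ``ceil((w * (#Homo + #Missing + 2) + n) / 8)`` bytes. Wins in the
  mid-frequency band where heterozygotes are too many to enumerate but the
  other classes are still sparse.

Because each size is a closed-form function of the per-marker genotype
tally, the optimal method is chosen *before* encoding. All payloads are
padded to whole bytes so a container can seek marker by marker.

Bit-layout conventions (normative for the container format): fields are
MSB-first within each byte; subject indices are 0-based and emitted in
ascending order; ``SUB2`` field order is homoCount, homo indices,
heterCount, heter indices, missingCount, missing indices; ``SUB3`` is
homoCount, homo indices, missingCount, missing indices, then the n-bit
heterozygosity vector with subject 0 at the most-significant bit of its
byte. No byte compatibility with any other tool is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable

import numpy as np

from ._bits import BitReader, BitWriter
from .ped_io import MISSING_CODE, GenotypeTally

__all__ = [
    "Method",
    "MarkerPayload",
    "PayloadCorruptionError",
    "index_width",
    "payload_size",
    "payload_sizes_from_counts",
    "select_method",
    "encode_marker",
    "encode_from_carriers",
    "decode_marker",
    "decode_carriers",
]


class Method(IntEnum):
    """The three sub-algorithm identifiers, in tie-break preference order."""

    SUB1 = 1
    SUB2 = 2
    SUB3 = 3


class PayloadCorruptionError(ValueError):
    """Payload bytes inconsistent with their self-described structure."""


@dataclass(frozen=True)
class MarkerPayload:
    """One marker's encoded genotype vector."""

    method: Method
    data: bytes
    n_subjects: int


def index_width(n_subjects: int) -> int:
    """Bits needed to store any subject index *or* any count in 0..n.

    ``w = ceil(log2(n+1))``: a count field can equal n itself, so the +1 is
    required; for n = 1000 this is 10 bits.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    return max(1, int(n_subjects).bit_length())


def _counts(tally: GenotypeTally | tuple[int, int, int]) -> tuple[int, int, int]:
    if isinstance(tally, GenotypeTally):
        return tally.n_rare_homo, tally.n_heter, tally.n_missing
    homo, het, miss = tally
    return int(homo), int(het), int(miss)


def payload_size(method: Method, n_subjects: int, tally) -> int:
    """Exact payload size in bytes for one marker under ``method``.

    ``tally`` is a :class:`GenotypeTally` or a ``(n_rare_homo, n_heter,
    n_missing)`` triple. Sizes are whole bytes (payloads are byte-aligned).
    """
    homo, het, miss = _counts(tally)
    if homo + het + miss > n_subjects:
        raise ValueError("tally counts exceed the number of subjects")
    w = index_width(n_subjects)
    method = Method(method)
    if method is Method.SUB1:
        bits = 2 * n_subjects
    elif method is Method.SUB2:
        bits = w * (homo + het + miss + 3)
    else:
        bits = w * (homo + miss + 2) + n_subjects
    return -(-bits // 8)


def payload_sizes_from_counts(
    n_subjects: int,
    n_rare_homo: np.ndarray,
    n_heter: np.ndarray,
    n_missing: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized ``(size_sub1, size_sub2, size_sub3)`` for many markers."""
    homo = np.asarray(n_rare_homo, dtype=np.int64)
    het = np.asarray(n_heter, dtype=np.int64)
    miss = np.asarray(n_missing, dtype=np.int64)
    w = index_width(n_subjects)
    s1 = np.broadcast_to(np.int64(-(-2 * n_subjects // 8)), homo.shape).copy()
    s2 = -(-(w * (homo + het + miss + 3)) // 8)
    s3 = -(-(w * (homo + miss + 2) + n_subjects) // 8)
    return s1, s2, s3


def select_method(n_subjects: int, tally) -> Method:
    """Choose the method with the smallest payload; ties prefer the
    simplest decoder (SUB1 < SUB2 < SUB3)."""
    sizes = [(payload_size(m, n_subjects, tally), m) for m in Method]
    return min(sizes)[1]


def _carrier_indices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        np.flatnonzero(codes == 2),
        np.flatnonzero(codes == 1),
        np.flatnonzero(codes == MISSING_CODE),
    )


def encode_marker(method: Method, codes) -> MarkerPayload:
    """Encode one marker's dosage vector under ``method``.

    ``decode_marker`` inverts this exactly; the payload length always equals
    :func:`payload_size` for the vector's tally.
    """
    codes = np.asarray(codes, dtype=np.uint8)
    if codes.ndim != 1 or codes.size == 0:
        raise ValueError("codes must be a non-empty 1-D vector")
    if codes.max() > 3:
        raise ValueError("genotype codes must be in {0,1,2,3}")
    n = codes.size
    method = Method(method)
    if method is Method.SUB1:
        return MarkerPayload(method, _encode_sub1(codes), n)
    homo, het, miss = _carrier_indices(codes)
    return encode_from_carriers(method, n, homo, het, miss)


def _encode_sub1(codes: np.ndarray) -> bytes:
    # two bits per code, subject 0 in the most-significant pair of byte 0
    bits = ((codes[:, None] >> np.array([1, 0], dtype=np.uint8)) & 1).ravel()
    return np.packbits(bits).tobytes()


def encode_from_carriers(
    method: Method,
    n_subjects: int,
    homo_indices: Iterable[int],
    heter_indices: Iterable[int],
    missing_indices: Iterable[int],
) -> MarkerPayload:
    """Encode directly from carrier index sets (ascending order enforced).

    This is the streaming-compression entry point: the second pass of the
    compressor accumulates carrier lists per marker and never materializes
    dense vectors for index-coded markers.
    """
    method = Method(method)
    homo = np.asarray(homo_indices, dtype=np.int64)
    het = np.asarray(heter_indices, dtype=np.int64)
    miss = np.asarray(missing_indices, dtype=np.int64)
    for arr in (homo, het, miss):
        if arr.size and (arr.min() < 0 or arr.max() >= n_subjects):
            raise ValueError("carrier index out of range")
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise ValueError("carrier indices must be strictly ascending")
    w = index_width(n_subjects)
    writer = BitWriter()
    if method is Method.SUB1:
        codes = np.zeros(n_subjects, dtype=np.uint8)
        codes[homo] = 2
        codes[het] = 1
        codes[miss] = MISSING_CODE
        return MarkerPayload(method, _encode_sub1(codes), n_subjects)
    if method is Method.SUB2:
        for arr in (homo, het, miss):
            writer.write(arr.size, w)
            for idx in arr:
                writer.write(int(idx), w)
    else:  # SUB3
        for arr in (homo, miss):
            writer.write(arr.size, w)
            for idx in arr:
                writer.write(int(idx), w)
        het_bits = np.zeros(n_subjects, dtype=np.uint8)
        het_bits[het] = 1
        writer.write_bytes(np.packbits(het_bits).tobytes(), n_subjects)
    return MarkerPayload(method, writer.getvalue(), n_subjects)


def decode_carriers(
    payload: MarkerPayload,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract ``(homo, heter, missing)`` carrier index arrays from a payload.

    For SUB2/SUB3 this reads the index fields directly without scanning all
    n subjects; for SUB1 it scans the packed codes.
    """
    n = payload.n_subjects
    if payload.method is Method.SUB1:
        codes = _decode_sub1(payload.data, n)
        return _carrier_indices(codes)
    w = index_width(n)
    reader = BitReader(payload.data)
    try:
        if payload.method is Method.SUB2:
            sets = []
            for _ in range(3):
                count = reader.read(w)
                sets.append(np.array([reader.read(w) for _ in range(count)], dtype=np.int64))
            homo, het, miss = sets
        else:
            sets = []
            for _ in range(2):
                count = reader.read(w)
                sets.append(np.array([reader.read(w) for _ in range(count)], dtype=np.int64))
            homo, miss = sets
            het_bytes = reader.read_bytes(n)
            het = np.flatnonzero(np.unpackbits(np.frombuffer(het_bytes, dtype=np.uint8))[:n]).astype(np.int64)
    except ValueError as exc:
        raise PayloadCorruptionError(str(exc)) from None
    if reader.bits_remaining >= 8:
        raise PayloadCorruptionError(
            f"payload has {reader.bits_remaining} trailing bits beyond its fields"
        )
    _validate_carriers(n, homo, het, miss)
    return homo, het, miss


def _validate_carriers(n: int, homo: np.ndarray, het: np.ndarray, miss: np.ndarray) -> None:
    for arr in (homo, het, miss):
        if arr.size and (arr.min() < 0 or arr.max() >= n):
            raise PayloadCorruptionError("carrier index out of range")
        if arr.size > 1 and np.any(np.diff(arr) <= 0):
            raise PayloadCorruptionError("carrier indices not strictly ascending")
    combined = np.concatenate([homo, het, miss])
    if combined.size != np.unique(combined).size:
        raise PayloadCorruptionError("subject listed in more than one carrier set")


def _decode_sub1(data: bytes, n: int) -> np.ndarray:
    expected = -(-2 * n // 8)
    if len(data) != expected:
        raise PayloadCorruptionError(
            f"SUB1 payload is {len(data)} bytes, expected {expected} for n={n}"
        )
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))[: 2 * n]
    return (bits[0::2] << 1 | bits[1::2]).astype(np.uint8)


def decode_marker(payload: MarkerPayload, n_subjects: int | None = None) -> np.ndarray:
    """Decode a payload back to the full dosage vector (exact inverse)."""
    n = payload.n_subjects if n_subjects is None else n_subjects
    if n != payload.n_subjects:
        raise ValueError("n_subjects disagrees with the payload")
    if payload.method is Method.SUB1:
        return _decode_sub1(payload.data, n)
    homo, het, miss = decode_carriers(payload)
    codes = np.zeros(n, dtype=np.uint8)  # common homozygous is the default
    codes[homo] = 2
    codes[het] = 1
    codes[miss] = MISSING_CODE
    return codes
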