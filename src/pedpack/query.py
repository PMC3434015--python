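"""Load a compressed container (fully or a marker range) and query it.

The loaded representation never materializes the 4-byte-per-genotype text
form: dense (SUB1) markers stay 2-bit packed with direct bit addressing,
and index-coded (SUB2/SUB3) markers are kept as ascending carrier index
sets. Memory therefore tracks the compressed payload. Carrier sets are also
the natural unit for permutation-based association tests: permuting subject
labels is equivalent to mapping the index sets through the permutation,
with no per-subject scan.

Partial loading is by contiguous half-open marker range ``[start, end)``:
only the payload bytes of the requested markers are read (seek via the
index), which is what makes independent parallel jobs over marker slices
cheap. Queries outside the loaded range raise — they never silently return
default genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import codec, container
from .codec import Method
from .ped_io import MISSING_CODE, SubjectRecord

__all__ = ["CarrierSets", "CompressedStore", "load"]


@dataclass(frozen=True)
class CarrierSets:
    """Ascending, pairwise-disjoint subject index sets for one marker."""

    rare_homo_indices: np.ndarray
    heter_indices: np.ndarray
    missing_indices: np.ndarray


class RangeError(IndexError):
    """Marker or subject index outside the loaded range."""


class CompressedStore:
    """In-memory view of a container over a marker range ``[start, end)``.

    Construct via :func:`load`. ``bytes_read`` records how many payload
    bytes were actually read from disk, which makes the partial-loading
    contract (only the requested slice is touched) directly testable.
    """

    def __init__(
        self,
        subjects: list[SubjectRecord],
        markers: list[container.MarkerRecord],
        start: int,
        end: int,
        n_markers_total: int,
        dense_payloads: dict[int, np.ndarray],
        carrier_sets: dict[int, CarrierSets],
        bytes_read: int,
    ) -> None:
        self.subjects = subjects
        self.markers = markers
        self.start = start
        self.end = end
        self.n_markers_total = n_markers_total
        self._dense = dense_payloads
        self._carriers = carrier_sets
        self.bytes_read = bytes_read

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def _check_marker(self, marker_idx: int) -> int:
        if not (self.start <= marker_idx < self.end):
            raise RangeError(
                f"marker {marker_idx} outside loaded range "
                f"[{self.start}, {self.end})"
            )
        return marker_idx - self.start

    def marker_record(self, marker_idx: int) -> container.MarkerRecord:
        return self.markers[self._check_marker(marker_idx)]

    def genotype_at(self, subject_idx: int, marker_idx: int) -> int:
        """Dosage code of one cell; O(1) for dense markers, O(log carriers)
        for index-coded markers."""
        local = self._check_marker(marker_idx)
        if not (0 <= subject_idx < self.n_subjects):
            raise RangeError(f"subject index {subject_idx} outside 0..{self.n_subjects - 1}")
        if local in self._dense:
            data = self._dense[local]
            byte = data[subject_idx >> 2]
            return int((byte >> (6 - 2 * (subject_idx & 3))) & 3)
        sets = self._carriers[local]
        for arr, code in (
            (sets.rare_homo_indices, 2),
            (sets.heter_indices, 1),
            (sets.missing_indices, MISSING_CODE),
        ):
            pos = np.searchsorted(arr, subject_idx)
            if pos < arr.size and arr[pos] == subject_idx:
                return code
        return 0  # common homozygous default

    def carriers(self, marker_idx: int) -> CarrierSets:
        """Carrier index sets; returned directly from the stored payload
        fields for SUB2/SUB3 markers, by a scan for dense SUB1 markers."""
        local = self._check_marker(marker_idx)
        if local in self._carriers:
            return self._carriers[local]
        payload = codec.MarkerPayload(
            Method.SUB1, self._dense[local].tobytes(), self.n_subjects
        )
        homo, het, miss = codec.decode_carriers(payload)
        return CarrierSets(homo, het, miss)

    def genotype_vector(self, marker_idx: int) -> np.ndarray:
        """Full dosage vector for one marker (decoded on demand)."""
        local = self._check_marker(marker_idx)
        if local in self._dense:
            payload = codec.MarkerPayload(
                Method.SUB1, self._dense[local].tobytes(), self.n_subjects
            )
            return codec.decode_marker(payload)
        sets = self._carriers[local]
        codes = np.zeros(self.n_subjects, dtype=np.uint8)
        codes[sets.rare_homo_indices] = 2
        codes[sets.heter_indices] = 1
        codes[sets.missing_indices] = MISSING_CODE
        return codes

    def marker_maf(self, marker_idx: int) -> float:
        """Minor allele frequency ``(2·#Homo + #Heter) / (2·(n − #Missing))``."""
        rec = self.marker_record(marker_idx)
        n_called = self.n_subjects - rec.n_missing
        if n_called == 0:
            raise ValueError(f"marker {rec.name!r}: every genotype is missing")
        return (2 * rec.n_rare_homo + rec.n_heter) / (2 * n_called)


def load(prefix, marker_range: tuple[int, int] | None = None) -> CompressedStore:
    """Load a container into a :class:`CompressedStore`.

    ``marker_range`` is a half-open ``(start, end)`` over 0-based marker
    positions; ``None`` loads everything. Only the payload bytes of the
    requested range are read.
    """
    header, records, subjects = container.read_index(prefix)
    m = header.n_markers
    if marker_range is None:
        start, end = 0, m
    else:
        start, end = marker_range
        if not (0 <= start <= end <= m):
            raise RangeError(f"marker range [{start}, {end}) outside [0, {m})")
    n = header.n_subjects
    dense: dict[int, np.ndarray] = {}
    carriers: dict[int, CarrierSets] = {}
    bytes_read = 0
    with open(container.binary_path(prefix), "rb") as fh:
        for local, rec in enumerate(records[start:end]):
            fh.seek(rec.payload_offset)
            data = fh.read(rec.payload_length)
            if len(data) != rec.payload_length:
                raise container.ContainerError(f"marker {rec.name!r}: payload truncated")
            bytes_read += len(data)
            if rec.method is Method.SUB1:
                dense[local] = np.frombuffer(data, dtype=np.uint8)
            else:
                payload = codec.MarkerPayload(rec.method, data, n)
                try:
                    homo, het, miss = codec.decode_carriers(payload)
                except codec.PayloadCorruptionError as exc:
                    raise container.ContainerError(f"marker {rec.name!r}: {exc}") from None
                if (homo.size, het.size, miss.size) != (
                    rec.n_rare_homo, rec.n_heter, rec.n_missing,
                ):
                    raise container.ContainerError(
                        f"marker {rec.name!r}: carrier counts disagree with the index"
                    )
                carriers[local] = CarrierSets(homo, het, miss)
    return CompressedStore(
        subjects, records[start:end], start, end, m, dense, carriers, bytes_read
    )
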