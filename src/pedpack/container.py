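"""On-disk compressed dataset: binary genotype file plus text sidecar.

A dataset ``<prefix>`` consists of two files, mirroring the split between
human-readable subject information and opaque genotype payloads:

* ``<prefix>.sgtxt`` — text sidecar: subject table (the six pedigree
  columns) and a marker table (name, method, alleles, tally, payload size).
* ``<prefix>.sgbin`` — binary file: fixed header, then the per-marker
  payloads concatenated in marker order, then an index block giving each
  marker's method, alleles, tally, byte offset and length.

The index sits at the end (located via the header's ``index_offset``) so
the compressor can stream payloads without knowing their sizes in advance;
the header's placeholder offset is patched last, which makes an interrupted
write detectable (``index_offset == 0``). All integers little-endian.

Compression is two passes over the PED file: pass 1 tallies genotype
classes per marker and fixes each marker's method from the closed-form
sizes; pass 2 re-reads the file subject by subject, accumulating carrier
lists (index-coded markers) or packed 2-bit columns (dense markers), so
peak memory tracks the *compressed* size plus O(n_subjects + n_markers) —
never the uncompressed subject-by-marker matrix.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import codec, ped_io
from .codec import Method
from .ped_io import GenotypeTally, SubjectRecord

__all__ = [
    "MAGIC",
    "FORMAT_VERSION",
    "MarkerRecord",
    "ContainerHeader",
    "CompressionSummary",
    "ContainerError",
    "compress_ped",
    "decompress",
    "read_index",
    "binary_path",
    "sidecar_path",
]

logger = logging.getLogger(__name__)

MAGIC = b"SGC1"
FORMAT_VERSION = 1

_HEADER = struct.Struct("<4sHxxQQQ")  # magic, version, pad, n_subjects, n_markers, index_offset
_INDEX_ENTRY = struct.Struct("<BBBxIIIQQ")  # method, minor, major, homo, heter, missing, offset, length

PED_BYTES_PER_GENOTYPE = 4  # "a b " — two allele chars and two separators


class ContainerError(ValueError):
    """Corrupt, truncated or inconsistent container files."""


def binary_path(prefix) -> Path:
    return Path(str(prefix) + ".sgbin")


def sidecar_path(prefix) -> Path:
    return Path(str(prefix) + ".sgtxt")


@dataclass(frozen=True)
class ContainerHeader:
    n_subjects: int
    n_markers: int
    index_offset: int
    format_version: int = FORMAT_VERSION


@dataclass(frozen=True)
class MarkerRecord:
    """Index entry for one marker: where its payload lives and how to read it."""

    name: str
    method: Method
    minor_allele: int
    major_allele: int
    n_rare_homo: int
    n_heter: int
    n_missing: int
    payload_offset: int
    payload_length: int

    def tally(self, n_subjects: int) -> GenotypeTally:
        return GenotypeTally(
            self.n_rare_homo,
            self.n_heter,
            self.n_missing,
            self.minor_allele,
            self.major_allele,
            n_subjects,
        )


@dataclass(frozen=True)
class CompressionSummary:
    """Byte accounting of one compression run.

    ``compression_factor`` compares genotype payload bytes against the PED
    genotype baseline of 4 bytes per genotype (allele, space, allele,
    space); header, index and sidecar overhead are reported separately so
    both payload-only and whole-dataset views are computable.
    """

    n_subjects: int
    n_markers: int
    method_counts: dict[Method, int]
    payload_bytes: int
    original_ped_bytes: int
    overhead_bytes: int

    @property
    def baseline_bytes(self) -> int:
        return PED_BYTES_PER_GENOTYPE * self.n_subjects * self.n_markers

    @property
    def compression_factor(self) -> float:
        return self.baseline_bytes / self.payload_bytes

    @property
    def bits_per_genotype(self) -> float:
        return 8.0 * self.payload_bytes / (self.n_subjects * self.n_markers)

    def __str__(self) -> str:
        lines = [
            f"subjects            {self.n_subjects}",
            f"markers             {self.n_markers}",
            f"genotype payload    {self.payload_bytes} bytes",
            f"PED genotype bytes  {self.baseline_bytes} (4 per genotype)",
            f"compression factor  {self.compression_factor:.2f}",
            f"bits per genotype   {self.bits_per_genotype:.4f}",
            f"container overhead  {self.overhead_bytes} bytes (header + index + sidecar)",
        ]
        for m in Method:
            lines.append(f"markers via {m.name}    {self.method_counts.get(m, 0)}")
        return "\n".join(lines)


def compress_ped(ped_path, out_prefix) -> CompressionSummary:
    """Compress a PED file into ``<out_prefix>.sgbin`` + ``.sgtxt``.

    Two passes: the first scans tallies and fixes each marker's method, the
    second streams subjects and encodes. Raises ``ped_io`` errors on
    malformed input; monomorphic or multi-allelic markers abort compression.
    """
    ped_path = Path(ped_path)
    subjects, tallies, marker_names = ped_io.scan_ped(ped_path)
    n = len(subjects)
    m = len(marker_names)
    if n == 0:
        raise ped_io.PedFormatError("PED file contains no subject lines")
    methods = [codec.select_method(n, t) for t in tallies]
    minors = np.array([t.minor_allele for t in tallies], dtype=np.int16)

    method_arr = np.array(methods)
    sub1_cols = np.flatnonzero(method_arr == Method.SUB1)
    indexed_mask = method_arr != Method.SUB1
    sub1_pos = {int(j): k for k, j in enumerate(sub1_cols)}
    sub1_bytes = -(-2 * n // 8)
    dense = np.zeros((len(sub1_cols), sub1_bytes), dtype=np.uint8)
    homo_lists: list[list[int]] = [[] for _ in range(m)]
    het_lists: list[list[int]] = [[] for _ in range(m)]
    miss_lists: list[list[int]] = [[] for _ in range(m)]

    # pass 2: stream subjects, accumulate per-marker compressed state
    for i, (_, alleles) in enumerate(ped_io.iter_subject_rows(ped_path)):
        a1, a2 = alleles[:, 0], alleles[:, 1]
        missing = (a1 == 0) | (a2 == 0)
        dosage = (a1 == minors).astype(np.uint8) + (a2 == minors)
        dosage[missing] = ped_io.MISSING_CODE
        if sub1_cols.size:
            dense[:, i // 4] |= dosage[sub1_cols] << (6 - 2 * (i % 4))
        for j in np.flatnonzero((dosage > 0) & indexed_mask):
            c = dosage[j]
            if c == 2:
                homo_lists[j].append(i)
            elif c == 1:
                het_lists[j].append(i)
            else:
                miss_lists[j].append(i)

    bin_file = binary_path(out_prefix)
    records: list[MarkerRecord] = []
    payload_bytes = 0
    with open(bin_file, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, FORMAT_VERSION, n, m, 0))  # offset patched below
        offset = fh.tell()
        for j, (name, method, tally) in enumerate(zip(marker_names, methods, tallies)):
            if method is Method.SUB1:
                data = dense[sub1_pos[j]].tobytes()
            else:
                data = codec.encode_from_carriers(
                    method, n, homo_lists[j], het_lists[j], miss_lists[j]
                ).data
            expected = codec.payload_size(method, n, tally)
            assert len(data) == expected, (name, method, len(data), expected)
            fh.write(data)
            records.append(
                MarkerRecord(
                    name, method, tally.minor_allele, tally.major_allele,
                    tally.n_rare_homo, tally.n_heter, tally.n_missing,
                    offset, len(data),
                )
            )
            offset += len(data)
            payload_bytes += len(data)
        index_offset = fh.tell()
        for rec in records:
            name_bytes = rec.name.encode("utf-8")
            fh.write(struct.pack("<H", len(name_bytes)))
            fh.write(name_bytes)
            fh.write(
                _INDEX_ENTRY.pack(
                    int(rec.method), rec.minor_allele, rec.major_allele,
                    rec.n_rare_homo, rec.n_heter, rec.n_missing,
                    rec.payload_offset, rec.payload_length,
                )
            )
        bin_size = fh.tell()
        fh.seek(0)
        fh.write(_HEADER.pack(MAGIC, FORMAT_VERSION, n, m, index_offset))

    _write_sidecar(sidecar_path(out_prefix), subjects, records)
    overhead = _HEADER.size + (bin_size - index_offset) + sidecar_path(out_prefix).stat().st_size
    summary = CompressionSummary(
        n_subjects=n,
        n_markers=m,
        method_counts={meth: sum(1 for x in methods if x is meth) for meth in Method},
        payload_bytes=payload_bytes,
        original_ped_bytes=ped_path.stat().st_size,
        overhead_bytes=overhead,
    )
    logger.info("compressed %s: factor %.1f", ped_path, summary.compression_factor)
    return summary


def _write_sidecar(path: Path, subjects, records) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pedpack container sidecar\n")
        fh.write(f"format_version\t{FORMAT_VERSION}\n")
        fh.write(f"n_subjects\t{len(subjects)}\n")
        fh.write(f"n_markers\t{len(records)}\n")
        fh.write("[subjects]\n")
        for s in subjects:
            fh.write(
                f"{s.pedigree_id}\t{s.subject_id}\t{s.father_id}\t{s.mother_id}"
                f"\t{s.sex}\t{s.affection}\n"
            )
        fh.write("[markers]\n")
        fh.write("name\tmethod\tminor\tmajor\tn_rare_homo\tn_heter\tn_missing\tpayload_bytes\n")
        for r in records:
            fh.write(
                f"{r.name}\t{r.method.name}\t{r.minor_allele}\t{r.major_allele}"
                f"\t{r.n_rare_homo}\t{r.n_heter}\t{r.n_missing}\t{r.payload_length}\n"
            )


def _read_sidecar(path: Path) -> tuple[int, int, list[SubjectRecord]]:
    if not path.exists():
        raise ContainerError(f"missing sidecar file {path}")
    n_subjects = n_markers = None
    subjects: list[SubjectRecord] = []
    section = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line == "[subjects]":
                section = "subjects"
                continue
            if line == "[markers]":
                section = "markers"
                continue
            if section is None:
                key, _, value = line.partition("\t")
                if key == "n_subjects":
                    n_subjects = int(value)
                elif key == "n_markers":
                    n_markers = int(value)
                elif key == "format_version" and int(value) != FORMAT_VERSION:
                    raise ContainerError(f"unsupported sidecar version {value}")
            elif section == "subjects":
                cols = line.split("\t")
                if len(cols) != 6:
                    raise ContainerError(f"malformed sidecar subject line: {line!r}")
                subjects.append(
                    SubjectRecord(cols[0], cols[1], cols[2], cols[3], int(cols[4]), int(cols[5]))
                )
    if n_subjects is None or n_markers is None:
        raise ContainerError("sidecar is missing n_subjects/n_markers")
    if len(subjects) != n_subjects:
        raise ContainerError(
            f"sidecar declares {n_subjects} subjects but lists {len(subjects)}"
        )
    return n_subjects, n_markers, subjects


def read_index(prefix) -> tuple[ContainerHeader, list[MarkerRecord], list[SubjectRecord]]:
    """Read header, marker index and subject table without touching payloads.

    Cost is independent of genotype data volume: only the fixed header and
    the trailing index block of the binary file are read.
    """
    bin_file = binary_path(prefix)
    if not bin_file.exists():
        raise ContainerError(f"missing binary file {bin_file}")
    file_size = bin_file.stat().st_size
    with open(bin_file, "rb") as fh:
        raw = fh.read(_HEADER.size)
        if len(raw) < _HEADER.size:
            raise ContainerError("binary file truncated before header end")
        magic, version, n, m, index_offset = _HEADER.unpack(raw)
        if magic != MAGIC:
            raise ContainerError(f"bad magic {magic!r}: not a pedpack container")
        if version != FORMAT_VERSION:
            raise ContainerError(f"unsupported container version {version}")
        if index_offset == 0:
            raise ContainerError("index offset is zero: interrupted or incomplete write")
        if not (_HEADER.size <= index_offset <= file_size):
            raise ContainerError("index offset outside file bounds")
        fh.seek(index_offset)
        index_blob = fh.read()

    records: list[MarkerRecord] = []
    pos = 0
    prev_end = _HEADER.size
    for _ in range(m):
        if pos + 2 > len(index_blob):
            raise ContainerError("index block truncated")
        (name_len,) = struct.unpack_from("<H", index_blob, pos)
        pos += 2
        name = index_blob[pos : pos + name_len].decode("utf-8")
        pos += name_len
        if pos + _INDEX_ENTRY.size > len(index_blob):
            raise ContainerError("index block truncated")
        method, minor, major, homo, heter, missing, offset, length = _INDEX_ENTRY.unpack_from(
            index_blob, pos
        )
        pos += _INDEX_ENTRY.size
        if offset != prev_end:
            raise ContainerError(f"marker {name!r}: payload regions not contiguous/ascending")
        if offset + length > index_offset:
            raise ContainerError(f"marker {name!r}: payload extends into the index block")
        try:
            rec = MarkerRecord(
                name, Method(method), minor, major, homo, heter, missing, offset, length
            )
        except ValueError as exc:
            raise ContainerError(f"marker {name!r}: {exc}") from None
        if length != codec.payload_size(rec.method, n, (homo, heter, missing)):
            raise ContainerError(
                f"marker {name!r}: payload length {length} inconsistent with its tally"
            )
        records.append(rec)
        prev_end = offset + length

    sc_subjects, sc_markers, subjects = _read_sidecar(sidecar_path(prefix))
    if sc_subjects != n or sc_markers != m:
        raise ContainerError(
            f"sidecar ({sc_subjects} subjects, {sc_markers} markers) disagrees with "
            f"binary header ({n}, {m})"
        )
    return ContainerHeader(n, m, index_offset), records, subjects


def decompress(prefix, out_ped_path) -> None:
    """Restore the PED text form, the lossless inverse of :func:`compress_ped`.

    Heterozygote allele order is normalized minor-first; everything the
    scan preserves (subjects, marker names, genotype codes) round-trips
    exactly. On any corruption the output file is not produced.
    """
    header, records, subjects = read_index(prefix)
    n, m = header.n_subjects, header.n_markers
    codes = np.empty((n, m), dtype=np.uint8)
    with open(binary_path(prefix), "rb") as fh:
        for j, rec in enumerate(records):
            fh.seek(rec.payload_offset)
            data = fh.read(rec.payload_length)
            if len(data) != rec.payload_length:
                raise ContainerError(f"marker {rec.name!r}: payload truncated")
            payload = codec.MarkerPayload(rec.method, data, n)
            try:
                codes[:, j] = codec.decode_marker(payload)
            except codec.PayloadCorruptionError as exc:
                raise ContainerError(f"marker {rec.name!r}: {exc}") from None
    with open(out_ped_path, "w", encoding="ascii") as fh:
        ped_io.write_ped(
            subjects,
            [r.name for r in records],
            codes,
            [r.minor_allele for r in records],
            [r.major_allele for r in records],
            fh,
        )
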