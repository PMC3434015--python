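"""Reading and writing LINKAGE/PLINK pedigree (``.ped``) text files.

The dialect handled here has a header line of marker names followed by one
line per subject: six pedigree columns (pedigree ID, subject ID, father ID,
mother ID, sex, affection status) and two numeric allele columns per marker.
Alleles are coded 1-4 (A, C, G, T) with 0 for missing. Only biallelic,
polymorphic markers are supported downstream, so scanning resolves a minor
and major allele per marker and reduces every genotype to a minor-allele
dosage code: 0, 1 or 2 copies of the minor allele, or 3 for missing.

Scanning is single-pass and keeps memory proportional to
``n_subjects + n_markers`` (never their product): per-marker tallies are
accumulated line by line and genotype columns are never stored.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence, TextIO

import numpy as np

__all__ = [
    "MISSING_CODE",
    "SubjectRecord",
    "GenotypeTally",
    "PedFormatError",
    "MultiAllelicError",
    "MonomorphicMarkerError",
    "determine_minor_allele",
    "classify_genotype",
    "scan_ped",
    "write_ped",
    "iter_subject_rows",
    "PedScan",
]

#: Genotype code reserved for missing genotypes (the other codes are the
#: minor-allele dosage 0, 1, 2).
MISSING_CODE = 3

_VALID_ALLELES = frozenset(range(5))  # 0 = missing, 1..4 = A,C,G,T


class PedFormatError(ValueError):
    """Malformed pedigree file (ragged line, bad token, bad header...)."""


class MultiAllelicError(PedFormatError):
    """A marker carries more than two distinct non-missing alleles."""


class MonomorphicMarkerError(PedFormatError):
    """A marker has fewer than two observed alleles, so no minor allele exists."""


@dataclass(frozen=True)
class SubjectRecord:
    """The six leading pedigree columns of one subject line."""

    pedigree_id: str
    subject_id: str
    father_id: str
    mother_id: str
    sex: int        # 1 male, 2 female
    affection: int  # 0 unknown, 1 unaffected, 2 affected


@dataclass(frozen=True)
class GenotypeTally:
    """Per-marker genotype counts plus the allele orientation.

    These counts are exactly the quantities the size formulas of the
    index-based codecs consume: the number of rare-homozygous subjects,
    heterozygous subjects and subjects with a missing genotype. The
    remaining ``n_subjects - (n_rare_homo + n_heter + n_missing)`` subjects
    carry the common-homozygous (default) genotype.
    """

    n_rare_homo: int
    n_heter: int
    n_missing: int
    minor_allele: int
    major_allele: int
    n_subjects: int

    def __post_init__(self) -> None:
        if min(self.n_rare_homo, self.n_heter, self.n_missing) < 0:
            raise ValueError("tally counts must be non-negative")
        if self.n_rare_homo + self.n_heter + self.n_missing > self.n_subjects:
            raise ValueError("tally counts exceed the number of subjects")
        if self.minor_allele == self.major_allele:
            raise ValueError("minor and major allele must differ")
        for a in (self.minor_allele, self.major_allele):
            if a not in (1, 2, 3, 4):
                raise ValueError(f"allele code {a} outside 1..4")

    @property
    def n_common_homo(self) -> int:
        return self.n_subjects - self.n_rare_homo - self.n_heter - self.n_missing


class PedScan(NamedTuple):
    subjects: list[SubjectRecord]
    tallies: list[GenotypeTally]
    marker_names: list[str]


def determine_minor_allele(allele_counts: dict[int, int]) -> tuple[int, int]:
    """Resolve the minor and major allele from non-missing allele counts.

    The allele with the strictly smaller count is minor; on a tie the
    smaller numeric code is minor. Code 0 (missing) never participates.

    Raises
    ------
    MultiAllelicError
        If more than two non-missing alleles have positive counts.
    MonomorphicMarkerError
        If fewer than two non-missing alleles are observed.
    """
    observed = sorted((a, c) for a, c in allele_counts.items() if a != 0 and c > 0)
    for a, _ in observed:
        if a not in _VALID_ALLELES:
            raise PedFormatError(f"allele code {a} outside 0..4")
    if len(observed) > 2:
        raise MultiAllelicError(
            f"marker is multi-allelic: alleles {[a for a, _ in observed]} observed"
        )
    if len(observed) < 2:
        raise MonomorphicMarkerError(
            "marker is monomorphic or entirely missing: no minor allele can be defined"
        )
    (a1, c1), (a2, c2) = observed
    # tie -> smaller code is minor; observed is sorted by code already
    if c2 < c1:
        return a2, a1
    return a1, a2


def classify_genotype(a1: int, a2: int, minor: int) -> int:
    """Map an allele pair to its minor-allele dosage code (3 = missing).

    A half-missing genotype (exactly one allele 0) is treated as fully
    missing; PED defines only the fully missing genotype ``0 0``.
    """
    if a1 not in _VALID_ALLELES or a2 not in _VALID_ALLELES:
        raise PedFormatError(f"allele codes ({a1}, {a2}) outside 0..4")
    if minor not in (1, 2, 3, 4):
        raise ValueError("minor allele must be in 1..4")
    if a1 == 0 or a2 == 0:
        return MISSING_CODE
    return int(a1 == minor) + int(a2 == minor)


def _open_maybe(path_or_stream) -> tuple[TextIO, bool]:
    if isinstance(path_or_stream, (str, Path)):
        return open(path_or_stream, "r", encoding="ascii"), True
    return path_or_stream, False


def _parse_subject_cols(tokens: Sequence[str], lineno: int) -> SubjectRecord:
    try:
        sex = int(tokens[4])
        affection = int(tokens[5])
    except ValueError as exc:
        raise PedFormatError(
            f"line {lineno}: non-numeric sex/affection column: {exc}"
        ) from None
    return SubjectRecord(tokens[0], tokens[1], tokens[2], tokens[3], sex, affection)


def _parse_alleles(tokens: Sequence[str], n_markers: int, lineno: int) -> np.ndarray:
    try:
        alleles = np.array(tokens, dtype=np.int16).reshape(n_markers, 2)
    except ValueError:
        raise PedFormatError(f"line {lineno}: non-numeric allele token") from None
    if alleles.min() < 0 or alleles.max() > 4:
        bad = alleles[(alleles < 0) | (alleles > 4)][0]
        raise PedFormatError(f"line {lineno}: allele code {bad} outside 0..4")
    return alleles


def iter_subject_rows(path_or_stream) -> Iterator[tuple[SubjectRecord, np.ndarray]]:
    """Yield ``(SubjectRecord, alleles)`` per subject line.

    ``alleles`` has shape ``(n_markers, 2)``. The marker-name header line is
    consumed first. This is the streaming primitive behind both scan passes.
    """
    stream, owned = _open_maybe(path_or_stream)
    try:
        header = stream.readline()
        if not header.strip():
            raise PedFormatError("empty file or blank header line")
        n_markers = len(header.split())
        for lineno, line in enumerate(stream, start=2):
            tokens = line.split()
            if not tokens:
                continue  # tolerate trailing blank lines
            if len(tokens) != 6 + 2 * n_markers:
                raise PedFormatError(
                    f"line {lineno}: expected {6 + 2 * n_markers} columns "
                    f"(6 + 2 x {n_markers} markers), found {len(tokens)}"
                )
            subject = _parse_subject_cols(tokens[:6], lineno)
            alleles = _parse_alleles(tokens[6:], n_markers, lineno)
            yield subject, alleles
    finally:
        if owned:
            stream.close()


def read_marker_names(path_or_stream) -> list[str]:
    stream, owned = _open_maybe(path_or_stream)
    try:
        header = stream.readline()
        if not header.strip():
            raise PedFormatError("empty file or blank header line")
        return header.split()
    finally:
        if owned:
            stream.close()


def scan_ped(path_or_stream) -> PedScan:
    """Single pass over a PED file producing subjects and per-marker tallies.

    This is the counting pass of the two-pass compressor: it resolves each
    marker's minor/major allele and the genotype-class counts without ever
    holding a subject-by-marker matrix in memory.
    """
    if isinstance(path_or_stream, (str, Path)):
        marker_names = read_marker_names(path_or_stream)
        rows = iter_subject_rows(path_or_stream)
    else:
        text = path_or_stream.read()
        marker_names = read_marker_names(io.StringIO(text))
        rows = iter_subject_rows(io.StringIO(text))

    m = len(marker_names)
    allele_counts = np.zeros((m, 5), dtype=np.int64)   # per allele code 0..4
    homo_counts = np.zeros((m, 5), dtype=np.int64)     # homozygous per allele
    n_heter = np.zeros(m, dtype=np.int64)
    n_missing = np.zeros(m, dtype=np.int64)

    subjects: list[SubjectRecord] = []
    seen_ids: set[tuple[str, str]] = set()
    half_missing = 0

    for subject, alleles in rows:
        key = (subject.pedigree_id, subject.subject_id)
        if key in seen_ids:
            warnings.warn(
                f"duplicate subject ID {subject.subject_id!r} within pedigree "
                f"{subject.pedigree_id!r}",
                stacklevel=2,
            )
        seen_ids.add(key)
        subjects.append(subject)

        a1, a2 = alleles[:, 0], alleles[:, 1]
        missing = (a1 == 0) | (a2 == 0)
        half_missing += int(np.count_nonzero((a1 == 0) ^ (a2 == 0)))
        n_missing += missing
        het = ~missing & (a1 != a2)
        n_heter += het
        hom = ~missing & (a1 == a2)
        for col in (a1, a2):
            vals = np.where(missing, 0, col)  # exclude half-missing alleles from counts
            np.add.at(allele_counts, (np.arange(m), vals), 1)
        np.add.at(homo_counts, (np.arange(m)[hom], a1[hom]), 1)

    if half_missing:
        warnings.warn(
            f"{half_missing} half-missing genotype(s) (one allele 0) treated as missing",
            stacklevel=2,
        )

    n_subjects = len(subjects)
    tallies: list[GenotypeTally] = []
    problems: list[str] = []
    for j, name in enumerate(marker_names):
        counts = {a: int(allele_counts[j, a]) for a in range(1, 5)}
        try:
            minor, major = determine_minor_allele(counts)
        except MonomorphicMarkerError:
            problems.append(name)
            continue
        except MultiAllelicError as exc:
            raise MultiAllelicError(f"marker {name!r}: {exc}") from None
        tallies.append(
            GenotypeTally(
                n_rare_homo=int(homo_counts[j, minor]),
                n_heter=int(n_heter[j]),
                n_missing=int(n_missing[j]),
                minor_allele=minor,
                major_allele=major,
                n_subjects=n_subjects,
            )
        )
    if problems:
        raise MonomorphicMarkerError(
            "monomorphic or all-missing marker(s) cannot be compressed: "
            + ", ".join(problems)
        )
    return PedScan(subjects, tallies, marker_names)


def write_ped(
    subjects: Sequence[SubjectRecord],
    marker_names: Sequence[str],
    genotype_codes: np.ndarray,
    minor_alleles: Sequence[int],
    major_alleles: Sequence[int],
    out_stream,
) -> None:
    """Write a PED file from dosage codes, the lossless inverse of scanning.

    ``genotype_codes`` has shape ``(n_subjects, n_markers)``. Heterozygotes
    are emitted minor-allele-first (PED carries no phase; one order is fixed
    so output is byte-identical on repeat). Code 3 becomes ``0 0``.
    """
    codes = np.asarray(genotype_codes)
    n, m = codes.shape
    if n != len(subjects) or m != len(marker_names):
        raise ValueError(
            f"genotype matrix {codes.shape} does not match "
            f"{len(subjects)} subjects x {len(marker_names)} markers"
        )
    if len(minor_alleles) != m or len(major_alleles) != m:
        raise ValueError("allele lists must have one entry per marker")
    if codes.size and (codes.min() < 0 or codes.max() > 3):
        raise ValueError("genotype codes must be in {0,1,2,3}")

    minor = np.asarray(minor_alleles, dtype=np.int16)
    major = np.asarray(major_alleles, dtype=np.int16)
    # code -> allele pair, per marker: 0 -> (maj, maj), 1 -> (min, maj),
    # 2 -> (min, min), 3 -> (0, 0)
    first = np.empty((4, m), dtype=np.int16)
    second = np.empty((4, m), dtype=np.int16)
    first[0], second[0] = major, major
    first[1], second[1] = minor, major
    first[2], second[2] = minor, minor
    first[3], second[3] = 0, 0

    out_stream.write(" ".join(marker_names) + "\n")
    cols = np.arange(m)
    for i, s in enumerate(subjects):
        c = codes[i]
        pair = np.empty(2 * m, dtype=np.int16)
        pair[0::2] = first[c, cols]
        pair[1::2] = second[c, cols]
        out_stream.write(
            f"{s.pedigree_id} {s.subject_id} {s.father_id} {s.mother_id} "
            f"{s.sex} {s.affection} " + " ".join(map(str, pair)) + "\n"
        )
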