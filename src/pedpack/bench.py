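"""Storage-performance profiles: payload size versus MAF and cohort size.

All accounting is against the PED text baseline of 4 bytes per genotype
("allele space allele space"), so for one marker and n subjects the
baseline is 4n bytes; a 2-bit dense encoding is then exactly a factor 16.
Two modes everywhere:

* ``expected`` — deterministic: genotype-class counts are the rounded HWE
  expectations at each MAF (no missingness). Suitable as a regression
  fixture; this is the default.
* ``simulated`` — genotypes are actually drawn, tallied and encoded
  (seeded). Converges to expected mode as n grows.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import codec, simulator
from .codec import Method
from .container import PED_BYTES_PER_GENOTYPE, CompressionSummary
from .ped_io import GenotypeTally

__all__ = [
    "ProfileRow",
    "RareVariantSummary",
    "compression_profile",
    "subjects_profile",
    "rare_variant_summary",
    "profile_frame",
]

BITS_PER_GENOTYPE_BASELINE = 8 * PED_BYTES_PER_GENOTYPE  # 32 bits of PED text


@dataclass(frozen=True)
class ProfileRow:
    """Sizes of all three encodings for one (MAF, n) point, plus the pick."""

    maf: float
    n_subjects: int
    size_sub1: int
    size_sub2: int
    size_sub3: int
    selected: Method

    @property
    def selected_size(self) -> int:
        return {
            Method.SUB1: self.size_sub1,
            Method.SUB2: self.size_sub2,
            Method.SUB3: self.size_sub3,
        }[self.selected]

    @property
    def bits_per_genotype(self) -> float:
        return 8.0 * self.selected_size / self.n_subjects

    @property
    def factor(self) -> float:
        # baseline 32 bits/genotype => factor * bits_per_genotype == 32
        return BITS_PER_GENOTYPE_BASELINE / self.bits_per_genotype


def _tally_for(
    n: int, q: float, mode: str, rng: np.random.Generator | None
) -> GenotypeTally:
    if mode == "expected":
        return simulator.expected_tally(n, q)
    if mode != "simulated":
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        raise ValueError("simulated mode requires a seed")
    codes = simulator.simulate_genotype_codes(n, np.array([q]), rng)[0]
    return GenotypeTally(
        n_rare_homo=int((codes == 2).sum()),
        n_heter=int((codes == 1).sum()),
        n_missing=0,
        minor_allele=1,
        major_allele=2,
        n_subjects=n,
    )


def _row(n: int, q: float, tally: GenotypeTally) -> ProfileRow:
    sizes = {m: codec.payload_size(m, n, tally) for m in Method}
    return ProfileRow(
        maf=q,
        n_subjects=n,
        size_sub1=sizes[Method.SUB1],
        size_sub2=sizes[Method.SUB2],
        size_sub3=sizes[Method.SUB3],
        selected=codec.select_method(n, tally),
    )


def compression_profile(
    n_subjects: int,
    maf_grid: Iterable[float],
    mode: str = "expected",
    seed: int | None = None,
) -> list[ProfileRow]:
    """One :class:`ProfileRow` per MAF at fixed cohort size."""
    grid = [float(q) for q in maf_grid]
    if not grid or any(not (0 < q <= 0.5) for q in grid):
        raise ValueError("MAF grid values must lie in (0, 0.5]")
    rng = np.random.default_rng(seed) if seed is not None else None
    return [_row(n_subjects, q, _tally_for(n_subjects, q, mode, rng)) for q in grid]


def subjects_profile(
    maf: float,
    n_grid: Iterable[int],
    mode: str = "expected",
    seed: int | None = None,
) -> list[ProfileRow]:
    """One :class:`ProfileRow` per cohort size at fixed MAF.

    Cohort sizes below 100 are rejected: with a handful of subjects the
    byte-padding term dominates every formula and the profile is not
    meaningful.
    """
    sizes = [int(n) for n in n_grid]
    if not sizes or any(n < 100 for n in sizes):
        raise ValueError("cohort sizes must be >= 100")
    if not (0 < maf <= 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    rng = np.random.default_rng(seed) if seed is not None else None
    return [_row(n, maf, _tally_for(n, maf, mode, rng)) for n in sizes]


def profile_frame(rows: Sequence[ProfileRow]) -> pd.DataFrame:
    """Profile rows as a DataFrame (TSV-ready), derived columns included."""
    df = pd.DataFrame([asdict(r) for r in rows])
    df["selected"] = [r.selected.name for r in rows]
    df["selected_size"] = [r.selected_size for r in rows]
    df["bits_per_genotype"] = [r.bits_per_genotype for r in rows]
    df["factor"] = [r.factor for r in rows]
    return df


@dataclass(frozen=True)
class RareVariantSummary:
    """End-to-end result of compressing a simulated rare-variant dataset."""

    summary: CompressionSummary
    avg_maf: float
    fraction_sub2: float

    @property
    def compression_factor(self) -> float:
        return self.summary.compression_factor

    @property
    def bits_per_genotype(self) -> float:
        return self.summary.bits_per_genotype


def rare_variant_summary(
    n_subjects: int,
    n_markers: int,
    params: simulator.WrightParams | None = None,
    seed: int = 0,
    chunk_markers: int = 2000,
) -> RareVariantSummary:
    """Simulate a Wright-spectrum dataset, compress every marker, account.

    MAFs are drawn from the truncated Wright density, genotypes under HWE,
    and each marker is run through method selection and the real encoder;
    the reported factor is (4 bytes x n x m) over the summed payload bytes.
    Markers are processed in chunks so memory stays modest at large m; the
    genotype text form is never materialized (the container round-trip is
    exercised at small scale in the test suite instead).
    """
    params = (params or simulator.WrightParams()).resolved(n_subjects)
    rng = np.random.default_rng(seed)
    mafs = simulator.sample_wright_mafs(params, n_markers, rng)

    payload_bytes = 0
    method_counts = {m: 0 for m in Method}
    for lo in range(0, n_markers, chunk_markers):
        chunk = mafs[lo : lo + chunk_markers]
        codes = simulator.simulate_genotype_codes(n_subjects, chunk, rng)
        homo = (codes == 2).sum(axis=1)
        het = (codes == 1).sum(axis=1)
        miss = np.zeros_like(homo)
        s1, s2, s3 = codec.payload_sizes_from_counts(n_subjects, homo, het, miss)
        for k in range(chunk.size):
            tally = (int(homo[k]), int(het[k]), int(miss[k]))
            method = codec.select_method(n_subjects, tally)
            payload = codec.encode_marker(method, codes[k])
            assert len(payload.data) == min(s1[k], s2[k], s3[k])
            payload_bytes += len(payload.data)
            method_counts[method] += 1

    summary = CompressionSummary(
        n_subjects=n_subjects,
        n_markers=n_markers,
        method_counts=method_counts,
        payload_bytes=payload_bytes,
        original_ped_bytes=0,  # text form not written at this scale
        overhead_bytes=0,
    )
    return RareVariantSummary(
        summary=summary,
        avg_maf=float(mafs.mean()),
        fraction_sub2=method_counts[Method.SUB2] / n_markers,
    )
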