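"""Synthetic PED generation: HWE genotypes at controlled allele frequencies.

Two layers. First, minor allele frequencies (MAFs): either fixed values, an
explicit per-marker list, or draws from the stationary allele-frequency
density of a Wright-Fisher population under mutation and directional
selection,

    f(p) ∝ p^(βs−1) · (1−p)^(βn−1) · e^(σ(1−p)),

with scaled mutation rates βs (default 0.001), βn (default βs/3) and
selection rate σ (default 12). With these defaults the density spikes at
p → 0 like p^(-0.999), i.e. the spectrum is overwhelmingly rare variants —
the regime sequencing studies produce. Draws are truncated to
[maf_floor, 0.5]; the floor defaults to 1/(2·n_subjects), the smallest
frequency a polymorphic sample of n diploid subjects can exhibit.

Second, genotypes: per subject i.i.d. under Hardy-Weinberg equilibrium with
probabilities ((1−q)², 2q(1−q), q²) for MAF q — equivalently a Binomial(2,q)
dosage draw — plus optional independent missingness. Markers that come out
monomorphic in the realized sample are redrawn at the same q, since the
codecs require a defined minor allele. The minor allele is written as code
1 and the major as code 2.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from . import ped_io
from .ped_io import MISSING_CODE, GenotypeTally, SubjectRecord

__all__ = [
    "WrightParams",
    "SimConfig",
    "wright_density",
    "sample_wright_mafs",
    "simulate_genotype_codes",
    "simulate_ped",
    "expected_tally",
    "make_subjects",
]


@dataclass(frozen=True)
class WrightParams:
    """Parameters of the truncated stationary allele-frequency density."""

    beta_s: float = 0.001
    beta_n: float | None = None  # defaults to beta_s / 3
    sigma: float = 12.0
    maf_floor: float | None = None  # defaults to 1/(2 n_subjects) at use site
    maf_ceiling: float = 0.5
    grid_points: int = 10_000

    def __post_init__(self) -> None:
        if self.beta_s <= 0:
            raise ValueError("beta_s must be positive")
        if self.beta_n is not None and self.beta_n <= 0:
            raise ValueError("beta_n must be positive")
        if not (0 < self.maf_ceiling <= 0.5):
            raise ValueError("maf_ceiling must be in (0, 0.5]")
        if self.maf_floor is not None and not (0 < self.maf_floor < self.maf_ceiling):
            raise ValueError("need 0 < maf_floor < maf_ceiling")

    @property
    def beta_n_value(self) -> float:
        return self.beta_s / 3 if self.beta_n is None else self.beta_n

    def resolved(self, n_subjects: int) -> "WrightParams":
        """Fill the default truncation floor 1/(2·n_subjects)."""
        if self.maf_floor is not None:
            return self
        return replace(self, maf_floor=1.0 / (2 * n_subjects))


def wright_density(p, params: WrightParams) -> np.ndarray | float:
    """Unnormalized density p^(βs−1)·(1−p)^(βn−1)·e^(σ(1−p)) on (0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("allele frequency must lie strictly inside (0, 1)")
    out = (
        arr ** (params.beta_s - 1)
        * (1 - arr) ** (params.beta_n_value - 1)
        * np.exp(params.sigma * (1 - arr))
    )
    return out if isinstance(p, np.ndarray) else float(out)


def _grid_cdf(params: WrightParams) -> tuple[np.ndarray, np.ndarray]:
    if params.maf_floor is None:
        raise ValueError("maf_floor unresolved; call WrightParams.resolved(n) first")
    if params.maf_floor >= params.maf_ceiling:
        raise ValueError("degenerate truncation interval")
    grid = np.logspace(
        np.log10(params.maf_floor), np.log10(params.maf_ceiling), params.grid_points
    )
    dens = wright_density(grid, params)
    seg = 0.5 * (dens[1:] + dens[:-1]) * np.diff(grid)  # trapezoid mass per cell
    cdf = np.concatenate([[0.0], np.cumsum(seg)])
    return grid, cdf / cdf[-1]


def sample_wright_mafs(
    params: WrightParams, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``m`` i.i.d. MAFs by numerical inverse-CDF on a log-spaced grid.

    The log spacing matters: with βs ≪ 1 nearly all mass sits within a few
    orders of magnitude of the floor, where a linear grid would put almost
    no points.
    """
    if m < 1:
        raise ValueError("need at least one draw")
    grid, cdf = _grid_cdf(params)
    return np.interp(rng.random(m), cdf, grid)


MafSpec = Union[float, Sequence[float], str]


@dataclass(frozen=True)
class SimConfig:
    """One simulated dataset: cohort size, marker count, MAF source."""

    n_subjects: int
    n_markers: int
    maf_spec: MafSpec = "wright"  # a float, a per-marker list, or "wright"
    wright: WrightParams = WrightParams()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")

    def marker_mafs(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.maf_spec, str):
            if self.maf_spec != "wright":
                raise ValueError(f"unknown maf_spec {self.maf_spec!r}")
            return sample_wright_mafs(
                self.wright.resolved(self.n_subjects), self.n_markers, rng
            )
        if np.isscalar(self.maf_spec):
            q = float(self.maf_spec)
            mafs = np.full(self.n_markers, q)
        else:
            mafs = np.asarray(self.maf_spec, dtype=float)
            if mafs.shape != (self.n_markers,):
                raise ValueError("explicit MAF list must have one entry per marker")
        if np.any(mafs <= 0) or np.any(mafs > 0.5):
            raise ValueError("MAF values must lie in (0, 0.5]")
        return mafs


def simulate_genotype_codes(
    n_subjects: int,
    mafs: np.ndarray,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
    max_redraws: int = 1000,
) -> np.ndarray:
    """HWE dosage codes, shape ``(n_markers, n_subjects)``, marker-major.

    Dosage ~ Binomial(2, q) per subject; missing genotypes (code 3) applied
    independently at ``missing_rate``. Markers whose realized sample is
    monomorphic (fewer than two distinct observed alleles) are redrawn at
    the same q so every marker has a well-defined minor allele.
    """
    mafs = np.asarray(mafs, dtype=float)
    m = mafs.size
    codes = rng.binomial(2, mafs[:, None], size=(m, n_subjects)).astype(np.uint8)
    if missing_rate > 0:
        codes[rng.random((m, n_subjects)) < missing_rate] = MISSING_CODE
    for _ in range(max_redraws):
        bad = np.flatnonzero(~_polymorphic(codes))
        if bad.size == 0:
            return codes
        redraw = rng.binomial(2, mafs[bad, None], size=(bad.size, n_subjects)).astype(np.uint8)
        if missing_rate > 0:
            redraw[rng.random((bad.size, n_subjects)) < missing_rate] = MISSING_CODE
        codes[bad] = redraw
    raise RuntimeError(
        f"{bad.size} marker(s) still monomorphic after {max_redraws} redraws; "
        "MAF or missing_rate too extreme for this cohort size"
    )


def _polymorphic(codes: np.ndarray) -> np.ndarray:
    """Markers (rows) whose non-missing genotypes show both alleles."""
    has_minor = ((codes == 1) | (codes == 2)).any(axis=1)
    has_major = ((codes == 0) | (codes == 1)).any(axis=1)
    return has_minor & has_major


def make_subjects(n: int) -> list[SubjectRecord]:
    """Unrelated founder subjects: one per pedigree, parents unknown,
    alternating sex, affection unknown."""
    return [
        SubjectRecord(f"F{i + 1}", f"S{i + 1}", "0", "0", 1 + i % 2, 0)
        for i in range(n)
    ]


def simulate_ped(config: SimConfig, out_prefix) -> tuple[Path, Path]:
    """Write ``<out_prefix>.ped`` and ``<out_prefix>.truth.tsv``.

    The PED codes the minor allele as 1 and the major as 2. The truth table
    records, per marker, the generating MAF and the realized genotype-class
    counts, which must (and, in tests, do) agree with a fresh scan of the
    emitted file. Byte-identical output for identical config + seed.
    """
    rng = np.random.default_rng(config.seed)
    mafs = config.marker_mafs(rng)
    codes = simulate_genotype_codes(
        config.n_subjects, mafs, rng, missing_rate=config.missing_rate
    )
    subjects = make_subjects(config.n_subjects)
    marker_names = [f"M{j + 1}" for j in range(config.n_markers)]

    out_prefix = Path(out_prefix)
    ped_path = Path(str(out_prefix) + ".ped")
    truth_path = Path(str(out_prefix) + ".truth.tsv")
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    with open(ped_path, "w", encoding="ascii") as fh:
        ped_io.write_ped(
            subjects,
            marker_names,
            codes.T,
            minor_alleles=[1] * config.n_markers,
            major_alleles=[2] * config.n_markers,
            out_stream=fh,
        )

    truth = pd.DataFrame(
        {
            "marker": marker_names,
            "true_maf": mafs,
            "n_rare_homo": (codes == 2).sum(axis=1),
            "n_heter": (codes == 1).sum(axis=1),
            "n_missing": (codes == MISSING_CODE).sum(axis=1),
        }
    )
    truth.to_csv(truth_path, sep="\t", index=False)
    return ped_path, truth_path


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def expected_tally(n_subjects: int, q: float) -> GenotypeTally:
    """Deterministic rounded-HWE tally at MAF ``q``: the noise-free stand-in
    for a simulated marker (no missingness), used by the benchmark's
    expected mode. Rounding is half-away-from-zero."""
    if not (0 < q <= 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    return GenotypeTally(
        n_rare_homo=_round_half_away(n_subjects * q * q),
        n_heter=_round_half_away(n_subjects * 2 * q * (1 - q)),
        n_missing=0,
        minor_allele=1,
        major_allele=2,
        n_subjects=n_subjects,
    )
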