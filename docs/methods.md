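# Methods

## The storage problem

A PED text file spends 4 bytes per genotype ("allele space allele space")
regardless of content. For sequencing-scale panels — millions of mostly rare
variants — almost every genotype is the common homozygote, so the text form
is overwhelmingly redundant. `pedpack` stores each biallelic marker under
whichever of three encodings is smallest *for that marker's genotype
counts*, computable in closed form before any encoding work.

Every genotype is first reduced to a minor-allele dosage code: 0, 1 or 2
copies of the minor allele, or 3 for missing. The minor allele is the one
with the strictly smaller count over non-missing genotypes (tie: smaller
numeric code).

## The three encodings and their exact sizes

Let `n` be the number of subjects, `#Homo`, `#Heter`, `#Missing` the counts
of rare-homozygous, heterozygous and missing genotypes at one marker, and

    w = ceil(log2(n + 1))

the index width: the number of bits needed to hold any subject index *or*
any count in `0..n` (the `+1` matters — a count field can equal `n`; for
n = 1000, w = 10). All payloads are padded to whole bytes so a container
can seek marker by marker.

| method | layout | size (bytes) |
|--------|--------|--------------|
| SUB1 | dense 2-bit codes, 4 genotypes/byte | `ceil(2n / 8)` |
| SUB2 | three w-bit counts, each followed by the w-bit indices of its carriers (homo, heter, missing) | `ceil(w (#Homo + #Heter + #Missing + 3) / 8)` |
| SUB3 | as SUB2 for homo + missing, heterozygotes as an n-bit bit-vector | `ceil((w (#Homo + #Missing + 2) + n) / 8)` |

Subjects not listed in any index set (and with heterozygote bit 0 for SUB3)
decode to the common-homozygous genotype — the default that makes sparse
coding pay. Selection takes the minimum of the three sizes; ties prefer the
simpler decoder (SUB1 < SUB2 < SUB3).

Under Hardy–Weinberg genotype proportions at n = 1000 this yields the
expected regimes: SUB2 wins below MAF ≈ 0.05 (factor ≥ 30 versus the
4-byte baseline, under 1 bit/genotype), SUB3 wins in the mid band
(factor ≈ 16–30), and SUB1's flat 250 bytes (factor 16, 2 bits/genotype)
wins from MAF ≈ 0.35 up. The SUB3/SUB1 crossover sits slightly above 0.3:
at MAF 0.31 the hybrid still saves 2 bytes (248 vs 250).

### Bit-layout conventions

The exact binary layout of the original implementation of this scheme is
unpublished, so one convention is fixed and documented rather than claimed
compatible with anything: MSB-first bits within each byte (subject 0 of a
SUB1 payload in the top 2 bits of byte 0; bit i of the SUB3 heterozygote
vector at the MSB end of its byte), 0-based subject indices in strictly
ascending order, zero padding in the low bits of the final byte. Ascending
indices make corruption detectable (decode rejects out-of-range, duplicate
or non-ascending indices and any payload whose self-described fields
disagree with its byte length). Note PLINK's `.bed` packs low-bits-first;
the two are deliberately not byte-compatible.

## Container

`<prefix>.sgbin`: 32-byte little-endian header (magic, version, n_subjects,
n_markers, index_offset), concatenated payloads in marker order, then a
per-marker index (name, method, alleles, tally, offset, length). The index
sits at the end so pass 2 can stream payloads; the header's `index_offset`
is patched last, so an interrupted write is detectable (offset 0).
`<prefix>.sgtxt`: human-readable sidecar with the subject table and a
marker summary; read-back cross-checks it against the binary header.

Compression is two passes over the PED file: pass 1 tallies genotype
classes per marker (memory `O(n_subjects + n_markers)`, never the product)
and fixes each marker's method; pass 2 re-reads subject by subject,
appending carrier indices for index-coded markers and OR-ing 2-bit codes
into place for dense markers — peak memory is the compressed size plus the
per-line buffers.

Compression factors are always quoted as *genotype payload only* against
the 4-bytes-per-genotype PED baseline (so 1000 genotypes = 4000 bytes, and
`factor × bits_per_genotype = 32` exactly); header, index and sidecar bytes
are reported separately as overhead. This keeps the factor well-defined and
independent of marker-name lengths.

## Queries and partial loading

The loaded store never expands to text-scale memory: dense markers stay
2-bit packed with direct bit addressing (O(1) genotype lookup), index-coded
markers stay as ascending carrier sets (binary-search lookup, direct
carrier retrieval with no per-subject scan). Carrier sets are the natural
hook for permutation-based association tests: permuting subject labels is
the same as mapping the stored index sets through the permutation.

Partial loading is by contiguous half-open marker range `[start, end)`,
seeking via the index and reading only those payload bytes; range loads are
independent and jointly consistent with a full load, which is the contract
parallel jobs rely on. Queries outside the loaded range raise rather than
returning the default genotype. Marker ranges (not subject ranges or
arbitrary subsets) were chosen because the payload layout is marker-major.

## Synthetic data

The simulator writes PED files with unrelated founder subjects and i.i.d.
Hardy–Weinberg genotypes: dosage ~ Binomial(2, q) per subject at MAF q,
optional independent missingness, minor allele coded 1 and major 2.
Markers whose realized sample is monomorphic are redrawn at the same q
(the codec requires a defined minor allele); at tiny q this conditions
mildly on segregation. Fully deterministic given a seed.

MAF spectra for rare-variant experiments come from the stationary
allele-frequency density of a Wright–Fisher population under mutation and
selection,

    f(p) ∝ p^(βs−1) (1−p)^(βn−1) e^(σ(1−p)),

with defaults βs = 0.001, βn = βs/3, σ = 12. Sampling is by numerical
inverse-CDF on a log-spaced grid (default 10⁴ points) — with βs ≪ 1 the
density spikes as p^(−0.999) near 0, where a linear grid or rejection
sampling would be hopeless — truncated to `[maf_floor, 0.5]` with
`maf_floor = 1/(2 n_subjects)` by default (the smallest MAF a polymorphic
sample can exhibit). The sampler is validated against a trapezoid-integrated
CDF on an independent finer grid (KS distance at 10⁵ draws).

**Truncation sensitivity.** The mean of the truncated density is dominated
by mass piled against the floor: with floor 1/2000 the mean MAF is ≈ 0.02,
with floor 10⁻⁵ it would be several-fold smaller. Consequently aggregate
numbers for "a Wright-spectrum dataset" — average MAF, end-to-end
compression factor — are only defined once a truncation convention is
fixed, and are reproducible to order of magnitude, not digit-for-digit,
across conventions. With the default floor, a 50 000-marker × 1000-subject
dataset compresses at a factor ≈ 100 (≈ 0.32 bits/genotype, ≥ 90% of
markers via SUB2); a spectrum with mean MAF ≈ 0.005 (a lower floor or
harsher conditioning) would compress at ≈ 200–230. The generator's stated
world is not tuned to hit any particular figure; `tests/test_acceptance.py`
records the discrepancy openly.

What a green simulator-backed test does *not* establish: realism w.r.t.
linkage disequilibrium (markers are independent), family structure
(founders only), genotype-error or call-rate patterns, or selection—
demography beyond the stated density.

The benchmark module's "expected" mode replaces simulation by rounded HWE
counts (`round(nq²)`, `round(2nq(1−q))`, no missingness; rounding
half-away-from-zero so results are deterministic) and is the regression
fixture; "simulated" mode draws genotypes and converges to it as n grows.

## Numerical and degenerate-input choices

- Half-missing genotypes (exactly one allele 0) are treated as fully
  missing, with a warning; PED defines only `0 0`. Their non-missing allele
  is excluded from allele counting.
- Monomorphic or all-missing markers abort compression with the offending
  marker names; silently inventing a minor allele would corrupt downstream
  frequency arithmetic.
- Multi-allelic markers are rejected by name (the codecs are biallelic by
  construction).
- Heterozygotes are written minor-allele-first on output; PED carries no
  phase, and a fixed order makes round trips byte-stable.
- Tokens may be separated by any run of spaces/tabs; alleles must be the
  numeric codes 0–4 (letter alleles are out of scope).
- MAF per marker is `(2·#Homo + #Heter) / (2·(n − #Missing))`; an
  all-missing marker has no defined frequency and raises.

## Known limitations

- The first line must be a marker-name header (the dialect shown in the
  formats this tool targets); canonical header-less PED is not auto-detected
  — such a file fails fast with a column-count parse error on line 2.
- No VCF ingestion, phasing, indels, or X-chromosome handling; no appending
  to an existing container; no concurrent writers.
- Decompression materializes the full dosage matrix (n × m bytes) before
  writing text; fine at the scales the text form itself is practical.
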