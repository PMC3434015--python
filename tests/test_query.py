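import numpy as np
import pytest

from pedpack import codec, container, ped_io, query
from tests.conftest import make_random_ped


@pytest.fixture
def store_and_truth(compressed_prefix):
    prefix, ped_path, _ = compressed_prefix
    store = query.load(prefix)
    # oracle: genotype codes parsed straight from the source PED text
    scan = ped_io.scan_ped(ped_path)
    codes = np.empty((len(scan.subjects), len(scan.marker_names)), dtype=np.uint8)
    for i, (_, alleles) in enumerate(ped_io.iter_subject_rows(ped_path)):
        for j, t in enumerate(scan.tallies):
            codes[i, j] = ped_io.classify_genotype(
                int(alleles[j, 0]), int(alleles[j, 1]), t.minor_allele
            )
    return store, codes, scan


class TestGenotypeQueries:
    def test_every_cell_matches_source_ped(self, store_and_truth):
        store, codes, _ = store_and_truth
        n, m = codes.shape
        for i in range(n):
            for j in range(m):
                assert store.genotype_at(i, j) == codes[i, j]

    def test_vector_matches_decode(self, store_and_truth):
        store, codes, _ = store_and_truth
        for j in range(codes.shape[1]):
            assert np.array_equal(store.genotype_vector(j), codes[:, j])

    def test_out_of_range_indices_raise(self, store_and_truth):
        store, codes, _ = store_and_truth
        with pytest.raises(IndexError):
            store.genotype_at(codes.shape[0], 0)
        with pytest.raises(IndexError):
            store.genotype_at(0, codes.shape[1])


class TestCarriers:
    def test_set_sizes_equal_tallies(self, store_and_truth):
        store, _, scan = store_and_truth
        for j, t in enumerate(scan.tallies):
            sets = store.carriers(j)
            assert sets.rare_homo_indices.size == t.n_rare_homo
            assert sets.heter_indices.size == t.n_heter
            assert sets.missing_indices.size == t.n_missing

    def test_sets_partition_subjects(self, store_and_truth):
        store, codes, _ = store_and_truth
        n = codes.shape[0]
        for j in range(codes.shape[1]):
            sets = store.carriers(j)
            listed = np.concatenate(
                [sets.rare_homo_indices, sets.heter_indices, sets.missing_indices]
            )
            assert listed.size == np.unique(listed).size  # pairwise disjoint
            defaults = np.setdiff1d(np.arange(n), listed)
            assert listed.size + defaults.size == n
            assert np.all(codes[defaults, j] == 0)

    def test_all_default_marker_has_empty_sets(self, tmp_path):
        # one heterozygote keeps the marker polymorphic; remove it via SUB2
        payload = codec.encode_from_carriers(codec.Method.SUB2, 9, [], [], [])
        homo, het, miss = codec.decode_carriers(payload)
        assert homo.size == het.size == miss.size == 0

    def test_permutation_of_subjects_permutes_carrier_sets(self, store_and_truth):
        """Relabelling subjects then re-querying equals mapping the stored
        index sets through the permutation — the hook that makes
        permutation-based association tests cheap on this layout."""
        store, codes, _ = store_and_truth
        rng = np.random.default_rng(3)
        perm = rng.permutation(codes.shape[0])  # new label of each subject
        j = 1
        direct = store.carriers(j)
        permuted_codes = np.empty_like(codes[:, j])
        permuted_codes[perm] = codes[:, j]
        re_encoded = codec.encode_marker(codec.Method.SUB2, permuted_codes)
        homo, het, miss = codec.decode_carriers(re_encoded)
        assert np.array_equal(homo, np.sort(perm[direct.rare_homo_indices]))
        assert np.array_equal(het, np.sort(perm[direct.heter_indices]))
        assert np.array_equal(miss, np.sort(perm[direct.missing_indices]))


class TestMarkerMaf:
    def test_arithmetic(self, store_and_truth):
        store, _, scan = store_and_truth
        for j, t in enumerate(scan.tallies):
            expect = (2 * t.n_rare_homo + t.n_heter) / (2 * (t.n_subjects - t.n_missing))
            assert store.marker_maf(j) == pytest.approx(expect)
            assert 0 <= store.marker_maf(j) <= 0.5

    def test_recovers_generating_maf_at_large_n(self, tmp_path):
        from pedpack import simulator

        config = simulator.SimConfig(4000, 1, maf_spec=0.1, seed=6)
        ped_path, _ = simulator.simulate_ped(config, tmp_path / "big")
        prefix = tmp_path / "big"
        container.compress_ped(ped_path, prefix)
        store = query.load(prefix)
        # sd of the allele-frequency estimate: sqrt(q(1-q)/2n) ~ 0.0034
        assert abs(store.marker_maf(0) - 0.1) < 5 * 0.0034


class TestPartialLoading:
    def test_full_range_equals_default_load(self, compressed_prefix):
        prefix, _, summary = compressed_prefix
        full = query.load(prefix)
        ranged = query.load(prefix, (0, summary.n_markers))
        for j in range(summary.n_markers):
            assert np.array_equal(full.genotype_vector(j), ranged.genotype_vector(j))

    @pytest.mark.parametrize("split_seed", [0, 1, 2, 3])
    def test_partition_consistency(self, compressed_prefix, split_seed):
        """Two disjoint range loads jointly answer every query exactly as a
        full load — the contract parallel jobs rely on."""
        prefix, _, summary = compressed_prefix
        m = summary.n_markers
        k = int(np.random.default_rng(split_seed).integers(1, m))
        full = query.load(prefix)
        left = query.load(prefix, (0, k))
        right = query.load(prefix, (k, m))
        for j in range(m):
            part = left if j < k else right
            assert np.array_equal(full.genotype_vector(j), part.genotype_vector(j))
            assert part.marker_maf(j) == full.marker_maf(j)

    def test_partial_load_reads_only_requested_bytes(self, compressed_prefix):
        prefix, _, summary = compressed_prefix
        full = query.load(prefix)
        _, records, _ = container.read_index(prefix)
        one = query.load(prefix, (4, 5))
        assert one.bytes_read == records[4].payload_length
        assert one.bytes_read < full.bytes_read
        assert full.bytes_read == summary.payload_bytes

    def test_queries_outside_range_fail_loudly(self, compressed_prefix):
        prefix, _, summary = compressed_prefix
        store = query.load(prefix, (2, 5))
        with pytest.raises(IndexError):
            store.genotype_at(0, 1)
        with pytest.raises(IndexError):
            store.carriers(summary.n_markers - 1)

    def test_range_out_of_bounds_rejected(self, compressed_prefix):
        prefix, _, summary = compressed_prefix
        with pytest.raises(IndexError):
            query.load(prefix, (0, summary.n_markers + 1))


def test_one_marker_from_wide_container_reads_under_one_percent(tmp_path):
    """Loading 1 of 600 rare markers touches a sub-percent slice of payload."""
    from pedpack import simulator

    config = simulator.SimConfig(300, 600, maf_spec="wright", seed=13)
    ped_path, _ = simulator.simulate_ped(config, tmp_path / "wide")
    prefix = tmp_path / "wide"
    summary = container.compress_ped(ped_path, prefix)
    one = query.load(prefix, (300, 301))
    assert one.bytes_read / summary.payload_bytes < 0.01
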