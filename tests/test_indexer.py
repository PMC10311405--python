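"""Seed packing, hashing, and reference index construction/query."""

import numpy as np
import pytest

from squigseed.indexer import (
    IndexParams,
    ReferenceIndex,
    build_index,
    hash_seed,
    hash_seeds,
    pack_seed,
    pack_seeds,
    query_index,
)
from squigseed.pore_model import normalize_events, seq_to_events
from squigseed.quantizer import QuantizationParams, quantize_events
from tests.conftest import random_sequence


def fmix32_oracle(h: int) -> int:
    """Independent reimplementation of the MurmurHash3 finalizer from its
    published constants."""
    h &= 0xFFFFFFFF
    h ^= h >> 16
    h = (h * 0x85EBCA6B) & 0xFFFFFFFF
    h ^= h >> 13
    h = (h * 0xC2B2AE35) & 0xFFFFFFFF
    h ^= h >> 16
    return h


class TestPacking:
    def test_single_code_identity(self):
        assert pack_seed([13], width=5) == 13

    def test_bit_concatenation_example(self):
        assert pack_seed([0b0011, 0b0101], width=4) == 0b00110101 == 53

    def test_order_preservation(self):
        assert pack_seed([1, 2, 3], 4) != pack_seed([3, 2, 1], 4)

    def test_code_overflow_rejected(self):
        with pytest.raises(ValueError):
            pack_seed([16], width=4)

    def test_vectorized_matches_scalar_windows(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 32, size=50).astype(np.uint32)
        n, w = 6, 5
        vec = pack_seeds(codes, n, w)
        for i, packed in enumerate(vec.tolist()):
            assert packed == pack_seed(codes[i : i + n].tolist(), w)


class TestHashing:
    def test_known_value_against_published_constants(self):
        for x in (0, 1, 0x3FF, 123456):
            assert hash_seed(x, width=32) == fmix32_oracle(x)

    def test_bijective_on_small_width(self):
        hashes = hash_seeds(np.arange(1024, dtype=np.uint64), width=10)
        assert len(np.unique(hashes)) == 1024

    def test_deterministic(self):
        a = hash_seeds(np.arange(100, dtype=np.uint64), width=30)
        b = hash_seeds(np.arange(100, dtype=np.uint64), width=30)
        np.testing.assert_array_equal(a, b)

    def test_wide_seeds_fold_to_32_bits(self):
        rng = np.random.default_rng(1)
        packed = rng.integers(0, 2**48, size=1000, dtype=np.uint64)
        hashes = hash_seeds(packed, width=48)
        assert hashes.dtype == np.uint32

    def test_out_of_range_packed_rejected(self):
        with pytest.raises(ValueError):
            hash_seed(1 << 10, width=10)


class TestIndexParams:
    def test_packing_must_fit_64_bits(self):
        with pytest.raises(ValueError):
            IndexParams(n=14, quant=QuantizationParams(q=9, p=4))

    def test_defaults_valid(self):
        p = IndexParams()
        assert p.packed_width == 6 * 5


class TestBuildIndex:
    def test_minimal_target_has_one_forward_seed(self, model_k6):
        n, k = 6, 6
        seq = random_sequence(n + k - 1, seed=7)  # exactly n events
        idx = build_index([("t", seq)], model_k6, IndexParams(n=n))
        fwd = int(np.sum(idx.hit_strand == 0))
        assert fwd == 1
        assert idx.target_event_counts == [n]

    def test_identical_targets_share_hashes(self, model_k6):
        seq = random_sequence(500, seed=8)
        idx = build_index([("a", seq), ("b", seq)], model_k6, IndexParams())
        for h in idx.unique_hashes[:50]:
            hits = query_index(idx, int(h))
            assert {hit.target_id for hit in hits} == {"a", "b"}

    def test_every_hit_reverified_by_scratch_recomputation(self, model_k6):
        """Full recomputation pass: each stored forward-strand hit's hash
        is rebuilt from the reference events at its position using the
        scalar primitives."""
        seq = random_sequence(2000, seed=9)
        params = IndexParams()
        idx = build_index([("t", seq)], model_k6, params, mask_frac=0.0)
        es = normalize_events(seq_to_events(seq, model_k6))
        codes = quantize_events(es.values, params.quant)
        for bucket_ix in range(0, idx.n_buckets, 17):
            h = int(idx.unique_hashes[bucket_ix])
            for hit in query_index(idx, h):
                if hit.strand != "+":
                    continue
                window = codes[hit.target_pos : hit.target_pos + params.n].tolist()
                packed = pack_seed(window, params.quant.width)
                assert hash_seed(packed, params.packed_width) == h

    def test_repeated_seed_found_by_linear_scan(self, model_k6):
        """A seed hash's hit positions equal the positions found by a
        linear scan over all reference windows."""
        seq = random_sequence(3000, seed=10)
        params = IndexParams()
        idx = build_index([("t", seq)], model_k6, params, mask_frac=0.0)
        es = normalize_events(seq_to_events(seq, model_k6))
        codes = quantize_events(es.values, params.quant)
        packed = pack_seeds(codes, params.n, params.quant.width)
        hashes = hash_seeds(packed, params.packed_width)
        h = int(hashes[123])
        scan_positions = set(np.nonzero(hashes == h)[0].tolist())
        idx_positions = {
            hit.target_pos for hit in query_index(idx, h) if hit.strand == "+"
        }
        assert idx_positions == scan_positions

    def test_absent_hash_returns_empty(self, index_100k):
        present = set(index_100k.unique_hashes.tolist())
        h = next(x for x in range(1, 1 << 32) if x not in present)
        assert query_index(index_100k, h) == []

    def test_masking_suppresses_largest_buckets(self, model_k6):
        seq = random_sequence(50_000, seed=11)
        idx = build_index([("t", seq)], model_k6, IndexParams(), mask_frac=0.001)
        sizes = idx.bucket_sizes()
        assert idx.masked.sum() == round(0.001 * idx.n_buckets)
        assert sizes[idx.masked].min() >= np.percentile(sizes, 99.8)
        masked_hash = int(idx.unique_hashes[np.nonzero(idx.masked)[0][0]])
        assert query_index(idx, masked_hash) == []

    def test_self_mapping_completeness(self, model_k6):
        """Each reference position's own seed retrieves a hit at that
        position (no masking)."""
        seq = random_sequence(1500, seed=12)
        params = IndexParams()
        idx = build_index([("t", seq)], model_k6, params, mask_frac=0.0)
        es = normalize_events(seq_to_events(seq, model_k6))
        codes = quantize_events(es.values, params.quant)
        packed = pack_seeds(codes, params.n, params.quant.width)
        hashes = hash_seeds(packed, params.packed_width)
        for pos in range(0, len(hashes), 29):
            hits = query_index(idx, int(hashes[pos]))
            assert any(h.strand == "+" and h.target_pos == pos for h in hits)

    def test_empty_reference_rejected(self, model_k6):
        with pytest.raises(ValueError):
            build_index([], model_k6, IndexParams())

    def test_parameter_mismatch_detected(self, index_100k):
        other = IndexParams(n=5, quant=QuantizationParams(q=9, p=4), k=6)
        with pytest.raises(ValueError, match="mismatch"):
            index_100k.check_compatible(other)

    def test_bucket_occupancy_is_hash_uniform(self, index_100k):
        """Bucket count at each hash-space decile is within 3 sd of the
        uniform expectation (sanity check on mix quality)."""
        edges = np.linspace(0, 2**32, 11)
        counts, _ = np.histogram(index_100k.unique_hashes.astype(np.float64), bins=edges)
        expected = index_100k.n_buckets / 10
        sd = np.sqrt(expected)
        assert np.all(np.abs(counts - expected) < 3 * sd * 1.5)


class TestRoundTrip:
    def test_save_load_identity(self, index_100k, tmp_path):
        path = tmp_path / "ref.idx"
        index_100k.save(path)
        loaded = ReferenceIndex.load(path)
        assert loaded.params == index_100k.params
        assert loaded.target_ids == index_100k.target_ids
        assert loaded.target_lengths == index_100k.target_lengths
        np.testing.assert_array_equal(loaded.unique_hashes, index_100k.unique_hashes)
        np.testing.assert_array_equal(loaded.offsets, index_100k.offsets)
        np.testing.assert_array_equal(loaded.hit_tid, index_100k.hit_tid)
        np.testing.assert_array_equal(loaded.hit_pos, index_100k.hit_pos)
        np.testing.assert_array_equal(loaded.hit_strand, index_100k.hit_strand)
        np.testing.assert_array_equal(loaded.masked, index_100k.masked)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "junk.idx"
        path.write_bytes(b"NOTANIDX" + b"\x00" * 64)
        with pytest.raises(ValueError, match="magic"):
            ReferenceIndex.load(path)
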