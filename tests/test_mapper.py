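"""Anchor collection, colinear chaining, and streaming mapping decisions."""

import itertools

import numpy as np
import pytest

from squigseed.indexer import IndexParams, build_index
from squigseed.mapper import (
    Anchor,
    ChainParams,
    chain_anchors,
    chunk_signal,
    collect_anchor_list,
    map_read_streaming,
    map_signal,
)
from squigseed.pore_model import normalize_events, seq_to_events
from squigseed.signal_sim import SimParams, simulate_read
from tests.conftest import random_sequence


def brute_force_best_score(anchors: list[Anchor], params: ChainParams) -> float:
    """Exhaustive enumeration over all ordered anchor subsets respecting
    admissibility (same target/strand, strictly increasing coordinates,
    deltas bounded by max_gap), scored like the chain DP."""
    gamma = params.gap_scale * params.match_score

    def admissible(a: Anchor, b: Anchor) -> bool:
        return (
            a.target_id == b.target_id
            and a.strand == b.strand
            and 0 < b.target_pos - a.target_pos <= params.max_gap
            and 0 < b.query_idx - a.query_idx <= params.max_gap
        )

    def extend(chain_score: float, last: Anchor, remaining: list[Anchor]) -> float:
        best = chain_score
        for i, nxt in enumerate(remaining):
            if admissible(last, nxt):
                gap = gamma * abs(
                    (nxt.target_pos - last.target_pos) - (nxt.query_idx - last.query_idx)
                )
                # chain scores never go below a fresh start at nxt
                extended = max(chain_score - gap, 0.0) + params.match_score
                best = max(best, extend(extended, nxt, remaining[i + 1 :]))
        return best

    best = 0.0
    for i, a in enumerate(anchors):
        best = max(best, extend(params.match_score, a, anchors[i + 1 :]))
    return best


def random_instance(rng, n_anchors: int) -> list[Anchor]:
    anchors = {
        (
            rng.choice(["tA", "tB"]),
            rng.choice(["+", "-"]),
            int(rng.integers(0, 40)),
            int(rng.integers(0, 40)),
        )
        for _ in range(n_anchors)
    }
    return [
        Anchor(target_id=t, strand=s, target_pos=tp, query_idx=q)
        for t, s, tp, q in sorted(anchors)
    ]


class TestChaining:
    def test_single_anchor_chain(self):
        params = ChainParams()
        chains = chain_anchors([Anchor("t", "+", 5, 3)], params)
        assert len(chains) == 1
        assert chains[0].score == params.match_score

    def test_perfectly_colinear_run(self):
        params = ChainParams(match_score=2.0)
        anchors = [Anchor("t", "+", i, i) for i in range(8)]
        chains = chain_anchors(anchors, params)
        assert chains[0].score == pytest.approx(8 * 2.0)
        assert len(chains[0].anchors) == 8

    def test_gap_cost_penalizes_coordinate_disagreement(self):
        params = ChainParams(match_score=1.0, gap_scale=0.1)
        anchors = [Anchor("t", "+", 0, 0), Anchor("t", "+", 10, 2)]
        chains = chain_anchors(anchors, params)
        assert chains[0].score == pytest.approx(1.0 + 1.0 - 0.1 * 8)

    def test_unsorted_anchors_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            chain_anchors([Anchor("t", "+", 5, 0), Anchor("t", "+", 1, 1)], ChainParams())

    def test_chains_do_not_mix_targets_or_strands(self):
        anchors = sorted(
            [Anchor("tA", "+", i, i) for i in range(4)]
            + [Anchor("tB", "+", i, i) for i in range(4)],
            key=lambda a: (a.target_id, a.strand, a.target_pos, a.query_idx),
        )
        chains = chain_anchors(anchors, ChainParams())
        for c in chains:
            assert len({(a.target_id, a.strand) for a in c.anchors}) == 1

    def test_dp_equals_brute_force_on_random_instances(self):
        """DP best-chain score matches exhaustive subset enumeration."""
        rng = np.random.default_rng(42)
        params = ChainParams(match_score=1.0, gap_scale=0.05, max_gap=25, max_skip=1000)
        for _ in range(200):
            anchors = random_instance(rng, int(rng.integers(1, 13)))
            chains = chain_anchors(anchors, params)
            best_dp = chains[0].score if chains else 0.0
            assert best_dp == pytest.approx(brute_force_best_score(anchors, params))

    def test_adding_anchor_never_decreases_best_score(self):
        rng = np.random.default_rng(7)
        params = ChainParams(max_skip=1000)
        for _ in range(50):
            anchors = random_instance(rng, 10)
            full = chain_anchors(anchors, params)[0].score
            reduced = chain_anchors(anchors[:-1], params)
            reduced_score = reduced[0].score if reduced else 0.0
            assert full >= reduced_score - 1e-12

    def test_anchor_used_by_at_most_one_chain(self):
        rng = np.random.default_rng(3)
        anchors = random_instance(rng, 12)
        chains = chain_anchors(anchors, ChainParams())
        seen = [a for c in chains for a in c.anchors]
        assert len(seen) == len(set(seen))


class TestCollectAnchors:
    def test_identical_reads_give_identical_anchors(self, index_100k, model_k6, reference_100k):
        seq = reference_100k[0][1][5000:5600]
        events = normalize_events(seq_to_events(seq, model_k6))
        a1 = collect_anchor_list(events, index_100k)
        a2 = collect_anchor_list(events, index_100k)
        assert a1 == a2

    def test_reference_slice_produces_diagonal_run(self, index_100k, model_k6, reference_100k):
        """Events taken verbatim from the reference anchor on the diagonal
        target_pos - query_idx = origin."""
        origin = 20_000
        seq = reference_100k[0][1][origin : origin + 800]
        events = normalize_events(seq_to_events(seq, model_k6))
        anchors = collect_anchor_list(events, index_100k)
        diag = [
            a
            for a in anchors
            if a.strand == "+" and abs((a.target_pos - a.query_idx) - origin) <= 2
        ]
        assert len(diag) > 100

    def test_foreign_events_yield_no_strong_chain(self, index_100k):
        """Random events unrelated to the reference produce only scattered
        hash collisions that never assemble into a confident chain."""
        rng = np.random.default_rng(0)
        events = rng.normal(0, 1, 500)  # unrelated to any reference region
        anchors = collect_anchor_list(events, index_100k)
        assert len(anchors) < len(events)  # far sparser than a true match run
        chains = chain_anchors(anchors, ChainParams())
        best = chains[0].score if chains else 0.0
        assert best < ChainParams().min_chain_score


class TestStreamingMapping:
    def test_clean_read_maps_to_origin_first_chunk(self, index_100k, model_k6, reference_100k):
        rng = np.random.default_rng(5)
        sp = SimParams(noise_sd=0.0, dwell_dispersion=0.0, p_stay=0.0, p_skip=0.0)
        read = simulate_read(
            reference_100k, model_k6, sp, rng,
            origin=("chr1", "+", 30_000, 33_000), read_id="clean",
        )
        m = map_signal(read.samples, sp.sample_rate, index_100k, ChainParams())
        assert m.mapped and m.target_id == "chr1" and m.strand == "+"
        assert m.chunks_used == 1
        assert abs((m.target_start - m.query_start) - 30_000) <= index_100k.params.n + model_k6.k

    def test_reverse_strand_read_maps_with_correct_orientation(
        self, index_100k, model_k6, reference_100k
    ):
        rng = np.random.default_rng(6)
        sp = SimParams(noise_sd=0.0, dwell_dispersion=0.0, p_stay=0.0, p_skip=0.0)
        read = simulate_read(
            reference_100k, model_k6, sp, rng,
            origin=("chr1", "-", 40_000, 43_000), read_id="rev",
        )
        m = map_signal(read.samples, sp.sample_rate, index_100k, ChainParams())
        assert m.mapped and m.strand == "-"
        assert abs((m.target_end + m.query_start) - 43_000) <= index_100k.params.n + model_k6.k

    def test_foreign_reads_stay_unmapped(self, index_100k, model_k6):
        """Reads from a reference absent from the index are rejected (at
        most a rare borderline collision chain slips through)."""
        sp = SimParams()
        unmapped = 0
        for s in range(10):
            foreign = [("alien", random_sequence(20_000, seed=990 + s))]
            rng = np.random.default_rng(s)
            read = simulate_read(foreign, model_k6, sp, rng, read_id=f"alien{s}")
            m = map_signal(read.samples, sp.sample_rate, index_100k, ChainParams(max_chunks=5))
            if not m.mapped:
                unmapped += 1
                assert m.chunks_used == min(
                    5, len(chunk_signal(read.samples, sp.sample_rate))
                )
        assert unmapped >= 9

    def test_duplicated_region_defers_or_rejects(self, model_k6):
        """A read from a region present twice fails the best/second-best
        ratio test and must not be confidently placed at either copy."""
        core = random_sequence(60_000, seed=55)
        dup = core[10_000:16_000]
        seq = core + random_sequence(3000, seed=56) + dup
        idx = build_index([("t", seq)], model_k6, IndexParams())
        rng = np.random.default_rng(9)
        sp = SimParams(noise_sd=0.0, dwell_dispersion=0.0, p_stay=0.0, p_skip=0.0)
        read = simulate_read(
            [("t", seq)], model_k6, sp, rng,
            origin=("t", "+", 11_000, 14_500), read_id="dup",
        )
        m = map_signal(read.samples, sp.sample_rate, idx, ChainParams(max_chunks=3))
        assert not m.mapped

    def test_empty_read_unmapped(self, index_100k):
        m = map_read_streaming([np.zeros(4000)], index_100k, ChainParams())
        assert not m.mapped and m.chunks_used == 1

    def test_streaming_and_single_pass_agree_on_locus(
        self, index_100k, model_k6, reference_100k
    ):
        """Chunk-by-chunk and whole-signal mapping accept the same locus
        (implied read origin within a small tolerance)."""
        rng = np.random.default_rng(10)
        sp = SimParams(noise_sd=0.25)
        for i in range(5):
            read = simulate_read(reference_100k, model_k6, sp, rng, read_id=f"s{i}")
            m_stream = map_signal(read.samples, sp.sample_rate, index_100k, ChainParams())
            m_whole = map_read_streaming([read.samples], index_100k, ChainParams())
            if not (m_stream.mapped and m_whole.mapped):
                continue
            assert m_stream.target_id == m_whole.target_id
            assert m_stream.strand == m_whole.strand
            # the two passes may accept different read prefixes, so their
            # intervals differ in extent; the implied read origin (interval
            # extrapolated back by the query offset) identifies the locus
            o_stream = m_stream.target_start - m_stream.query_start
            o_whole = m_whole.target_start - m_whole.query_start
            if m_stream.strand == "-":
                o_stream = m_stream.target_end + m_stream.query_start
                o_whole = m_whole.target_end + m_whole.query_start
            assert abs(o_stream - o_whole) <= 500

    def test_max_chunks_bounds_consumption(self, index_100k):
        rng = np.random.default_rng(11)
        chunks = [rng.normal(90, 12, 4000) for _ in range(10)]
        m = map_read_streaming(chunks, index_100k, ChainParams(max_chunks=4))
        assert not m.mapped and m.chunks_used == 4
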