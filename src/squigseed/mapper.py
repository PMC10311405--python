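"""Streaming seeding, colinear chaining, and the per-read mapping decision.

Per chunk of raw signal the mapper detects events, normalizes them over
the chunk, quantizes them, and queries the reference index with every
window of n consecutive quantized events.  Each (query seed, reference
hit) pair is an anchor.  All anchors accumulated so far are chained by
dynamic programming: a chain is a colinear subset of anchors on one
target and strand, with both the reference and the query coordinate
strictly increasing, scored as one match score per anchor minus a gap
penalty proportional to |Δtarget - Δquery|.  There is deliberately no
per-anchor distance coefficient in the gap cost — the absolute distance
between seed matches carries no information here, only the disagreement
between the two coordinate deltas does.

A read is accepted as mapped when the best chain both clears an absolute
score threshold and beats the best chain from any other region by a
ratio margin; acceptance stops consumption of further chunks (the Read
Until surrogate — on a sequencer this is the point where the strand
would be ejected).  If no decision is reached after ``max_chunks``
chunks the read is reported unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .event_detector import (
    DetectedEvent,
    SegmentationParams,
    SignalChunk,
    StreamingEventDetector,
    normalize_chunk_events,
)
from .indexer import ReferenceIndex, pack_seeds, hash_seeds
from .quantizer import quantize_events

try:  # DP kernel is hot; numba accelerates it when present
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def wrap(f):
            return f

        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@dataclass(frozen=True)
class ChainParams:
    """Chaining and acceptance configuration.

    ``gap_scale`` multiplies match_score to give the per-unit gap
    penalty γ, so the cost of chaining anchors whose reference and query
    deltas disagree by d is γ·d.  ``best_ratio`` is the required margin
    of the best chain score over the best chain from a different region;
    ``max_chunks`` bounds how long an undecidable read is consumed.
    """

    match_score: float = 1.0
    gap_scale: float = 0.01
    max_gap: int = 200
    max_skip: int = 25
    min_chain_score: float = 6.0
    best_ratio: float = 1.2
    max_chunks: int = 20

    def __post_init__(self) -> None:
        if min(self.match_score, self.max_gap, self.max_skip, self.min_chain_score) <= 0:
            raise ValueError("chain parameters must be positive")
        if self.best_ratio < 1.0:
            raise ValueError(f"best_ratio must be >= 1, got {self.best_ratio}")


@dataclass(frozen=True)
class Anchor:
    """One (query seed, reference hit) match pair."""

    target_id: str
    strand: str
    target_pos: int
    query_idx: int


@dataclass
class Chain:
    """A scored colinear anchor subsequence on one target and strand."""

    score: float
    anchors: list[Anchor]

    @property
    def target_id(self) -> str:
        return self.anchors[0].target_id

    @property
    def strand(self) -> str:
        return self.anchors[0].strand

    @property
    def target_start(self) -> int:
        return self.anchors[0].target_pos

    @property
    def target_end(self) -> int:
        return self.anchors[-1].target_pos

    @property
    def query_start(self) -> int:
        return self.anchors[0].query_idx

    @property
    def query_end(self) -> int:
        return self.anchors[-1].query_idx


@dataclass
class Mapping:
    """Placement of a read prefix on the reference (or an unmapped verdict).

    Coordinates: ``target_start``/``target_end`` are base positions
    (half-open, forward strand); ``query_start``/``query_end`` are event
    indices in the read's event stream.  ``chunks_used`` counts signal
    chunks consumed before the decision — the quantity a Read Until
    controller would act on.
    """

    read_id: str
    mapped: bool
    target_id: str = "*"
    strand: str = "+"
    target_start: int = 0
    target_end: int = 0
    query_start: int = 0
    query_end: int = 0
    chain_score: float = 0.0
    n_anchors: int = 0
    chunks_used: int = 0
    events_used: int = 0


@_njit(cache=False)
def _chain_dp_kernel(group, tpos, qidx, match_score, gap_scale, max_gap, max_skip):
    m = len(group)
    f = np.empty(m, dtype=np.float64)
    parent = np.full(m, -1, dtype=np.int64)
    gamma = gap_scale * match_score
    for j in range(m):
        best = 0.0
        best_i = -1
        skipped = 0
        i = j - 1
        while i >= 0:
            if group[i] != group[j]:
                break
            dt = tpos[j] - tpos[i]
            if dt > max_gap:
                break
            if dt > 0:
                dq = qidx[j] - qidx[i]
                if 0 < dq <= max_gap:
                    cand = f[i] - gamma * abs(dt - dq)
                    if cand > best:
                        best = cand
                        best_i = i
                else:
                    skipped += 1
            else:
                skipped += 1
            if skipped > max_skip:
                break
            i -= 1
        f[j] = match_score + best
        parent[j] = best_i
    return f, parent


def _chain_arrays(
    group: np.ndarray,
    tpos: np.ndarray,
    qidx: np.ndarray,
    params: ChainParams,
) -> tuple[np.ndarray, np.ndarray]:
    """DP scores and predecessor links over anchors sorted by (group, tpos, qidx)."""
    return _chain_dp_kernel(
        group.astype(np.int64),
        tpos.astype(np.int64),
        qidx.astype(np.int64),
        float(params.match_score),
        float(params.gap_scale),
        int(params.max_gap),
        int(params.max_skip),
    )


def _extract_chains(
    f: np.ndarray, parent: np.ndarray, order_key: np.ndarray, max_chains: int = 0
) -> list[tuple[float, list[int]]]:
    """Backtrack chains in descending score; each anchor used at most once.

    ``order_key`` breaks score ties deterministically (lower key first).
    A chain that runs into an already-used anchor is truncated there and
    its score reduced by the used prefix's contribution.
    """
    m = len(f)
    used = np.zeros(m, dtype=bool)
    chains: list[tuple[float, list[int]]] = []
    for j in np.lexsort((order_key, -f)):
        if used[j]:
            continue
        idxs: list[int] = []
        i = int(j)
        truncated_at = -1
        while i >= 0:
            if used[i]:
                truncated_at = i
                break
            idxs.append(i)
            i = int(parent[i])
        if not idxs:
            continue
        score = float(f[j]) - (float(f[truncated_at]) if truncated_at >= 0 else 0.0)
        if score <= 0:
            continue
        for i in idxs:
            used[i] = True
        idxs.reverse()
        chains.append((score, idxs))
        if max_chains and len(chains) >= max_chains:
            break
    chains.sort(key=lambda c: -c[0])
    return chains


def chain_anchors(anchors: Sequence[Anchor], params: ChainParams) -> list[Chain]:
    """Chain a sorted anchor list into scored colinear chains.

    Anchors must be sorted by (target_id, strand, target_pos, query_idx).
    Returns chains in descending score; ties broken by (target_id,
    target_start).  Every anchor appears in at most one chain.
    """
    if not anchors:
        return []
    keys = sorted({(a.target_id, a.strand) for a in anchors})
    key_ix = {k: i for i, k in enumerate(keys)}
    group = np.array([key_ix[(a.target_id, a.strand)] for a in anchors], dtype=np.int64)
    tpos = np.array([a.target_pos for a in anchors], dtype=np.int64)
    qidx = np.array([a.query_idx for a in anchors], dtype=np.int64)
    order = np.lexsort((qidx, tpos, group))
    if not np.array_equal(order, np.arange(len(anchors))):
        raise ValueError("anchors must be sorted by (target_id, strand, target_pos, query_idx)")
    f, parent = _chain_arrays(group, tpos, qidx, params)
    # deterministic tie-break: lower (target_id, target_start) first
    tie = group * (tpos.max() + 1) + tpos
    out = []
    for score, idxs in _extract_chains(f, parent, tie):
        out.append(Chain(score=score, anchors=[anchors[i] for i in idxs]))
    return out


def collect_anchors(
    codes: np.ndarray, index: ReferenceIndex, start_seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Query the index with every n-window of quantized read events.

    ``codes`` must contain at least the events from seed window
    ``start_seed`` onward (i.e. pass ``all_codes[start_seed:]`` to get
    only the windows introduced by the latest chunk).  Returns parallel
    (query_idx, tid, tpos, strand) arrays; query indices are offset by
    ``start_seed``.
    """
    p = index.params
    packed = pack_seeds(codes, p.n, p.quant.width)
    if len(packed) == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.astype(np.int32), e.astype(np.int32), e.astype(np.uint8)
    hashes = hash_seeds(packed, p.packed_width)
    qrep, tid, tpos, strand = index.query_arrays(hashes)
    return qrep + start_seed, tid, tpos.astype(np.int32), strand


def collect_anchor_list(read_events, index: ReferenceIndex) -> list[Anchor]:
    """Anchor objects for a full normalized read event series (batch API)."""
    values = getattr(read_events, "values", read_events)
    codes = quantize_events(np.asarray(values), index.params.quant)
    qidx, tid, tpos, strand = collect_anchors(codes, index)
    anchors = [
        Anchor(
            target_id=index.target_ids[int(t)],
            strand="-" if s else "+",
            target_pos=int(tp),
            query_idx=int(q),
        )
        for q, t, tp, s in zip(qidx, tid, tpos, strand)
    ]
    anchors.sort(key=lambda a: (a.target_id, a.strand, a.target_pos, a.query_idx))
    return anchors


class _ReadState:
    """Accumulated per-read mapping state across chunks."""

    def __init__(self, index: ReferenceIndex, chain_params: ChainParams) -> None:
        self.index = index
        self.cp = chain_params
        self.codes = np.empty(0, dtype=np.uint32)
        self.n_seeds = 0
        self.qidx = np.empty(0, dtype=np.int64)
        self.tid = np.empty(0, dtype=np.int32)
        self.tpos = np.empty(0, dtype=np.int64)  # chain coordinate (mirrored on '-')
        self.strand = np.empty(0, dtype=np.uint8)
        self.pending: list[DetectedEvent] = []

    def add_events(self, events: list[DetectedEvent]) -> None:
        """Normalize one chunk's events, quantize, and extend the anchor set."""
        self.pending.extend(events)
        if len(self.pending) < 2:
            return  # buffer and merge with the next chunk
        series = normalize_chunk_events(self.pending)
        self.pending = []
        new_codes = quantize_events(series.values, self.index.params.quant)
        prev_seed_start = max(0, self.n_seeds)
        self.codes = np.concatenate([self.codes, new_codes])
        qidx, tid, tpos, strand = collect_anchors(
            self.codes[prev_seed_start:], self.index, start_seed=prev_seed_start
        )
        self.n_seeds = max(0, len(self.codes) - self.index.params.n + 1)
        if len(qidx) == 0:
            return
        # mirror reverse-strand positions so chains run in increasing
        # coordinates on both strands (query later => smaller forward pos)
        tpos = tpos.astype(np.int64)
        rev = strand == 1
        if np.any(rev):
            n_ev = np.array(self.index.target_event_counts, dtype=np.int64)[tid[rev]]
            tpos[rev] = (n_ev - self.index.params.n) - tpos[rev]
        self.qidx = np.concatenate([self.qidx, qidx])
        self.tid = np.concatenate([self.tid, tid])
        self.tpos = np.concatenate([self.tpos, tpos])
        self.strand = np.concatenate([self.strand, strand])

    def best_chains(self) -> list[tuple[float, int, int, np.ndarray]]:
        """Chain all anchors so far; return (score, group, tstart, anchor rows)."""
        if len(self.qidx) == 0:
            return []
        group = self.tid.astype(np.int64) * 2 + self.strand
        order = np.lexsort((self.qidx, self.tpos, group))
        g, tp, qi = group[order], self.tpos[order], self.qidx[order]
        f, parent = _chain_arrays(g, tp, qi, self.cp)
        tie = g * (int(tp.max()) + 1) + tp
        chains = []
        for score, idxs in _extract_chains(f, parent, tie, max_chains=16):
            rows = order[np.array(idxs, dtype=np.int64)]
            chains.append((score, int(g[idxs[0]]), int(tp[idxs[0]]), rows))
        return chains

    def decide(self, chunks_used: int, read_id: str) -> Mapping | None:
        chains = self.best_chains()
        if not chains:
            return None
        best = chains[0]
        best_score, best_group = best[0], best[1]
        rows = best[3]
        t_lo, t_hi = int(self.tpos[rows].min()), int(self.tpos[rows].max())
        second_score = 0.0
        for score, grp, _, rws in chains[1:]:
            if grp != best_group:
                second_score = score
                break
            lo, hi = int(self.tpos[rws].min()), int(self.tpos[rws].max())
            if hi < t_lo or lo > t_hi:  # same target+strand but disjoint region
                second_score = score
                break
        if best_score < self.cp.min_chain_score:
            return None
        if second_score > 0 and best_score < self.cp.best_ratio * second_score:
            return None
        return self._to_mapping(best_score, rows, chunks_used, read_id)

    def _to_mapping(
        self, score: float, rows: np.ndarray, chunks_used: int, read_id: str
    ) -> Mapping:
        p = self.index.params
        tix = int(self.tid[rows[0]])
        strand = "-" if self.strand[rows[0]] else "+"
        tp = self.tpos[rows]
        qi = self.qidx[rows]
        if strand == "-":  # un-mirror to forward coordinates
            n_ev = self.index.target_event_counts[tix]
            tp = (n_ev - p.n) - tp
        t_lo, t_hi = int(tp.min()), int(tp.max())
        return Mapping(
            read_id=read_id,
            mapped=True,
            target_id=self.index.target_ids[tix],
            strand=strand,
            target_start=t_lo,
            target_end=t_hi + p.n - 1 + p.k,  # bases, half-open
            query_start=int(qi.min()),
            query_end=int(qi.max()) + p.n,  # event indices, half-open
            chain_score=float(score),
            n_anchors=len(rows),
            chunks_used=chunks_used,
            events_used=len(self.codes),
        )


def map_read_streaming(
    chunks: Iterable[SignalChunk | np.ndarray],
    index: ReferenceIndex,
    chain_params: ChainParams | None = None,
    seg_params: SegmentationParams | None = None,
    read_id: str = "",
) -> Mapping:
    """Map one read from an incremental chunk stream.

    Consumes chunks in order; after each chunk the cumulative anchor set
    is re-chained and the accept rule evaluated, so evidence from earlier
    chunks carries over when a chunk alone is inconclusive.  Stops
    consuming on acceptance; reports unmapped after ``max_chunks`` chunks
    (or stream end) without acceptance.
    """
    cp = chain_params or ChainParams()
    sp = seg_params or SegmentationParams()
    detector = StreamingEventDetector(params=sp)
    state = _ReadState(index, cp)
    chunks_seen = 0
    for chunk in chunks:
        samples = chunk.samples if isinstance(chunk, SignalChunk) else np.asarray(chunk)
        if isinstance(chunk, SignalChunk) and not read_id:
            read_id = chunk.read_id
        chunks_seen += 1
        state.add_events(detector.feed(samples))
        mapping = state.decide(chunks_seen, read_id)
        if mapping is not None:
            return mapping
        if chunks_seen >= cp.max_chunks:
            break
    else:
        # stream exhausted: flush the detector tail and decide once more
        state.add_events(detector.finalize())
        mapping = state.decide(chunks_seen, read_id)
        if mapping is not None:
            return mapping
    return Mapping(
        read_id=read_id,
        mapped=False,
        chunks_used=chunks_seen,
        events_used=len(state.codes),
    )


def chunk_signal(
    samples: np.ndarray,
    sample_rate: float,
    read_id: str = "",
    chunk_seconds: float = 1.0,
) -> list[SignalChunk]:
    """Split a full raw signal into one-second (by default) chunks."""
    spc = max(1, int(round(sample_rate * chunk_seconds)))
    samples = np.asarray(samples, dtype=np.float64)
    return [
        SignalChunk(
            read_id=read_id,
            samples=samples[i : i + spc],
            chunk_index=i // spc,
            samples_per_chunk=spc,
        )
        for i in range(0, len(samples), spc)
    ]


def map_signal(
    samples: np.ndarray,
    sample_rate: float,
    index: ReferenceIndex,
    chain_params: ChainParams | None = None,
    seg_params: SegmentationParams | None = None,
    read_id: str = "",
    chunk_seconds: float = 1.0,
) -> Mapping:
    """Convenience wrapper: chunk a full signal and map it streamingly."""
    return map_read_streaming(
        chunk_signal(samples, sample_rate, read_id, chunk_seconds),
        index,
        chain_params,
        seg_params,
        read_id=read_id,
    )
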