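"""Seed packing, hashing, and the reference hash-table index.

A seed is formed from n consecutive quantized events: their (Q-p)-bit
codes are concatenated MSB-first (earliest event in the highest bits)
into an n*(Q-p)-bit word, which is then mixed to a 32-bit hash value.
The reference index maps every seed hash observed across both strands of
every reference sequence to its hits (target, forward-coordinate
position, strand), stored in a compact sorted-bucket layout.

Hash function: for packed widths <= 32 bits the MurmurHash3 32-bit
finalizer (fmix32) is used, which is a bijection on [0, 2^32) and hence
collision-free on the packed domain; for wider seeds the SplitMix64
finalizer is applied and the two 32-bit halves are folded with XOR, so
collisions may occur and are tolerated downstream by chaining, which
requires several colinear matches in close proximity.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pore_model import PoreModel, normalize_events, reverse_complement, seq_to_events
from .quantizer import QuantizationParams, quantize_events

_MAGIC = b"SQSDIDX1"

# MurmurHash3 fmix32 constants
_F32_C1 = np.uint32(0x85EBCA6B)
_F32_C2 = np.uint32(0xC2B2AE35)
# SplitMix64 finalizer constants
_F64_C1 = np.uint64(0xBF58476D1CE4E5B9)
_F64_C2 = np.uint64(0x94D049BB133111EB)

HASH_FUNCTION_ID = "fmix32|splitmix64-fold"


class IndexError_(ValueError):
    """Raised for malformed indexes or incompatible parameters."""


@dataclass(frozen=True)
class IndexParams:
    """Seeding parameters recorded in (and enforced by) the index.

    ``n`` consecutive quantized events form one seed; the packed width
    n*(Q-p) must fit a 64-bit word.  ``pore_model_id`` identifies the
    k-mer model the index was built with so that mapping refuses to run
    with a different model.
    """

    n: int = 6
    quant: QuantizationParams = field(default_factory=QuantizationParams)
    pore_model_id: str = ""
    k: int = 0  # k-mer length of the pore model (bases)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.n * self.quant.width > 64:
            raise ValueError(
                f"packed seed width n*(Q-p) = {self.n * self.quant.width} exceeds 64 bits"
            )

    @property
    def packed_width(self) -> int:
        return self.n * self.quant.width


@dataclass(frozen=True)
class SeedHit:
    """One reference occurrence of a seed hash.

    ``target_pos`` is the forward-coordinate k-mer start of the leftmost
    k-mer covered by the seed, for both strands (PAF-style convention).
    """

    target_id: str
    target_pos: int
    strand: str  # '+' or '-'


def pack_seed(codes, width: int) -> int:
    """Concatenate quantized event codes MSB-first into one integer.

    The earliest event occupies the highest bits, preserving order:
    reversing distinct codes changes the packed value.
    """
    packed = 0
    for c in codes:
        c = int(getattr(c, "code", c))
        if not 0 <= c < (1 << width):
            raise ValueError(f"code {c} does not fit {width} bits")
        packed = (packed << width) | c
    return packed


def pack_seeds(codes: np.ndarray, n: int, width: int) -> np.ndarray:
    """Vectorized sliding-window packing of all n-event seeds in ``codes``."""
    m = len(codes) - n + 1
    if m < 1:
        return np.empty(0, dtype=np.uint64)
    seeds = np.zeros(m, dtype=np.uint64)
    w = np.uint64(width)
    for j in range(n):
        seeds = (seeds << w) | codes[j : j + m].astype(np.uint64)
    return seeds


def _fmix32(h: np.ndarray) -> np.ndarray:
    h = h.astype(np.uint32)
    h ^= h >> np.uint32(16)
    h *= _F32_C1
    h ^= h >> np.uint32(13)
    h *= _F32_C2
    h ^= h >> np.uint32(16)
    return h


def _splitmix64_fin(h: np.ndarray) -> np.ndarray:
    h = h.astype(np.uint64)
    h ^= h >> np.uint64(30)
    h *= _F64_C1
    h ^= h >> np.uint64(27)
    h *= _F64_C2
    h ^= h >> np.uint64(31)
    return h


def hash_seeds(packed: np.ndarray, width: int) -> np.ndarray:
    """32-bit hashes for an array of packed seeds of the given bit width."""
    packed = np.asarray(packed, dtype=np.uint64)
    if width <= 32:
        return _fmix32(packed.astype(np.uint32))
    h = _splitmix64_fin(packed)
    return ((h >> np.uint64(32)) ^ (h & np.uint64(0xFFFFFFFF))).astype(np.uint32)


def hash_seed(packed: int, width: int) -> int:
    """32-bit hash of one packed seed (invertible mix for width <= 32)."""
    if not 0 <= packed < (1 << width):
        raise ValueError(f"packed value {packed} does not fit {width} bits")
    return int(hash_seeds(np.array([packed], dtype=np.uint64), width)[0])


class ReferenceIndex:
    """Hash table from 32-bit seed hashes to reference hits.

    Storage is a sorted-bucket (CSR-like) layout: ``unique_hashes`` holds
    the distinct hashes in ascending order, ``offsets[i]:offsets[i+1]``
    delimits bucket i in the parallel hit arrays ``hit_tid``, ``hit_pos``
    and ``hit_strand`` (0 forward, 1 reverse).  Buckets flagged in
    ``masked`` belong to the most repetitive seeds and return no hits.
    """

    def __init__(
        self,
        params: IndexParams,
        target_ids: list[str],
        target_lengths: list[int],
        target_event_counts: list[int],
        unique_hashes: np.ndarray,
        offsets: np.ndarray,
        hit_tid: np.ndarray,
        hit_pos: np.ndarray,
        hit_strand: np.ndarray,
        masked: np.ndarray,
        mask_frac: float,
    ) -> None:
        self.params = params
        self.target_ids = list(target_ids)
        self.target_lengths = list(target_lengths)
        self.target_event_counts = list(target_event_counts)
        self.unique_hashes = unique_hashes
        self.offsets = offsets
        self.hit_tid = hit_tid
        self.hit_pos = hit_pos
        self.hit_strand = hit_strand
        self.masked = masked
        self.mask_frac = mask_frac

    @property
    def n_seeds(self) -> int:
        return int(len(self.hit_tid))

    @property
    def n_buckets(self) -> int:
        return int(len(self.unique_hashes))

    def check_compatible(self, params: IndexParams) -> None:
        """Refuse to serve a query pipeline built with different parameters."""
        if params != self.params:
            raise IndexError_(
                f"index/query parameter mismatch: index has {self.params}, "
                f"query pipeline has {params}"
            )

    def bucket_sizes(self) -> np.ndarray:
        return np.diff(self.offsets)

    def _bucket(self, hash_value: int) -> tuple[int, int]:
        i = int(np.searchsorted(self.unique_hashes, np.uint32(hash_value)))
        if i >= len(self.unique_hashes) or self.unique_hashes[i] != np.uint32(hash_value):
            return 0, 0
        if self.masked[i]:
            return 0, 0
        return int(self.offsets[i]), int(self.offsets[i + 1])

    def query(self, hash_value: int) -> list[SeedHit]:
        """Exact-match bucket lookup; empty for absent or masked hashes."""
        lo, hi = self._bucket(hash_value)
        return [
            SeedHit(
                target_id=self.target_ids[int(self.hit_tid[j])],
                target_pos=int(self.hit_pos[j]),
                strand="-" if self.hit_strand[j] else "+",
            )
            for j in range(lo, hi)
        ]

    def query_arrays(
        self, hashes: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Bulk lookup used by the mapper.

        Returns (query_index, tid, pos, strand) arrays, one row per hit,
        where ``query_index`` is the position of the querying hash in the
        input array.
        """
        hashes = np.asarray(hashes, dtype=np.uint32)
        idx = np.searchsorted(self.unique_hashes, hashes)
        idx_c = np.minimum(idx, len(self.unique_hashes) - 1) if len(self.unique_hashes) else idx
        found = (
            (idx < len(self.unique_hashes))
            & (self.unique_hashes[idx_c] == hashes)
            & ~self.masked[idx_c]
            if len(self.unique_hashes)
            else np.zeros(len(hashes), dtype=bool)
        )
        qpos = np.nonzero(found)[0]
        buckets = idx[qpos]
        los = self.offsets[buckets]
        his = self.offsets[buckets + 1]
        counts = (his - los).astype(np.int64)
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, dtype=np.int64)
            return e, e.astype(np.int32), e.astype(np.int32), e.astype(np.uint8)
        # expand bucket ranges into flat hit indices
        starts = np.repeat(los, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        flat = starts + within
        qrep = np.repeat(qpos, counts)
        return qrep, self.hit_tid[flat], self.hit_pos[flat], self.hit_strand[flat]

    # ------------------------------------------------------------------
    # serialization: little-endian binary container, bit-exact across
    # platforms (magic, JSON params block, packed arrays)
    # ------------------------------------------------------------------

    def save(self, path: str | Path) -> None:
        header = {
            "n": self.params.n,
            "q": self.params.quant.q,
            "p": self.params.quant.p,
            "pore_model_id": self.params.pore_model_id,
            "k": self.params.k,
            "hash_function": HASH_FUNCTION_ID,
            "mask_frac": self.mask_frac,
            "target_ids": self.target_ids,
            "target_lengths": self.target_lengths,
            "target_event_counts": self.target_event_counts,
        }
        hjson = json.dumps(header).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<I", len(hjson)))
            fh.write(hjson)
            for arr, dt in (
                (self.unique_hashes, "<u4"),
                (self.offsets, "<i8"),
                (self.masked, "<u1"),
                (self.hit_tid, "<i4"),
                (self.hit_pos, "<i4"),
                (self.hit_strand, "<u1"),
            ):
                data = np.ascontiguousarray(arr).astype(dt).tobytes()
                fh.write(struct.pack("<Q", len(data)))
                fh.write(data)

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceIndex":
        with open(path, "rb") as fh:
            if fh.read(len(_MAGIC)) != _MAGIC:
                raise IndexError_(f"{path}: not a squigseed index (bad magic)")
            (hlen,) = struct.unpack("<I", fh.read(4))
            header = json.loads(fh.read(hlen).decode())
            arrays = []
            for dt in ("<u4", "<i8", "<u1", "<i4", "<i4", "<u1"):
                (alen,) = struct.unpack("<Q", fh.read(8))
                arrays.append(np.frombuffer(fh.read(alen), dtype=dt).copy())
        if header.get("hash_function") != HASH_FUNCTION_ID:
            raise IndexError_(
                f"{path}: index built with hash function "
                f"{header.get('hash_function')!r}, this build uses {HASH_FUNCTION_ID!r}"
            )
        params = IndexParams(
            n=header["n"],
            quant=QuantizationParams(q=header["q"], p=header["p"]),
            pore_model_id=header["pore_model_id"],
            k=header["k"],
        )
        uh, off, masked, tid, pos, strand = arrays
        return cls(
            params=params,
            target_ids=header["target_ids"],
            target_lengths=header["target_lengths"],
            target_event_counts=header["target_event_counts"],
            unique_hashes=uh.astype(np.uint32),
            offsets=off.astype(np.int64),
            hit_tid=tid.astype(np.int32),
            hit_pos=pos.astype(np.int32),
            hit_strand=strand.astype(np.uint8),
            masked=masked.astype(bool),
            mask_frac=header["mask_frac"],
        )


def reference_seed_hashes(
    seq: str, model: PoreModel, params: IndexParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Seed hashes and forward-coordinate positions for one target.

    Returns (hashes, positions, strands, n_events) arrays covering both
    strands.  The reverse strand is obtained by processing the reverse
    complement; its positions are converted back to forward k-mer starts
    of the leftmost covered k-mer.
    """
    n, width = params.n, params.quant.width
    k = model.k
    L = len(seq)
    out_h, out_p, out_s = [], [], []
    n_events = 0
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        es = seq_to_events(s, model)
        if len(es) < max(2, n):
            continue
        if strand == "+":
            n_events = len(es)
        es = normalize_events(es)
        codes = quantize_events(es.values, params.quant)
        packed = pack_seeds(codes, n, width)
        if len(packed) == 0:
            continue
        hashes = hash_seeds(packed, params.packed_width)
        # position of the first (leftmost retained) event in each window
        first = es.positions[: len(packed)]
        last = es.positions[n - 1 : n - 1 + len(packed)]
        if strand == "+":
            pos = first
        else:
            # leftmost covered forward k-mer corresponds to the window's
            # last reverse-complement event
            pos = L - k - last
        out_h.append(hashes)
        out_p.append(pos.astype(np.int64))
        out_s.append(np.full(len(packed), 0 if strand == "+" else 1, dtype=np.uint8))
    if not out_h:
        e = np.empty(0)
        return e.astype(np.uint32), e.astype(np.int64), e.astype(np.uint8), 0
    return np.concatenate(out_h), np.concatenate(out_p), np.concatenate(out_s), n_events


def build_index(
    reference: str | Path | list[tuple[str, str]],
    model: PoreModel,
    params: IndexParams | None = None,
    mask_frac: float = 2e-4,
) -> ReferenceIndex:
    """Build the reference hash table from a FASTA path or (id, seq) pairs.

    Every window of n consecutive (retained) events on each strand of
    each target contributes one hit.  After building, the ``mask_frac``
    fraction of most frequent hashes (default: top 0.02%) is masked so
    that highly repetitive seeds return no hits, bounding chaining cost.
    """
    from .pore_model import read_fasta

    if params is None:
        params = IndexParams()
    if isinstance(reference, (str, Path)):
        targets = read_fasta(reference)
    else:
        targets = list(reference)
    if not targets:
        raise IndexError_("empty reference")
    if params.k and params.k != model.k:
        raise IndexError_(f"params.k={params.k} does not match model k={model.k}")
    params = IndexParams(
        n=params.n,
        quant=params.quant,
        pore_model_id=params.pore_model_id,
        k=model.k,
    )
    all_h, all_p, all_s, all_t = [], [], [], []
    target_ids, target_lengths, target_event_counts = [], [], []
    for tix, (tid, seq) in enumerate(targets):
        h, p, s, n_ev = reference_seed_hashes(seq, model, params)
        target_ids.append(tid)
        target_lengths.append(len(seq))
        target_event_counts.append(n_ev)
        if len(h):
            all_h.append(h)
            all_p.append(p)
            all_s.append(s)
            all_t.append(np.full(len(h), tix, dtype=np.int32))
    if not all_h:
        raise IndexError_("reference produced no seeds (targets too short?)")
    hashes = np.concatenate(all_h)
    pos = np.concatenate(all_p).astype(np.int32)
    strand = np.concatenate(all_s)
    tid_arr = np.concatenate(all_t)
    # group hits into sorted buckets; stable secondary order keeps output
    # deterministic across runs
    order = np.lexsort((pos, strand, tid_arr, hashes))
    hashes, pos, strand, tid_arr = hashes[order], pos[order], strand[order], tid_arr[order]
    unique_hashes, starts = np.unique(hashes, return_index=True)
    offsets = np.append(starts, len(hashes)).astype(np.int64)
    sizes = np.diff(offsets)
    masked = np.zeros(len(unique_hashes), dtype=bool)
    n_mask = int(round(mask_frac * len(unique_hashes)))
    if n_mask > 0:
        # mask the n_mask largest buckets; ties broken by hash value
        order_by_size = np.lexsort((unique_hashes, -sizes))
        masked[order_by_size[:n_mask]] = True
    return ReferenceIndex(
        params=params,
        target_ids=target_ids,
        target_lengths=target_lengths,
        target_event_counts=target_event_counts,
        unique_hashes=unique_hashes,
        offsets=offsets,
        hit_tid=tid_arr,
        hit_pos=pos,
        hit_strand=strand,
        masked=masked,
        mask_frac=mask_frac,
    )


def query_index(index: ReferenceIndex, hash_value: int) -> list[SeedHit]:
    """Exact-match lookup of one 32-bit seed hash (see ReferenceIndex.query)."""
    return index.query(hash_value)
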