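"""Nanopore k-mer models and reference-side event generation.

A nanopore k-mer model (pore model) tabulates the expected mean ionic
current while each of the 4^k possible k-mers resides in the pore.  The
reference side of the mapping pipeline converts a DNA sequence into the
series of expected event values by looking up every overlapping k-mer in
this table, then z-score normalizes the series per reference sequence so
that it is comparable with normalized events segmented from raw signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

BASES = "ACGT"
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class PoreModelError(ValueError):
    """Raised for malformed or incomplete k-mer model tables."""


@dataclass(frozen=True)
class PoreModel:
    """Expected mean current level per k-mer for one pore chemistry.

    Parameters
    ----------
    k
        k-mer length in bases.
    levels
        Mapping from each of the 4^k k-mers over ACGT to its expected
        mean current.  Units (picoamps or otherwise) are irrelevant to
        mapping because both sides of the comparison are z-scored.
    """

    k: int
    levels: dict[str, float]
    # dense table indexed by the 2-bit base encoding, for vectorized lookup
    _table: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise PoreModelError(f"k must be >= 1, got {self.k}")
        expected = 4**self.k
        if len(self.levels) != expected:
            raise PoreModelError(
                f"k={self.k} model must have {expected} levels, got {len(self.levels)}"
            )
        table = np.empty(expected, dtype=np.float64)
        for kmer, level in self.levels.items():
            if len(kmer) != self.k or any(b not in _BASE_CODE for b in kmer):
                raise PoreModelError(f"invalid k-mer key {kmer!r} for k={self.k}")
            table[kmer_to_code(kmer)] = float(level)
        object.__setattr__(self, "_table", table)

    @property
    def level_scale(self) -> float:
        """Population standard deviation of the level table.

        Used by the signal simulator to express noise amplitudes on the
        natural scale of the model, independent of its current units.
        """
        return float(np.std(self._table))

    def level(self, kmer: str) -> float:
        return self.levels[kmer.upper()]


@dataclass
class EventSeries:
    """An ordered series of event values from one reference sequence or read.

    ``positions`` carries, for each value, the absolute k-mer start
    position (reference side) or the event's sample offset (signal side);
    it is preserved through normalization so that gaps introduced by
    ambiguous bases keep absolute coordinates.
    """

    values: np.ndarray
    source: str = ""
    normalized: bool = False
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != self.values.shape:
                raise ValueError("positions and values must have equal length")

    def __len__(self) -> int:
        return len(self.values)


def all_kmers(k: int) -> Iterator[str]:
    """Enumerate all 4^k k-mers over ACGT in lexicographic order."""
    for tup in itertools.product(BASES, repeat=k):
        yield "".join(tup)


def kmer_to_code(kmer: str) -> int:
    code = 0
    for b in kmer:
        code = (code << 2) | _BASE_CODE[b]
    return code


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def load_pore_model(path: str | Path) -> PoreModel:
    """Load a whitespace/tab-delimited k-mer model table.

    The table must contain at least two columns: the k-mer and its mean
    level.  A header line is detected by a non-numeric second field and
    skipped.  Extra columns (level spread, dwell statistics...) are
    ignored; only mean levels enter the pipeline.  The table must be
    complete: exactly one row per each of the 4^k k-mers.
    """
    path = Path(path)
    levels: dict[str, float] = {}
    k: int | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise PoreModelError(f"{path}:{lineno}: expected >= 2 columns: {line!r}")
            kmer, level_str = fields[0], fields[1]
            if lineno == 1 and not _looks_numeric(level_str):
                continue  # header
            if not _looks_numeric(level_str):
                raise PoreModelError(f"{path}:{lineno}: non-numeric level {level_str!r}")
            kmer = kmer.upper()
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise PoreModelError(
                    f"{path}:{lineno}: inconsistent k-mer length {kmer!r} (expected k={k})"
                )
            if any(b not in _BASE_CODE for b in kmer):
                raise PoreModelError(f"{path}:{lineno}: invalid k-mer {kmer!r}")
            if kmer in levels:
                raise PoreModelError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            levels[kmer] = float(level_str)
    if k is None:
        raise PoreModelError(f"{path}: empty model file")
    if len(levels) != 4**k:
        missing = sorted(set(all_kmers(k)) - set(levels))
        raise PoreModelError(
            f"{path}: incomplete k={k} model: {len(levels)}/{4 ** k} k-mers"
            + (f"; missing e.g. {missing[:5]}" if missing else "")
        )
    return PoreModel(k=k, levels=levels)


def write_pore_model(model: PoreModel, path: str | Path) -> None:
    """Write a model as a two-column headered table (round-trips with load)."""
    with open(path, "w") as fh:
        fh.write("kmer\tlevel_mean\n")
        for kmer in all_kmers(model.k):
            fh.write(f"{kmer}\t{model.levels[kmer]:.6f}\n")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes; non-ACGT characters become -1.

    Case-insensitive: soft-masked lowercase bases map to their uppercase
    base.
    """
    lut = np.full(256, -1, dtype=np.int8)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
        lut[ord(b.lower())] = c
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[arr]


def seq_to_events(seq: str, model: PoreModel, *, strict: bool = False) -> EventSeries:
    """Convert a DNA sequence into its expected (unnormalized) event values.

    Value i is the model level of ``seq[i:i+k]``.  k-mers containing a
    non-ACGT character produce no event; the ``positions`` array keeps the
    absolute k-mer start of every emitted event so coordinates survive
    the gaps.  Under ``strict=True`` any non-ACGT character is an error.
    A sequence shorter than k yields an empty series.
    """
    k = model.k
    codes = encode_sequence(seq)
    if strict and np.any(codes < 0):
        bad = int(np.argmax(codes < 0))
        raise ValueError(f"invalid character {seq[bad]!r} at position {bad}")
    n_win = len(seq) - k + 1
    if n_win < 1:
        return EventSeries(np.empty(0), source="", positions=np.empty(0, dtype=np.int64))
    # rolling 2k-bit k-mer codes; windows containing a -1 base are dropped
    valid = codes >= 0
    window_valid = np.ones(n_win, dtype=bool)
    for j in range(k):
        window_valid &= valid[j : j + n_win]
    kcodes = np.zeros(n_win, dtype=np.int64)
    safe = np.where(valid, codes, 0).astype(np.int64)
    for j in range(k):
        kcodes = (kcodes << 2) | safe[j : j + n_win]
    positions = np.nonzero(window_valid)[0].astype(np.int64)
    values = model._table[kcodes[window_valid]]
    return EventSeries(values=values, positions=positions)


def normalize_events(series: EventSeries) -> EventSeries:
    """z-score normalize an event series (population standard deviation).

    Applied per reference sequence (chromosome/contig) on the reference
    side and per time chunk on the signal side; both sides use the same
    formula so that normalized values are directly comparable.
    Idempotent up to floating tolerance.  Raises on series shorter than
    2 values or with zero variance.
    """
    v = series.values
    if len(v) < 2:
        raise ValueError(f"cannot normalize series of length {len(v)}")
    mean = float(np.mean(v))
    sd = float(np.std(v))  # population sd, consistent on both sides
    if sd == 0.0 or not np.isfinite(sd):
        raise ValueError("cannot normalize a constant (zero-variance) series")
    return replace(series, values=(v - mean) / sd, normalized=True)


_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA into (record id, sequence) pairs.

    Record ids are preserved verbatim (first whitespace-delimited token),
    as they become PAF target names downstream.
    """
    from Bio import SeqIO

    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records
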