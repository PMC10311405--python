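"""Raw nanopore signal simulator with ground truth.

Generates raw-current-like reads from any reference by reversing the
reference-side event model: walk the k-mers of the sampled region, emit
each k-mer's expected model level for a dwell of roughly
sample_rate/bases_per_second samples (jittered), and add Gaussian
amplitude noise.  Stay errors duplicate a k-mer's dwell; skip errors
drop a k-mer entirely.  Every read carries its origin (target, strand,
forward-coordinate interval) so that mapping output can be scored
against ground truth with no external data.

Noise is specified relative to the population spread of the pore-model
levels (``noise_sd`` is multiplied by the model's level standard
deviation), so the same noise setting means the same difficulty
regardless of the model's current units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .pore_model import PoreModel, all_kmers, reverse_complement, seq_to_events


@dataclass(frozen=True)
class SimParams:
    """Simulator configuration.

    Defaults model an R9.4-style pore: 450 bases/s translocation sampled
    at 4 kHz (about 8.9 samples per base), moderate amplitude noise of
    0.25 model-level standard deviations, 30% dwell jitter, and 5%
    stay/skip rates.  Read lengths are drawn from a gamma distribution
    with shape 3 around ``read_length_mean``.
    """

    bases_per_second: float = 450.0
    sample_rate: float = 4000.0
    dwell_dispersion: float = 0.3
    noise_sd: float = 0.25
    p_stay: float = 0.05
    p_skip: float = 0.05
    read_length_mean: float = 4000.0
    read_length_min: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_stay", "p_skip"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.bases_per_second <= 0:
            raise ValueError("bases_per_second must be > 0")

    @property
    def samples_per_base(self) -> float:
        return self.sample_rate / self.bases_per_second


@dataclass
class SimulatedRead:
    """One simulated read with its ground-truth origin.

    ``truth`` is (target_id, strand, start, end): the forward-coordinate
    half-open base interval of the sampled region.  ``dwell_boundaries``
    are the sample offsets at which each emitted k-mer step begins.
    """

    read_id: str
    samples: np.ndarray
    sample_rate: float
    truth: tuple[str, str, int, int]
    dwell_boundaries: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_steps(self) -> int:
        """Number of emitted k-mer steps (after skips, including stays)."""
        return len(self.dwell_boundaries)


def synthetic_pore_model(k: int = 6, seed: int = 20, mean: float = 90.0, sd: float = 12.0) -> PoreModel:
    """A synthetic k-mer model with i.i.d. Gaussian levels (pA-scale).

    Stands in for a manufacturer k-mer model in tests and simulations;
    levels carry no sequence structure beyond being a fixed deterministic
    function of the seed.
    """
    rng = np.random.default_rng(seed)
    kmers = list(all_kmers(k))
    levels = dict(zip(kmers, rng.normal(mean, sd, size=len(kmers)).tolist()))
    return PoreModel(k=k, levels=levels)


def simulate_read(
    reference: list[tuple[str, str]],
    model: PoreModel,
    params: SimParams,
    rng: np.random.Generator,
    origin: tuple[str, str, int, int] | None = None,
    read_length: int | None = None,
    read_id: str = "read_0",
) -> SimulatedRead:
    """Simulate one read.

    ``origin``, if given, fixes (target_id, strand, start, end) with end
    exclusive; otherwise the target is drawn length-weighted, the strand
    uniformly, and the start uniformly among feasible positions.
    Deterministic given ``rng`` state.
    """
    k = model.k
    targets = dict(reference)
    if origin is not None:
        target_id, strand, start, end = origin
        seq = targets[target_id]
        if not (0 <= start < end <= len(seq)) or end - start < k:
            raise ValueError(f"infeasible origin {origin} for target of length {len(seq)}")
    else:
        if read_length is None:
            read_length = int(rng.gamma(3.0, params.read_length_mean / 3.0))
        ids = [t for t, s in reference]
        lens = np.array([len(s) for t, s in reference], dtype=np.float64)
        target_id = ids[int(rng.choice(len(ids), p=lens / lens.sum()))]
        seq = targets[target_id]
        read_length = int(np.clip(read_length, params.read_length_min, len(seq) - k))
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, len(seq) - read_length - k + 2))
        end = start + read_length + k - 1
    sub = seq[start:end]
    if strand == "-":
        sub = reverse_complement(sub)
    levels = seq_to_events(sub, model).values
    n_kmers = len(levels)
    if n_kmers < 1:
        raise ValueError(f"origin region too short for k={k}")

    keep = rng.random(n_kmers) >= params.p_skip
    stay = rng.random(n_kmers) < params.p_stay
    # emitted step sequence: each kept k-mer once, plus a duplicate on stay
    reps = np.where(keep, 1 + stay.astype(np.int64), 0)
    step_levels = np.repeat(levels, reps)
    n_steps = len(step_levels)
    if n_steps == 0:  # pathological (tiny read, everything skipped)
        step_levels = levels[:1]
        n_steps = 1

    base_dwell = params.samples_per_base
    if params.dwell_dispersion == 0.0:
        dwells = np.full(n_steps, max(1, round(base_dwell)), dtype=np.int64)
    else:
        raw = rng.normal(base_dwell, params.dwell_dispersion * base_dwell, size=n_steps)
        dwells = np.maximum(1, np.rint(raw)).astype(np.int64)
    samples = np.repeat(step_levels, dwells)
    if params.noise_sd > 0:
        samples = samples + rng.normal(0.0, params.noise_sd * model.level_scale, size=len(samples))
    boundaries = np.concatenate(([0], np.cumsum(dwells)[:-1]))
    return SimulatedRead(
        read_id=read_id,
        samples=samples,
        sample_rate=params.sample_rate,
        truth=(target_id, strand, start, end),
        dwell_boundaries=boundaries,
    )


def simulate_run(
    reference: list[tuple[str, str]],
    model: PoreModel,
    mixture: dict[str, float],
    n_reads: int,
    params: SimParams,
    seed: int | None = None,
    read_id_prefix: str = "read",
) -> list[SimulatedRead]:
    """Simulate a shuffled sequencing run from a taxon mixture.

    ``mixture`` maps target ids to proportions (summing to 1); the origin
    target of each read is drawn i.i.d. from the mixture, which yields a
    random arrival order of taxa as in a real pooled run.
    """
    props = np.array(list(mixture.values()), dtype=np.float64)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError(f"mixture proportions sum to {props.sum()}, expected 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    targets = dict(reference)
    ids = list(mixture.keys())
    for tid in ids:
        if tid not in targets:
            raise KeyError(f"mixture target {tid!r} not in reference")
    k = model.k
    choices = rng.choice(len(ids), size=n_reads, p=props)
    reads = []
    for i, cix in enumerate(choices):
        tid = ids[int(cix)]
        seq = targets[tid]
        read_length = int(
            np.clip(
                rng.gamma(3.0, params.read_length_mean / 3.0),
                params.read_length_min,
                max(params.read_length_min, len(seq) - k),
            )
        )
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, max(1, len(seq) - read_length - k + 2)))
        end = min(len(seq), start + read_length + k - 1)
        reads.append(
            simulate_read(
                reference,
                model,
                params,
                rng,
                origin=(tid, strand, start, end),
                read_id=f"{read_id_prefix}_{i}",
            )
        )
    return reads


# ----------------------------------------------------------------------
# plain-text signal format: one read per line,
#   read_id <TAB> sample_rate <TAB> space-separated current samples
# A generator-based adapter with the same (read_id, sample_rate, samples)
# record shape is the seam where a FAST5/POD5 front-end would plug in.
# ----------------------------------------------------------------------


def write_signals(reads: list[SimulatedRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            vals = " ".join(f"{v:.2f}" for v in r.samples)
            fh.write(f"{r.read_id}\t{r.sample_rate:g}\t{vals}\n")


def read_signals(path: str | Path) -> Iterator[tuple[str, float, np.ndarray]]:
    """Stream (read_id, sample_rate, samples) records from a signal file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            read_id, rate_str, samples_str = parts
            yield read_id, float(rate_str), np.array(samples_str.split(), dtype=np.float64)


def truth_paf_records(reads: list[SimulatedRead], reference: list[tuple[str, str]]):
    """Ground-truth PAF records (full origin interval per read)."""
    from .io_eval import PafRecord

    tlens = {tid: len(seq) for tid, seq in reference}
    records = []
    for r in reads:
        tid, strand, start, end = r.truth
        qlen = end - start
        records.append(
            PafRecord(
                qname=r.read_id,
                qlen=qlen,
                qstart=0,
                qend=qlen,
                strand=strand,
                tname=tid,
                tlen=tlens[tid],
                tstart=start,
                tend=end,
                nmatch=qlen,
                blocklen=end - start,
                mapq=60,
            )
        )
    return records
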