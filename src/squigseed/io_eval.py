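"""PAF input/output, ground-truth comparison, and config/logging plumbing.

Mappings are serialized in the minimap2 PAF dialect: 12 mandatory
tab-separated columns with 0-based half-open coordinates, followed by
typed ``TAG:TYPE:VALUE`` fields.  Unmapped reads are emitted with ``*``
as target name, 0/0 coordinates and strand ``+`` by convention, so every
read in a run appears exactly once in the output.

Evaluation follows the pafstats convention: a mapped call is a true
positive when it hits the same target and strand as the ground truth
with a start position within a base tolerance; reads mapped in truth but
unmapped or absent in the calls are false negatives; reads unmapped in
the truth are excluded from all counts.  For streamed (prefix) mappings
the strand-aware ``anchored_distance`` is the right error measure: the
mapped interval is anchored at the end of the read that entered the pore
first, which is the truth start on the forward strand and the truth end
on the reverse strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mapper import Mapping

logger = logging.getLogger(__name__)

_TAG_TYPES = {"i": int, "f": float, "A": str, "Z": str}


class PafError(ValueError):
    """Raised for malformed PAF input, naming the offending line."""


@dataclass
class PafRecord:
    qname: str
    qlen: int
    qstart: int
    qend: int
    strand: str
    tname: str
    tlen: int
    tstart: int
    tend: int
    nmatch: int
    blocklen: int
    mapq: int
    tags: dict[str, int | float | str] = field(default_factory=dict)

    @property
    def mapped(self) -> bool:
        return self.tname != "*"


def _format_tag(name: str, value) -> str:
    if isinstance(value, bool):
        raise PafError(f"boolean tag value for {name!r}")
    if isinstance(value, (int, np.integer)):
        return f"{name}:i:{int(value)}"
    if isinstance(value, (float, np.floating)):
        return f"{name}:f:{float(value):g}"
    return f"{name}:Z:{value}"


def write_paf(records: list[PafRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            cols = [
                r.qname,
                str(r.qlen),
                str(r.qstart),
                str(r.qend),
                r.strand,
                r.tname,
                str(r.tlen),
                str(r.tstart),
                str(r.tend),
                str(r.nmatch),
                str(r.blocklen),
                str(r.mapq),
            ]
            cols.extend(_format_tag(k, v) for k, v in r.tags.items())
            fh.write("\t".join(cols) + "\n")


def read_paf(path: str | Path) -> list[PafRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise PafError(f"{path}:{lineno}: {len(cols)} columns, expected >= 12")
            try:
                rec = PafRecord(
                    qname=cols[0],
                    qlen=int(cols[1]),
                    qstart=int(cols[2]),
                    qend=int(cols[3]),
                    strand=cols[4],
                    tname=cols[5],
                    tlen=int(cols[6]),
                    tstart=int(cols[7]),
                    tend=int(cols[8]),
                    nmatch=int(cols[9]),
                    blocklen=int(cols[10]),
                    mapq=int(cols[11]),
                )
            except ValueError as exc:
                raise PafError(f"{path}:{lineno}: {exc}") from exc
            for tag in cols[12:]:
                parts = tag.split(":", 2)
                if len(parts) != 3 or parts[1] not in _TAG_TYPES:
                    raise PafError(f"{path}:{lineno}: malformed tag {tag!r}")
                name, typ, val = parts
                rec.tags[name] = _TAG_TYPES[typ](val)
            records.append(rec)
    return records


def mapping_to_paf(mapping: Mapping, target_lengths: dict[str, int]) -> PafRecord:
    """Serialize one mapping decision as a PAF record.

    Query coordinates are event indices (one event advances one base
    through the pore); query length is the number of events consumed
    before the decision.  Chain score, chunk and event accounting travel
    in the ``s1``/``ch``/``ev`` tags.
    """
    tags = {
        "s1": round(mapping.chain_score, 3),
        "ch": mapping.chunks_used,
        "ev": mapping.events_used,
    }
    if not mapping.mapped:
        return PafRecord(
            qname=mapping.read_id,
            qlen=mapping.events_used,
            qstart=0,
            qend=0,
            strand="+",
            tname="*",
            tlen=0,
            tstart=0,
            tend=0,
            nmatch=0,
            blocklen=0,
            mapq=0,
            tags=tags,
        )
    return PafRecord(
        qname=mapping.read_id,
        qlen=mapping.events_used,
        qstart=mapping.query_start,
        qend=mapping.query_end,
        strand=mapping.strand,
        tname=mapping.target_id,
        tlen=target_lengths.get(mapping.target_id, 0),
        tstart=mapping.target_start,
        tend=mapping.target_end,
        nmatch=mapping.n_anchors,
        blocklen=mapping.target_end - mapping.target_start,
        mapq=min(60, int(mapping.chain_score)),
        tags=tags,
    )


@dataclass
class EvalResult:
    """Precision/recall accounting against ground truth."""

    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def _primary_calls(calls: list[PafRecord]) -> dict[str, PafRecord]:
    """Keep one call per read: highest chain score (s1 tag), then first."""
    best: dict[str, PafRecord] = {}
    for rec in calls:
        prev = best.get(rec.qname)
        if prev is None:
            best[rec.qname] = rec
            continue
        if rec.mapped and (
            not prev.mapped
            or rec.tags.get("s1", rec.mapq) > prev.tags.get("s1", prev.mapq)
        ):
            best[rec.qname] = rec
    return best


def compare_to_truth(
    calls: list[PafRecord], truth: list[PafRecord], tolerance: int = 500
) -> EvalResult:
    """pafstats-style comparison of calls against ground truth.

    TP: mapped call on the truth's target and strand with
    |tstart difference| <= tolerance.  FP: any other mapped call for a
    truth-mapped read.  FN: truth-mapped reads unmapped or missing in
    the calls.  Truth-unmapped reads contribute to no count.
    """
    truth_by_read = _primary_calls(truth)
    call_by_read = _primary_calls(calls)
    res = EvalResult()
    for qname, t in truth_by_read.items():
        if not t.mapped:
            continue
        c = call_by_read.get(qname)
        if c is None or not c.mapped:
            res.fn += 1
        elif (
            c.tname == t.tname
            and c.strand == t.strand
            and abs(c.tstart - t.tstart) <= tolerance
        ):
            res.tp += 1
        else:
            res.fp += 1
    return res


def anchored_distance(call: PafRecord, truth: PafRecord) -> float:
    """Strand-aware position error for a prefix mapping, in bases.

    The streamed mapping covers part of the read sequenced before the
    accept decision, starting ``qstart`` events into the read.  Its
    implied position for the first base through the pore is
    ``tstart - qstart`` on the forward strand and ``tend + qstart`` on
    the reverse strand (one event advances one base); the error is the
    distance between that implied position and the corresponding end of
    the truth interval.  Returns inf on target or strand mismatch.
    """
    if not call.mapped or call.tname != truth.tname or call.strand != truth.strand:
        return float("inf")
    if call.strand == "+":
        return abs((call.tstart - call.qstart) - truth.tstart)
    return abs((call.tend + call.qstart) - truth.tend)


def abundance_distance(estimate, truth) -> float:
    """Euclidean (L2) distance between two abundance vectors.

    Accepts aligned arrays or taxon->proportion dicts (aligned over the
    union of taxa, missing entries 0).
    """
    if isinstance(estimate, dict) or isinstance(truth, dict):
        taxa = sorted(set(estimate) | set(truth))
        e = np.array([estimate.get(t, 0.0) for t in taxa])
        t = np.array([truth.get(t_, 0.0) for t_ in taxa])
    else:
        e = np.asarray(estimate, dtype=np.float64)
        t = np.asarray(truth, dtype=np.float64)
        if e.shape != t.shape:
            raise ValueError(f"dimension mismatch: {e.shape} vs {t.shape}")
    return float(np.linalg.norm(e - t))


def write_abundance_tsv(
    path: str | Path,
    counts: dict[str, int],
    proportions: dict[str, float],
    reads_consumed: int,
    stopped_early: bool,
) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tcount\tproportion\n")
        for taxon in sorted(proportions):
            fh.write(f"{taxon}\t{counts.get(taxon, 0)}\t{proportions[taxon]:.6f}\n")
        fh.write(f"# reads_consumed={reads_consumed}\tstopped_early={stopped_early}\n")


def load_config(path: str | Path) -> dict:
    """Load a YAML config file (flat or nested keys, e.g. seg.window_short)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
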