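"""Real-time relative abundance estimation with early run termination.

In a multi-genome (metagenomic) run, each mapped read is assigned to a
taxon through its reference sequence id, and the running per-taxon
proportions of mapped reads form the relative abundance estimate.  Every
``estimate_every`` mapped reads the current estimate vector is appended
to a sliding window of the last ``window_w`` estimates.  The run is
stopped — the whole-run analogue of Read Until, stopping the sequencer
for all subsequent reads — once the window contains no outlier: every
estimate in the window correlates with the leave-one-out mean of the
others above ``outlier_threshold``.  A window still containing an
outlier means recent reads are still moving the estimate and sequencing
should continue.

Taxon resolution convention: reference record ids of the multi-genome
reference carry a ``taxid|<id>|`` prefix (e.g. ``taxid|562|chr``);
records without the prefix count under the taxon "unknown".
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .mapper import Mapping

logger = logging.getLogger(__name__)

TAXON_PREFIX = "taxid|"
UNKNOWN_TAXON = "unknown"


@dataclass(frozen=True)
class SequenceUntilParams:
    """Convergence-detection configuration.

    ``estimate_every``: mapped reads between successive estimates;
    ``window_w``: number of recent estimates compared; a window of
    identical estimates has all leave-one-out correlations equal to 1,
    so ``outlier_threshold`` close to 1 demands near stationarity before
    stopping.  Because the estimates are cumulative proportions, window
    members are strongly correlated even while the mixture is still
    moving; the default threshold (0.998) is set tight enough that a
    drifting mixture keeps registering outliers while a stationary one
    converges within a few windows (see the methods note).
    """

    estimate_every: int = 100
    window_w: int = 5
    outlier_threshold: float = 0.998

    def __post_init__(self) -> None:
        if self.estimate_every < 1:
            raise ValueError("estimate_every must be >= 1")
        if self.window_w < 3:
            raise ValueError("window_w must be >= 3")


@dataclass
class AbundanceState:
    """Running mapped-read counts and the sliding window of estimates."""

    counts: dict[str, int] = field(default_factory=dict)
    estimates_history: deque = field(default_factory=deque)
    reads_since_estimate: int = 0
    total_mapped: int = 0

    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {t: c / total for t, c in sorted(self.counts.items())}


def taxon_of(target_id: str) -> str:
    """Resolve a reference record id to its taxon id."""
    if target_id.startswith(TAXON_PREFIX):
        rest = target_id[len(TAXON_PREFIX) :]
        tax = rest.split("|", 1)[0]
        if tax:
            return tax
    logger.warning("target id %r carries no taxon prefix; counting as %r", target_id, UNKNOWN_TAXON)
    return UNKNOWN_TAXON


def update_abundance(
    state: AbundanceState, mapping: Mapping, params: SequenceUntilParams
) -> AbundanceState:
    """Fold one mapping into the abundance state.

    Unmapped reads are ignored.  Every ``estimate_every`` mapped reads
    the cumulative proportions are appended to the estimate window
    (keeping the last ``window_w``).
    """
    if not mapping.mapped:
        return state
    taxon = taxon_of(mapping.target_id)
    state.counts[taxon] = state.counts.get(taxon, 0) + 1
    state.total_mapped += 1
    state.reads_since_estimate += 1
    if state.reads_since_estimate >= params.estimate_every:
        state.estimates_history.append(state.proportions())
        while len(state.estimates_history) > params.window_w:
            state.estimates_history.popleft()
        state.reads_since_estimate = 0
    return state


def _align(history: Iterable[dict[str, float]]) -> np.ndarray:
    """Stack estimate dicts into a matrix over the union of taxa."""
    history = list(history)
    taxa = sorted({t for est in history for t in est})
    return np.array([[est.get(t, 0.0) for t in taxa] for est in history])


def _loo_correlation(mat: np.ndarray, i: int) -> float:
    """Pearson correlation of estimate i with the mean of the others."""
    v = mat[i]
    others = np.delete(mat, i, axis=0).mean(axis=0)
    dv = v - v.mean()
    do = others - others.mean()
    # degenerate windows: identical vectors converge; zero variance with a
    # real difference cannot be scored and counts as an outlier
    if np.max(np.abs(v - others)) < 1e-12:
        return 1.0
    denom = np.linalg.norm(dv) * np.linalg.norm(do)
    if denom == 0.0:
        return 0.0
    return float(np.dot(dv, do) / denom)


def is_converged(history: Iterable[dict[str, float]], params: SequenceUntilParams) -> bool:
    """True iff the window holds window_w estimates and none is an outlier.

    An estimate is an outlier when its leave-one-out correlation falls
    below ``outlier_threshold``; no outliers in the window indicates the
    estimate has converged and sequencing can stop.
    """
    history = list(history)
    if len(history) < params.window_w:
        return False
    mat = _align(history)
    return all(
        _loo_correlation(mat, i) >= params.outlier_threshold for i in range(len(history))
    )


@dataclass
class SequenceUntilResult:
    abundance: dict[str, float]
    reads_consumed: int
    stopped_early: bool
    fraction_consumed: float = 0.0


def run_sequence_until(
    mappings: Iterable[Mapping],
    params: SequenceUntilParams | None = None,
    total_reads: int | None = None,
) -> SequenceUntilResult:
    """Consume a mapping stream until convergence or stream end.

    Stops at the first converged estimate window (the Run Until
    surrogate) and reports the estimate at stop time plus how much of
    the stream was consumed.  ``total_reads``, when known, lets the
    consumed fraction be reported even on early stop.
    """
    params = params or SequenceUntilParams()
    state = AbundanceState()
    consumed = 0
    stopped = False
    for mapping in mappings:
        consumed += 1
        update_abundance(state, mapping, params)
        appended = mapping.mapped and state.reads_since_estimate == 0
        if appended and is_converged(state.estimates_history, params):
            stopped = True
            break
    total = total_reads if total_reads is not None else consumed
    return SequenceUntilResult(
        abundance=state.proportions(),
        reads_consumed=consumed,
        stopped_early=stopped,
        fraction_consumed=consumed / total if total else 0.0,
    )
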