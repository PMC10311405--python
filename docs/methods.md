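# Methods

squigseed maps raw nanopore current signals to a reference genome in
real time, without basecalling, and estimates relative abundance in
multi-genome runs with an early-stop rule.  This note records the model,
the parameter choices, and the design decisions behind the
implementation, together with what the synthetic-data experiments do and
do not demonstrate.

## Signal model and event generation

A nanopore reports current samples while a DNA strand translocates at
roughly 450 bases/s, sampled at ~4 kHz, so each base step contributes
about 9 samples at a level characteristic of the k-mer occupying the
pore (k = 6 for the models used here).  Both sides of the comparison are
reduced to *events*:

- **Reference side.** Every overlapping k-mer of a reference sequence is
  looked up in the pore model (only the mean level column is used), and
  the resulting series is z-scored per reference sequence (chromosome or
  contig).  k-mers containing non-ACGT characters produce no event;
  event positions remain absolute so coordinates survive the gaps.
  Lowercase (soft-masked) bases are treated as their uppercase base.
- **Signal side.** The raw sample stream is segmented at level changes
  detected by Welch's t-test between the w samples before and after each
  position, run for two window lengths (3 and 6 samples) with paired
  thresholds (4.3 and 2.57).  A position qualifies only when its
  statistic exceeds the window's threshold and is a local peak; peaks
  from the two windows closer than 4 samples are one level change and
  the stronger peak wins.  Each segment becomes an event summarized by
  its sample mean; segments shorter than 3 samples are dropped as
  stay/skip artefacts.  Event means are z-scored per time chunk (the
  events from one second of signal, configurable), streamed chunk by
  chunk; a chunk with fewer than two events is merged into the next.

The z-score uses the population standard deviation on both sides.  The
choice of population vs sample denominator is immaterial to matching as
long as it is consistent, which is the property that matters.

Segmentation thresholds are deliberately permissive.  With short
windows the t statistic has few degrees of freedom and heavy tails, so
pure noise occasionally produces a spurious boundary; those split one
dwell into two same-level events, which the minimum-segment filter and
the gap-tolerant chaining absorb.  Raising the thresholds enough to
eliminate such peaks would instead miss genuine level changes between
k-mers with similar levels, which costs seed matches.  The defaults were
chosen so that (i) a clean staircase's change points are recovered
within ±3 samples essentially always, (ii) constant input produces no
boundaries, and (iii) on noise-free uniform-dwell simulated reads the
number of detected events matches the number of simulated k-mer steps
to well under 2%.

## Quantization

Normalized event values from the same k-mer differ slightly between
runs, so exact matching requires deliberate coarsening.  An event value
is viewed in its IEEE-754 single-precision bit pattern (bit 1 = sign,
MSB first); the top Q bits are kept and p bits immediately after the top
two are pruned, leaving the (Q−p)-bit code E[1,2]·E[3+p,Q] with the
constraint 2+p < Q.  Negative zero is canonicalized before extraction.
Two values collide exactly when they agree on the sign bit, the exponent
MSB, and the retained low bits — i.e. when they are close on the
float's log-magnitude scale.  Buckets are therefore octave-shaped:
coarse near |v| ≈ 1–3 and fine near zero.  Coarsening is monotone:
decreasing Q or increasing p merges buckets and never splits them.

Default (Q, p) = (9, 4), giving 5-bit codes: the sign bit, the exponent
MSB, and the three low exponent bits.  Per-application presets (viral /
small / large genome) share these bits and vary the seed length below.

## Seeding and indexing

n consecutive codes (default n = 6, ~11 bases of context per seed) are
packed MSB-first — earliest event in the highest bits — into an
n×(Q−p)-bit word and mixed to a 32-bit hash.  For packed widths ≤ 32
the MurmurHash3 32-bit finalizer is used (a bijection on the packed
domain, so no avoidable collisions); wider seeds go through the
SplitMix64 finalizer with the two 32-bit halves XOR-folded, and the
resulting collisions are tolerated because mapping requires several
colinear matches.  The hash function identifier is recorded in the
index header.

The index stores, for every seed hash across both strands of every
target, its hits (target, position, strand) in a sorted-bucket layout.
Reverse-strand seeds are generated from the reverse complement and
recorded in forward coordinates (position of the leftmost covered
k-mer), PAF-style.  The most frequent 0.02% of hashes are masked and
return no hits: these are low-complexity/repetitive quantization
patterns whose buckets would dominate chaining cost while carrying
little placement information.  The on-disk format is a little-endian
binary container (magic, JSON parameter block, raw arrays), bit-exact
across platforms; mapping refuses an index whose (Q, p, n, model)
disagree with the query pipeline.

## Chaining and the mapping decision

Each query seed window that hits the index yields anchors (query event
index, reference position, strand).  Chains are scored by dynamic
programming over anchors sorted by (target, strand, position): each
anchor contributes one match score, a predecessor must strictly
precede the anchor in both coordinates with both deltas bounded by
`max_gap`, and the gap cost is γ·|Δtarget − Δquery| with γ = 0.01 ×
match score.  There is intentionally no term proportional to the anchor
distance itself: with stay/skip noise the absolute spacing of seed
matches is uninformative, only the disagreement between the reference
and query deltas is penalized.  Look-back is capped at `max_skip` (25)
predecessors; score ties are broken toward the lexicographically lower
target and lower start.  Reverse-strand anchors are chained in mirrored
coordinates so colinearity always means "both increasing", and
un-mirrored on output.

Streaming decision: after each one-second chunk the cumulative anchor
set is re-chained (evidence transfers between chunks), and the read is
accepted when the best chain clears `min_chain_score` (6) **and** beats
the best chain from a different region — another target, or a disjoint
interval of the same target — by the factor `best_ratio` (1.2).  The
ratio test is what rejects reads from duplicated regions.  On accept the
read stops being consumed (the Read Until surrogate: on a sequencer this
is the ejection point); after `max_chunks` (20) chunks without a
decision the read is reported unmapped.  The accept rule itself (score
threshold + distinct-region ratio) is a design choice of this package,
exposed in configuration.

Coordinates: one event is taken to advance one base, so query event
indices map 1:1 to bases, and the k-mer span is added to the target end.
Skips and merged events make this conversion approximate (an event
index undercounts bases by roughly 5–20%), which is why locus accuracy
is evaluated at the read's *anchored* end: the implied position of the
first base through the pore, obtained by extrapolating the mapped
interval back by the query offset (forward strand: tstart − qstart;
reverse: tend + qstart).  The plain start-position comparison in
`compare_to_truth` follows the pafstats convention with a 500-base
default tolerance and is the right tool for full-length mappings.

## Sequence Until

For multi-genome runs, reference ids carry a `taxid|<id>|` prefix.
Each mapped read increments its taxon's count; every `estimate_every`
(100) mapped reads the cumulative proportions are appended to a window
of the last `window_w` (5) estimates.  The run stops when no window
member is an outlier, where an estimate is an outlier if its Pearson
correlation with the leave-one-out mean of the others falls below
`outlier_threshold`.

The threshold default is 0.998.  Because the estimates are cumulative,
window members share most of their data and correlate strongly even
while the mixture composition is still moving; a threshold of 0.998 is
the level at which (measured on synthetic streams) a stationary 5-taxon
mixture converges after roughly 600–900 mapped reads while a
continuously drifting mixture keeps registering outliers until well
after its drift ends.  Two caveats are inherent to the construction:
with only two taxa every pair of proportion vectors has Pearson
correlation ±1, so the rule degenerates (use three or more taxa, or
treat the single-taxon/two-taxon cases as converging at the earliest
legal window); and a *step* change in the mixture cannot be
distinguished beforehand from stationarity — no rule operating on the
estimates can defer past a change point whose prefix is stationary, so
only sustained drift defers the stop.

## Signal simulator

The simulator reverses the reference event model: it draws an origin
(length-weighted target, uniform strand and position), walks the
k-mers of the region (reverse-complemented on the reverse strand), and
emits per k-mer a dwell of sample_rate/bases_per_second samples
(default 4000/450 ≈ 8.9), jittered by a 30% dispersion, at the model
level plus white Gaussian noise.  Noise is specified relative to the
population spread of the model levels (default 0.25 sd) so difficulty
is invariant to the model's current units.  Stay errors (5%) duplicate
a k-mer's dwell; skip errors (5%) drop a k-mer.  Read lengths follow a
gamma distribution (shape 3, mean 4000 bases, minimum 500).  Runs over
a taxon mixture draw each read's taxon i.i.d., giving the shuffled
arrival order of a pooled run, and carry ground truth (target, strand,
forward interval) per read.

What the simulator does *not* model: adapter/stall regions at read
starts, per-pore calibration drift, low-frequency baseline wander,
correlated (pink) noise, ADC quantization, and RNA kinetics.  Passing
the synthetic end-to-end suite therefore demonstrates the internal
consistency of the pipeline — segmentation, quantization, seeding and
chaining recover planted signal under realistic dwell/noise/stay/skip
statistics — not performance on real flow-cell data, which varies with
chemistry and basecalling-model fit.

## Numerical and degenerate-input choices

- Welch statistic with zero denominator: equal means give t = 0
  (constant signal); differing means give an effectively infinite
  statistic (ideal noise-free step).
- Series shorter than 2 values or with zero variance cannot be
  z-scored and raise; a chunk with fewer than 2 events is buffered into
  the next chunk.
- Non-finite event values are rejected by the quantizer (they cannot
  arise from a valid z-score and indicate upstream corruption).
- Chain extraction assigns each anchor to at most one chain; a chain
  backtracking into a consumed anchor is truncated there with its score
  reduced by the consumed prefix.
- All tie-breaks (boundary clusters, equal-score chains, masking ties)
  are deterministic, so output is byte-stable across runs.

## Problem sizes used in the shipped experiments

The acceptance experiments use a 1 Mb random reference with 500
simulated reads at default noise (plus 200 noise-free reads), and a
50,000-read synthetic mapping stream at a fixed 5-taxon mixture for the
early-stop experiment.  These sizes give binomial standard errors of
about 1% on acceptance rates and keep the whole suite in the
seconds-to-minutes range on one CPU; the pipeline itself has no
size-specific assumptions (indexing is linear in reference length, and
per-read cost is bounded by `max_chunks`).

## Known limitations

- The quantizer's octave-shaped buckets are finest near zero, where
  z-scored events are densest; heavy per-event noise therefore breaks
  matches for small-magnitude events first.  Larger Q would help only
  with correspondingly cleaner signals.
- Precision is high but not 1: a rare borderline collision chain can
  clear the accept rule (observed at roughly the 1-in-100 level on
  foreign reads at default settings).
- The event↔base conversion is approximate (see above); reported base
  intervals are accurate at the anchored end and drift with distance
  from it.
- FAST5/POD5 parsing is out of scope; the plain-text signal format and
  the generator-based reader in `signal_sim` are the adapter seam where
  a binary front-end would plug in.
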