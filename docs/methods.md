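# Methods

## Signal model

A replication origin that fires in a fraction *e*/100 of cells (efficiency
*e*, in percent) contributes that fraction of an extra genome copy to the
probes around it when S phase proceeds in hydroxyurea (HU). HU stalls forks
near initiation sites, and the distance forks travel before arrest varies
between cells, so the population-average replicated fraction around a fired
origin is modeled as a trapezoid: fully replicated within a core of ±2 kb and
decaying linearly to zero at the maximal extent of ±7 kb (replication around
an origin in HU can reach 10–15 kb; 7 kb is the default reach under the
stronger HU dose used for comparative profiling). Overlapping contributions
from neighboring origins are summed and capped at 1, since a probe cannot be
replicated in more than 100% of cells. The expected two-channel ratio at a
probe is

```
ratio = (1 + b) × (1 + Σ_origins e/100 × shape(distance))
```

where *b* is a global baseline offset (the replicating sample is never purely
"1 genome" relative to the reference; real experiments report correction
factors of 0.1–0.2, and the generator defaults to b = 0.15).

The fully replicated core matters for two reasons. First, it guarantees that
the single 5-probe geometric mean applied during normalization does not
attenuate the peak apex (the core spans ±8 probes at 250-bp spacing). Second,
a shape that is *not* flat over many kilobases keeps the apex identifiable:
with a broad plateau the smoothed maximum can sit anywhere on the flat top
under noise, and apex positions become irreproducible at the multi-kilobase
scale. The 2-kb core also means two origins 3 kb apart each contribute fully
at their midpoint (their summed ratio there is 1.4 at 20% efficiency each).

## Noise and the dye swap

Each hybridization of a probe receives one multiplicative lognormal noise
draw with mean 1 and coefficient of variation `noise_cv` (default 0.05) on
the replicated channel, so the per-hybridization two-channel ratio has CV
`noise_cv`. Two-channel ratio data are positive and multiplicative, which is
why the noise is lognormal rather than additive. A dye-specific gain
(`dye_bias`) multiplies channel 1 of the non-swapped hybridization only; it
scales the whole track uniformly after dye-swap averaging and is removed
exactly by baseline correction.

## Normalization chain

Order of operations, per condition:

1. per-hybridization ratio (channels of the swapped hybridization flipped
   first); non-positive intensities invalidate the probe only;
2. 5-probe moving geometric mean per hybridization, never across chromosome
   boundaries, with truncated (shrinking) windows at chromosome ends so the
   track keeps the grid's length;
3. arithmetic mean of the two dye-swapped hybridizations (the procedure is
   stated simply as "averaged"; a geometric-mean variant would differ only at
   second order for these noise levels);
4. outlier removal (below);
5. arithmetic mean of the two biological repeats (a probe is invalid only if
   invalid in every contributing track);
6. baseline correction: m = median of the lowest 10% of valid ratios; every
   ratio is divided by m (a subtraction mode, ratio − (m − 1), is available
   via `baseline_mode="subtract"`); the reported correction factor is m − 1.
   Division is the default because it preserves the ratio→efficiency reading
   multiplicatively at the baseline. The operation is exactly idempotent.

Whether outlier removal precedes or follows repeat averaging is not
determined by the procedure's published description; this implementation
removes outliers per repeat, before averaging, so that an artifact present in
one repeat cannot contaminate the average.

### Outlier removal

Probes are flagged when their log-ratio deviates from the chromosome-wise
running median (51-probe window) by more than k × MAD (scaled MAD of the
running-median residuals per chromosome, k = 5) **and** by more than an
absolute floor of ln 2.5. The floor restricts the filter to
order-of-magnitude hybridization artifacts: genuine origin peaks reach ratios
of at most ~2, safely below it, and on a noise-free track — where the MAD is
zero and a pure k×MAD rule would flag every peak shoulder — nothing is
flagged.

## Origin calling

Smoothing applies the 5-probe geometric mean for 10 further rounds. Candidate
peaks are strict local maxima of the smoothed track above ratio 1.05;
plateaus resolve to the central probe (left of center for even widths). A
prominence filter (≥ 0.01 over the higher flanking saddle) replaces manual
visual confirmation with a deterministic rule: it suppresses secondary maxima
created by noise on one peak top while leaving any isolated peak untouched
(an isolated peak's prominence is its full height above the surrounding
baseline). Efficiencies are read from the non-smoothed, baseline-corrected
track as the maximum valid ratio within ±2 probes of the apex — the ±2-probe
reach absorbs small localization errors of the smoothed apex — and
candidates below copy number 1.1 (10% efficiency) are dropped. Origins closer
than 5 kb are merged iteratively (closest pair first, ties to the left),
keeping the member with the higher copy number, because HU-limited
replication around one origin spans several kilobases and sub-5-kb peak
pairs are not independent initiation events. Cross-condition matching is
greedy by increasing distance with a strict 5-kb tolerance; an exhaustive
assignment differs only on pathological ties.

## Regional profiles and statistics

Regional profiles average an origin-level quantity (efficiency, or Cdc45
IP/input) over windows of 1000 probes (~250 kb). "Continuous windows" is
implemented as a sliding window with a 1-probe step by default — the regional
curves are then smooth — with a tiled (non-overlapping) mode available;
conclusions do not depend on the choice. Windows containing no origin carry
no value (never zero, which would masquerade as 0% efficiency). Comparisons
use Spearman rank correlation (average ranks on ties, two-sided p) and
independent-samples two-sided t-tests, Welch by default since nothing
guarantees equal variances between conditions (pooled variance available).
No multiple-testing correction is applied anywhere; reports carry raw
p-values.

## Cdc45 ChIP-chip

Origins come exclusively from the replication pipeline; no peaks are called
on ChIP signal. Per-origin binding is the highest IP/input value within ±3
probes (inclusive, 7 probes total) of the origin's nearest probe, taken on
raw probe values; the 5-probe geometric-mean/replicate-average smoothing
exists only for display. The synthetic Cdc45 track places
`background + gain × efficiency` on the probe nearest each origin with a
linear decay over 8 probes, so noiseless origin-level recovery is exact and
binding rank-matches efficiency by construction.

## DNA combing

Raw BrdU intervals on a fiber are first merged across gaps shorter than 3 kb
(such a gap is below the threshold for a genuine unlabeled stretch), then
merged tracks shorter than 0.6 kb are discarded. The order matters and is
pinned by a fixture (two 0.4-kb blips separated by 1 kb survive as one
1.8-kb track). IODs are measured midpoint-to-midpoint — under symmetric
bidirectional synthesis the origin sits at the track center — with a
start-to-start mode available. Display truncation of IODs above 100 kb never
affects statistics. The implied pixel size (0.6 kb = 3 px) is 0.2 kb/px; all
inputs are in kb.

## Synthetic-data defaults and what they do (and do not) show

The default genome is three chromosomes of 5.6/4.5/2.5 Mb tiled every 250 bp,
mimicking a fission-yeast tiling array. 300 origins are placed with a 20-kb
minimum spacing (at least twice the replication footprint, so neighboring
peaks stay separable). Domain-structured efficiencies alternate low-mean
(15%) and high-mean (35%) segments, sd 8, clipped to [2, 70]; these values
put the genome mean near 25–28%, matching the range of published HU origin
maps, and give regional profiles genuine peaks and troughs. Fibers are
150–400 kb (uniform; real studies report per-condition totals, not a length
law) with 3-kb label half-widths. The probe-level noise CV (0.05) is a
deliberate choice that makes recovery tests discriminating; it is not fitted
to any particular array dataset. The generator emulates baseline offset, dye
bias, multiplicative probe noise, efficiency domains and Bernoulli per-cell
firing, but not spatial artifacts on the array surface, probe-specific
affinity differences, GC effects, or copy-number variation in the genome
itself — so passing recovery tests demonstrate correctness of the analysis
chain, not robustness to every failure mode of real arrays.

## Known estimator biases

Two elements of the published estimator chain are biased upward under probe
noise, and the effect is visible in parameter-recovery tests at noise CV
0.05 (per-origin efficiency RMSE ≈ 3.9 percentage points despite 99.6%
recall within 2.5 kb and no false calls):

* the baseline "median of the lowest 10% of ratios" is the 5th percentile of
  the track, which under symmetric noise lies below the true unreplicated
  level by about 1.4 noise-sigma; dividing by it inflates every corrected
  ratio (~+1.8% here, i.e. +2–2.5 efficiency points at typical
  efficiencies);
* "maximum value within a ±2-probe window" is an extremum statistic and adds
  ~+1 point, plus a smaller contribution from centering that window on the
  noise-correlated detected apex.

Both rules are kept as published; reading the single apex probe instead of
the window maximum would roughly halve the error but would depart from the
established procedure. In a noiseless setting the whole chain is exact
(positions to probe resolution, efficiencies to < 1 point).

## Numerical and convention notes

* Coordinates are 1-based inclusive in TSVs and in memory; BED/bedGraph
  exports are 0-based half-open. Probes and origins are strandless; BED
  strand is ".".
* Geometric means are computed in log space; all-invalid windows produce
  invalid probes rather than placeholder values.
* All randomness flows from explicit seeds (`numpy.random.default_rng`);
  repeat sub-seeds are derived deterministically from the config seed, and
  the written parameter manifest suffices to re-run bit-identically.
* Degenerate inputs: constant input to Spearman and zero-variance t-tests
  return NaN statistics with an explanatory note instead of raising;
  baseline correction requires ≥ 10 valid probes; merging and matching
  tolerate empty sets.
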