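# Methods

This note records the models, conventions and numerical choices behind
`paircn`, and what the synthetic-data experiments do and do not show.

## Coordinate system

All profiles live on a `GenomeGrid`: an ordered probe map over
chromosomes 1–22 and X (Y is absent). Segments are 1-based inclusive in
bp (SEG convention). For bp-weighted statistics each probe owns the
half-open interval reaching to the midpoints of its neighbours, clipped
to the chromosome; the intervals of a chromosome tile it exactly, so a
chromosome's probe weights always sum to its length. A chromosome with
no probes is excluded from the analysed genome (with a warning), so
denominators refer to probed sequence only.

## Signal model and cellularity

The observed log2 ratio of a probe is modelled as a two-population
mixture of tumor cells (fraction `c`, true tumor ratio `2^t`) and normal
cells (ratio 1), plus probe noise:

    y = log2(c · 2^t + (1 − c)) + ε,   ε ~ N(0, σ²)

Admixture shrinks `|y|` toward 0 monotonically in `c`. The correction
inverts this map on **segment means** before calling (not on raw probes
before segmentation): means are far less noisy than single probes, and
inverting a noisy probe near the admixture baseline is numerically
explosive. The alternative (`cellularity_stage: "probes"`) is available
in the run configuration. The inferred tumor ratio is floored at `2^-8`
so observations below the baseline (deep deletions plus noise) stay
finite; the inversion is exact (≤ 1e-12) whenever the floor is not hit.

Median normalization subtracts the median of all non-missing probes —
all chromosomes including X — so a profile's median is exactly 0 and
the operation is idempotent.

## Segmentation

Proprietary rank-segmentation implementations are undocumented, so the
package implements the closest published analogue: circular binary
segmentation with a Wilcoxon rank-sum statistic. Within a segment of
`n` probes, every arc `[i, j)` (with `min_probes` on each side, and both
outer pieces viable for interior arcs) is scored by

    Z = |W − k·r̄| / sqrt(k(n−k)/(n−1) · Var(r)),

where `r` are tie-averaged ranks, `W` the rank sum of the arc and
`k = j − i`. This is the exact mean/variance of a k-subset rank sum
under sampling without replacement, so ties need no separate correction.
An arc ending at `n` duplicates the complementary edge split and is
dropped. The arc maximizing `|Z|` is tested by permutation: the segment's
values are shuffled `n_permutations` times (default 1000) and the null
statistic is the maximum `|Z|` over all arcs; the split is accepted when
the add-one p-value falls below `alpha` (default 0.01). Accepted arcs
recurse into the up-to-three resulting pieces.

A plain single-split scan was rejected during design: an interior focal
event (e.g. 8 amplified probes among 118) yields a near-zero edge-split
rank statistic and is never found, which would break focal-amplification
screening; the arc scan subsumes edge splits and retains that power.

Choices worth knowing:

- **Tie-break**: on exactly tied `|Z|`, the shortest arc wins, then the
  leftmost — results are deterministic.
- **Determinism across alpha**: each recursion node seeds its RNG from
  `(seed, chromosome, node bounds)`, so p-values are identical across
  runs and lowering `alpha` can only prune splits, never add them.
- **Missing probes** are excluded from splitting and afterwards inherit
  the mean of their enclosing segment (a run of missing probes between
  two segments joins the left one).
- **Power**: a permutation stop has p-resolution `1/(B+1)` and little
  power on very short segments — with 3-versus-3 probes the best split's
  permutation p cannot go below ~0.1 — so exact breakpoint recovery is
  only expected when true segments carry roughly 20 probes or more.
  Cohort-scale experiments use `n_permutations = 150–200` (p-resolution
  ≈ 0.006, still well below alpha); the per-operation default stays 1000.

## Calling and aberrant-genome fraction

Segment means, after cellularity correction, are thresholded at
gain ≥ 0.2, loss ≤ −0.2, amplification ≥ 0.6, homozygous deletion ≤ −1.0
(log2 units). Boundary values are called aberrant; this inclusive
convention only matters on a measure-zero set for continuous data.
Calling is monotone in the segment mean. The aberrant-genome fraction is
bp-weighted by default (probe intervals), with a probe-counted variant
available, since published per-cohort figures do not state which
weighting was used.

## Pairwise concordance

Concordance of a matched pair is the percent of analysed bp on which
both profiles carry the same three-state call (gain/loss/normal,
amplifications collapsed into gains, homozygous deletions into losses).
Because calls are constant within segments and probe intervals tile the
genome, overlaying the union of both samples' segment boundaries is
exactly equivalent to a bp-weighted comparison of per-probe calls, which
is how it is computed; the test suite verifies equality with a literal
per-bp expansion to 1e-9. Probes missing in either sample are excluded
from numerator and denominator alike. Cohort pairs are binned as >95,
70–95 and <70 percent; both boundary values are assigned to the middle
bin (the convention is documented because published group ranges never
touch the boundaries, so any convention reproduces them).

## Clustering and pairwise joining

Distances are `1 − ρ_Spearman` between segmented per-probe mean vectors,
so clustering sees the same piecewise-constant signal as the rest of the
pipeline and is invariant to monotone transforms of each profile. A flat
(zero-variance) profile has undefined rank correlation and is rejected
by name. Agglomeration is scipy's deterministic linkage (average by
default; complete and single available); every report names the linkage
used, since the literature the procedure follows does not fix one.

A primary/metastasis pair is **joined pairwise** when the smallest
dendrogram cluster containing both contains only that patient's samples —
so a patient's two metastases merging first still counts. For pairs that
are not joined, `leaves_between` counts other patients' samples strictly
between the two leaves in the dendrogram leaf order.

## Difference profiles and G score

For each metastasis the segmented per-probe means of its matched primary
are subtracted, giving one difference vector per metastasis. The G score
aggregates recurrence and amplitude of differences across the cohort:

    higher: G_j = Σ_i max(0, d_ij − θ)     lower: G_j = Σ_i max(0, −d_ij − θ)

with θ defaulting to 0.2, the gain/loss cut-off magnitude. Significance
uses a permutation null of random per-sample cyclic shifts of the
exceedance vectors: shifts preserve each sample's segmental
autocorrelation (free per-marker shuffles would be anti-conservative on
segmented data) while destroying cross-sample alignment. Marker p-values
pool all `B × m` permuted values (add-one smoothed), BH correction runs
across markers, and peaks are maximal runs of contiguous markers with
q < 0.05 within one chromosome, annotated with the contiguous
"core" of markers within 5% of the run's maximal G. On no-signal
cohorts the q < 0.05 marker fraction stays below 0.05 (verified over
seeded cohorts); a planted region of amplitude 1.0 in 30% of 20 pairs is
recovered exactly.

The group-level comparison is a per-probe Fisher exact test of gain (and
separately loss) frequency between the primary and metastasis groups,
BH-corrected across probes.

## Amplification and FISH screens

High-level amplifications are maximal merged runs of segments whose
(cellularity-corrected) mean exceeds log2 = 2 strictly; correcting before
thresholding matters because admixture easily pulls a true 10-copy
amplification below an uncorrected cut-off of 2. A sample is
co-amplified for a locus pair when both loci overlap (≥ 1 bp) one of its
amplification regions; a metastasis whose matched primary lacks the
co-amplification is flagged metastasis-specific. FISH scoring is
positive iff strictly more than a 3:1 locus-to-centromere signal ratio
occurs in at least 10% of cells, with at least 40 cells required and
zero-centromere cells excluded with a warning; the strict ">" and
inclusive "≥ 10%" are deliberate verbatim readings of the standard rule.

## Synthetic cohorts

The generator emulates a paired tumor aCGH study: an evenly spaced grid
(default 17 kb) over 23 chromosomes; per patient, ancestral events shared
by primary and metastases plus private events per sample; observed
ratios through the mixture model above. Defaults — 14–20 shared events
per patient (half arm-level, half focal of 100–600 kb), 1–3 private
events per sample, single-copy gain/loss amplitudes log2(3/2) and
log2(1/2), occasional 6-copy amplifications and deep deletions, noise
σ = 0.1, cellularity 0.7–1.0, ~10% of patients with two metastatic
sites — were chosen once to produce a cohort that looks like colorectal
cancer at the aberrant-genome level (median ≈ 25% of the genome
aberrant) and are not tuned per experiment. Overlapping sampled events
are resolved "last applied wins", keeping the truth single-valued per bp.
The test genome is scaled down (23 × 2 Mb) so that full-cohort
experiments run in seconds; probe spacing and amplitudes stay realistic,
chromosome lengths do not.

Ground truth is kept as bp-resolution interval maps, from which the
exact expected three-state concordance of any pair is computed
independently of the pipeline (interval arithmetic, no noise); the
pipeline estimate recovers it to well under one percentage point in
median absolute deviation under default noise.

What the generator does **not** model: GC/wave artefacts, probe-specific
biases, clonal heterogeneity beyond the two-population mixture, FFPE
artefacts, or allele-specific signal. Passing tests therefore show the
statistics are implemented correctly and calibrated under i.i.d. probe
noise — not that any specific published cohort's numbers will reproduce,
which would additionally require the original arrays and the proprietary
segmentation they were processed with.

## Known limitations

- The rank-CBS analogue approximates, but does not byte-reproduce, any
  commercial "Rank" segmentation; cohort-level results on real data are
  approximate reproductions by construction.
- The G-score peak-boundary rule (q < 0.05 runs, 5% core) is one of
  several defensible conventions; published GISTIC variants differ.
- Fisher tests treat probes as independent; spatial correlation along
  the genome is handled only through BH, as in the group-comparison
  procedures the pipeline mirrors.
- The per-probe Fisher scan caches p-values by 2×2 table, which assumes
  group sizes are constant across probes (true here by construction).
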