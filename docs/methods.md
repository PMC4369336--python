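# Methods

## Signal model

Per-base read depth r<sub>i</sub> is a full aligned-span pileup: each
retained read (primary, mapped, non-duplicate, non-QC-fail; MAPQ 0 kept)
increments every reference base its CIGAR covers. A read-center convention
is used only in two places that are defined that way: the per-window mean
mapping quality and window read counts that feed the mean-normalization
diagnostic. Coordinates are 0-based half-open internally; BED output keeps
that convention.

Depth is never rescaled. Instead each base is assigned to a normalization
population (a GC bin or a repeat distance bin — every non-N, unmasked base
belongs to exactly one) and converted to standard-deviation units through
its within-bin rank:

    p = R/n        if 2R <= n
    p = (n - R)/n  if 2R > n        (numerator floored at 0.5)
    x = sign * |Phi^-1(p)|,  negative below the median

with ranks 0..n−1. The floor applies only on the reachable R = 0 case, so
the mapping is minutely asymmetric at the extreme ranks; tests assert odd
symmetry away from the endpoints. Phi^-1 is `scipy.special.ndtri`.

**Ties.** Tied depths receive their block's mean rank (midranks). Breaking
ties by genome position instead would hand the low end of every tie block
to early coordinates and imprint a chromosome-scale gradient on x — at
desk-scale bin sizes this measurably inflates the variance of large windows.
Midranks are deterministic and spatially unbiased; the residual effect is a
per-bin SD of x slightly below 1 (≈ 0.95–0.99 for Poisson-like depth),
which the tests bound.

**High-coverage capping.** A member whose depth exceeds 2× its chromosome
mean has its rank averaged with the interpolated rank that the exact 2×
value would take in the bin (ties take the tied block's mean rank; absent
values interpolate linearly between neighbors; averaging preserves order,
so no re-ranking is needed and fractional ranks feed the p-formula
directly).

## GC weighting and binning

h<sub>i</sub> sums, over every placement of a mean-insert-length window that
fits the chromosome and covers base i, the placement's G+C and non-N counts;
the ratio of the two sums is h. This is computed exactly in O(N) with two
box-filter cumulative sums, including the truncation near chromosome ends
where fewer placements fit. N bases contribute to neither count; a base
whose every covering placement is all-N gets NaN and is never binned.

h is discretized at 0.01 (101 levels — fine enough to track the bias curve,
coarse enough that desk-scale bins stay large), crossed with the
mapping-quality stratum of the containing 100-base window (mean MAPQ < 5 is
"low"; windows with zero reads carry no MAPQ evidence and stay in the high
stratum, which matters because homozygous deletions would otherwise be
normalized against a bin of other zero-coverage windows and vanish). Levels
holding fewer than 100 bases merge into the nearest populated level of the
same stratum, smallest first.

## Dinucleotide repeats

Maximal period-2 runs with two distinct bases (homopolymers excluded, N
terminates, length ≥ 20) are found by scanning s[i] = s[i−2] stretches;
motifs are canonicalized to the smaller rotation (TATA… reports AT) and
strand/complement classes are kept distinct. A motif with ≥ 50 runs is
flagged biased when its pooled run coverage deviates from the genome mean
by more than 1.5 SD, testing against **both** the genome-wide per-base
depth SD and the motif's own per-base depth SD (the smaller margin
decides). The second framing carries the power at modest coverage: a
motif suppressed to half coverage has a proportionally tighter depth
distribution, and at 10× a 0.5× suppression sits just inside 1.5 genome
SDs while clearly outside 1.5 of its own.

Bases within half a mean insert of a biased run (ties to the nearest,
then earlier, run) leave their GC bins: run-internal bases (distance 0)
form one population per motif, and flanking bases bin in 10-base distance
increments starting at distance 1 — pooling the run interior with its
first flank decade would leave residual bias inside the run, since the
suppression profile steps exactly at the run boundary. Underfull distance
bins merge with the adjacent farther bin; a motif whose merged population
still falls short of 100 bases falls back to GC normalization.

## Excessive-coverage masking

Blocks of 10,000 bases are "high" when their mean depth (over non-N bases;
the trailing partial block on its actual length) strictly exceeds 2× the
chromosome average. High blocks merge by single linkage with the maximum
low-gap implied by the density bound (the largest g with 2/(g+2) > 0.25,
i.e. 5 blocks); merged groups qualify as mask clusters when they hold ≥ 4
high blocks at > 25 % density, and are trimmed to start and end on high
blocks. Single linkage was chosen over a left-to-right greedy because it is
symmetric under reversal of the block sequence — a directional greedy can
return different clusters on a mirrored genome, which is an artifact, not a
property of coverage. Pipeline 1 applies the mask before bin assignment,
distribution sampling and scanning; pipeline 2 ignores it; same-type calls
from the two pipelines that overlap are unioned into the spanning interval
with the more extreme z. When no clusters exist the pipelines are
provably identical and the search runs once.

## The sliding-window search

For ~20 window sizes on a geometric grid from 100 to 10,000 bases, the
caller samples up to 2,000 windows per size, uniformly over positions whose
windows contain no N/masked base, and records the location and scale of the
window-averaged x; intermediate sizes interpolate log-linearly. Location
and scale are the median and the normal-consistent MAD (1.4826·MAD) rather
than mean/SD: on a desk-scale genome the sampled windows include a
non-negligible fraction overlapping real CNVs, and a plain SD would be
inflated by the very signal under test (on a 3-Gb genome the two estimators
coincide; the robust pair is the faithful-at-scale choice).

Candidates are bases abnormal in raw depth relative to their own bin's mean
(≤ 0.70× for deletions, ≥ 1.3× for duplications — diploid defaults, both
exposed) heading a minimum window at least half abnormal. From a candidate
the window grows in one-base increments (evaluated lazily in doubling
chunks); growth stops when the abnormal fraction falls below one half. The
call fires when the one-sided normal tail probability of
z = (mean x − μ<sub>l</sub>)/σ<sub>l</sub> falls below α = 10⁻⁶ — "the tail
probability of z", since comparing a z-score itself to 10⁻⁶ is
dimensionally inconsistent. The call extent is the most extreme passing
window: |z(l)| rises like √l while the window is inside the event and
decays once it dilutes, so the peak sits at the event length. Windows
passing at the maximum size extend by sliding a max-size window while both
conditions hold. Both breakpoints are then refined to the boundaries of
the sustained abnormal run — the argmax of the cumulative abnormal excess
(+½ per abnormal base, −½ otherwise) scanned from each side, never
shrinking below the minimum window. The reported z is the most extreme
over the sweep; scanning resumes past the call end (no nested calls).
Screening is additionally suppressed within one mean insert of N-gaps and
chromosome ends, where fragments cannot fit and depth genuinely sits near
half coverage — indistinguishable from a heterozygous deletion.

## The synthetic generator

Fragment starts follow a Poisson process with rate
coverage/(2·read length) × the product of: a piecewise-linear multiplier in
the fragment's GC fraction (PCR acts on the whole insert, so the bias is
fragment-level); the minimum motif-suppression multiplier over the span
(a 40-base suppressed run therefore depresses coverage over roughly a
fragment length around it, which is what the repeat model must undo);
a hotspot multiplier at the fragment midpoint; zero where the nominal
fragment window contains N. Copy number acts per *read*: each mate is
emitted with multiplicity of mean CN/2 evaluated at the read center, so
depth transitions at event breakpoints are sharp at read-length scale —
as in real data, where junction-spanning fragments still contribute their
mapped-side read. Fragment lengths jitter normally (SD 25); reads are
written as perfectly aligned proper pairs at MAPQ 60 (configurable low-MAPQ
regions) into a sorted, indexed BAM, with a truth BED and a JSON sidecar.

Default study conditions: two 2-Mb chromosomes, 10× coverage, 100-base
reads, 500-base inserts; a 0.30→0.60 GC gradient under a unimodal bias
curve (0.35× at AT-rich extremes, 1.15× at mid-GC); AT/AC/AG/CG runs with
AT suppressed to 0.5×; one 25-kb N-gap per chromosome; 10 heterozygous
deletions (CN 1) and 10 duplications (CN drawn uniformly from 3–10), sizes
log-uniform in 500–10,000 bases, spaced ≥ 30 kb apart. Two purpose-built
fixtures deviate deliberately: the variance-demonstration fixture uses
three GC plateaus (0.20/0.45/0.70) spanning the bias curve so that
window-GC binning does not smear exposures, with the top exposure kept
well under 2× the genome mean so rank capping stays out of the comparison;
the repeat-bias fixture uses 20× flat coverage because the 1.5-SD rule's
margin at 10× (~0.3 reads/base) is within estimation noise, while at 20×
the deficit (10) clears the threshold (~6.7) decisively.

What the generator does not emulate: sequencing error and base qualities,
alignment ambiguity and mismapping (beyond constant configurable MAPQ),
chimeric/discordant pairs, overdispersion sources other than GC and
repeats, and breakpoint microhomology. Passing tests therefore demonstrate
the *bias-correction and detection logic*, not robustness to alignment
artifacts on real genomes.

## Detection limits at desk scale

At 10× with 100-base reads, a window of l bases holds ~0.1·l reads. A
heterozygous deletion removes half of them, so even an oracle read-counter
gets z ≈ 0.5·√(0.1·l): about 3.5 SD at 700 bases and 5 SD only near 1,500
bases. The window-mean-of-x statistic runs at roughly 60–70 % of that
efficiency because pileup depth is autocorrelated over the read length and
mates add a correlation bump at insert distance, both honestly captured in
the sampled σ<sub>l</sub>. With α = 10⁻⁶ (z ≈ 4.75), heterozygous
deletions below ~1.5–2.5 kb and CN-3 duplications of similar size are
mostly undetectable *in principle* at these conditions; on the default
fixture this caps overall sensitivity near ~0.85 (deletions ~0.7–0.8,
duplications ~0.9–1.0) with FDR ≈ 0 and mean breakpoint error well under
150 bases. High-copy duplications and multi-kilobase events are recovered
essentially always. The corresponding recovery test asserts the 0.90
sensitivity bar and is expected to fail for exactly this reason; the other
acceptance properties (variance equalization, oracle equivalences, masking
rules, null control, two-pipeline behavior, determinism) pass.

## Numerical and degenerate-input choices

* σ<sub>l</sub> is floored at 10⁻¹² before dividing; a constant track
  yields σ = 0 and can never fire a call.
* Window means over NaN (N/masked) bases use the finite subset; the
  abnormal fraction divides by the full window length, so NaN dilutes
  toward "not abnormal".
* Chromosomes shorter than the insert use one full-length placement for h;
  all-N chromosomes are excluded from depth summaries with a warning.
* Bin/stratum or eligible-window shortfalls degrade gracefully with
  warnings (merge, drop, or use-all-windows) rather than erroring.
* All randomness flows through `numpy.random.default_rng` seeded from the
  caller's single seed (per-chromosome offsets for the generator; distinct
  offsets per pipeline for window sampling), making every artifact —
  including BED bytes — reproducible.

## Known limitations

* Sensitivity at sub-kilobase scale is information-limited at 10× (above);
  the fixed α is not adapted to the number of effective tests.
* Copy-number genotyping is out of scope; calls carry mean fold-coverage
  only.
* The unmasked pipeline inherits bin contamination from very large
  hotspots (rank capping tempers but does not remove it), so calls inside
  and at the edges of excessive-coverage territory have elevated false
  rates — the price of keeping those regions callable at all.
* Single-sample, single-library assumptions: one read length, one insert
  distribution; mate-pair or mixed libraries are not modeled.
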