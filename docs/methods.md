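# Methods

## Coordinate conventions

All intervals are 0-based half-open, in BED style, internally and in every
file the package writes. Window grids tile each chromosome in fixed steps
from position 0; a partial tail window is dropped. Baseline copy number is
1 — a single copy relative to the reference genome — so a deletion carrier
has CN 0 and duplication carriers CN ≥ 2. There is no diploid doubling.

## Synthetic cohort generator (`cndiverse.simulate`)

The generator emulates a cohort of haploid-reference yeast strains
profiled by whole-genome short-read depth. What it models:

- **Genome layout.** `build_genome` places `n_chrom` equal-length
  chromosomes with one centromere each at a configurable fraction of the
  length (± 2% uniform jitter) and, optionally, 1.5 kb essential-gene
  anchors at a configurable spacing — these anchor the
  end-to-first-essential-gene subtelomere definition.
- **Events.** `n_loci` non-overlapping events are placed per genome.
  Duplication sizes are lognormal (default log-mean ln 600 bp, log-sd 0.7,
  so ≥ 60% of duplications are ≤ 1 kb); deletion sizes are a mixture of
  short (uniform 250–1000 bp) and long (uniform 5–7 kb) components with
  default weights 0.3/0.7, reproducing the empirical pattern that
  duplications skew small while deletions cluster at 5–7 kb. An event is
  duplicated with probability `p_duplication` (default 0.4, reflecting the
  observed excess of deletions); duplication CN is uniform on
  {2, …, 1 + max_extra_copies} with `max_extra_copies` = 6 — a modeling
  choice, since per-event CN distributions in real cohorts are only known
  from examples (single-gene CN can reach double digits at tandem arrays).
- **Placement.** Each event is flagged subtelomeric with probability
  `p_subtelomeric` *before* placement, and placement is then retried
  within that stratum, so the realized subtelomeric count is exactly
  binomial — this keeps placement-recovery checks statistically clean.
  Subtelomeric events lie wholly inside the 25 kb end zones; others lie
  wholly outside. Events never span centromeres (so context labels are
  unambiguous) and keep two windows of clearance from one another (so
  run-merging segmentation cannot fuse distinct events). Placement failure
  after bounded retries raises an error rather than silently under-filling.
- **Population structure.** Each locus draws a carrier frequency q from
  Beta(0.8, 0.8) (both rare and common CN alleles occur, which PIC must
  discriminate); each strain independently carries the event CN with
  probability q, else stays at baseline 1.
- **Depth emission.** Per-window GC is a smoothed Gaussian field clipped
  to [0.30, 0.60]; the depth response to GC is a Gaussian bump centered at
  GC 0.45, scaled by `gc_amplitude` (default 0.3) and centered so its mean
  over the genome is exactly 1 (coverage is modulated, not shifted).
  Window counts are negative binomial with mean
  `base_depth × CN × gc_factor` and size parameter `dispersion`
  (default 100; variance m + m²/100), because Poisson underfits the
  coverage variance of real libraries. `base_depth` defaults to 30 reads
  per window, matching the ~30× coverage regime the protocol is designed
  for. Windows partially covered by an event receive a fractional dose.
- **Breakpoints.** By default (`snap_to_window`) event breakpoints snap to
  the 250 bp grid. The caller is window-resolution by construction, so
  grid-aligned truth keeps truth-vs-call reciprocal-overlap matching
  exact; turning snapping off exposes sub-window boundary effects for
  sensitivity analyses.

What the generator does **not** model: real read mapping (mappability,
repeats, multi-mapping around Ty elements), SNPs, sequence divergence
between copies, strain-specific GC response, aneuploidy, or loci absent
from the reference. Passing recovery tests therefore demonstrates the
pipeline's statistical machinery, not robustness to alignment artifacts.

## CNV caller (`cndiverse.calling`)

1. **Normalization.** Per-window ratio = depth / median depth of windows
   in the same GC bin (25 equal-width bins over the observed GC range).
   Bin medians exclude windows within 7 kb of chromosome ends or
   centromeres (telocentromeric regions are atypical but still *called* —
   the mask affects only the reference statistics). Empty bins fall back
   to the global unmasked median with a logged warning. Ratios are
   rescaled so the genome-wide median is 1; tracks with > 50% zero-depth
   windows are rejected as corrupt. Binned medians were chosen over local
   regression for bit-reproducibility and absence of smoothing
   hyperparameters.
2. **States.** `cn_state` = round-half-up(ratio), so ratios in [0.5, 1.5)
   map to the neutral state 1. Before segmentation, `call_strain` applies
   a 3-window running median to the ratios and re-derives states
   (configurable; width 1 disables). Isolated single-window rounding flips
   at high CN would otherwise fragment true regions; the width-3 median
   removes them while preserving clean run boundaries exactly and leaving
   runs of ≥ 3 windows intact.
3. **Segmentation.** Maximal runs of adjacent windows that are all
   duplicated (state > 1) or all deleted (state < 1) become candidate
   regions; the region CN is the round-half-up of the median ratio over
   the run. Same-class (rather than same-state) merging is deliberate:
   at CN ≥ 3 the per-window state is noisy because depth variance grows
   with CN, and same-state merging fragments true events, while the
   dup/del class is essentially never misassigned. The median-ratio CN of
   a dup run is guaranteed ≥ 2 and of a del run 0, so no candidate can
   land on baseline. Runs shorter than `min_windows` (default 2 = 500 bp)
   are discarded; single-window calls are reserved for the 25 bp
   intragenic mode. When benchmarking against simulations whose smallest
   event spans k windows, calls are made with `min_windows = k` so the
   evidence threshold matches the event spectrum being assayed.
4. **Significance.** Each candidate's raw window ratios are compared to
   the neutral (state = 1) windows of the same chromosome by a two-sided
   Wilcoxon rank-sum test; candidates are retained iff p < α (default
   0.05). Chromosomes with no neutral windows fall back to the
   genome-wide neutral set with a logged warning. The test uses exact
   enumeration when both samples have ≤ 20 tie-free observations and the
   normal approximation with continuity correction otherwise.

Scale invariance (multiplying a strain's depths by any constant changes
nothing) follows from median normalization and is property-tested.

## Gene-level quantities (`cndiverse.genic`)

A CNVR is *genic* iff it overlaps an annotated gene by ≥ 1 bp (half-open
intersection). Genic CN is the unweighted mean of integer window states
over all windows overlapping the gene by ≥ 1 bp — partially overlapping
windows count fully, matching the windows-that-overlap convention; a
base-weighted variant was considered and rejected as the default because
integer window states are the caller's native output. Genic CN is binned
to `cn_int` by round-half-up for allele-based statistics (PIC needs
discrete alleles). Annotations read from BED (native) or GFF3 (1-based,
converted on read). The duplicated-versus-deleted comparison applies the
two-sided continuity-corrected Mann-Whitney U test to per-strain dup and
del count vectors, separately for genic and nongenic regions.

## Diversity scoring (`cndiverse.diversity`)

Cohort loci are the connected components of overlapping CNVR intervals
pooled over strains (abutting intervals stay separate). Each matrix cell
is the strain's integer CN at the locus — the CN of its largest-overlap
CNVR there — with baseline 1 where the strain has no overlapping call;
largest-overlap assignment prevents a short high-CN fragment from being
averaged away inside a long union locus. All strains, including baseline
carriers, enter both measures. s² uses the n−1 denominator (the symbol
conventionally denotes the sample variance); log10(s²) is undefined at
zero variance and such loci are excluded from that measure's percentile
pool (they remain eligible via PIC). "Top 50%" is inclusive: score ≥
median, with midpoint interpolation for even counts, so tied cohorts
saturate rather than split arbitrarily. The CN-diverse set is the union
of the two top-halves, and the summary reports both/only-s²/only-PIC/union
counts.

## Genomic context (`cndiverse.context`)

Definition A subtelomeres: the fixed `subtel_span` (default 25 kb) at each
chromosome end. Definition B: from each end to the nearest boundary of the
first/last essential gene; chromosomes without an essential gene are
wholly subtelomeric under B, and spans longer than half the chromosome
produce a whole-chromosome zone with a warning. Pericentromere: centromere
± 7 kb (the telocentromeric mask width; the literature gives no standard
pericentromere span, so this is a declared assumption, configurable).
Classification is by ≥ 1 bp overlap with subtelomere taking precedence
over pericentromere when zones collide on short chromosomes, since
subtelomeres are the headline category in context summaries.

## Summaries and pipeline (`cndiverse.report`)

Per-strain summaries report CNVR counts and affected base pairs (CNVRs are
disjoint per strain, so the sum of lengths is exact). Cohort aggregates
emit both SD and SE, labeled, since "mean ± x" conventions differ between
sources. Size-distribution bins default to (0,1], (1,2], (2,3], (3,4],
(4,5], (5,7], (7,10], >10 kb, exposing both the ≤ 1 kb duplication mode
and the 5–7 kb deletion mode. Gene-family views count a strain as
duplicated/deleted by integer-binned genic CN. The intragenic profile
renormalizes a fine-window (default 25 bp) track and labels a gene
intact / partial / whole-gene dup or del, with 80% of gene windows as the
partial-versus-whole threshold (matching the spans-most-of-the-gene usage
in the field). `run_pipeline` executes simulate → call → matrix →
diversity → context → report and writes a manifest of SHA-256 checksums;
outputs carry no timestamps, so a fixed seed reproduces every byte.

## Problem sizes and numerical choices

Validation runs use desk-scale cohorts chosen to make the statistics
decisive: parameter recovery uses 20 strains on a 3 Mb genome with 60
events of ≥ 4 windows at 30× (precision/recall ≥ 0.9 at reciprocal
overlap 0.8); calibration uses 1000 null candidates against ~4000 neutral
windows; placement recovery uses 200 events on a 16-chromosome genome.
The demo pipeline uses 5 strains × 600 kb. Seeds are fixed throughout;
every random draw flows from a single `numpy` Generator per stage.

## Known limitations

- Segmentation is run-merging on rounded states, not a penalized
  changepoint model; breakpoints are window-resolution and sub-window
  boundary placement is out of scope.
- The rank-sum filter inherits the selection effect of testing candidates
  found in the same data; its p-values are screening scores, not
  inferential quantities.
- No mappability or control-sample correction; GC correction assumes a
  genome-wide shared GC response.
- Diversity measures treat CN alleles as unordered labels and ignore
  sequence variation between copies.
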