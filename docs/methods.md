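# Methods

This note records the models `replixi` implements, the parameter choices
that matter, what the synthetic-data generator does and does not emulate,
and the numerical decisions taken where the design was genuinely open.

## Coordinate and data conventions

All genomic coordinates are 0-based, half-open, in every container and
on-disk format (BED, bedGraph, TSV).  Bin grids are uniform per genome;
terminal remainders shorter than one bin are dropped.  Missing values are
explicit everywhere: `NaN` in memory, an `NA` token in TSV matrices,
omitted rows in bedGraph — never 0, which is a meaningful RT score.

## Bulk RT scoring

Early- and late-S BrdU-IP counts are scaled to reads per million per
sample, then each bin receives r = E/(E+L) and the score

    RT = 2r − 1  ∈ [−1, +1],   positive = early replicating.

The affine map is chosen over rank-rescaling because it is monotone, maps
E = L to exactly 0 and single-fraction bins to ±1, and keeps replicate
averaging meaningful.  Bins whose scaled total E+L falls strictly below
the 5% quantile of all bins (computed per sample pair, after scaling,
before replicate pooling; ties kept) are masked, as are zero-total bins.

Quantile normalization maps each sample's sorted non-missing values onto
the mean sorted distribution across samples; ties within a sample share
the average reference value, and unequal non-missing counts are handled by
interpolating onto a common quantile grid.  Replicates are averaged
element-wise *after* normalization (the order is not forced by the math;
normalizing first keeps replicate distributions comparable before they are
pooled).  Sliding-window binning (200-kb windows at 80-kb steps for
non-haplotype analysis) counts a read in every window containing it;
windows are labeled by start.

## RT classes

Classification is per-bin on replicate-mean, quantile-normalized profiles.
Differentiation mode: EtoE both > 0; LtoL both < 0; EtoL (esc > 0,
nsc < 0, esc − nsc > 0.5); LtoE symmetric; a sign switch inside the 0.5
margin is `unclassified`.  SmcHD1 mode: a bin is *affected* when the
mutant NSC profile is earlier than wild type by more than 0.4 (signed by
default — the phenotype of interest is RT reversal toward early; an
`absolute` option tests |Δ| > 0.4).  SD = EtoL ∧ affected, SI = EtoL ∧
¬affected, CL = LtoL ∧ ¬affected, CE = EtoE ∧ ¬affected; affected bins
outside EtoL get an explicit `affected_other` label rather than being
silently merged.  All threshold comparisons are strict, so RT exactly 0 or
a delta exactly at threshold falls to `unclassified`.  Spans are reported
as bin_count × bin_size with a single division, so 30 bins at 400 kb is
exactly 12.0 Mb.

## Single-cell binarization

A cell at S-phase fraction f has doubled coverage over replicated bins.
The binarizer forms the log₂ ratio of library-scaled cell counts to a
library-scaled G1 reference (zero-G1 bins are missing; a half-minimum
pseudocount keeps zero cell counts finite) and segments each chromosome
with a two-state Gaussian HMM with fixed sticky transitions
(self-transition 0.99) and a **tied** covariance.  The tied covariance is
deliberate: with free per-state variances the EM reliably finds the
pathological optimum in which one state inflates its variance and swallows
both coverage levels.  State means are initialized at the 25th/75th
percentiles of the ratio; the higher-mean state is replicated — against a
G1 reference this naming is unambiguous, because replication can only
raise coverage.

Two guards handle cells the two-state model cannot identify:

1. **Bimodality check.**  The per-bin noise scale is estimated robustly
   from adjacent-bin differences (RT domains make most neighbours share a
   state, so the difference distribution is noise-dominated):
   σ̂ = 1.4826·median|Δ|/√2.  If the overall standard deviation of the
   ratio does not exceed 1.4·σ̂ there is no second level to segment — the
   cell is at the very start or end of S — and every informative bin gets
   the FACS gate's majority state (unreplicated for the early-S gate,
   replicated for mid/late), with a warning.
2. **Separation check.**  A fitted state gap below 0.5 log₂ units (half
   the 1.0 gap a true doubling produces) is treated the same way, after a
   2-means fallback.

The gate therefore *disambiguates* cells the data cannot, rather than
overriding the mean ordering: a mid-S-gate cell that has genuinely
replicated only 40% of its genome keeps its minority-replicated labeling.
A `strict_gate` option restores literal majority enforcement (the
behaviour of frequency-anchored somy assignment) for users who want it;
it is off by default because it inverts exactly those legitimate cells.
Binarization is invariant to uniform scaling of a cell's counts by
construction (library scaling precedes the ratio).

Genome percentage-replication scores exclude X bins by default, since a
uniformly late X would bias the whole-genome S-phase coordinate.

## Replication kinetics (T₁₀₋₉₀%)

Cells are ranked by genome percentage replication and split into 18
equal-count groups (stable ties by input order); group means (x̄, ȳ) of
(genome %, chromosome %) are augmented with pseudo points (0,0) and
(100,100) — with unit weight — to pin the S-phase ends, then fitted with

* linear: y = a·x + b, or
* sigmoid: y = 100 / (1 + e^(−k(x − x₀))) — a 2-parameter logistic with
  fixed 0/100 asymptotes (the pseudo points justify pinning the tails).

T₁₀₋₉₀% is the fitted x-distance from y = 10 to y = 90, clamped to
[0, 100], scaled to hours on a 10-h S phase.  For the logistic the span is
closed-form, 2·ln 9 / k percentage points, so k = 0.2 gives 2.197 h; on
the identity line the linear model gives exactly 8.0 h.  A non-convergent
sigmoid or fewer than 3 points raises with diagnostics.

## scRT values

Per-bin percentage replication p (fraction of cells that replicated the
bin) is ranked, split into one-percentile equal-count groups (earliest =
highest p), and each group's mean p̄ converts to

    scRT = S · (1 − p̄/100),  rounded half-up to 0.1 h.

This is the unbiased estimator of a bin's mean replication time under
uniform sampling of cells across S.  Equal-count groups (not equal-width)
keep group occupancy stable when p is non-uniform.  scRT is non-increasing
in p by construction.

## Virtual 4C and interaction calling

A viewpoint profile sums the contact-matrix rows of all bins in the
viewpoint span (400-kb viewpoints at 5-kb resolution = 80 rows in the
standard configuration), masks the viewpoint ± the test-window width in
cis, and scales the rest to 10,000 total — making profiles invariant to
global sequencing depth.

Calling works on binarized coverage (signal > 0), following the windowed
z-score logic of established 4C pipelines:

* **far-cis**: windows of w = 50 bins sliding by 1 along the viewpoint
  chromosome; the background probability p_bg is the covered fraction of
  the surrounding W = 1,200 bins, centered, *excluding* the test window
  and truncated at chromosome ends.  Fragment-level calling uses the same
  machinery at w = 100 / W = 3,000 on fragment-indexed signal.
* **trans**: windows of 250 bins tiling every other chromosome at
  half-window steps (a compromise between sensitivity and test count; the
  final window is anchored to the chromosome end), with p_bg the
  viewpoint's genome-wide trans covered fraction.

Each window's covered count k gets the normal-approximation z
(k − w·p_bg)/√(w·p_bg(1 − p_bg)) and an exact one-sided binomial upper
tail; windows with degenerate background (p_bg ∈ {0, 1}) carry missing
statistics and are excluded from FDR.  Benjamini–Hochberg runs per
viewpoint (far-cis) or across all trans windows, at FDR 0.01; overlapping
or adjacent significant windows merge, and the merged-interval count is
the reported number of interactions.  The implementation is
cumulative-sum based and is tested window-for-window against a brute-force
enumeration oracle; under a homogeneous coverage null the viewpoint-level
false-call rate is verified below FDR + Monte-Carlo tolerance.

Z-score tracks rebin to coarser grids (e.g. 5 kb → 400 kb) by
missing-aware arithmetic mean.  Aggregate pair analysis averages the
(2·flank+1)² submatrices centered on all ordered pairs of a bin set,
skipping pairs that fall off the matrix edge.  Per-class trans-call
distributions are compared with one-sided Wilcoxon rank-sum
(Mann–Whitney) tests, Bonferroni-corrected by the number of comparisons
performed — rank-sum rather than signed-rank because viewpoint classes
have unequal sizes, so a paired test is undefined.

4C allele demultiplexing is SNP-exact: a read-2 prefix is assigned to an
allele only on a mismatch-free match to that allele's expected
primer+SNP sequence; everything else is unassigned.  Fragment smoothing
is a centered 201-fragment running mean, truncated at chromosome ends.

## Enrichment

Features are assigned to the RT class of the bin containing their midpoint
(genes spanning bin boundaries get a single, deterministic assignment).
Density is count per Mb of class span; with a normalizer feature set
(e.g. all genes under an escapee analysis) the normalized density is the
ratio of densities (missing where the normalizer density is 0), and folds
against a reference class use normalized densities when a normalizer is
supplied, raw densities otherwise — both are available.  Xi probability is
xi/(xi + xa) (0 = fully silenced, 0.5 = fully reactivated), missing when
both read counts are zero, and scale-invariant.  KO/WT comparisons are
per-bin log₂ ratios, missing for non-positive input.

## Synthetic-data generator

The generator exists so every analysis stage has ground truth.  Per cell,
replication is irreversible: each bin gets one latent replication time and
is replicated iff f·S has passed it (never independent Bernoulli draws per
time point).

* **Graded program** (autosome/Xa-like): latent time t_b + σ·Logistic(0,1),
  so P(replicated | f) = logistic((f·S − t_b)/σ).  Defaults σ = 0.5 h,
  S = 10 h.  The `random_domain_times` helper draws domain-structured
  landscapes (white noise smoothed over ~20 bins, rank-mapped to a uniform
  marginal over [0.3, 9.7] h) because real RT is organized in megabase
  domains — and the sticky HMM the binarizer uses presumes that spatial
  coherence.
* **Xi uniform-late program**: a per-cell onset o_c ~ Normal(μ_o, σ_o)
  truncated to [S/2, S] (defaults μ_o = 6.5 h, σ_o = 0.5 h — the second
  half of S with moderate cell-to-cell onset variability), then each bin
  completes at o_c + U(0, d): the whole chromosome replicates within a
  d-hour window per cell, out of phase with the genome.
* **Counts**: Poisson with mean depth·(1 + state), default 50 reads per
  bin per cell; an overdispersion knob gamma-mixes the rate
  (variance μ + a·μ²).  G1 references in tests are simulated at 10× the
  single-cell depth, emulating the pooled multi-G1-cell references real
  assays use.
* **Bulk fractions**: cells pool at f < 0.5 (early) vs f ≥ 0.5 (late) —
  the midpoint, since FACS gate boundaries are instrument-specific — and
  per-fraction bin counts are Poisson around the pooled replicated-state
  totals, calibrated to the requested mean depth.
* **Layered contacts**: cis rates decay as depth/(1 + d)^α with bin
  distance d; trans rates are multiplicative in per-bin layer rates
  (λ_ij = r_i·r_j·depth), so a layer with a 5× rate shows ~5× trans
  contacts per bin; an optional cis boost multiplies the rate of
  distant same-label (SD–SD) pairs to plant hotspots.  Matrices are
  sampled on the upper triangle and mirrored, hence exactly symmetric.

S-phase fractions are sampled uniformly on (0,1) — the real sorting
density of S-phase cells is unknown, and uniform sampling is what makes
percentage replication an unbiased clock.  Everything is bit-reproducible
under a seed.

What the generator does **not** emulate: GC/mappability bias, whole-genome
amplification artifacts, copy-number variation, read-level error, distance
structure within trans contacts, or Hi-C matrix balancing.  Passing tests
therefore demonstrate correctness of the computations under the stated
statistical model, not robustness to those real-data pathologies.

## Numerical choices and degenerate inputs

* Quantile-normalization reference = mean of sorted values; ties share the
  average reference value.
* The low-count filter removes bins strictly below the quantile; ties at
  the cutoff are kept.
* fit_t1090 sigmoid: initial k from the inter-decile x-span, x₀ from
  inverse interpolation at y = 50; bounds k ∈ [10⁻⁴, 100],
  x₀ ∈ [−50, 150].
* scrt rounding is half-up (⌊10t + 0.5⌋/10), so 6.25 h → 6.3 h.
* Contact-matrix triplet input: duplicates summed (warning), triangles
  reconciled by element-wise max on mismatch (warning), unknown bin ids
  rejected.
* A viewpoint with no contacts outside its mask yields an all-zero profile
  with a warning rather than an error.
* Windows touching masked/invalid bins are skipped; windows with
  degenerate background are reported with missing statistics and excluded
  from multiplicity correction.

## Test problem sizes

The suite exercises the stochastic properties at sizes chosen to make the
checks sharp yet quick: 10,000 cells for closed-form %replication
agreement; 2,000–3,000 cells for bulk recovery; 200 cells × 200 bins for
the full single-cell pipeline (RMSE ≤ 0.5 h against the generating
program); 20 seeds × 100 cells for Xi kinetics recovery (±0.5 h);
2,000-bin coverage vectors × 50 seeds for caller/oracle equivalence and
200 replicates for null calibration; and a 2,100-bin four-chromosome
layered matrix for the trans-ordering and aggregate-hotspot checks.

## Known limitations

* The binarizer assumes a diploid, CNV-free genome and a faithful G1
  reference; aneuploid or high-CNV cells need upstream QC (deliberately
  out of scope).
* T₁₀₋₉₀% from whole-S snapshots uses genome %replication as the S-phase
  clock; chromosomes whose replication is uncorrelated with the genome
  (the Xi itself) make that clock noisier exactly where the signal is
  steep, so sigmoid fits on few cells are overestimate-prone.
* The interaction caller's binarized-coverage model discards magnitude
  information above "covered"; deeply sequenced matrices saturate
  coverage and lose contrast (rebinning or subsampling restores it).
* Per-bin RT classes are called independently; no segmentation or
  smoothing across bins is attempted.
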