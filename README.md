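# replixi

Replication-timing and chromosome-conformation analysis of the inactive X
chromosome (Xi), as a tested, reusable Python pipeline.

During X-chromosome inactivation the Xi abandons the graded early/late
replication-timing (RT) program of the autosomes and replicates rapidly and
uniformly in the second half of S phase.  A subset of its formerly-early
domains depends on the heterochromatin protein SmcHD1 to stay late
(SmcHD1-dependent, "SD" domains); these domains sit on the Xi surface,
contact other chromosomes unusually often, are escapee-rich, and contact
each other when SmcHD1 is lost.  `replixi` implements the computations this
kind of study rests on:

* **Bulk Repli-seq RT scoring** — early/late BrdU-IP counts per bin,
  reads-per-million scaled; RT = 2·E/(E+L) − 1 ∈ [−1, +1] (positive =
  early), low-coverage filtering, quantile normalization, replicate
  averaging.
* **RT-class calling** — differentiation classes (EtoE / EtoL / LtoE /
  LtoL; sign switch with |ΔRT| > 0.5) and SmcHD1-dependence classes
  (SD / SI / CL / CE; mutant-vs-WT ΔRT > 0.4), with exact span bookkeeping.
* **Single-cell Repli-seq** — two-state sticky Gaussian-HMM binarization of
  per-cell counts against a G1 reference, percentage-replication scores,
  chromosome kinetics fits (T₁₀₋₉₀%: time from 10% to 90% replicated on a
  10-h S phase; linear or 0/100-asymptote logistic with pseudo points), and
  per-bin single-cell RT values (scRT = S·(1 − p̄/100) by percentile group).
* **Virtual 4C and interaction calling** — viewpoint profiles from
  symmetric contact matrices (rows summed, scaled to 10⁴), binarized
  coverage tested in sliding windows (w = 50 bins against a 1,200-bin local
  background in far-cis; 250-bin tiled windows against the global trans
  coverage), binomial z and one-sided tail, Benjamini–Hochberg FDR 0.01,
  merged-interval call counts, SNP-exact 4C allele demultiplexing,
  201-fragment smoothing, and aggregate pair pile-ups.
* **Feature-density enrichment** — gene/escapee density per RT class,
  normalized densities and fold ratios, Xi expression probability
  xi/(xi + xa), KO/WT log₂ differentials.
* **A seeded synthetic-data generator** — graded and uniformly-late
  replication programs with cell-to-cell onset jitter, bulk fraction
  pooling, Poisson (optionally overdispersed) counts, and layered contact
  matrices with per-class trans rates — so every stage runs, and is tested,
  without downloads.

## Worked example

```python
import numpy as np
from replixi.genome import make_genome
from replixi.simulate import (GradedProgram, XiUniformLateProgram,
                              simulate_cells, simulate_bulk)
from replixi.bulk_rt import BinnedCounts, rt_score
from replixi.screpli import fit_t1090, percent_replication

# Bulk RT on a chromosome with an early and a late domain
genome = make_genome([("chr1", 8_000_000)], 400_000)
t = np.array([2.0] * 10 + [8.0] * 10)           # mean replication times (h)
early, late = simulate_bulk(genome, GradedProgram(t_hours=t, noise_sd=0.3),
                            n_cells=2000, depth=100.0, seed=1)
prof = rt_score(BinnedCounts(genome=genome, counts=early),
                BinnedCounts(genome=genome, counts=late))

# Xi kinetics: cells shared between a graded autosome and a late-uniform X
auto = make_genome([("chr1", 50_000_000)], 100_000)
chrx = make_genome([("chrX", 40_000_000)], 400_000)
ref = simulate_cells(auto, GradedProgram(
    t_hours=np.linspace(0.01, 9.99, auto.n_bins), noise_sd=0.0),
    100, seed=11, depth=0)
xi = simulate_cells(chrx, XiUniformLateProgram(
    onset_mean=6.5, onset_sd=0.5, duration=3.5),
    100, seed=12, s_fractions=ref.s_fractions, depth=0)
gp = np.array([percent_replication(r) for r in ref.states])
xp = np.array([percent_replication(r) for r in xi.states])
fit = fit_t1090(gp, xp, model="sigmoid", n_groups=18)
```

This prints (seeds as above):

```
RT scores, first 3 early-domain bins: [0.114 0.199 0.234]
RT scores, first 3 late-domain bins:  [-1. -1. -1.]
Xi sigmoid fit: k = 0.138, x0 = 83.4, T10-90% = 3.19 h
Autosome linear fit: T10-90% = 8.00 h
```

The early domain scores positive and the late domain pins at −1 (its bins
draw essentially no early-fraction reads at these depths).  The Xi's fitted
logistic is steep and late-centered (half-replication at 83% genome
replication): it completes 10→90% replication in ≈3 h, while a chromosome
tracking the genome-wide program takes exactly 8 h on the identity line —
the late-but-fast Xi signature.

A command-line layer mirrors the library (`replixi simulate`, `replixi rt
score|normalize|classify`, `replixi sc binarize|percent|t1090|scrt`,
`replixi v4c profile|cis|trans|aggregate`, `replixi enrich density`); every
subcommand takes `--config`, `--seed`, `--log-level`, reads/writes
bedGraph, BED, TSV matrices and triplet contact TSVs, and logs the resolved
configuration next to its outputs.

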