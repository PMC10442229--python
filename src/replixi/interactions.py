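"""Virtual-4C extraction and windowed interaction calling.

A 4C(-like) viewpoint profile is the row-sum of a symmetric contact matrix
over the bins of a viewpoint span, scaled to 10,000 total contacts, with
the viewpoint and its immediate flank masked in cis.  Interaction calling
binarizes the profile (covered = signal > 0) and slides a test window of
``w`` bins against a local (far-cis) or global (trans) background coverage
fraction: the window's covered count is scored with a normal-approximation
z and an exact one-sided binomial tail, Benjamini-Hochberg control is
applied across windows, and adjacent significant windows merge into
intervals.  Fragment-level 4C support (SNP-exact allele demultiplexing,
201-fragment running-mean smoothing) and aggregate pair pile-ups live here
too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel
from .simulate import ContactMatrix

__all__ = [
    "ContactMatrix",
    "ViewpointProfile",
    "InteractionCallSet",
    "assign_allele",
    "smooth_fragments",
    "virtual_4c",
    "windowed_enrichment",
    "far_cis_calls",
    "trans_calls",
    "rebin_z",
    "aggregate_pairs",
    "trans_counts_by_class",
]

PROFILE_TOTAL = 10_000.0


def assign_allele(read2_prefix: str, primer_snp_table: dict[str, str]) -> str:
    """SNP-exact allele assignment of a read-2 prefix.

    ``primer_snp_table`` maps allele label (e.g. ``"B6"``, ``"JF1"``) to the
    expected primer+SNP sequence.  Only an exact, mismatch-free match to one
    allele's expected prefix assigns the read; anything else (including a
    single mismatching base) is ``"unassigned"``.
    """
    seqs = list(primer_snp_table.values())
    if len(set(seqs)) != len(seqs):
        raise ValueError("ambiguous table: identical expected sequence for two alleles")
    for allele, expected in primer_snp_table.items():
        if read2_prefix[: len(expected)] == expected:
            return allele
    return "unassigned"


def smooth_fragments(fragment_signal: np.ndarray, window: int = 201) -> np.ndarray:
    """Centered running mean over restriction fragments.

    The window is truncated at the ends of the fragment list, so edge values
    average over fewer fragments.  ``window`` must be odd.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    s = pd.Series(np.asarray(fragment_signal, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


@dataclass(frozen=True)
class ViewpointProfile:
    """One viewpoint's normalized genome-wide contact signal.

    ``signal`` sums to 10,000 over unmasked bins (reads per 10,000
    contacts); ``mask`` covers the viewpoint span plus its cis exclusion
    flank.  ``viewpoint`` is ``(chrom, start, end)``.
    """

    genome: GenomeModel
    signal: np.ndarray
    mask: np.ndarray
    viewpoint: tuple[str, int, int]

    @property
    def chrom(self) -> str:
        return self.viewpoint[0]

    def coverage(self) -> np.ndarray:
        """Binarized coverage (signal > 0), masked bins 0."""
        return ((self.signal > 0) & ~self.mask).astype(np.int8)


def virtual_4c(
    matrix: ContactMatrix,
    viewpoint: tuple[str, int, int],
    exclusion_bins: int = 50,
) -> ViewpointProfile:
    """Extract a one-viewpoint contact profile from a contact matrix.

    Rows of all bins inside the viewpoint span are summed, the viewpoint
    span plus ``exclusion_bins`` flanking bins (cis only) is masked, and the
    unmasked signal is scaled to 10,000 total.  A zero-contact viewpoint
    yields an all-zero profile with a warning.
    """
    chrom, start, end = viewpoint
    genome = matrix.genome
    sl = genome.chrom_slice(chrom)
    bs = genome.bin_size
    vp_first = sl.start + start // bs
    vp_last = sl.start + (end - 1) // bs
    if vp_first < sl.start or vp_last >= sl.stop:
        raise ValueError("viewpoint outside the binned chromosome")

    signal = matrix.counts[vp_first : vp_last + 1].sum(axis=0).astype(float)
    mask = np.zeros(genome.n_bins, dtype=bool)
    lo = max(sl.start, vp_first - exclusion_bins)
    hi = min(sl.stop, vp_last + 1 + exclusion_bins)
    mask[lo:hi] = True

    signal[mask] = 0.0
    total = signal.sum()
    if total == 0:
        warnings.warn(f"viewpoint {viewpoint} has no contacts outside the mask")
    else:
        signal *= PROFILE_TOTAL / total
    return ViewpointProfile(genome=genome, signal=signal, mask=mask, viewpoint=viewpoint)


@dataclass(frozen=True)
class InteractionCallSet:
    """Per-window statistics plus merged significant intervals.

    ``windows`` has one row per tested window (chrom, start, end in bin
    units, k, p_bg, z, p, q, significant); windows with a degenerate
    background (p_bg of 0 or 1) carry NaN statistics and are excluded from
    FDR.  ``intervals`` are the merged significant windows; ``n_calls``
    counts merged intervals.
    """

    windows: pd.DataFrame
    intervals: pd.DataFrame
    fdr: float

    @property
    def n_calls(self) -> int:
        return len(self.intervals)


def _binom_window_stats(k: np.ndarray, w: int, p_bg: np.ndarray):
    """Vectorized z and one-sided binomial upper-tail p for window counts."""
    with np.errstate(invalid="ignore", divide="ignore"):
        var = w * p_bg * (1.0 - p_bg)
        z = np.where(var > 0, (k - w * p_bg) / np.sqrt(np.where(var > 0, var, 1.0)), np.nan)
    pval = np.full(k.shape, np.nan)
    ok = (p_bg > 0) & (p_bg < 1)
    pval[ok] = stats.binom.sf(k[ok] - 1, w, p_bg[ok])
    z[~ok] = np.nan
    return z, pval


def _bh_and_merge(df: pd.DataFrame, fdr: float) -> InteractionCallSet:
    """BH-adjust valid windows, flag significance, merge overlapping calls."""
    df = df.copy()
    df["q"] = np.nan
    df["significant"] = False
    ok = df["p"].notna()
    if ok.any():
        reject, q, _, _ = multipletests(df.loc[ok, "p"], alpha=fdr, method="fdr_bh")
        df.loc[ok, "q"] = q
        df.loc[ok, "significant"] = reject

    intervals = []
    for chrom, grp in df[df["significant"]].groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:  # overlapping or adjacent windows merge
                cur_e = max(cur_e, e)
            else:
                intervals.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            intervals.append((chrom, cur_s, cur_e))
    idf = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
    return InteractionCallSet(windows=df.reset_index(drop=True), intervals=idf, fdr=fdr)


def windowed_enrichment(
    coverage: np.ndarray,
    w: int = 50,
    bg_w: int = 1200,
    fdr: float = 0.01,
    valid: np.ndarray | None = None,
    chrom: str = "chr",
) -> InteractionCallSet:
    """Far-cis style sliding-window enrichment on one binary coverage vector.

    For each window of ``w`` consecutive valid bins (sliding by 1), the
    covered count ``k`` is tested against the covered fraction of the
    surrounding ``bg_w`` bins (centered, window excluded, truncated at the
    vector ends).  Windows touching invalid bins are skipped.
    """
    cov = np.asarray(coverage).astype(np.int8)
    n = cov.size
    if bg_w <= w:
        raise ValueError("background window must exceed the test window")
    if valid is None:
        valid = np.ones(n, dtype=bool)
    if n < w:
        return _bh_and_merge(
            pd.DataFrame(columns=["chrom", "start", "end", "k", "p_bg", "z", "p"]), fdr
        )

    cov_v = np.where(valid, cov, 0)
    csum = np.concatenate([[0], np.cumsum(cov_v)])
    vsum = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    half = bg_w // 2

    starts = np.arange(0, n - w + 1)
    ends = starts + w
    k = csum[ends] - csum[starts]
    win_valid = (vsum[ends] - vsum[starts]) == w

    lo = np.maximum(starts - half, 0)
    hi = np.minimum(ends + half, n)
    bg_cov = (csum[hi] - csum[lo]) - k
    bg_n = (vsum[hi] - vsum[lo]) - w
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bg = np.where(bg_n > 0, bg_cov / np.maximum(bg_n, 1), np.nan)
    z, pval = _binom_window_stats(k, w, p_bg)
    z[~win_valid] = np.nan
    pval[~win_valid] = np.nan

    df = pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "k": k, "p_bg": p_bg, "z": z, "p": pval}
    )
    return _bh_and_merge(df, fdr)


def far_cis_calls(
    profile: ViewpointProfile,
    w: int = 50,
    bg_w: int = 1200,
    fdr: float = 0.01,
) -> InteractionCallSet:
    """Significant far-cis windows of a viewpoint on its own chromosome."""
    genome = profile.genome
    sl = genome.chrom_slice(profile.chrom)
    cov = (profile.signal[sl] > 0).astype(np.int8)
    valid = ~profile.mask[sl]
    calls = windowed_enrichment(cov, w=w, bg_w=bg_w, fdr=fdr, valid=valid, chrom=profile.chrom)
    for frame in (calls.windows, calls.intervals):
        if len(frame):
            frame[["start", "end"]] = frame[["start", "end"]] * genome.bin_size
    return calls


def trans_calls(
    profile: ViewpointProfile,
    window: int = 250,
    fdr: float = 0.01,
) -> InteractionCallSet:
    """Significant trans (interchromosomal) windows of a viewpoint.

    Windows of ``window`` bins tile every non-viewpoint chromosome with a
    half-window step; the background probability is the viewpoint's
    genome-wide trans covered fraction.  BH control runs across all trans
    windows together; merged significant intervals are the reported calls.
    """
    genome = profile.genome
    trans_chroms = [c for c in genome.chrom_names if c != profile.chrom]
    if not trans_chroms:
        raise ValueError("trans calling requires at least 2 chromosomes")
    cov_all = (profile.signal > 0).astype(np.int8)

    trans_mask = np.zeros(genome.n_bins, dtype=bool)
    for c in trans_chroms:
        trans_mask[genome.chrom_slice(c)] = True
    p_bg = float(cov_all[trans_mask].mean())

    step = max(window // 2, 1)
    rows = []
    for c in trans_chroms:
        sl = genome.chrom_slice(c)
        cov = cov_all[sl]
        n = cov.size
        if n < window:
            starts = [0] if n > 0 else []
            win = n
        else:
            starts = list(range(0, n - window + 1, step))
            if starts and starts[-1] + window < n:
                starts.append(n - window)
            win = window
        csum = np.concatenate([[0], np.cumsum(cov)])
        for s in starts:
            e = min(s + win, n)
            rows.append((c, s, e, int(csum[e] - csum[s]), e - s))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "k", "w"])
    zs, ps = [], []
    for _, row in df.iterrows():
        z, p = _binom_window_stats(
            np.array([row["k"]]), int(row["w"]), np.array([p_bg])
        )
        zs.append(z[0])
        ps.append(p[0])
    df["p_bg"] = p_bg
    df["z"] = zs
    df["p"] = ps
    df = df.drop(columns="w")
    calls = _bh_and_merge(df, fdr)
    for frame in (calls.windows, calls.intervals):
        if len(frame):
            frame[["start", "end"]] = frame[["start", "end"]] * genome.bin_size
    return calls


def rebin_z(
    z: np.ndarray,
    source_genome: GenomeModel,
    target_bin_size: int,
) -> tuple[GenomeModel, np.ndarray]:
    """Mean of z-scores in non-overlapping coarser bins (missing-aware).

    ``target_bin_size`` must be a multiple of the source resolution.
    Returns the coarse genome grid and the per-coarse-bin mean of
    non-missing source z values (NaN where none are present).
    """
    from .genome import make_genome

    z = np.asarray(z, dtype=float)
    if z.shape != (source_genome.n_bins,):
        raise ValueError("z length must equal source bin count")
    factor, rem = divmod(target_bin_size, source_genome.bin_size)
    if rem or factor < 1:
        raise ValueError("target bin size must be a multiple of the source resolution")

    coarse = make_genome(list(source_genome.chromosomes), target_bin_size)
    out = np.full(coarse.n_bins, np.nan)
    for chrom, _ in source_genome.chromosomes:
        src = z[source_genome.chrom_slice(chrom)]
        dst = coarse.chrom_slice(chrom)
        n_coarse = dst.stop - dst.start
        for i in range(n_coarse):
            chunk = src[i * factor : (i + 1) * factor]
            obs = ~np.isnan(chunk)
            if obs.any():
                out[dst.start + i] = chunk[obs].mean()
    return coarse, out


def aggregate_pairs(
    matrix: ContactMatrix,
    bin_set: np.ndarray,
    flank: int = 5,
) -> np.ndarray:
    """Average contact submatrix around all ordered pairs of a bin set.

    For every ordered pair ``(a, b)`` of distinct bins in ``bin_set``, the
    ``(2*flank+1)^2`` submatrix centered at ``(a, b)`` is extracted; pairs
    whose submatrix would fall off the matrix edge are skipped.  The
    element-wise mean over surviving pairs is returned.
    """
    bins = np.asarray(bin_set, dtype=int)
    if bins.size < 2:
        raise ValueError("bin_set needs at least 2 bins")
    n = matrix.genome.n_bins
    size = 2 * flank + 1
    acc = np.zeros((size, size))
    count = 0
    for a in bins:
        for b in bins:
            if a == b:
                continue
            if a - flank < 0 or a + flank >= n or b - flank < 0 or b + flank >= n:
                continue
            acc += matrix.counts[a - flank : a + flank + 1, b - flank : b + flank + 1]
            count += 1
    if count == 0:
        raise ValueError("all pairs fall off the matrix edge")
    return acc / count


def trans_counts_by_class(
    counts_per_viewpoint: dict,
    labels_per_viewpoint: dict,
    classes: tuple[str, ...] = ("SD", "SI", "CL", "CE"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class trans-call count distributions with pairwise one-sided tests.

    Each viewpoint contributes its number of significant trans interactions
    to the distribution of its RT class.  All ordered class pairs with data
    are compared with a one-sided Wilcoxon rank-sum (Mann-Whitney) test
    (alternative: first class greater), Bonferroni-corrected by the number
    of comparisons performed.  Returns ``(summary, tests)`` DataFrames.
    """
    groups: dict[str, list] = {c: [] for c in classes}
    for vp, cnt in counts_per_viewpoint.items():
        lab = labels_per_viewpoint.get(vp)
        if lab in groups:
            groups[lab].append(cnt)

    summary = pd.DataFrame(
        [
            {
                "class": c,
                "n": len(v),
                "median": float(np.median(v)) if v else np.nan,
                "mean": float(np.mean(v)) if v else np.nan,
            }
            for c, v in groups.items()
        ]
    )
    pairs = [
        (a, b)
        for i, a in enumerate(classes)
        for b in classes[i + 1 :]
        if groups[a] and groups[b]
    ]
    rows = []
    m = len(pairs)
    for a, b in pairs:
        try:
            stat, p = stats.mannwhitneyu(groups[a], groups[b], alternative="greater")
        except ValueError:
            stat, p = np.nan, np.nan
        rows.append(
            {"class_a": a, "class_b": b, "statistic": stat, "p": p,
             "p_bonferroni": min(p * m, 1.0) if np.isfinite(p) else np.nan}
        )
    return summary, pd.DataFrame(rows)
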