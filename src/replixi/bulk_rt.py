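"""Bulk BrdU-IP Repli-seq replication-timing profiles.

The RT score of a bin is derived from early- and late-S-phase BrdU-IP read
counts: both samples are scaled to reads-per-million, the early fraction
``r = E / (E + L)`` is computed, and the score is mapped affinely onto
``[-1, +1]`` as ``rt = 2r - 1`` (positive = early replicating, negative =
late).  Bins in the bottom tail of scaled total coverage are masked as
missing, profiles are quantile-normalized to a common distribution, and
replicates are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = [
    "BinnedCounts",
    "RTProfile",
    "bin_counts",
    "rt_score",
    "quantile_normalize",
    "normalize_profiles",
]


@dataclass(frozen=True)
class BinnedCounts:
    """Per-bin non-negative read counts on a genome's bin grid."""

    genome: GenomeModel
    counts: np.ndarray
    library_size: int | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (self.genome.n_bins,):
            raise ValueError("counts length must equal bin count")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)
        if self.library_size is None:
            object.__setattr__(self, "library_size", int(c.sum()))

    def rpm(self) -> np.ndarray:
        """Reads-per-million-scaled counts (zeros if the library is empty)."""
        if self.library_size == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts * (1e6 / self.library_size)


@dataclass(frozen=True)
class RTProfile:
    """Per-bin RT scores; NaN marks missing (filtered) bins, never 0."""

    genome: GenomeModel
    rt: np.ndarray
    sample_id: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        r = np.asarray(self.rt, dtype=float)
        if r.shape != (self.genome.n_bins,):
            raise ValueError("rt length must equal bin count")
        object.__setattr__(self, "rt", r)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.rt)


def bin_counts(
    read_positions: dict[str, np.ndarray],
    genome: GenomeModel,
    window_bp: int | None = None,
    step_bp: int | None = None,
) -> BinnedCounts | pd.DataFrame:
    """Count reads in sliding or non-overlapping windows.

    With ``window_bp == step_bp`` (or both omitted, defaulting to the
    genome's bin size) each read lands in its unique bin and a
    :class:`BinnedCounts` on the genome grid is returned.  In sliding mode
    (``step_bp < window_bp``) a read is counted in *every* window containing
    it, and a DataFrame ``(chrom, start, end, count)`` of windows (labeled by
    start, terminal partial windows dropped) is returned.

    ``read_positions`` maps chromosome name to sorted 0-based coordinates.
    """
    if window_bp is None:
        window_bp = genome.bin_size
    if step_bp is None:
        step_bp = window_bp
    if step_bp > window_bp:
        raise ValueError("step_bp must be <= window_bp")
    if step_bp <= 0:
        raise ValueError("step_bp must be positive")

    lengths = dict(genome.chromosomes)
    for chrom, pos in read_positions.items():
        if chrom not in lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        pos = np.asarray(pos)
        if pos.size and (np.any(np.diff(pos) < 0)):
            raise ValueError(f"positions on {chrom!r} are not sorted")
        if pos.size and (pos[0] < 0 or pos[-1] >= lengths[chrom]):
            raise ValueError(f"positions on {chrom!r} out of chromosome bounds")

    if window_bp == step_bp == genome.bin_size:
        counts = np.zeros(genome.n_bins, dtype=np.int64)
        for chrom, pos in read_positions.items():
            sl = genome.chrom_slice(chrom)
            n_bins = sl.stop - sl.start
            b = np.asarray(pos, dtype=np.int64) // genome.bin_size
            b = b[b < n_bins]  # reads in the dropped terminal remainder
            np.add.at(counts, sl.start + b, 1)
        return BinnedCounts(genome=genome, counts=counts)

    frames = []
    for chrom, length in genome.chromosomes:
        n_windows = (length - window_bp) // step_bp + 1 if length >= window_bp else 0
        if n_windows <= 0:
            continue
        starts = np.arange(n_windows, dtype=np.int64) * step_bp
        counts = np.zeros(n_windows, dtype=np.int64)
        pos = np.asarray(read_positions.get(chrom, []), dtype=np.int64)
        if pos.size:
            # window w contains pos iff start_w <= pos < start_w + window_bp
            last = np.minimum(pos // step_bp, n_windows - 1)
            first = np.maximum((pos - window_bp) // step_bp + 1, 0)
            for f, l in zip(first, last):
                if l >= f:
                    counts[f : l + 1] += 1
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": starts + window_bp, "count": counts}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "count"])
    return pd.concat(frames, ignore_index=True)


def rt_score(
    early: BinnedCounts,
    late: BinnedCounts,
    low_count_quantile: float = 0.05,
    sample_id: str = "",
) -> RTProfile:
    """Early/total RT score on RPM-scaled counts, mapped to ``[-1, +1]``.

    Bins whose scaled total ``E + L`` falls strictly below the
    ``low_count_quantile`` quantile of all bins are masked as missing, as are
    bins with no coverage at all.
    """
    if not early.genome.same_grid(late.genome):
        raise ValueError("early and late counts are on different bin grids")
    if not 0 <= low_count_quantile < 1:
        raise ValueError("low_count_quantile must be in [0, 1)")

    e, l = early.rpm(), late.rpm()
    total = e + l
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, e / np.where(total > 0, total, 1.0), np.nan)
    rt = 2.0 * r - 1.0
    if low_count_quantile > 0:
        cutoff = np.quantile(total, low_count_quantile)
        rt = np.where(total < cutoff, np.nan, rt)  # strictly below; ties kept
    rt = np.where(total == 0, np.nan, rt)
    return RTProfile(genome=early.genome, rt=rt, sample_id=sample_id, normalized=False)


def quantile_normalize(profiles: list[RTProfile]) -> list[RTProfile]:
    """Quantile-normalize profiles to the mean sorted distribution.

    Missing bins are excluded from ranking and preserved as missing.  Ties
    within a sample share the average reference value for their ranks.  When
    samples have unequal numbers of non-missing bins, each sample's sorted
    values are interpolated onto a common quantile grid before averaging.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    genome = profiles[0].genome
    for p in profiles:
        if not p.genome.same_grid(genome):
            raise ValueError("profiles are on different bin grids")
        if np.all(np.isnan(p.rt)):
            raise ValueError(f"profile {p.sample_id!r} is all-missing")

    sorted_vals = [np.sort(p.rt[~np.isnan(p.rt)]) for p in profiles]
    n_ref = max(v.size for v in sorted_vals)
    grid = (np.arange(n_ref) + 0.5) / n_ref
    ref = np.mean(
        [
            v if v.size == n_ref else np.quantile(v, grid)
            for v in sorted_vals
        ],
        axis=0,
    )

    out = []
    for p in profiles:
        rt = p.rt.copy()
        obs = ~np.isnan(rt)
        vals = rt[obs]
        n = vals.size
        if n == n_ref:
            ref_s = ref
        else:
            ref_s = np.quantile(ref, (np.arange(n) + 0.5) / n)
        order = np.argsort(vals, kind="stable")
        mapped = np.empty(n)
        mapped[order] = ref_s
        # ties share the average reference value
        df = pd.DataFrame({"v": vals, "m": mapped})
        mapped = df.groupby("v")["m"].transform("mean").to_numpy()
        rt[obs] = mapped
        out.append(replace(p, rt=rt, normalized=True))
    return out


def normalize_profiles(
    profiles: list[RTProfile],
    groups: list | None = None,
) -> list[RTProfile]:
    """Quantile-normalize, then average replicates per group.

    ``groups[i]`` names the replicate group of ``profiles[i]``; omitted, each
    profile is its own group.  The group mean ignores missing bins present in
    only some replicates; bins missing in all replicates stay missing.
    Returns one profile per group, in first-appearance order.
    """
    normed = quantile_normalize(profiles)
    if groups is None:
        return normed
    if len(groups) != len(profiles):
        raise ValueError("groups length must match profiles")
    out = []
    seen: dict = {}
    for g, p in zip(groups, normed):
        seen.setdefault(g, []).append(p)
    for g, members in seen.items():
        stacked = np.vstack([m.rt for m in members])
        obs = ~np.isnan(stacked)
        n_obs = obs.sum(axis=0)
        total = np.where(obs, stacked, 0.0).sum(axis=0)
        mean = np.where(n_obs > 0, total / np.maximum(n_obs, 1), np.nan)
        out.append(
            RTProfile(genome=members[0].genome, rt=mean, sample_id=str(g), normalized=True)
        )
    return out
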