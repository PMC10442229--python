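"""Signal binning, KO/WT differentials, Xi expression probability, and
feature-density enrichment by RT class.

The Xi probability of an X-linked gene is the allele-resolved read fraction
``xi / (xi + xa)``: 0 for a fully silenced Xi allele and 0.5 for full
reactivation (both alleles expressed equally).  Feature densities (genes,
escapees) per RT class are counts per Mb of class span, optionally
normalized by a reference feature set's density, with folds reported
against a chosen reference class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .rt_classes import ClassTrack, class_spans

__all__ = [
    "FeatureSet",
    "bin_track_mean",
    "log2_differential",
    "xi_probability",
    "density_by_class",
]


@dataclass(frozen=True)
class FeatureSet:
    """Genomic features (0-based half-open) with an optional category."""

    features: pd.DataFrame  # chrom, start, end, name[, category]
    source: str = ""

    def __post_init__(self) -> None:
        df = self.features
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"feature table needs columns {sorted(required)}")
        if (df["end"] <= df["start"]).any():
            raise ValueError("features must have end > start")
        if (df["start"] < 0).any():
            raise ValueError("negative feature coordinates")

    def midpoints(self) -> pd.DataFrame:
        mid = (self.features["start"] + self.features["end"]) // 2
        return pd.DataFrame({"chrom": self.features["chrom"], "pos": mid})


def bin_track_mean(
    positions: dict[str, np.ndarray],
    values: dict[str, np.ndarray],
    genome: GenomeModel,
) -> np.ndarray:
    """Per-bin arithmetic mean of a positioned signal track.

    ``positions[chrom]`` are sorted coordinates, ``values[chrom]`` the
    matching signal values.  Bins with no overlapping values are NaN, never
    zero.
    """
    total = np.zeros(genome.n_bins)
    n = np.zeros(genome.n_bins, dtype=np.int64)
    for chrom, pos in positions.items():
        pos = np.asarray(pos, dtype=np.int64)
        val = np.asarray(values[chrom], dtype=float)
        if pos.shape != val.shape:
            raise ValueError(f"positions/values mismatch on {chrom!r}")
        if pos.size and np.any(np.diff(pos) < 0):
            raise ValueError(f"positions on {chrom!r} are not sorted")
        sl = genome.chrom_slice(chrom)
        b = pos // genome.bin_size
        keep = b < (sl.stop - sl.start)
        np.add.at(total, sl.start + b[keep], val[keep])
        np.add.at(n, sl.start + b[keep], 1)
    with np.errstate(invalid="ignore"):
        return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def log2_differential(ko: np.ndarray, wt: np.ndarray) -> np.ndarray:
    """Per-bin log2(KO / WT); non-positive or missing input gives NaN."""
    ko = np.asarray(ko, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if ko.shape != wt.shape:
        raise ValueError("KO and WT tracks are on different grids")
    ok = np.isfinite(ko) & np.isfinite(wt) & (ko > 0) & (wt > 0)
    out = np.full(ko.shape, np.nan)
    out[ok] = np.log2(ko[ok] / wt[ok])
    return out


def xi_probability(xi_reads, xa_reads):
    """Xi read fraction ``xi / (xi + xa)``; NaN when both are zero.

    Scale-invariant: multiplying both read counts by a constant leaves the
    value unchanged.  0 marks a fully silenced Xi allele, 0.5 full
    reactivation.
    """
    xi = np.asarray(xi_reads, dtype=float)
    xa = np.asarray(xa_reads, dtype=float)
    if np.any(xi < 0) or np.any(xa < 0):
        raise ValueError("read counts must be non-negative")
    total = xi + xa
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, xi / np.where(total > 0, total, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


def density_by_class(
    features: FeatureSet,
    track: ClassTrack,
    normalizer: FeatureSet | None = None,
    reference_class: str = "CL",
) -> pd.DataFrame:
    """Feature density per RT class, optionally normalized and with folds.

    Each feature is assigned to the class of the bin containing its
    midpoint; features falling outside the binned genome are dropped.
    Density is count per Mb of class span.  With a ``normalizer`` feature
    set (e.g. all genes when the features are escapees), the normalized
    density is feature density over normalizer density (NaN when the
    normalizer density is zero).  ``fold_vs_reference`` divides by the
    ``reference_class`` row, using normalized densities when a normalizer
    is supplied and raw densities otherwise.
    """
    genome = track.genome

    def class_counts(fs: FeatureSet) -> pd.Series:
        labels = []
        for chrom, pos in fs.midpoints().itertuples(index=False):
            try:
                labels.append(track.labels[genome.bin_at(chrom, int(pos))])
            except (KeyError, ValueError):
                continue
        return pd.Series(labels).value_counts()

    counts = class_counts(features)
    norm_counts = class_counts(normalizer) if normalizer is not None else None

    spans = class_spans(track).set_index("label")
    rows = []
    for label, row in spans.iterrows():
        span = row["span_mb"]
        if span == 0:
            continue
        n = int(counts.get(label, 0))
        density = n / span
        rec = {"label": label, "count": n, "span_mb": span, "density_per_mb": density}
        if norm_counts is not None:
            norm_density = float(norm_counts.get(label, 0)) / span
            rec["normalizer_density_per_mb"] = norm_density
            rec["normalized_density"] = density / norm_density if norm_density > 0 else np.nan
        rows.append(rec)
    out = pd.DataFrame(rows)

    key = "normalized_density" if normalizer is not None else "density_per_mb"
    ref = out.loc[out["label"] == reference_class, key]
    if len(ref) == 1 and np.isfinite(ref.iloc[0]) and ref.iloc[0] > 0:
        out["fold_vs_reference"] = out[key] / ref.iloc[0]
    else:
        out["fold_vs_reference"] = np.nan
    return out
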