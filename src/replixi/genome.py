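"""Fixed bin grids over a small model genome.

Every stage of the pipeline — RT scoring, single-cell binarization,
contact-matrix work, feature enrichment — operates on per-bin vectors over a
shared grid of equal-width, non-overlapping bins (0-based, half-open).  A
:class:`GenomeModel` owns that grid and the per-bin chromosome bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "make_genome"]


@dataclass(frozen=True)
class GenomeModel:
    """A binned genome: chromosome sizes plus the derived bin table.

    Attributes
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in bp.  Terminal partial bins are dropped, so every bin in
        ``bins`` has exactly this width.
    bins
        DataFrame with columns ``chrom``, ``start``, ``end`` (0-based,
        half-open), ordered by (chromosome order, start).
    is_x
        Boolean per-bin flag marking X-chromosome bins.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int
    bins: pd.DataFrame = field(repr=False)
    is_x: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def chrom_index(self) -> np.ndarray:
        """Integer chromosome id per bin (order of ``chromosomes``)."""
        order = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        return self.bins["chrom"].map(order).to_numpy()

    def chrom_slice(self, name: str) -> slice:
        """Contiguous bin-index slice covering one chromosome."""
        mask = (self.bins["chrom"] == name).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(f"chromosome {name!r} not in genome")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def bin_at(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing ``pos`` on ``chrom``."""
        sl = self.chrom_slice(chrom)
        offset = pos // self.bin_size
        if pos < 0 or sl.start + offset >= sl.stop:
            raise ValueError(f"position {chrom}:{pos} outside binned region")
        return sl.start + offset

    def same_grid(self, other: "GenomeModel") -> bool:
        return (
            self.bin_size == other.bin_size
            and self.chromosomes == other.chromosomes
        )


def make_genome(
    chromosomes: list[tuple[str, int]],
    bin_size: int,
    x_chroms: tuple[str, ...] = ("chrX", "X"),
) -> GenomeModel:
    """Tile each chromosome into non-overlapping ``bin_size`` bins.

    Terminal remainders shorter than ``bin_size`` are dropped, so the grid is
    fully uniform.  Chromosomes named in ``x_chroms`` are flagged per-bin in
    ``is_x``.

    Raises
    ------
    ValueError
        If ``bin_size`` is not positive, a chromosome length is not positive,
        or a chromosome is shorter than one bin.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if not chromosomes:
        raise ValueError("at least one chromosome is required")
    names = [name for name, _ in chromosomes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")

    records = []
    for name, length in chromosomes:
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        n = length // bin_size
        if n == 0:
            raise ValueError(
                f"chromosome {name!r} ({length} bp) shorter than bin_size {bin_size}"
            )
        starts = np.arange(n, dtype=np.int64) * bin_size
        records.append(
            pd.DataFrame(
                {"chrom": name, "start": starts, "end": starts + bin_size}
            )
        )
    bins = pd.concat(records, ignore_index=True)
    is_x = bins["chrom"].isin(x_chroms).to_numpy()
    return GenomeModel(
        chromosomes=tuple((str(n), int(l)) for n, l in chromosomes),
        bin_size=int(bin_size),
        bins=bins,
        is_x=is_x,
    )
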