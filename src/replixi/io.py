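"""Readers and writers for the pipeline's on-disk formats.

All coordinates are 0-based half-open.  Missing values are serialized as an
explicit ``NA`` token, never as 0; bedGraph output simply omits missing
bins.  Contact matrices travel as a bin table plus a triplet TSV
``(bin_id_1, bin_id_2, count)``; on read, the two triangles are
symmetrized (element-wise max, with a warning on mismatch) and duplicate
entries are summed with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome import GenomeModel, make_genome
from .simulate import ContactMatrix

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "write_track_bedgraph",
    "read_bed",
    "write_bed",
    "read_value_matrix",
    "write_value_matrix",
    "read_contacts",
    "write_contacts",
    "write_genome_bins",
    "read_genome_bins",
]

NA_TOKEN = "NA"


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph into (chrom, start, end, value), sorted.

    Overlapping intervals are preserved, not merged.  Malformed lines raise
    with their line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            chrom, start, end, value = parts
            try:
                start_i, end_i = int(start), int(end)
                value_f = np.nan if value == NA_TOKEN else float(value)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric field in {line!r}") from None
            rows.append((chrom, start_i, end_i, value_f))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_bedgraph(df: pd.DataFrame, path) -> Path:
    """Write (chrom, start, end, value) records as bedGraph, sorted."""
    out = df.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        for chrom, start, end, value in out[["chrom", "start", "end", "value"]].itertuples(
            index=False
        ):
            fh.write(f"{chrom}\t{int(start)}\t{int(end)}\t{value:g}\n")
    return Path(path)


def write_track_bedgraph(genome: GenomeModel, values: np.ndarray, path) -> Path:
    """Write a per-bin track as bedGraph, omitting missing (NaN) bins."""
    df = genome.bins.copy()
    df["value"] = np.asarray(values, dtype=float)
    df = df[np.isfinite(df["value"])]
    return write_bedgraph(df, path)


def read_bed(path) -> pd.DataFrame:
    """Read a BED3+ file into (chrom, start, end[, name])."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            try:
                rec = (parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else "")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from None
            rows.append(rec)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path) -> Path:
    """Write (chrom, start, end[, name]) records as BED."""
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    out = df.sort_values(["chrom", "start"], kind="stable")
    with open(path, "w") as fh:
        for row in out[cols].itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")
    return Path(path)


def read_value_matrix(path) -> pd.DataFrame:
    """Read a bins x cells TSV matrix (bin rows, header of cell ids).

    The first three columns are chrom/start/end; ``NA`` tokens become NaN.
    """
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN])
    expected = {"chrom", "start", "end"}
    if not expected.issubset(df.columns):
        raise ValueError(f"matrix file needs columns {sorted(expected)}")
    return df


def write_value_matrix(genome: GenomeModel, matrix: np.ndarray, cell_ids: list, path) -> Path:
    """Write a cells x bins array as a bins-as-rows TSV with NA sentinels."""
    m = np.asarray(matrix, dtype=float).T  # -> bins x cells
    df = genome.bins.copy()
    for i, cid in enumerate(cell_ids):
        df[str(cid)] = m[:, i]
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
    return Path(path)


def write_genome_bins(genome: GenomeModel, path) -> Path:
    """Write the bin table with global bin ids."""
    df = genome.bins.copy()
    df.insert(0, "bin_id", np.arange(len(df)))
    df["is_x"] = genome.is_x.astype(int)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_genome_bins(path) -> GenomeModel:
    """Rebuild a GenomeModel from a bin table written by write_genome_bins."""
    df = pd.read_csv(path, sep="\t")
    sizes = df["end"] - df["start"]
    if sizes.nunique() != 1:
        raise ValueError("bin table has non-uniform bin sizes")
    bin_size = int(sizes.iloc[0])
    chroms = [(c, int(df.loc[df["chrom"] == c, "end"].max())) for c in df["chrom"].unique()]
    if "is_x" in df.columns:
        x_names = tuple(df.loc[df["is_x"] == 1, "chrom"].unique())
    else:
        x_names = ()
    genome = make_genome(chroms, bin_size, x_chroms=x_names or ("chrX", "X"))
    if genome.n_bins != len(df):
        raise ValueError("bin table does not tile its chromosomes")
    return genome


def write_contacts(matrix: ContactMatrix, path) -> Path:
    """Write the upper triangle of a contact matrix as triplet TSV."""
    counts = matrix.counts
    i, j = np.nonzero(np.triu(counts))
    df = pd.DataFrame({"bin_id_1": i, "bin_id_2": j, "count": counts[i, j]})
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_contacts(path, genome: GenomeModel) -> ContactMatrix:
    """Read a triplet TSV into a symmetric ContactMatrix.

    Duplicate (i, j) entries are summed (warning); when both triangles are
    present and disagree, the element-wise max is kept (warning).  Unknown
    bin ids raise.
    """
    df = pd.read_csv(path, sep="\t")
    n = genome.n_bins
    i = df["bin_id_1"].to_numpy(dtype=np.int64)
    j = df["bin_id_2"].to_numpy(dtype=np.int64)
    c = df["count"].to_numpy()
    if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
        bad = df[(i < 0) | (i >= n) | (j < 0) | (j >= n)].iloc[0]
        raise ValueError(f"unknown bin id in triplet {tuple(bad)}")
    if np.any(c < 0):
        raise ValueError("negative contact count")

    if pd.DataFrame({"i": i, "j": j}).duplicated().any():
        warnings.warn("duplicate (i, j) triplets summed")
    up_mask = i <= j
    tri_u = np.zeros((n, n))
    tri_l = np.zeros((n, n))
    np.add.at(tri_u, (i[up_mask], j[up_mask]), c[up_mask])
    np.add.at(tri_l, (j[~up_mask], i[~up_mask]), c[~up_mask])
    if np.any(~up_mask):
        overlap = (tri_u > 0) & (tri_l > 0)
        if np.any(tri_u[overlap] != tri_l[overlap]):
            warnings.warn("triangle mismatch; keeping element-wise max")
    upper = np.maximum(tri_u, tri_l)
    full = upper + np.triu(upper, 1).T
    return ContactMatrix(genome=genome, counts=full)


def read_config(path) -> dict:
    """Read a flat YAML key-value config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def write_config(cfg: dict, path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return Path(path)
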