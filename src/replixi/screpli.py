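"""Single-cell Repli-seq: binarization, S-phase kinetics, scRT values.

A mid-S cell's sequencing coverage doubles over bins it has replicated.
Binarization takes the cell's binned counts against a G1 (unreplicated)
reference, log2-transforms the library-size-scaled ratio, and segments each
chromosome with a two-state Gaussian HMM (sticky self-transitions); the
higher-mean state is "replicated".  A FACS-gate constraint pins which state
must be in the majority (early-S cells have replicated a minority of the
genome, mid/late-S a majority) and decides cells whose coverage shows only
a single level, where the fit alone cannot.

Chromosome-level kinetics are summarized as T10-90%: cells are ranked and
grouped by genome-wide percentage replication, chromosome-vs-genome group
means are fitted with a linear or logistic curve (pseudo points (0,0) and
(100,100) pin the tails), and the fitted time from 10% to 90% replication
is reported on a 10-hour S-phase scale.

Per-bin percentage replication across cells maps to a single-cell RT (scRT)
value: bins are ranked into one-percentile groups and each group's mean
percentage converts to an S-phase time ``t = S * (1 - p/100)``, reported at
0.1 h resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bulk_rt import BinnedCounts
from .genome import GenomeModel

__all__ = [
    "BinaryReplicationMatrix",
    "KineticsFit",
    "ScrtTrack",
    "binarize_cell",
    "binarize_cells",
    "percent_replication",
    "per_bin_percent_replication",
    "fit_t1090",
    "t1090_from_sigmoid_k",
    "scrt_values",
]

MISSING = np.int8(-1)


@dataclass
class BinaryReplicationMatrix:
    """Cells x bins replicated/unreplicated states with per-cell metadata.

    ``states`` is int8 with 1 = replicated, 0 = unreplicated, -1 = missing.
    ``cell_meta`` carries gate and genome percentage-replication columns.
    """

    genome: GenomeModel
    states: np.ndarray
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        s = np.asarray(self.states, dtype=np.int8)
        if s.ndim != 2 or s.shape[1] != self.genome.n_bins:
            raise ValueError("states must be (n_cells, n_bins)")
        self.states = s

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]


def _two_means_threshold(x: np.ndarray) -> np.ndarray:
    """Fallback 1D 2-means split; returns 0/1 by cluster mean order."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(x.size, dtype=np.int8)
    c = np.array([lo, hi], dtype=float)
    for _ in range(50):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([x[assign == k].mean() if np.any(assign == k) else c[k] for k in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return (assign == int(np.argmax(c))).astype(np.int8)


def binarize_cell(
    cell_counts: BinnedCounts,
    g1_reference: BinnedCounts,
    gate: str = "mid",
    self_transition: float = 0.99,
    min_separation: float = 0.5,
    strict_gate: bool = False,
    random_state: int = 0,
) -> np.ndarray:
    """Call per-bin replicated (1) / unreplicated (0) states for one cell.

    Bins with zero G1 coverage are returned as -1 (missing).  States are
    named by mean: against a G1 reference, the higher-coverage state is
    always the replicated one.  The FACS gate (``"early"`` expects a
    minority of the genome replicated, ``"mid"``/``"late"`` a majority)
    resolves cells whose fit is degenerate — near the very start or end of
    S the coverage is essentially single-level (state means closer than
    ``min_separation`` log2 units — half the 1.0 log2 gap a true
    replication doubling produces — after a 2-means fallback) and every
    informative bin is assigned the gate's majority state, with a warning.

    ``strict_gate=True`` additionally relabels any non-degenerate fit whose
    majority state contradicts the gate, overriding the mean ordering the
    way a frequency-anchored somy assignment would; this inverts legitimate
    minority-replicated mid-S cells and is off by default.
    """
    if gate not in ("early", "mid", "late"):
        raise ValueError(f"gate must be early|mid|late, got {gate!r}")
    if not cell_counts.genome.same_grid(g1_reference.genome):
        raise ValueError("cell and G1 reference are on different bin grids")

    genome = cell_counts.genome
    g1 = g1_reference.rpm()
    cell = cell_counts.rpm()
    valid = g1 > 0
    states = np.full(genome.n_bins, MISSING, dtype=np.int8)
    if not np.any(valid):
        return states

    # log2 ratio to G1; pseudocount on the cell side keeps zero-count bins finite
    ratio = (cell[valid] + 0.5 * np.min(cell[valid][cell[valid] > 0], initial=1.0)) / g1[valid]
    log2r = np.log2(ratio)

    # bimodality check: cells at the very start/end of S show a single
    # coverage level.  The per-bin noise scale is estimated robustly from
    # adjacent-bin differences (RT domains make most neighbours share a
    # state); if the overall spread does not exceed it, there is no second
    # level to segment and the gate decides.
    sigma_noise = _adjacent_noise_sd(log2r, genome, valid)
    if np.std(log2r) < 1.4 * sigma_noise:
        majority = 0 if gate == "early" else 1
        warnings.warn("degenerate single-state fit; assigning gate majority state")
        states[valid] = majority
        return states

    labels = _hmm_decode(log2r, genome, valid, self_transition, random_state)
    if labels is None or _state_separation(log2r, labels) < min_separation:
        fallback = _two_means_threshold(log2r)
        if _state_separation(log2r, fallback) < min_separation:
            majority = 0 if gate == "early" else 1
            warnings.warn("degenerate single-state fit; assigning gate majority state")
            states[valid] = majority
            return states
        if labels is None:
            warnings.warn("HMM fit failed; fell back to 2-means threshold")
        labels = fallback

    if strict_gate:
        frac_rep = labels.mean()
        if (gate == "early" and frac_rep > 0.5) or (gate != "early" and frac_rep < 0.5):
            labels = (1 - labels).astype(np.int8)
    states[valid] = labels
    return states


def _adjacent_noise_sd(log2r: np.ndarray, genome: GenomeModel, valid: np.ndarray) -> float:
    """Robust per-bin noise scale from within-chromosome adjacent differences."""
    chrom_idx = genome.chrom_index()[valid]
    diffs = np.diff(log2r)[np.diff(chrom_idx) == 0]
    if diffs.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(diffs))) / np.sqrt(2.0)


def _state_separation(x: np.ndarray, labels: np.ndarray) -> float:
    if labels.min() == labels.max():
        return 0.0
    return abs(float(x[labels == 1].mean()) - float(x[labels == 0].mean()))


def _hmm_decode(log2r, genome, valid, self_transition, random_state):
    """Two-state sticky Gaussian HMM along each chromosome; 1 = higher mean."""
    from hmmlearn.hmm import GaussianHMM

    chrom_idx = genome.chrom_index()[valid]
    lengths = np.bincount(chrom_idx)
    lengths = lengths[lengths > 0]
    x = log2r.reshape(-1, 1)
    # tied covariance: a free per-state variance lets one state inflate and
    # swallow both coverage levels (a classic EM pathology on 1D mixtures)
    model = GaussianHMM(
        n_components=2,
        covariance_type="tied",
        init_params="",
        params="mc",
        n_iter=100,
        random_state=random_state,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array(
        [[self_transition, 1 - self_transition], [1 - self_transition, self_transition]]
    )
    lo, hi = np.quantile(log2r, [0.25, 0.75])
    model.means_ = np.array([[lo], [hi]])
    spread = max(float(np.var(log2r)) / 2, 1e-4)
    model.covars_ = np.array([[spread]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, lengths)
            raw = model.predict(x, lengths)
    except Exception:
        return None
    means = model.means_.ravel()
    return (raw == int(np.argmax(means))).astype(np.int8)


def binarize_cells(
    counts: np.ndarray,
    g1_counts: np.ndarray,
    genome: GenomeModel,
    gates: list[str],
    exclude_x: bool = True,
    **kwargs,
) -> BinaryReplicationMatrix:
    """Binarize a cells x bins count matrix against a shared G1 reference.

    Genome percentage-replication in the metadata excludes X-chromosome bins
    when ``exclude_x`` is set (the default), since a uniformly late X would
    bias the whole-genome S-phase coordinate.
    """
    counts = np.asarray(counts)
    if counts.ndim != 2 or counts.shape[1] != genome.n_bins:
        raise ValueError("counts must be (n_cells, n_bins)")
    if len(gates) != counts.shape[0]:
        raise ValueError("one gate per cell required")
    g1 = BinnedCounts(genome=genome, counts=np.asarray(g1_counts))
    states = np.vstack(
        [
            binarize_cell(BinnedCounts(genome=genome, counts=row), g1, gate, **kwargs)
            for row, gate in zip(counts, gates)
        ]
    )
    mask = ~genome.is_x if exclude_x else np.ones(genome.n_bins, bool)
    pct = np.array([percent_replication(row, mask) for row in states])
    meta = pd.DataFrame({"gate": gates, "pct_genome": pct})
    return BinaryReplicationMatrix(genome=genome, states=states, cell_meta=meta)


def percent_replication(states: np.ndarray, region_mask: np.ndarray | None = None) -> float:
    """Percentage of non-missing bins replicated within a region mask."""
    states = np.asarray(states)
    if region_mask is None:
        region_mask = np.ones(states.shape[-1], dtype=bool)
    if not np.any(region_mask):
        raise ValueError("empty region mask")
    sub = states[..., region_mask]
    obs = sub != MISSING
    n = obs.sum()
    if n == 0:
        raise ValueError("no non-missing bins in mask")
    return 100.0 * float((sub == 1).sum()) / float(n)


def per_bin_percent_replication(matrix: BinaryReplicationMatrix) -> np.ndarray:
    """Per-bin percentage of cells that have replicated the bin (NaN if never observed)."""
    if matrix.n_cells < 1:
        raise ValueError("at least one cell is required")
    s = matrix.states
    obs = (s != MISSING).sum(axis=0)
    rep = (s == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs > 0, 100.0 * rep / np.maximum(obs, 1), np.nan)
    return p


@dataclass(frozen=True)
class KineticsFit:
    """A fitted chromosome-replication kinetics curve and its T10-90%."""

    model: str  # "linear" | "sigmoid"
    params: dict
    points: pd.DataFrame  # grouped (x, y) means incl. pseudo points
    t_10_90: float
    s_hours: float = 10.0

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.model == "linear":
            y = self.params["slope"] * x + self.params["intercept"]
        else:
            y = 100.0 / (1.0 + np.exp(-self.params["k"] * (x - self.params["x0"])))
        return np.clip(y, 0.0, 100.0)


def t1090_from_sigmoid_k(k: float, s_hours: float = 10.0) -> float:
    """Closed-form T10-90% of a 0/100 logistic with steepness ``k``.

    The logistic crosses 10% and 90% at ``x0 -/+ ln(9)/k``, so the
    10-to-90% span is ``2 ln 9 / k`` percentage points, i.e.
    ``(2 ln 9 / k) / 100 * S`` hours.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    return (2.0 * np.log(9.0) / k) / 100.0 * s_hours


def fit_t1090(
    genome_pct: np.ndarray,
    chrom_pct: np.ndarray,
    model: str = "linear",
    n_groups: int = 18,
    s_hours: float = 10.0,
    pseudo_points: bool = True,
) -> KineticsFit:
    """Fit chromosome-vs-genome replication kinetics and report T10-90%.

    Cells are ranked by genome percentage replication and split into
    ``n_groups`` equal-count groups (stable ties by input order); group
    means, plus pseudo points (0,0) and (100,100) anchoring the S-phase
    ends, are fitted with ``y = a*x + b`` (linear) or a 0/100-asymptote
    logistic (sigmoid).  T10-90% is the fitted x-span from y=10 to y=90
    (x clamped to [0,100]) scaled onto an ``s_hours`` S phase.
    """
    x = np.asarray(genome_pct, dtype=float)
    y = np.asarray(chrom_pct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("genome_pct and chrom_pct must be equal-length 1D arrays")
    if model not in ("linear", "sigmoid"):
        raise ValueError(f"unknown model {model!r}")

    n_cells = x.size
    k_groups = min(n_groups, n_cells)
    order = np.argsort(x, kind="stable")
    group_of = (np.arange(n_cells) * k_groups) // n_cells
    gx = np.array([x[order[group_of == g]].mean() for g in range(k_groups)])
    gy = np.array([y[order[group_of == g]].mean() for g in range(k_groups)])
    if pseudo_points:
        gx = np.concatenate([[0.0], gx, [100.0]])
        gy = np.concatenate([[0.0], gy, [100.0]])
    if gx.size < 3:
        raise ValueError("need at least 3 points to fit")
    points = pd.DataFrame({"x": gx, "y": gy})

    if model == "linear":
        slope, intercept = np.polyfit(gx, gy, 1)
        if slope <= 0:
            raise ValueError("non-increasing linear fit; kinetics undefined")
        x10 = (10.0 - intercept) / slope
        x90 = (90.0 - intercept) / slope
        params = {"slope": float(slope), "intercept": float(intercept)}
    else:
        def logistic(xv, k, x0):
            return 100.0 / (1.0 + np.exp(-k * (xv - x0)))

        k0 = 4.0 / max(np.ptp(gx[(gy > 10) & (gy < 90)]), 1.0) if np.any((gy > 10) & (gy < 90)) else 0.1
        x0_0 = float(np.interp(50.0, gy, gx))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    logistic, gx, gy, p0=[k0, x0_0],
                    bounds=([1e-4, -50.0], [100.0, 150.0]), maxfev=20000,
                )
        except RuntimeError as e:
            raise ValueError(f"sigmoid fit did not converge: {e}") from e
        k, x0 = popt
        x10 = x0 - np.log(9.0) / k
        x90 = x0 + np.log(9.0) / k
        params = {"k": float(k), "x0": float(x0)}

    x10 = float(np.clip(x10, 0.0, 100.0))
    x90 = float(np.clip(x90, 0.0, 100.0))
    t = max(x90 - x10, 0.0) / 100.0 * s_hours
    return KineticsFit(model=model, params=params, points=points,
                       t_10_90=float(np.clip(t, 0.0, s_hours)), s_hours=s_hours)


@dataclass(frozen=True)
class ScrtTrack:
    """Per-bin percentage replication and derived scRT hours (0.1 h steps)."""

    genome: GenomeModel
    percent: np.ndarray
    scrt: np.ndarray


def scrt_values(
    per_bin_p: np.ndarray,
    genome: GenomeModel | None = None,
    s_hours: float = 10.0,
) -> ScrtTrack:
    """Convert per-bin percentage replication to scRT hours.

    Bins are ranked by percentage replication (earliest = highest p) and
    split into one-percentile equal-count groups; each group takes its mean
    percentage ``p_bar`` and the scRT value ``S * (1 - p_bar/100)``, rounded
    half-up to 0.1 h.  Missing (NaN) bins stay missing.
    """
    p = np.asarray(per_bin_p, dtype=float)
    if p.size == 0:
        raise ValueError("empty input")
    obs = ~np.isnan(p)
    vals = p[obs]
    if vals.size == 0:
        raise ValueError("all bins missing")
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("percentages must lie in [0, 100]")

    n = vals.size
    k_groups = min(100, n)
    order = np.argsort(-vals, kind="stable")  # earliest (highest p) first
    group_of = (np.arange(n) * k_groups) // n
    scrt_obs = np.empty(n)
    for g in range(k_groups):
        members = order[group_of == g]
        p_bar = vals[members].mean()
        t = s_hours * (1.0 - p_bar / 100.0)
        scrt_obs[members] = np.floor(t * 10.0 + 0.5) / 10.0  # round half-up to 0.1 h

    scrt = np.full(p.shape, np.nan)
    scrt[obs] = scrt_obs
    if genome is None:
        from .genome import make_genome  # placeholder grid for bare arrays

        genome = make_genome([("track", p.size)], 1)
    return ScrtTrack(genome=genome, percent=p, scrt=scrt)
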