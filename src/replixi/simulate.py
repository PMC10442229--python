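"""Seeded synthetic data with the statistical structure the pipeline assumes.

The generator emulates three kinds of raw material:

* **Single-cell replication states and counts.**  Each cell sits at an
  S-phase fraction ``f``; each bin carries a latent replication time drawn
  once per cell, and the bin is replicated iff ``f * S`` has passed it
  (replication is irreversible within a cell).  Two replication programs are
  provided: a *graded* autosome/Xa-like program where bin ``b`` replicates
  around its mean time ``t_b`` with logistic jitter ``sigma``, and an
  Xi-like *uniform-late* program where a whole-chromosome onset ``o_c`` is
  drawn per cell (truncated normal in the second half of S) and every bin
  finishes within ``[o_c, o_c + duration]``.

* **Bulk BrdU-IP early/late fractions.**  Cells are pooled by ``f`` at the
  midpoint of S; per-fraction bin counts are Poisson around the pooled
  replicated-state totals.

* **Layered contact matrices.**  Cis contacts decay with bin distance by a
  power law; trans contacts are Poisson with a per-layer rate, so one bin
  class (e.g. SD) can be given elevated inter-chromosomal contact, and an
  optional cis boost plants SD-SD hotspots.

All functions are bit-reproducible given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel

__all__ = [
    "random_domain_times",
    "GradedProgram",
    "XiUniformLateProgram",
    "CellCollection",
    "simulate_cells",
    "simulate_bulk",
    "LayeredContactModel",
    "simulate_contacts",
    "ContactMatrix",
]

S_HOURS_DEFAULT = 10.0


def random_domain_times(
    genome: GenomeModel,
    seed,
    t_min: float = 0.3,
    t_max: float = 9.7,
    domain_bins: int = 20,
) -> np.ndarray:
    """Draw a domain-structured per-bin replication-time landscape.

    Real RT profiles are organized in megabase-scale early/late domains, not
    bin-to-bin noise.  White noise is smoothed per chromosome with a moving
    window of ``domain_bins`` bins and rank-mapped onto an even grid over
    ``[t_min, t_max]``, giving spatially correlated times with a uniform
    marginal across S phase.
    """
    rng = np.random.default_rng(seed)
    raw = np.empty(genome.n_bins)
    kernel = np.ones(max(domain_bins, 1)) / max(domain_bins, 1)
    for chrom, _ in genome.chromosomes:
        sl = genome.chrom_slice(chrom)
        noise = rng.normal(size=sl.stop - sl.start)
        raw[sl] = np.convolve(noise, kernel, mode="same")
    ranks = np.argsort(np.argsort(raw))
    return t_min + (t_max - t_min) * ranks / max(genome.n_bins - 1, 1)


@dataclass(frozen=True)
class GradedProgram:
    """Graded replication program: per-bin mean time with logistic noise.

    ``t_hours[b]`` is the mean replication time of bin ``b`` in hours within
    ``[0, s_hours]``; ``noise_sd`` (hours) scales the per-cell logistic
    jitter, so the probability that a cell at S-fraction ``f`` has replicated
    bin ``b`` is ``logistic((f*S - t_b)/noise_sd)``.
    """

    t_hours: np.ndarray
    noise_sd: float = 0.5
    s_hours: float = S_HOURS_DEFAULT

    def __post_init__(self) -> None:
        t = np.asarray(self.t_hours, dtype=float)
        object.__setattr__(self, "t_hours", t)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.s_hours <= 0:
            raise ValueError("s_hours must be positive")
        if np.any(t < 0) or np.any(t > self.s_hours):
            raise ValueError("t_hours must lie in [0, s_hours]")

    def latent_times(self, rng: np.random.Generator, n_cells: int, n_bins: int) -> np.ndarray:
        if self.t_hours.size not in (1, n_bins):
            raise ValueError("t_hours length does not match bin count")
        jitter = rng.logistic(0.0, 1.0, size=(n_cells, n_bins)) if self.noise_sd > 0 else 0.0
        return np.broadcast_to(self.t_hours, (n_cells, n_bins)) + self.noise_sd * jitter


@dataclass(frozen=True)
class XiUniformLateProgram:
    """Xi-like program: per-cell onset in late S, then rapid uniform completion.

    Onset ``o_c`` is drawn per cell from a normal(``onset_mean``,
    ``onset_sd``) truncated to the second half of S (``[s_hours/2,
    s_hours]``); each bin then replicates at ``o_c + U(0, duration)``, so all
    of the chromosome finishes within a ``duration``-hour window per cell.
    """

    onset_mean: float = 6.5
    onset_sd: float = 0.5
    duration: float = 3.0
    s_hours: float = S_HOURS_DEFAULT

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.onset_sd < 0:
            raise ValueError("onset_sd must be >= 0")
        if not (self.s_hours / 2 <= self.onset_mean <= self.s_hours):
            raise ValueError("onset_mean must lie in the second half of S")

    def draw_onsets(self, rng: np.random.Generator, n_cells: int) -> np.ndarray:
        lo, hi = self.s_hours / 2, self.s_hours
        if self.onset_sd == 0:
            return np.full(n_cells, self.onset_mean)
        a = (lo - self.onset_mean) / self.onset_sd
        b = (hi - self.onset_mean) / self.onset_sd
        u = rng.uniform(size=n_cells)
        return stats.truncnorm.ppf(u, a, b, loc=self.onset_mean, scale=self.onset_sd)

    def latent_times(self, rng: np.random.Generator, n_cells: int, n_bins: int) -> np.ndarray:
        onsets = self.draw_onsets(rng, n_cells)
        within = rng.uniform(0.0, self.duration, size=(n_cells, n_bins)) if self.duration > 0 else 0.0
        return onsets[:, None] + within

    def expected_percent_replication(self, t_hours: np.ndarray) -> np.ndarray:
        """Population expected %replication of the chromosome at time t.

        Closed-form: E over onsets of ``clip((t - o)/duration, 0, 1)``,
        evaluated by integrating the truncated-normal onset density.
        """
        t = np.atleast_1d(np.asarray(t_hours, dtype=float))
        lo, hi = self.s_hours / 2, self.s_hours
        if self.onset_sd == 0:
            frac = np.clip((t - self.onset_mean) / max(self.duration, 1e-12), 0.0, 1.0)
            return 100.0 * frac
        a = (lo - self.onset_mean) / self.onset_sd
        b = (hi - self.onset_mean) / self.onset_sd
        dist = stats.truncnorm(a, b, loc=self.onset_mean, scale=self.onset_sd)
        grid = np.linspace(lo, hi, 2001)
        pdf = dist.pdf(grid)
        out = np.empty_like(t)
        for i, ti in enumerate(t):
            frac = np.clip((ti - grid) / max(self.duration, 1e-12), 0.0, 1.0)
            out[i] = np.trapezoid(frac * pdf, grid)
        return 100.0 * out


@dataclass
class CellCollection:
    """Simulated single cells: true states, observed counts, S-phase metadata."""

    genome: GenomeModel
    s_fractions: np.ndarray
    states: np.ndarray  # (n_cells, n_bins) int8 0/1
    counts: np.ndarray  # (n_cells, n_bins) int64
    gates: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]


def _gate_for_fraction(f: float) -> str:
    if f < 1 / 3:
        return "early"
    if f < 2 / 3:
        return "mid"
    return "late"


def simulate_cells(
    genome: GenomeModel,
    program,
    n_cells: int,
    seed,
    *,
    s_fractions: np.ndarray | None = None,
    depth: float = 50.0,
    overdispersion: float = 0.0,
) -> CellCollection:
    """Simulate single S-phase cells under a replication program.

    Parameters
    ----------
    program
        :class:`GradedProgram` or :class:`XiUniformLateProgram`.
    s_fractions
        Per-cell S-phase fractions in (0, 1).  Sampled uniformly when
        omitted.  Passing the same fractions to a second call lets two
        programs (e.g. autosomes and the X) share cells.
    depth
        Mean reads per unreplicated bin; replicated bins double their rate.
    overdispersion
        Gamma-mixing coefficient; 0 gives pure Poisson counts, larger values
        give negative-binomial-like extra variance (variance ``mu + a*mu^2``).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    rng = np.random.default_rng(seed)
    if s_fractions is None:
        s_fractions = rng.uniform(0.0, 1.0, size=n_cells)
    else:
        s_fractions = np.asarray(s_fractions, dtype=float)
        if s_fractions.shape != (n_cells,):
            raise ValueError("s_fractions length must equal n_cells")

    n_bins = genome.n_bins
    latent = program.latent_times(rng, n_cells, n_bins)
    elapsed = s_fractions[:, None] * program.s_hours
    states = (elapsed >= latent).astype(np.int8)

    rate = depth * (1.0 + states)
    if overdispersion > 0:
        shape = 1.0 / overdispersion
        rate = rate * rng.gamma(shape, 1.0 / shape, size=rate.shape)
    counts = rng.poisson(rate).astype(np.int64)

    gates = [_gate_for_fraction(f) for f in s_fractions]
    cell_ids = [f"cell{i:04d}" for i in range(n_cells)]
    return CellCollection(genome, s_fractions, states, counts, gates, cell_ids)


def simulate_bulk(
    genome: GenomeModel,
    program,
    n_cells: int,
    depth: float,
    seed,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate pooled early/late BrdU-IP fraction counts.

    Cells at S-fraction below 0.5 are pooled as the early fraction, the rest
    as late.  Per-bin counts are Poisson around each fraction's
    replicated-state totals, calibrated so the mean reads per bin equals
    ``depth``.  Returns ``(early_counts, late_counts)``.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.0, 1.0, size=n_cells)
    latent = program.latent_times(rng, n_cells, genome.n_bins)
    states = (f[:, None] * program.s_hours >= latent).astype(np.float64)

    out = []
    for mask in (f < 0.5, f >= 0.5):
        totals = states[mask].sum(axis=0)
        mean_total = totals.mean()
        lam = depth * totals / mean_total if mean_total > 0 else np.zeros_like(totals)
        out.append(rng.poisson(lam).astype(np.int64))
    return out[0], out[1]


@dataclass(frozen=True)
class ContactMatrix:
    """Symmetric binned genome-wide contact counts on a genome's bin grid."""

    genome: GenomeModel
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (self.genome.n_bins, self.genome.n_bins):
            raise ValueError("counts shape does not match genome bin count")
        if np.any(c < 0):
            raise ValueError("contact counts must be non-negative")
        object.__setattr__(self, "counts", c)

    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.counts, self.counts.T))


@dataclass(frozen=True)
class LayeredContactModel:
    """Layered-X contact model: per-bin layer labels driving trans rates.

    ``layers`` assigns each bin a label (e.g. SD/SI/CL/CE on the X, "auto"
    elsewhere); ``trans_rates`` maps labels to non-negative rates, and the
    expected trans count between bins i, j is ``rate_i * rate_j *
    trans_depth`` — so a layer with a 5x rate shows ~5x total trans contacts
    per bin.  Cis contacts decay as ``cis_depth / (1 + d)^cis_decay`` with
    bin distance d; pairs of bins both labeled ``boost_label`` and at least
    ``boost_min_sep`` bins apart get their cis rate multiplied by
    ``cis_pair_boost`` (hotspot planting).
    """

    layers: np.ndarray
    trans_rates: dict
    cis_decay: float = 1.0
    cis_depth: float = 100.0
    trans_depth: float = 1.0
    cis_pair_boost: float = 1.0
    boost_label: str = "SD"
    boost_min_sep: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", np.asarray(self.layers, dtype=object))
        if any(r < 0 for r in self.trans_rates.values()):
            raise ValueError("trans rates must be >= 0")
        if self.cis_depth < 0 or self.trans_depth < 0 or self.cis_pair_boost < 0:
            raise ValueError("depths and boosts must be >= 0")


def simulate_contacts(genome: GenomeModel, model: LayeredContactModel, seed) -> ContactMatrix:
    """Draw a symmetric integer contact matrix from a layered model."""
    if model.layers.shape != (genome.n_bins,):
        raise ValueError("layer labels must have one entry per bin")
    if len(genome.chromosomes) < 2 and any(r > 0 for r in model.trans_rates.values()):
        warnings.warn("single-chromosome genome: no trans structure possible")
    rng = np.random.default_rng(seed)
    n = genome.n_bins
    chrom = genome.chrom_index()
    idx = np.arange(n)

    try:
        rates = np.array([float(model.trans_rates[l]) for l in model.layers])
    except KeyError as e:
        raise ValueError(f"no trans rate for layer {e.args[0]!r}") from None

    same = chrom[:, None] == chrom[None, :]
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = np.where(
        same,
        model.cis_depth / (1.0 + dist) ** model.cis_decay,
        model.trans_depth * rates[:, None] * rates[None, :],
    )
    if model.cis_pair_boost != 1.0:
        is_boost = model.layers == model.boost_label
        hot = same & is_boost[:, None] & is_boost[None, :] & (dist >= model.boost_min_sep)
        lam = np.where(hot, lam * model.cis_pair_boost, lam)

    upper = rng.poisson(np.triu(lam))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(genome=genome, counts=counts.astype(np.int64))
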