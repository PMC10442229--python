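import numpy as np
import pandas as pd
import pytest
from scipy import stats

from replixi.genome import make_genome
from replixi.interactions import (
    ContactMatrix,
    aggregate_pairs,
    assign_allele,
    far_cis_calls,
    rebin_z,
    smooth_fragments,
    trans_calls,
    trans_counts_by_class,
    virtual_4c,
    windowed_enrichment,
)
from replixi.simulate import LayeredContactModel, simulate_contacts


class TestAssignAllele:
    TABLE = {"B6": "ACGTAC", "JF1": "ACGTTC"}

    def test_exact_match_assigns(self):
        assert assign_allele("ACGTACGGG", self.TABLE) == "B6"
        assert assign_allele("ACGTTCGGG", self.TABLE) == "JF1"

    def test_single_mismatch_unassigned(self):
        assert assign_allele("ACGTGCGGG", self.TABLE) == "unassigned"

    def test_foreign_prefix_unassigned(self):
        assert assign_allele("TTTTTTTTT", self.TABLE) == "unassigned"

    def test_ambiguous_table_raises(self):
        with pytest.raises(ValueError):
            assign_allele("ACGTAC", {"B6": "ACGTAC", "JF1": "ACGTAC"})


class TestSmoothFragments:
    def test_constant_signal_unchanged(self):
        x = np.full(500, 3.5)
        assert np.allclose(smooth_fragments(x), 3.5)

    def test_unit_impulse_spreads_to_1_over_window(self):
        x = np.zeros(1001)
        x[500] = 1.0
        sm = smooth_fragments(x, window=201)
        covered = sm[400:601]
        assert np.allclose(covered, 1 / 201)
        assert np.allclose(sm[:400], 0) and np.allclose(sm[601:], 0)

    def test_small_toy_matches_brute_force(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        sm = smooth_fragments(x, window=3)
        expected = [np.mean(x[max(i - 1, 0): i + 2]) for i in range(5)]
        assert np.allclose(sm, expected)

    def test_even_window_raises(self):
        with pytest.raises(ValueError):
            smooth_fragments(np.ones(10), window=4)


@pytest.fixture
def two_chrom_matrix():
    """200 bins on chrX + 100 on chr2 at 5 kb, seeded random contacts."""
    genome = make_genome([("chrX", 1_000_000), ("chr2", 500_000)], 5_000)
    rng = np.random.default_rng(12)
    a = rng.poisson(2.0, (genome.n_bins, genome.n_bins))
    counts = np.triu(a) + np.triu(a, 1).T
    return ContactMatrix(genome=genome, counts=counts)


class TestVirtual4C:
    def test_viewpoint_rows_summed_and_scaled(self, two_chrom_matrix):
        prof = virtual_4c(two_chrom_matrix, ("chrX", 400_000, 800_000), exclusion_bins=10)
        # 400 kb viewpoint at 5 kb = 80 matrix rows
        assert prof.mask[80:160].all()
        assert prof.signal[prof.mask].sum() == 0
        assert prof.signal.sum() == pytest.approx(10_000)

    def test_scale_invariance(self, two_chrom_matrix):
        vp = ("chrX", 400_000, 800_000)
        a = virtual_4c(two_chrom_matrix, vp)
        scaled = ContactMatrix(genome=two_chrom_matrix.genome,
                               counts=two_chrom_matrix.counts * 7)
        b = virtual_4c(scaled, vp)
        assert np.allclose(a.signal, b.signal)

    def test_viewpoint_only_contacts_give_empty_profile(self):
        genome = make_genome([("chrX", 500_000), ("chr2", 250_000)], 5_000)
        counts = np.zeros((genome.n_bins, genome.n_bins))
        counts[10, 12] = counts[12, 10] = 50  # inside viewpoint+flank only
        m = ContactMatrix(genome=genome, counts=counts)
        with pytest.warns(UserWarning, match="no contacts"):
            prof = virtual_4c(m, ("chrX", 50_000, 75_000), exclusion_bins=5)
        assert prof.signal.sum() == 0


def brute_force_windowed(cov, w, bg_w, fdr):
    """Independent per-window enumeration oracle for windowed_enrichment."""
    from statsmodels.stats.multitest import multipletests

    n = cov.size
    half = bg_w // 2
    rows = []
    for s in range(n - w + 1):
        k = int(cov[s: s + w].sum())
        lo, hi = max(s - half, 0), min(s + w + half, n)
        bg = np.concatenate([cov[lo:s], cov[s + w: hi]])
        p_bg = bg.mean() if bg.size else np.nan
        if not np.isfinite(p_bg) or p_bg in (0.0, 1.0):
            rows.append((s, k, np.nan, np.nan))
            continue
        z = (k - w * p_bg) / np.sqrt(w * p_bg * (1 - p_bg))
        p = stats.binom.sf(k - 1, w, p_bg)
        rows.append((s, k, z, p))
    df = pd.DataFrame(rows, columns=["start", "k", "z", "p"])
    ok = df["p"].notna()
    sig = np.zeros(len(df), bool)
    if ok.any():
        sig[ok.to_numpy()] = multipletests(df.loc[ok, "p"], alpha=fdr, method="fdr_bh")[0]
    df["significant"] = sig
    return df


class TestWindowedEnrichment:
    def test_flat_coverage_gives_zero_z_no_calls(self):
        cov = np.ones(500, dtype=np.int8)
        cov[::2] = 0  # exactly half covered everywhere
        calls = windowed_enrichment(cov, w=50, bg_w=200, fdr=0.01)
        assert calls.n_calls == 0
        mid = calls.windows.iloc[200]
        assert abs(mid["z"]) < 1.0

    def test_hand_binomial_z(self):
        # k = 50 of 50 covered against p_bg = 0.05 -> z ~ 30.8
        z = (50 - 50 * 0.05) / np.sqrt(50 * 0.05 * 0.95)
        assert z == pytest.approx(30.82, abs=0.01)
        cov = np.zeros(2450, dtype=np.int8)
        cov[1200:1250] = 1
        rest = np.random.default_rng(1).random(2450) < 0.05
        cov = np.maximum(cov, rest.astype(np.int8))
        calls = windowed_enrichment(cov, w=50, bg_w=1200, fdr=0.01)
        win = calls.windows[calls.windows["start"] == 1200].iloc[0]
        assert win["z"] > 25 and win["significant"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cov = (rng.random(2000) < rng.uniform(0.05, 0.4)).astype(np.int8)
        block = rng.integers(0, 1900)
        cov[block: block + rng.integers(20, 80)] = 1
        calls = windowed_enrichment(cov, w=50, bg_w=600, fdr=0.01)
        oracle = brute_force_windowed(cov, w=50, bg_w=600, fdr=0.01)
        assert len(calls.windows) == len(oracle)
        assert np.allclose(calls.windows["k"], oracle["k"])
        assert np.allclose(calls.windows["z"], oracle["z"], equal_nan=True)
        assert np.allclose(calls.windows["p"], oracle["p"], equal_nan=True)
        assert (calls.windows["significant"] == oracle["significant"]).all()

    def test_degenerate_background_excluded_from_fdr(self):
        cov = np.zeros(300, dtype=np.int8)  # p_bg = 0 everywhere
        calls = windowed_enrichment(cov, w=50, bg_w=200, fdr=0.01)
        assert calls.windows["p"].isna().all()
        assert calls.n_calls == 0

    def test_q_at_least_p(self):
        rng = np.random.default_rng(3)
        cov = (rng.random(1000) < 0.2).astype(np.int8)
        calls = windowed_enrichment(cov, w=50, bg_w=400, fdr=0.01)
        ok = calls.windows.dropna(subset=["p"])
        assert (ok["q"] >= ok["p"] - 1e-12).all()


class TestFarCisCalls:
    def test_planted_block_called_and_merged(self, two_chrom_matrix):
        genome = make_genome([("chrX", 10_000_000), ("chr2", 500_000)], 5_000)
        counts = np.zeros((genome.n_bins, genome.n_bins))
        rng = np.random.default_rng(5)
        vp = slice(80, 160)
        # sparse background plus a contacted block far in cis
        bg_bins = rng.choice(2000, 60, replace=False)
        counts[vp, bg_bins[None, :]] = 1
        counts[vp, 1000:1060] = 3
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = ContactMatrix(genome=genome, counts=counts)
        prof = virtual_4c(m, ("chrX", 400_000, 800_000), exclusion_bins=50)
        calls = far_cis_calls(prof, w=50, bg_w=1200, fdr=0.01)
        assert calls.n_calls >= 1
        hit = calls.intervals.iloc[0]
        assert hit["start"] <= 1000 * 5000 and hit["end"] >= 1060 * 5000


class TestTransCalls:
    def test_zero_trans_contacts_zero_calls(self):
        genome = make_genome([("chrX", 2_000_000), ("chr2", 2_000_000)], 5_000)
        counts = np.zeros((genome.n_bins, genome.n_bins))
        counts[:400, :400] = 1  # cis only
        m = ContactMatrix(genome=genome, counts=np.triu(counts) + np.triu(counts, 1).T)
        prof = virtual_4c(m, ("chrX", 0, 400_000), exclusion_bins=5)
        calls = trans_calls(prof, window=50, fdr=0.01)
        assert calls.n_calls == 0

    def test_planted_trans_block_called(self):
        genome = make_genome([("chrX", 2_500_000), ("chr2", 5_000_000)], 5_000)
        n = genome.n_bins
        rng = np.random.default_rng(9)
        counts = np.zeros((n, n))
        vp = slice(100, 180)
        chr2 = genome.chrom_slice("chr2")
        scatter = rng.choice(np.arange(chr2.start, chr2.stop), 40, replace=False)
        counts[vp, scatter[None, :]] = 1
        block = slice(chr2.start + 400, chr2.start + 650)  # 250-bin enriched block
        counts[vp, block] = rng.poisson(2.0, (80, 250)) + 1
        counts = np.triu(counts) + np.triu(counts, 1).T
        m = ContactMatrix(genome=genome, counts=counts)
        prof = virtual_4c(m, ("chrX", 500_000, 900_000), exclusion_bins=50)
        calls = trans_calls(prof, window=250, fdr=0.01)
        assert calls.n_calls == 1
        hit = calls.intervals.iloc[0]
        assert hit["chrom"] == "chr2"
        assert hit["start"] <= 400 * 5000 and hit["end"] >= 650 * 5000


class TestRebinZ:
    def test_constant_preserved(self):
        src = make_genome([("chrX", 800_000)], 5_000)
        coarse, out = rebin_z(np.full(src.n_bins, 2.5), src, 400_000)
        assert coarse.n_bins == 2 and np.allclose(out, 2.5)

    def test_alternating_mean(self):
        src = make_genome([("chrX", 400_000)], 5_000)
        z = np.tile([0.0, 1.0], 40)
        _, out = rebin_z(z, src, 400_000)
        assert out[0] == pytest.approx(0.5)

    def test_missing_aware_mean(self):
        src = make_genome([("chrX", 40_000)], 5_000)
        z = np.array([1.0, np.nan, 3.0, np.nan, np.nan, np.nan, np.nan, np.nan])
        _, out = rebin_z(z, src, 40_000)
        assert out[0] == pytest.approx(2.0)

    def test_non_multiple_target_raises(self):
        src = make_genome([("chrX", 40_000)], 5_000)
        with pytest.raises(ValueError):
            rebin_z(np.zeros(src.n_bins), src, 12_500)


class TestAggregatePairs:
    def test_single_pair_returns_submatrix(self):
        genome = make_genome([("chrX", 2_000_000), ("chr2", 400_000)], 100_000)
        rng = np.random.default_rng(2)
        a = rng.poisson(5.0, (genome.n_bins, genome.n_bins))
        m = ContactMatrix(genome=genome, counts=np.triu(a) + np.triu(a, 1).T)
        agg = aggregate_pairs(m, np.array([5, 15]), flank=2)
        manual = (m.counts[3:8, 13:18] + m.counts[13:18, 3:8]) / 2
        assert np.allclose(agg, manual)

    def test_homogeneous_matrix_center_corner_ratio_near_1(self):
        genome = make_genome([("chrX", 10_000_000), ("chr2", 400_000)], 100_000)
        rng = np.random.default_rng(7)
        a = rng.poisson(20.0, (genome.n_bins, genome.n_bins))
        m = ContactMatrix(genome=genome, counts=np.triu(a) + np.triu(a, 1).T)
        bins = rng.choice(np.arange(10, 90), 12, replace=False)
        agg = aggregate_pairs(m, bins, flank=3)
        ratio = agg[3, 3] / agg[0, 0]
        assert 0.5 < ratio < 2.0

    def test_edge_pairs_skipped_and_all_skipped_raises(self):
        genome = make_genome([("chrX", 400_000)], 100_000)
        m = ContactMatrix(genome=genome, counts=np.ones((4, 4)))
        with pytest.raises(ValueError):
            aggregate_pairs(m, np.array([0, 3]), flank=2)


class TestTransCountsByClass:
    def test_dominant_class_significant(self):
        counts = {f"sd{i}": 10 + i for i in range(6)} | {f"cl{i}": i % 2 for i in range(6)}
        labels = {f"sd{i}": "SD" for i in range(6)} | {f"cl{i}": "CL" for i in range(6)}
        summary, tests = trans_counts_by_class(counts, labels)
        sd_row = summary.set_index("class").loc["SD"]
        assert sd_row["n"] == 6 and sd_row["median"] > 10
        row = tests[(tests["class_a"] == "SD") & (tests["class_b"] == "CL")].iloc[0]
        assert row["p_bonferroni"] < 0.05

    def test_identical_distributions_not_significant(self):
        counts = {f"a{i}": v for i, v in enumerate([1, 2, 3, 4, 5])}
        counts |= {f"b{i}": v for i, v in enumerate([1, 2, 3, 4, 5])}
        labels = {f"a{i}": "SD" for i in range(5)} | {f"b{i}": "SI" for i in range(5)}
        _, tests = trans_counts_by_class(counts, labels)
        assert (tests["p_bonferroni"] > 0.05).all()

    def test_bonferroni_factor_is_number_of_comparisons(self):
        counts = {"a": 1, "b": 2, "c": 3}
        labels = {"a": "SD", "b": "SI", "c": "CL"}
        _, tests = trans_counts_by_class(counts, labels)
        # 3 populated classes -> 3 pairwise comparisons
        assert len(tests) == 3
        assert np.allclose(tests["p_bonferroni"],
                           np.minimum(tests["p"] * 3, 1.0), equal_nan=True)
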