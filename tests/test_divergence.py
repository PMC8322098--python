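"""Hudson F_ST, Slatkin linearisation, sliding windows, jackknife, f3 and D."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glpop.divergence import (FstEstimate, assign_blocks, block_jackknife,
                              colony_freqs_em, dstat, f3stat, fst_from_sfs2d,
                              hudson_components, site_fst_components,
                              sliding_window_fst)
from glpop.gl import GLMatrix
from glpop.sfs import FoldedSFS2D, sfs2d_em
from conftest import certain_gl, make_gl


class TestHudsonFst:
    def test_population_frequency_value(self):
        # two populations at true frequencies 0.2 and 0.8: with many sampled
        # chromosomes the unbiased estimator approaches 0.36/0.68
        n = 500
        m = np.zeros((n + 1, n + 1))
        m[100, 400] = 0.5
        m[400, 100] = 0.5
        est = fst_from_sfs2d(FoldedSFS2D((n, n), m))
        assert abs(est.fst - 0.36 / 0.68) < 0.005

    def test_equal_frequency_mass_gives_zero(self):
        n = 8
        m = np.zeros((n + 1, n + 1))
        for j in range(n + 1):
            m[j, j] = 1.0
        est = fst_from_sfs2d(FoldedSFS2D((n, n), m))
        # equal sample frequencies: numerator is the (negative) sampling
        # correction, so the estimate is <= 0 and near 0
        assert est.fst <= 0 and est.fst > -0.2

    def test_no_variation_flagged(self):
        n = 4
        m = np.zeros((n + 1, n + 1))
        m[0, 0] = m[n, n] = 1.0
        assert np.isnan(fst_from_sfs2d(FoldedSFS2D((n, n), m)).fst)

    def test_slatkin_transform(self):
        assert np.isclose(FstEstimate(0.5, 1.0).slatkin, 1.0)

    @given(f=st.floats(0.0, 0.95))
    @settings(max_examples=30, deadline=None)
    def test_slatkin_monotone_invertible(self, f):
        fp = FstEstimate(f, 1.0).slatkin
        assert fp >= f - 1e-12
        assert np.isclose(fp / (1 + fp), f, atol=1e-12)

    def test_folding_symmetry_of_components(self):
        a, b = hudson_components(6, 8)
        assert np.allclose(a, a[::-1, ::-1]) and np.allclose(b, b[::-1, ::-1])


def drifted_two_pop(seed=0, S=3000, n=6, F=0.1, n_chrom_mb=5):
    rng = np.random.default_rng(seed)
    p0 = rng.uniform(0.1, 0.9, size=S)
    aa = p0 * (1 - F) / F
    bb = (1 - p0) * (1 - F) / F
    f1, f2 = rng.beta(aa, bb), rng.beta(aa, bb)
    ga = rng.binomial(2, f1[:, None], size=(S, n))
    gb = rng.binomial(2, f2[:, None], size=(S, n))
    base = make_gl(np.zeros((S, n), dtype=int), spacing=n_chrom_mb * 1_000_000 // S)
    gla = GLMatrix(sites=base.sites, individuals=[f"a{i}" for i in range(n)],
                   colonies=["A"] * n, L=certain_gl(ga),
                   chrom_lengths=base.chrom_lengths)
    glb = GLMatrix(sites=base.sites, individuals=[f"b{i}" for i in range(n)],
                   colonies=["B"] * n, L=certain_gl(gb),
                   chrom_lengths=base.chrom_lengths)
    return gla, glb, f1, f2


class TestSlidingWindows:
    def test_window_sums_reproduce_global_exactly(self):
        gla, glb, *_ = drifted_two_pop(seed=1, S=800)
        prior = sfs2d_em(gla, glb, max_iter=200)
        a, b = site_fst_components(gla, glb, prior)
        tab = sliding_window_fst(gla, glb, prior, window=50_000, step=12_500)
        # every site lies in exactly window/step windows of the edge-covering
        # tiling, so summed window components reproduce the global ratio
        ratio_windows = tab["alpha"].sum() / tab["beta"].sum()
        assert np.isclose(ratio_windows, a.sum() / b.sum(), rtol=1e-12)
        # and the global ratio agrees with the SFS-mass estimate at the EM
        # fixed point
        est = fst_from_sfs2d(prior)
        assert np.isclose(a.sum() / b.sum(), est.fst, rtol=1e-4)

    def test_empty_window_flagged_not_zero(self):
        gla, glb, *_ = drifted_two_pop(seed=2, S=50, n_chrom_mb=1)
        gla.chrom_lengths["chr1"] = 5_000_000  # empty tail windows
        glb.chrom_lengths["chr1"] = 5_000_000
        prior = sfs2d_em(gla, glb, max_iter=100)
        tab = sliding_window_fst(gla, glb, prior)
        empty = tab[tab["n_sites"] == 0]
        assert len(empty) > 0 and empty["fst"].isna().all()

    def test_step_larger_than_window_rejected(self):
        gla, glb, *_ = drifted_two_pop(seed=3, S=30)
        prior = sfs2d_em(gla, glb, max_iter=50)
        with pytest.raises(ValueError):
            sliding_window_fst(gla, glb, prior, window=1000, step=2000)


class TestBlockJackknife:
    def test_matches_hand_computed_equal_weights(self):
        rng = np.random.default_rng(4)
        num = rng.random(12)
        den = np.ones(12)
        theta, se, z = block_jackknife(num, den, weights=np.ones(12))
        # textbook delete-one jackknife
        t = num.sum() / 12
        tj = np.array([(num.sum() - num[j]) / 11 for j in range(12)])
        se_ref = np.sqrt(11 / 12 * np.sum((tj - tj.mean()) ** 2))
        assert np.isclose(theta, t, atol=1e-12)
        assert np.isclose(se, se_ref, atol=1e-12)
        assert np.isclose(z, t / se_ref, atol=1e-9)

    def test_identical_blocks_zero_se_flagged(self):
        num = np.full(10, 2.0)
        den = np.full(10, 4.0)
        theta, se, z = block_jackknife(num, den)
        assert theta == 0.5 and se == 0 and np.isinf(z)

    def test_too_few_blocks_rejected(self):
        with pytest.raises(ValueError):
            block_jackknife(np.ones(5), np.ones(5))


class TestDStat:
    @staticmethod
    def pattern_panel(n_abba=40, n_baba=10, n_aabb=50):
        """Populations fixed for ABBA/BABA/AABB patterns, certain genotypes."""
        S = n_abba + n_baba + n_aabb
        # derived=minor; outgroup fixed ancestral (0)
        g1 = np.concatenate([np.zeros(n_abba), np.full(n_baba, 2), np.full(n_aabb, 2)])
        g2 = np.concatenate([np.full(n_abba, 2), np.zeros(n_baba), np.full(n_aabb, 2)])
        g3 = np.concatenate([np.full(n_abba, 2), np.full(n_baba, 2), np.zeros(n_aabb)])
        go = np.zeros(S)
        geno = np.stack([g1, g1, g2, g2, g3, g3, go, go], axis=1).astype(int)
        base = make_gl(geno, spacing=500_000)  # 10 blocks of 5 Mb over 50 Mb
        return GLMatrix(sites=base.sites,
                        individuals=[f"i{k}" for k in range(8)],
                        colonies=["P1", "P1", "P2", "P2", "P3", "P3", "O", "O"],
                        L=certain_gl(geno), chrom_lengths={"chr1": 50_000_000})

    def test_counts_and_arithmetic(self):
        g = self.pattern_panel()
        res = dstat(g, "P1", "P2", "P3", "O", block_bp=5_000_000, seed=0)
        assert res["nABBA"] == 40 and res["nBABA"] == 10
        assert np.isclose(res["D"], 0.6)

    def test_balanced_counts_give_zero(self):
        g = self.pattern_panel(n_abba=30, n_baba=30)
        res = dstat(g, "P1", "P2", "P3", "O", block_bp=5_000_000, seed=0)
        assert np.isclose(res["D"], 0.0)

    def test_polymorphic_outgroup_sites_skipped(self):
        g = self.pattern_panel()
        # make the outgroup heterozygous at the first 5 sites
        g.L[:5, 6, :] = 0
        g.L[:5, 6, 1] = 1
        g.L[:5, 7, :] = 0
        g.L[:5, 7, 1] = 1
        res = dstat(g, "P1", "P2", "P3", "O", block_bp=5_000_000, seed=0)
        assert res["n_skipped_outgroup"] == 5
        assert res["nABBA"] == 35


class TestF3:
    def test_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        geno = rng.binomial(2, 0.5, size=(60, 9))
        base = make_gl(geno, spacing=1_000_000)
        g = GLMatrix(sites=base.sites, individuals=[f"i{k}" for k in range(9)],
                     colonies=["C"] * 3 + ["A"] * 3 + ["B"] * 3,
                     L=certain_gl(geno), chrom_lengths={"chr1": 60_000_000})
        res = f3stat(g, "C", "A", "B", block_bp=5_000_000)
        c = geno[:, :3].sum(axis=1) / 6
        a = geno[:, 3:6].sum(axis=1) / 6
        b = geno[:, 6:].sum(axis=1) / 6
        per_site = (c - a) * (c - b) - c * (1 - c) / 5
        assert np.isclose(res["f3"], per_site.mean(), atol=1e-6)

    def test_clone_of_source_non_negative(self):
        rng = np.random.default_rng(6)
        f = rng.uniform(0.1, 0.9, size=4000)
        # target and source A drawn from the same population frequencies
        geno_c = rng.binomial(2, f[:, None], size=(4000, 3))
        geno_a = rng.binomial(2, f[:, None], size=(4000, 3))
        geno_b = rng.binomial(2, 0.5, size=(4000, 3))
        geno = np.concatenate([geno_c, geno_a, geno_b], axis=1)
        base = make_gl(geno, spacing=15_000)
        g = GLMatrix(sites=base.sites, individuals=[f"i{k}" for k in range(9)],
                     colonies=["C"] * 3 + ["A"] * 3 + ["B"] * 3,
                     L=certain_gl(geno), chrom_lengths={"chr1": 60_000_000})
        res = f3stat(g, "C", "A", "B", block_bp=5_000_000)
        assert res["f3"] > -0.005

    def test_single_diploid_target_rejected(self):
        geno = np.zeros((20, 3), dtype=int)
        g = GLMatrix(sites=make_gl(geno).sites, individuals=["c", "a", "b"],
                     colonies=["C", "A", "B"], L=certain_gl(geno),
                     chrom_lengths={"chr1": 1_000_000})
        with pytest.raises(ValueError):
            f3stat(g, "C", "A", "B")


def test_assign_blocks_contiguous():
    sites = pd.DataFrame({"chrom": ["c1"] * 4 + ["c2"] * 2,
                          "pos": [1, 4_999_999, 5_000_001, 9_000_000, 10, 20],
                          "major": "A", "minor": "C"})
    ids = assign_blocks(sites, block_bp=5_000_000)
    assert list(ids) == [0, 0, 1, 1, 2, 2]


class TestClusterRankProperty:
    def test_between_cluster_exceeds_within_cluster(self, default_dataset):
        ef = default_dataset.truth.expected_fst
        within = [ef.loc["Hornoya", "Rost"], ef.loc["Faroe", "Papey"],
                  ef.loc["GannetIsl", "GullIsl"]]
        between = [ef.loc["Spitsbergen", "Hornoya"], ef.loc["IsleOfMay", "Faroe"],
                   ef.loc["GannetIsl", "Grimsey"]]
        assert max(within) < min(between)
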