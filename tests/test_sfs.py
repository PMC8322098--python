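"""Folded SFS estimation, diversity statistics, heterozygosity and RoH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glpop.gl import gl_from_count_arrays
from glpop.sfs import (FoldedSFS1D, HetTrack, call_roh_and_froh,
                       individual_heterozygosity, roh_cutoff, sfs1d_em,
                       sfs2d_em, sfs_summary_stats, site_count_likelihoods,
                       tajima_constants, window_het_track)
from conftest import certain_gl, make_gl


def folded_histogram(genotypes):
    S, N = genotypes.shape
    j = genotypes.sum(axis=1)
    k = np.minimum(j, 2 * N - j)
    return np.bincount(k, minlength=N + 1).astype(float)


class TestSFS1D:
    def test_certain_genotypes_equal_histogram(self):
        rng = np.random.default_rng(0)
        geno = rng.binomial(2, 0.3, size=(1500, 6))
        sfs = sfs1d_em(certain_gl(geno), tol=1e-10, max_iter=3000)
        assert np.allclose(sfs.counts, folded_histogram(geno), atol=1e-4)

    def test_single_individual_all_homozygous(self):
        geno = np.zeros((50, 1), dtype=int)
        geno[:25] = 2  # homozygous minor folds onto class 0
        sfs = sfs1d_em(certain_gl(geno), tol=1e-10)
        assert np.isclose(sfs.counts[0], 50) and np.isclose(sfs.counts[1], 0)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(1)
        L = rng.random((300, 4, 3))
        L /= L.max(axis=2, keepdims=True)
        _, traj = sfs1d_em(L, return_trajectory=True)
        assert np.all(np.diff(traj) >= -1e-8)

    def test_noisy_colony_recovers_truth(self):
        # 6 diploids, 8x depth, 1% error: TV distance to realised SFS < 0.02
        rng = np.random.default_rng(2)
        S = 20_000
        f = rng.uniform(0.05, 0.95, size=S)
        geno = rng.binomial(2, f[:, None], size=(S, 6))
        reads = rng.poisson(8.0, size=(S, 6))
        pm = geno / 2 * 0.99 + (1 - geno / 2) * 0.01
        nmin = rng.binomial(reads, pm)
        L = gl_from_count_arrays(reads - nmin, nmin, 0.01)
        sfs = sfs1d_em(L)
        tv = 0.5 * np.abs(sfs.proportions - folded_histogram(geno) / S).sum()
        assert tv < 0.02

    def test_all_missing_sites_dropped_or_rejected(self):
        L = certain_gl(np.zeros((3, 2), dtype=int))
        L[1] = 1.0  # uninformative site: dropped from the spectrum
        assert sfs1d_em(L).total_sites == pytest.approx(2)
        with pytest.raises(ValueError):
            sfs1d_em(np.ones((3, 2, 3)))


class TestSFS2D:
    def test_certain_genotypes_equal_joint_histogram(self):
        rng = np.random.default_rng(3)
        ga = rng.binomial(2, 0.3, size=(800, 4))
        gb = rng.binomial(2, 0.6, size=(800, 4))
        s2 = sfs2d_em(certain_gl(ga), certain_gl(gb), tol=1e-10, max_iter=3000)
        H = np.zeros((9, 9))
        for a, b in zip(ga.sum(axis=1), gb.sum(axis=1)):
            H[a, b] += 0.5
            H[8 - a, 8 - b] += 0.5
        assert np.abs(s2.matrix - H).max() < 1e-3

    def test_identical_populations_mass_on_diagonal(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, size=(500, 3))
        s2 = sfs2d_em(certain_gl(g), certain_gl(g), tol=1e-10, max_iter=2000)
        off = s2.matrix.copy()
        np.fill_diagonal(off, 0)
        assert off.sum() / s2.total_sites < 1e-6

    def test_marginals_match_1d(self):
        rng = np.random.default_rng(5)
        ga = rng.binomial(2, 0.3, size=(600, 3))
        gb = rng.binomial(2, 0.5, size=(600, 3))
        s2 = sfs2d_em(certain_gl(ga), certain_gl(gb), tol=1e-9, max_iter=2000)
        s1 = sfs1d_em(certain_gl(ga), tol=1e-9, max_iter=2000)
        tv = 0.5 * np.abs(s2.marginal(0).proportions - s1.proportions).sum()
        assert tv < 0.02


class TestSummaryStats:
    def test_matches_independent_formula(self):
        # independent implementation with explicit sums
        counts = np.array([900.0, 40, 25, 15, 12, 8])
        n = 10
        sfs = FoldedSFS1D(n, counts)
        st_ = sfs_summary_stats(sfs)

        k = np.arange(6)
        pi_w = [kk * (n - kk) / (n * (n - 1) / 2) for kk in k]
        theta_pi = sum(w * c for w, c in zip(pi_w, counts))
        S = counts[1:].sum()
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        var = c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1)
        d_ref = (theta_pi - S / a1) / np.sqrt(var)
        assert np.isclose(st_.theta_pi_per_site, theta_pi / counts.sum(), atol=1e-10)
        assert np.isclose(st_.theta_w_per_site, S / a1 / counts.sum(), atol=1e-10)
        assert np.isclose(st_.tajimas_d, d_ref, atol=1e-10)

    def test_singleton_excess_strongly_negative(self):
        counts = np.zeros(6)
        counts[0], counts[1] = 950, 50
        assert sfs_summary_stats(FoldedSFS1D(10, counts)).tajimas_d < -2

    def test_zero_segregating_sites_flagged(self):
        counts = np.zeros(6)
        counts[0] = 100
        assert np.isnan(sfs_summary_stats(FoldedSFS1D(10, counts)).tajimas_d)

    def test_folding_involution(self):
        # folding weights are symmetric: theta_pi from a folded spectrum equals
        # theta_pi from the unfolded spectrum it came from
        rng = np.random.default_rng(6)
        n = 8
        eta = rng.random(n + 1) * 100
        folded = np.array([eta[k] + eta[n - k] if k != n - k else eta[k]
                           for k in range(n // 2 + 1)])
        w_unf = [k * (n - k) / (n * (n - 1) / 2) for k in range(n + 1)]
        ref = sum(w * e for w, e in zip(w_unf, eta))
        got = sfs_summary_stats(FoldedSFS1D(n, folded))
        assert np.isclose(got.theta_pi_per_site * folded.sum(), ref)


class TestHeterozygosity:
    def test_fraction(self):
        assert np.isclose(
            individual_heterozygosity(FoldedSFS1D(2, [900.0, 100.0])), 0.1)

    def test_all_homozygous(self):
        assert individual_heterozygosity(FoldedSFS1D(2, [50.0, 0.0])) == 0

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(7)
        S = 30_000
        f = rng.uniform(0.05, 0.95, size=S)
        geno = rng.binomial(2, f[:, None], size=(S, 1))
        reads = rng.poisson(10.0, size=(S, 1))
        pm = geno / 2 * 0.99 + (1 - geno / 2) * 0.01
        nmin = rng.binomial(reads, pm)
        L = gl_from_count_arrays(reads - nmin, nmin, 0.01)
        est = individual_heterozygosity(sfs1d_em(L))
        truth = (geno == 1).mean()
        assert abs(est - truth) / truth < 0.05


class TestWindowHetTrack:
    def test_uniform_genome_and_boundary_rule(self):
        rng = np.random.default_rng(8)
        S = 2600
        geno = (rng.random((S, 1)) < 0.25).astype(int)  # het at 25% of sites
        g = make_gl(geno, spacing=1000, chrom_len=2_600_000)
        t = window_het_track(g, "ind0", window=100_000, step=50_000)
        w = t.windows
        # tiling: starts at multiples of 50 kb, truncated at the chromosome
        # end, no window shorter than one step
        assert w["start"].iloc[0] == 0
        assert (w["end"] - w["start"]).min() >= 50_000
        assert w["end"].max() == 2_600_000
        usable = w[w["usable"]]
        assert np.allclose(usable["het"].mean(), 0.25, atol=0.03)

    def test_window_in_roh_is_zero(self):
        geno = (np.arange(3000) % 4 == 0).astype(int)[:, None]
        geno[1000:2000] = 0  # homozygous tract
        g = make_gl(geno, spacing=1000, chrom_len=3_000_000)
        t = window_het_track(g, "ind0", window=100_000, step=50_000)
        w = t.windows
        inside = w[(w["start"] >= 1_000_000) & (w["end"] <= 2_000_000)]
        assert (inside["het"] < 1e-6).all()

    def test_sparse_window_flagged_unusable(self):
        geno = np.zeros((15, 1), dtype=int)
        g = make_gl(geno, spacing=100_000, chrom_len=1_500_000)
        t = window_het_track(g, "ind0", window=100_000, step=50_000, min_sites=10)
        assert not t.windows["usable"].any()

    def test_bad_window_config_rejected(self):
        g = make_gl(np.zeros((5, 1), dtype=int))
        with pytest.raises(ValueError):
            window_het_track(g, "ind0", window=100, step=0)


class TestRoH:
    @staticmethod
    def track(hets, individual="x", chrom="chr1", usable=None):
        n = len(hets)
        usable = [True] * n if usable is None else usable
        w = pd.DataFrame({
            "chrom": chrom, "start": 50_000 * np.arange(n),
            "end": 50_000 * np.arange(n) + 100_000,
            "n_sites": 50, "het": hets, "usable": usable,
        })
        return HetTrack(individual=individual, windows=w)

    def test_cutoff_identical_windows(self):
        t = self.track([0.2] * 10)
        assert np.isclose(roh_cutoff([t]), 0.2)

    def test_cutoff_matches_hand_quantile(self):
        a = self.track([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0], "a")
        b = self.track([0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2], "b")
        # per-window means 0.2..1.1; 10% quantile with linear interpolation
        ref = np.quantile(np.arange(0.2, 1.11, 0.1), 0.10)
        assert np.isclose(roh_cutoff([a, b]), ref, atol=1e-12)

    def test_segment_pattern(self):
        t = self.track([0.5, 0.5, 0.01, 0.01, 0.01, 0.5])
        segs, froh = call_roh_and_froh(t, cutoff=0.1, min_len=150_000)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start, s.end, s.n_windows) == (100_000, 300_000, 3)
        # scanned span = union of the six windows = 0..350 kb
        assert np.isclose(froh, (s.end - s.start) / 350_000)

    def test_single_low_window_never_a_segment(self):
        t = self.track([0.5, 0.01, 0.5, 0.5])
        segs, froh = call_roh_and_froh(t, cutoff=0.1)
        assert segs == [] and froh == 0

    def test_unusable_window_breaks_run(self):
        t = self.track([0.01, 0.01, 0.01], usable=[True, False, True])
        segs, _ = call_roh_and_froh(t, cutoff=0.1)
        assert segs == []

    @given(min_len=st.integers(100_000, 500_000))
    @settings(max_examples=20, deadline=None)
    def test_froh_bounded_and_monotone_in_min_len(self, min_len):
        t = self.track([0.01, 0.01, 0.5, 0.01, 0.01, 0.01, 0.5, 0.2])
        _, f1 = call_roh_and_froh(t, cutoff=0.1, min_len=min_len)
        _, f2 = call_roh_and_froh(t, cutoff=0.1, min_len=min_len + 100_000)
        assert 0 <= f2 <= f1 <= 1


def test_tajima_constants_reference_values():
    # Tajima (1989) constants for n=10 against direct evaluation
    c = tajima_constants(10)
    assert np.isclose(c["a1"], sum(1 / i for i in range(1, 10)))
    assert np.isclose(c["b1"], 11 / 27)
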