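"""The synthetic multi-colony generator: model validation, frequency drift,
read emission, RoH implanting, mito alignment, geography and determinism."""

import copy

import numpy as np
import pytest

from glpop.gl import allele_freq_em
from glpop.mito import pairwise_phist
from glpop.simdata import (DEFAULT_CONFIG, build_population_model,
                           draw_allele_frequencies, implant_roh_tracts,
                           make_geography, sample_genotypes_and_reads,
                           simulate_dataset, simulate_mito_alignment)


class TestBuildModel:
    def test_default_model(self):
        m = build_population_model({})
        assert len(m.colonies) == 12
        assert m.n_per_colony == 6
        assert m.n_individuals == 72
        assert len(m.cluster_names) == 4
        assert len(m.admixture_events) == 1
        assert m.bottleneck["colony"] == "Spitsbergen"

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            build_population_model({"not_a_key": 1})

    def test_invalid_alpha_rejected(self):
        cfg = {"admixture_events": [("Bjornoya", "Spitsbergen", "Hornoya", 1.5)]}
        with pytest.raises(ValueError, match="alpha"):
            build_population_model(cfg)

    def test_branch_f_one_rejected(self):
        tree = dict(DEFAULT_CONFIG["tree"])
        tree["arctic_anc"] = ("root", 1.0)
        with pytest.raises(ValueError, match="F"):
            build_population_model({"tree": tree})

    def test_cyclic_tree_rejected(self):
        tree = dict(DEFAULT_CONFIG["tree"])
        tree["arctic_anc"] = ("Spitsbergen", 0.1)
        with pytest.raises(ValueError, match="cycle"):
            build_population_model({"tree": tree})

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            build_population_model({"n_per_colony": -1})
        with pytest.raises(ValueError):
            build_population_model({"depth_range": (0.0, 5.0)})


class TestFrequencies:
    def test_zero_drift_everywhere_copies_ancestral(self):
        tree = {k: (v[0], 0.0) for k, v in DEFAULT_CONFIG["tree"].items()}
        m = build_population_model({"tree": tree, "n_sites": 500})
        freqs, node = draw_allele_frequencies(m)
        for c in m.colonies:
            if c == "Bjornoya":
                continue
            assert np.allclose(freqs.loc[c], node["root"])

    def test_admixed_colony_is_exact_mixture(self):
        m = build_population_model({"n_sites": 500})
        freqs, _ = draw_allele_frequencies(m)
        mix = 0.5 * freqs.loc["Spitsbergen"] + 0.5 * freqs.loc["Hornoya"]
        assert np.allclose(freqs.loc["Bjornoya"], mix)

    def test_alpha_zero_equals_source_b(self):
        cfg = {"admixture_events": [("Bjornoya", "Spitsbergen", "Hornoya", 0.0)],
               "n_sites": 300}
        m = build_population_model(cfg)
        freqs, _ = draw_allele_frequencies(m)
        assert np.allclose(freqs.loc["Bjornoya"], freqs.loc["Hornoya"])

    def test_stepping_stone_fst_increases_with_chain_distance(self):
        m = build_population_model({"n_sites": 20_000})
        freqs, _ = draw_allele_frequencies(m)
        from glpop.simdata import expected_pairwise_fst
        ef = expected_pairwise_fst(freqs, m.colonies)
        chain = ["Hornoya", "Rost", "Faroe", "Papey", "Vestmannaeyjar",
                 "Breidafjordur", "Grimsey"]
        d1 = ef.loc["Hornoya", "Rost"]
        d3 = ef.loc["Hornoya", "Papey"]
        d6 = ef.loc["Hornoya", "Grimsey"]
        assert d1 < d3 < d6

    def test_frequencies_in_unit_interval(self):
        m = build_population_model({"n_sites": 1000})
        freqs, _ = draw_allele_frequencies(m)
        assert (freqs.to_numpy() >= 0).all() and (freqs.to_numpy() <= 1).all()


class TestReadEmission:
    def test_extreme_depth_recovers_genotypes(self):
        m = build_population_model({"n_sites": 800, "depth_range": (300.0, 300.0),
                                    "error_rate": 0.001})
        rng = np.random.default_rng(0)
        freqs, _ = draw_allele_frequencies(m, rng)
        glm, truth = sample_genotypes_and_reads(freqs, m, rng=rng)
        called = np.argmax(glm.L, axis=2)
        agree = (called == truth.genotypes).mean()
        assert agree > 0.999

    def test_invalid_depth_and_error_rejected(self):
        with pytest.raises(ValueError):
            build_population_model({"depth_range": (-1.0, 2.0)})
        with pytest.raises(ValueError):
            build_population_model({"error_rate": 0.7})

    def test_full_missingness_gives_flat_triples(self):
        m = build_population_model({"n_sites": 100, "missing_rate": 1.0})
        rng = np.random.default_rng(1)
        freqs, _ = draw_allele_frequencies(m, rng)
        glm, _ = sample_genotypes_and_reads(freqs, m, rng=rng)
        assert glm.missing_mask().all()

    def test_alpha_one_draws_all_copies_from_source_a(self):
        cfg = {"admixture_events": [("Bjornoya", "Spitsbergen", "Hornoya", 1.0)],
               "n_sites": 4000}
        m = build_population_model(cfg)
        rng = np.random.default_rng(2)
        freqs, _ = draw_allele_frequencies(m, rng)
        glm, truth = sample_genotypes_and_reads(freqs, m, rng=rng)
        idx = [j for j, (n, c) in enumerate(m.individuals()) if c == "Bjornoya"]
        fa = freqs.loc["Spitsbergen"].to_numpy()
        mean_dose = truth.genotypes[:, idx].mean(axis=1) / 2
        # sample frequency tracks the Spitsbergen frequency, not Hornoya's
        err_a = np.abs(mean_dose - fa).mean()
        err_b = np.abs(mean_dose - freqs.loc["Hornoya"].to_numpy()).mean()
        assert err_a < err_b


class TestRoHImplanting:
    def test_whole_chromosome_tract_kills_heterozygosity(self):
        m = build_population_model({
            "n_sites": 2000, "chromosomes": {"chr1": 1_000_000},
            "bottleneck": {"colony": "Spitsbergen", "roh_fraction": 1.0,
                           "tract_length_range": (1_000_000, 1_000_000)}})
        rng = np.random.default_rng(3)
        freqs, _ = draw_allele_frequencies(m, rng)
        glm, truth = sample_genotypes_and_reads(freqs, m, rng=rng)
        geno = truth.genotypes[:, : m.n_individuals]
        geno, roh = implant_roh_tracts(geno, m, "Spitsbergen", m.bottleneck,
                                       glm.sites, rng, freqs)
        idx = [j for j, (n, c) in enumerate(m.individuals()) if c == "Spitsbergen"]
        assert (geno[:, idx] != 1).all()

    def test_tract_longer_than_chromosome_rejected(self):
        m = build_population_model({
            "chromosomes": {"chr1": 1_000_000},
            "bottleneck": {"colony": "Spitsbergen", "roh_fraction": 0.2,
                           "tract_length_range": (2_000_000, 3_000_000)}})
        rng = np.random.default_rng(4)
        freqs, _ = draw_allele_frequencies(m, rng)
        glm, truth = sample_genotypes_and_reads(freqs, m, rng=rng)
        with pytest.raises(ValueError, match="longer than"):
            implant_roh_tracts(truth.genotypes[:, : m.n_individuals], m,
                               "Spitsbergen", m.bottleneck, glm.sites, rng, freqs)

    def test_default_fraction_realised(self, default_dataset):
        roh = default_dataset.truth.roh_intervals
        genome = sum(default_dataset.model.chromosomes.values())
        frac = roh.assign(length=roh["end"] - roh["start"]) \
                  .groupby("individual")["length"].sum() / genome
        assert np.allclose(frac, 0.16, atol=0.03)


class TestMitoSimulation:
    def test_zero_rate_identical_sequences(self):
        m = build_population_model({"mito": {"length": 300, "private_rate": 0.0,
                                             "island_fixed_diffs": 0,
                                             "outgroup_diffs": 10}})
        recs = simulate_mito_alignment(m)
        body = {s for n, s in recs if not n.startswith("Outgroup")}
        assert len(body) == 1

    def test_high_rate_many_haplotypes(self):
        from glpop.mito import collapse_haplotypes
        m = build_population_model({"mito": {"length": 8000, "private_rate": 10.0,
                                             "island_fixed_diffs": 0,
                                             "outgroup_diffs": 100}})
        recs = [r for r in simulate_mito_alignment(m)
                if not r[0].startswith("Outgroup")]
        hs = collapse_haplotypes(recs, {n: "x" for n, _ in recs})
        assert hs.n_haplotypes >= 60

    def test_two_island_model_positive_phist(self):
        m = build_population_model({"mito": {"length": 2000, "private_rate": 2.0,
                                             "island_fixed_diffs": 8,
                                             "outgroup_diffs": 50}})
        recs = [r for r in simulate_mito_alignment(m)
                if not r[0].startswith("Outgroup")]
        half = set(m.colonies[len(m.colonies) // 2 :])
        island_of = {n: ("I2" if n.rsplit("_", 1)[0] in half else "I1")
                     for n, _ in recs}
        phi, _ = pairwise_phist(recs, island_of, n_perm=9, seed=0)
        assert phi.loc["I1", "I2"] > 0.3

    def test_zero_length_rejected(self):
        m = build_population_model({"mito": {"length": 0, "private_rate": 1.0,
                                             "island_fixed_diffs": 0,
                                             "outgroup_diffs": 1}})
        with pytest.raises(ValueError):
            simulate_mito_alignment(m)


class TestGeography:
    def test_default_layout_valid(self, default_dataset):
        geo = default_dataset.geography
        assert geo.water.ndim == 2
        assert len(geo.colonies) == 12
        # reachability is exercised by water_lcp_distance in test_geoflow

    def test_colony_on_deep_land_rejected(self):
        cfg = copy.deepcopy(DEFAULT_CONFIG["geography"])
        cfg["land"].append((75.0, 80.0, 8.0, 24.0))  # bury Spitsbergen
        m = build_population_model({"geography": cfg})
        with pytest.raises(ValueError, match="water cell"):
            make_geography(m)


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        a = simulate_dataset({"n_sites": 500}, seed=9)
        b = simulate_dataset({"n_sites": 500}, seed=9)
        assert np.array_equal(a.gl.L, b.gl.L)
        assert a.gl.sites.equals(b.gl.sites)
        assert a.mito == b.mito
        assert np.array_equal(a.truth.genotypes, b.truth.genotypes)
        assert a.truth.roh_intervals.equals(b.truth.roh_intervals)

    def test_different_seed_differs(self):
        a = simulate_dataset({"n_sites": 500}, seed=9)
        b = simulate_dataset({"n_sites": 500}, seed=10)
        assert not np.array_equal(a.gl.L, b.gl.L)


class TestNullModel:
    def test_no_drift_no_admixture_fst_near_zero(self):
        tree = {k: (v[0], 0.0) for k, v in DEFAULT_CONFIG["tree"].items()}
        tree["Bjornoya"] = ("Hornoya", 0.0)
        m_cfg = {"tree": tree, "admixture_events": [], "bottleneck": None,
                 "n_sites": 10_000,
                 "clusters": {c: "one" for c in DEFAULT_CONFIG["colonies"]}}
        ds = simulate_dataset(m_cfg, seed=11)
        ef = ds.truth.expected_fst
        vals = ef.to_numpy()[np.triu_indices(len(ef), k=1)]
        assert np.abs(vals).max() < 1e-12  # identical frequencies exactly
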