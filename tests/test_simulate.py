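import numpy as np
import pandas as pd
import pytest

from poolscan import bsa_scan, simulate


class TestCrossDesign:
    def test_qtl_outside_map_rejected(self):
        with pytest.raises(ValueError, match="outside chromosome"):
            simulate.CrossDesign(chromosomes={"chr1": 50.0}, qtl=[("chr1", 60.0, 0.1)])
        with pytest.raises(ValueError, match="not in the simulated map"):
            simulate.CrossDesign(chromosomes={"chr1": 50.0}, qtl=[("chrX", 10.0, 0.1)])

    def test_invalid_pool_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate.CrossDesign(pool_fraction=0.0)
        with pytest.raises(ValueError):
            simulate.CrossDesign(pool_fraction=0.6)


class TestSimulateBc1:
    def test_family_totals_within_design_range(self):
        pop = simulate.simulate_bc1(simulate.CrossDesign(seed=3))
        assert 7 * 127 <= pop.n_individuals <= 7 * 174
        assert len(np.unique(pop.family_id)) == 7

    def test_marker_genotype_frequencies_near_one_half(self, small_population):
        # BC1 segregates 1:1 at every locus; allow 3 binomial SD
        n = small_population.n_individuals
        freq_ab = small_population.genotypes.mean(axis=0)
        tol = 3 * np.sqrt(0.25 / n)
        assert np.all(np.abs(freq_ab - 0.5) < tol + 0.02)

    def test_zero_effect_phenotype_uncorrelated_with_markers(self):
        design = simulate.CrossDesign(
            n_families=7, chromosomes={"chr1": 50.0}, qtl=[], seed=11
        )
        pop = simulate.simulate_bc1(design)
        r = np.array(
            [
                np.corrcoef(pop.genotypes[:, j], pop.phenotypes)[0, 1]
                for j in range(pop.genotypes.shape[1])
            ]
        )
        assert np.max(np.abs(r)) < 4 / np.sqrt(pop.n_individuals)

    def test_dominant_effect_limit_separates_phenotypes(self):
        design = simulate.CrossDesign(
            chromosomes={"chr1": 20.0},
            qtl=[("chr1", 10.0, 0.5)],  # 10 SD of the 0.05 noise
            seed=2,
        )
        pop = simulate.simulate_bc1(design)
        carrier = pop.qtl_genotypes[:, 0] == 1
        assert pop.phenotypes[carrier].min() > pop.phenotypes[~carrier].max()

    def test_recombination_decays_with_distance(self):
        design = simulate.CrossDesign(
            n_families=7, chromosomes={"chr1": 50.0}, marker_spacing_cm=1.0, seed=5
        )
        pop = simulate.simulate_bc1(design)
        g = pop.genotypes
        r_adjacent = np.mean(g[:, :-1] != g[:, 1:])
        r_far = np.mean(g[:, 0:1] != g[:, 40:41])
        assert r_adjacent == pytest.approx(simulate.haldane_r(1.0), abs=0.004)
        assert r_far > 0.25

    def test_reproducible_under_fixed_seed(self):
        a = simulate.simulate_bc1(simulate.CrossDesign(chromosomes={"chr1": 10.0}, seed=4))
        b = simulate.simulate_bc1(simulate.CrossDesign(chromosomes={"chr1": 10.0}, seed=4))
        assert np.array_equal(a.genotypes, b.genotypes)
        assert a.phenotypes == pytest.approx(b.phenotypes)


class TestBuildPools:
    def test_exact_decile_per_family(self):
        design = simulate.CrossDesign(
            n_families=5, family_size_range=(100, 100),
            chromosomes={"chr1": 10.0}, seed=1,
        )
        pop = simulate.simulate_bc1(design)
        low, high = simulate.build_pools(pop, 0.10)
        assert low.size == high.size == 50  # 10 per family x 5 families
        assert np.intersect1d(low, high).size == 0

    def test_half_fraction_partitions_each_family(self):
        design = simulate.CrossDesign(
            n_families=2, family_size_range=(40, 40),
            chromosomes={"chr1": 5.0}, seed=6,
        )
        pop = simulate.simulate_bc1(design)
        low, high = simulate.build_pools(pop, 0.5)
        assert np.intersect1d(low, high).size == 0
        assert low.size + high.size == pop.n_individuals

    def test_tied_phenotypes_fall_back_to_index_order(self):
        design = simulate.CrossDesign(
            n_families=1, family_size_range=(10, 10),
            chromosomes={"chr1": 2.0}, phenotype_noise_sd=1e-12, seed=0,
        )
        pop = simulate.simulate_bc1(design)
        pop.phenotypes[:] = 0.3  # force exact ties
        low, high = simulate.build_pools(pop, 0.2)
        assert low.tolist() == [0, 1]
        assert high.tolist() == [8, 9]

    def test_extremes_selected_within_each_family(self):
        pop = simulate.simulate_bc1(simulate.CrossDesign(seed=9))
        low, high = simulate.build_pools(pop, 0.1)
        for fam in range(7):
            fam_low = pop.phenotypes[low[pop.family_id[low] == fam]]
            fam_high = pop.phenotypes[high[pop.family_id[high] == fam]]
            others = pop.phenotypes[
                np.setdiff1d(np.flatnonzero(pop.family_id == fam), np.concatenate([low, high]))
            ]
            assert fam_low.max() <= others.min()
            assert fam_high.min() >= others.max()


class TestPooledDepths:
    def _two_group_population(self, n_markers=400, pool=100):
        genotypes = np.concatenate(
            [np.zeros((pool, n_markers), np.int8), np.ones((pool, n_markers), np.int8)]
        )
        markers = pd.DataFrame(
            {
                "marker_id": [f"m{i}" for i in range(n_markers)],
                "chrom": "chr1",
                "pos_cm": np.arange(n_markers, dtype=float),
                "pos": np.arange(1, n_markers + 1),
            }
        )
        return simulate.SimulatedPopulation(
            genotypes=genotypes, markers=markers,
            phenotypes=np.r_[np.zeros(pool), np.ones(pool)],
            family_id=np.zeros(2 * pool, int),
            qtl_genotypes=np.empty((2 * pool, 0)), truth=[],
        )

    def test_pure_aa_pool_emits_no_ab_reads_without_error(self):
        pop = self._two_group_population()
        depths = simulate.pooled_depths(
            pop, np.arange(100), np.arange(100, 200), error_rate=0.0, seed=0
        )
        assert (depths["Mab"] == 0).all()

    def test_unlinked_marker_is_symmetric_between_pools(self):
        rng = np.random.default_rng(12)
        n_markers, pool = 600, 100
        genotypes = rng.integers(0, 2, size=(2 * pool, n_markers)).astype(np.int8)
        pop = self._two_group_population(n_markers, pool)
        pop.genotypes[:] = genotypes
        depths = simulate.pooled_depths(
            pop, np.arange(pool), np.arange(pool, 2 * pool), seed=1
        )
        share = depths["Maa"] / (depths["Maa"] + depths["Paa"])
        assert share.mean() == pytest.approx(0.5, abs=0.01)

    def test_fully_linked_marker_delta_approaches_two_thirds(self):
        pop = self._two_group_population(n_markers=2000)
        depths = simulate.pooled_depths(
            pop, np.arange(100), np.arange(100, 200), error_rate=0.0, seed=3
        )
        _, _, delta = bsa_scan.snp_index(
            depths["Maa"], depths["Mab"], depths["Paa"], depths["Pab"]
        )
        assert np.nanmean(delta) == pytest.approx(2 / 3, abs=0.005)

    def test_dosage_convention_matches_allele_in_expectation(self):
        pop = self._two_group_population(n_markers=2000)
        kwargs = dict(low_ids=np.arange(100), high_ids=np.arange(100, 200), seed=5)
        allele = simulate.pooled_depths(pop, convention="allele", **kwargs)
        dosage = simulate.pooled_depths(pop, convention="dosage", **kwargs)
        assert allele["Paa"].mean() == pytest.approx(dosage["Paa"].mean(), rel=0.02)

    def test_overlapping_pools_rejected(self):
        pop = self._two_group_population(n_markers=10)
        with pytest.raises(ValueError, match="overlap"):
            simulate.pooled_depths(pop, np.arange(50), np.arange(40, 90))


class TestDegAndExpressionGenerators:
    def test_two_genes_give_exactly_one_interval(self):
        from poolscan.clusters import adjacent_intervals

        positions = simulate.simulate_deg_positions(2, genome_size=10**6, seed=0)
        assert len(adjacent_intervals(positions)) == 1

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate.simulate_deg_positions(100, genome_size=50, min_gap=1)

    def test_fully_clustered_positions_sit_in_tight_runs(self):
        positions = simulate.simulate_deg_positions(
            100, genome_size=10**8, mode="clustered",
            clustered_fraction=1.0, within_run_gap=1, seed=1,
        )
        from poolscan.clusters import adjacent_intervals

        intervals = adjacent_intervals(positions)["interval"]
        assert (intervals <= 1).mean() > 0.75  # runs of 5 share 4 one-bp gaps

    def test_expression_bundle_shapes_and_invariants(self):
        bundle = simulate.simulate_expression_tables(n_strains=8, n_days=6, seed=2)
        assert len(bundle.strain_expression) == len(bundle.csw) == 8
        assert len(bundle.gland_volume) == len(bundle.temporal_expression) == 6
        assert (bundle.csw >= 0).all()
        assert bundle.gland_volume.is_monotonic_increasing
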