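"""Meiosis, drift, the size schedule, and historical-population behaviour."""
import numpy as np
import pytest

from matesim import (ConfigurationError, GenomeMap, SizeSchedule,
                     build_genome_map, iterate_historical, make_gametes,
                     mean_r2, segregating_loci, simulate_historical)
from matesim.popsim_historical import HaplotypePopulation


def _constant_schedule(n, gens):
    return SizeSchedule(((0, n), (gens, n))) if gens else SizeSchedule(((0, n),))


class TestMeiosis:
    def test_homozygous_parent_transmits_exactly(self, rng):
        hap = np.tile(rng.integers(0, 2, size=(1, 1, 30), dtype=np.uint8), (5, 2, 1))
        gam = make_gametes(hap, np.linspace(1, 100, 30), 100.0, rng)
        assert np.array_equal(gam, hap[:, 0, :])

    def test_tiny_map_no_mutation_copies_a_strand(self, rng):
        # with ~0 map length the crossover count is ~always 0
        hap = rng.integers(0, 2, size=(200, 2, 10), dtype=np.uint8)
        gam = make_gametes(hap, np.linspace(1e-9, 1e-6, 10), 1e-6, rng)
        match0 = (gam == hap[:, 0, :]).all(axis=1)
        match1 = (gam == hap[:, 1, :]).all(axis=1)
        assert np.all(match0 | match1)

    def test_haldane_recombination_fraction_at_10cM(self):
        # expected c = (1 - exp(-0.2)) / 2 ~= 0.0906 under Haldane
        rng = np.random.default_rng(42)
        n = 100_000
        parent = np.zeros((n, 2, 2), dtype=np.uint8)
        parent[:, 1, :] = 1  # strands fully informative at both loci
        gam = make_gametes(parent, np.array([10.0, 20.0]), 100.0, rng)
        recomb = (gam[:, 0] != gam[:, 1]).mean()
        expected = 0.5 * (1 - np.exp(-0.2))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(recomb - expected) < 3 * se

    def test_mutation_rate_realized(self):
        rng = np.random.default_rng(9)
        hap = np.zeros((2000, 2, 100), dtype=np.uint8)
        gam = make_gametes(hap, np.linspace(1, 100, 100), 100.0, rng,
                           mutation_rate=1e-3)
        rate = gam.mean()
        assert abs(rate - 1e-3) < 3 * np.sqrt(1e-3 / gam.size)


class TestSizeSchedule:
    def test_linear_interpolation_even_rounding(self):
        sched = SizeSchedule(((0, 100), (10, 1000), (20, 400)))
        sizes = sched.sizes()
        assert sizes[0] == 100 and sizes[10] == 1000 and sizes[20] == 400
        assert np.all(sizes % 2 == 0)
        assert sizes[5] == 550  # midpoint of the growth leg

    def test_default_full_scale_anchors(self):
        sizes = SizeSchedule.default().sizes()
        assert (sizes[0], sizes[1000], sizes[2020]) == (1000, 10000, 4000)

    def test_scaled_default_preserves_shape(self):
        sizes = SizeSchedule.default(scale=0.1).sizes()
        assert (sizes[0], sizes[100], sizes[202]) == (100, 1000, 400)

    def test_invalid_anchors(self):
        with pytest.raises(ConfigurationError):
            SizeSchedule(((0, 100), (0, 50)))
        with pytest.raises(ConfigurationError):
            SizeSchedule(((0, 1),))


class TestHistoricalSimulation:
    def test_zero_generations_returns_founders(self, small_map, rng):
        pop = simulate_historical(small_map, _constant_schedule(100, 0),
                                  mutation_rate=0.0, rng=rng)
        assert pop.n == 100 and pop.generation == 0
        assert abs(pop.allele_frequencies().mean() - 0.5) < 0.05

    def test_census_follows_schedule(self, small_map, rng):
        sched = SizeSchedule(((0, 40), (4, 80), (8, 20)))
        sizes = [pop.n for pop in
                 iterate_historical(small_map, sched, 0.0, rng)]
        assert sizes == sched.sizes().tolist()

    def test_final_sex_split_honoured(self, small_map, rng):
        pop = simulate_historical(small_map, _constant_schedule(60, 3), 0.0,
                                  rng, final_sex_split=(10, 50))
        assert pop.is_male.sum() == 10 and (~pop.is_male).sum() == 50

    def test_bit_reproducible_for_fixed_seed(self, small_map):
        pops = [simulate_historical(small_map, _constant_schedule(30, 10), 2.5e-5,
                                    np.random.default_rng(5)) for _ in range(2)]
        assert np.array_equal(pops[0].haplotypes, pops[1].haplotypes)
        assert np.array_equal(pops[0].is_male, pops[1].is_male)

    def test_wright_fisher_heterozygosity_decay(self):
        # E[H_t] = H_0 (1 - 1/2N)^t; N=50, t=100, H_0=0.5 -> ~0.183
        gmap = build_genome_map(20, 1, 100.0, np.random.default_rng(0))
        n_rep, N, t = 200, 50, 100
        het = []
        for rep in range(n_rep):
            pop = simulate_historical(gmap, _constant_schedule(N, t), 0.0,
                                      np.random.default_rng(1000 + rep))
            p = pop.allele_frequencies()
            het.append(np.mean(2 * p * (1 - p)))
        het = np.array(het)
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        se = het.std(ddof=1) / np.sqrt(n_rep)
        assert abs(het.mean() - expected) < 3 * se

    def test_drift_is_directionless_and_fixation_balanced(self):
        gmap = build_genome_map(40, 1, 100.0, np.random.default_rng(1))
        freqs = []
        fixed_high = fixed_total = 0
        for rep in range(50):
            pop = simulate_historical(gmap, _constant_schedule(20, 60), 0.0,
                                      np.random.default_rng(2000 + rep))
            p = pop.allele_frequencies()
            freqs.append(p.mean())
            fixed = (p == 0) | (p == 1)
            fixed_total += fixed.sum()
            fixed_high += (p == 1).sum()
        freqs = np.array(freqs)
        se = freqs.std(ddof=1) / np.sqrt(freqs.size)
        assert abs(freqs.mean() - 0.5) < 3 * se
        # starting at p0 = 0.5, fixation should hit either allele equally
        frac = fixed_high / fixed_total
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / fixed_total) + 0.02

    def test_bottleneck_raises_adjacent_ld(self):
        gmap = build_genome_map(60, 1, 100.0, np.random.default_rng(2))
        sched = SizeSchedule(((0, 400), (40, 400), (80, 80)))
        before, after = [], []
        for rep in range(4):
            rng = np.random.default_rng(3000 + rep)
            for pop in iterate_historical(gmap, sched, 0.0, rng):
                if pop.generation == 40:
                    before.append(mean_r2(pop, gmap, max_dist=3.0))
            after.append(mean_r2(pop, gmap, max_dist=3.0))
        assert np.mean(after) > np.mean(before)


class TestSegregatingLoci:
    def test_toy_population_hand_count(self):
        # 2 diploids, 3 loci: locus0 het, locus1 fixed at 0, locus2 fixed at 1
        haps = np.array([[[1, 0, 1], [0, 0, 1]],
                         [[1, 0, 1], [0, 0, 1]]], dtype=np.uint8)
        pop = HaplotypePopulation(haps, np.array([True, False]))
        assert segregating_loci(pop).tolist() == [0]

    def test_all_heterozygote_population_keeps_everything(self):
        haps = np.stack([np.stack([np.ones(5), np.zeros(5)])] * 4).astype(np.uint8)
        pop = HaplotypePopulation(haps, np.array([True, False, True, False]))
        assert segregating_loci(pop).size == 5


def test_plink_dump_round_trips_alleles(tmp_path, small_map, rng):
    from matesim.popsim_historical import write_plink
    pop = simulate_historical(small_map, _constant_schedule(10, 2), 0.0, rng)
    write_plink(pop, small_map, tmp_path / "dump")
    ped = (tmp_path / "dump.ped").read_text().splitlines()
    assert len(ped) == 10
    first = ped[0].split()
    assert len(first) == 6 + 2 * small_map.n_loci
    alleles = np.array(first[6:], dtype=int).reshape(small_map.n_loci, 2).T
    assert np.array_equal(alleles - 1, pop.haplotypes[0])
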