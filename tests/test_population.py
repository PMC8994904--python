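import numpy as np
import pytest

from qgvar.genome import GeneMap, build_gene_map, haldane
from qgvar.ld import TwoLocusDist, founder_delta
from qgvar.population import (
    FounderSpec,
    Population,
    advance_random_mating,
    advance_selfing,
    found_ld_population,
    meiosis,
    sample_le_population,
    sample_parental_freqs,
)


def _two_gene_map(r: float) -> GeneMap:
    """Map with two genes at the distance giving Haldane fraction r."""
    d = -50.0 * np.log(1.0 - 2.0 * r) if r < 0.5 else None
    if d is None:
        return GeneMap(chrom_lengths=(10.0, 10.0), positions=((0.0,), (0.0,)))
    return GeneMap(chrom_lengths=(d + 1.0,), positions=((0.0, d),))


class TestLEPopulation:
    def test_fixation(self, rng):
        gm = build_gene_map(1, 50.0, 4)
        pop = sample_le_population(np.ones(4), 20, gm, rng)
        assert np.all(pop.haplotypes == 1)

    def test_frequencies_and_le(self, rng):
        gm = build_gene_map(1, 50.0, 4)
        N = 50000
        pop = sample_le_population(np.full(4, 0.5), N, gm, rng)
        se = np.sqrt(0.25 / (2 * N))
        assert np.all(np.abs(pop.allele_freqs() - 0.5) < 3 * se)
        # empirical gametic Delta ~ 0 by construction
        se_d = np.sqrt(0.25 * 0.25 / (2 * N))
        for j in range(1, 4):
            assert abs(pop.empirical_delta(0, j)) < 3 * se_d + 1e-6

    def test_invalid_inputs(self, rng):
        gm = build_gene_map(1, 50.0, 4)
        with pytest.raises(ValueError):
            sample_le_population(np.full(4, 0.5), 0, gm, rng)
        with pytest.raises(ValueError):
            sample_le_population(np.full(4, 1.5), 5, gm, rng)


class TestMeiosis:
    def test_homozygote_gamete(self, rng):
        gm = build_gene_map(1, 50.0, 6)
        hap = np.tile(rng.integers(0, 2, 6).astype(np.int8), (2, 1))
        g = meiosis(hap, gm, rng)
        assert np.array_equal(g, hap[0])

    @pytest.mark.parametrize("r", [0.05, 0.2, 0.5])
    def test_recombinant_frequency(self, r, rng):
        gm = _two_gene_map(r)
        n = 200000
        hap = np.zeros((n, 2, 2), dtype=np.int8)
        hap[:, 0, :] = 1  # AB / ab double heterozygotes
        pop = Population(haplotypes=hap, gene_map=gm)
        from qgvar.population import _gametes

        g = _gametes(pop.haplotypes, gm.adjacent_recomb(), rng)
        rec = np.mean(g[:, 0] != g[:, 1])
        se = np.sqrt(r * (1 - r) / n)
        assert abs(rec - r) < 3 * se + 1e-9


class TestFounder:
    def test_parametric_delta_zero_when_parents_equal(self, rng):
        gm = _two_gene_map(0.1)
        p = np.array([0.4, 0.7])
        pop = found_ld_population(FounderSpec(N=2000), gm, rng, p1=p, p2=p)
        assert founder_delta(p[0], p[0], p[1], p[1], 0.1) == 0.0

    def test_empirical_delta_matches_formula(self, rng):
        r = 0.1
        gm = _two_gene_map(r)
        N = 50000
        p1 = np.array([0.9, 0.9])
        p2 = np.array([0.1, 0.1])
        pop = found_ld_population(FounderSpec(N=N), gm, rng, p1=p1, p2=p2)
        expected = founder_delta(0.9, 0.1, 0.9, 0.1, r)
        se = np.sqrt(0.25**2 / (2 * N))  # conservative haplotype-sampling SE
        assert abs(pop.empirical_delta(0, 1) - expected) < 4 * se

    def test_tight_linkage_example(self):
        # r ~ 0: Delta = 0.25 * 0.8 * 0.8 = 0.16
        assert founder_delta(0.9, 0.1, 0.9, 0.1, 0.0) == pytest.approx(0.16)

    def test_parental_vector_length_checked(self, rng):
        gm = _two_gene_map(0.1)
        with pytest.raises(ValueError):
            found_ld_population(
                FounderSpec(N=10), gm, rng,
                p1=np.array([0.5]), p2=np.array([0.5, 0.5]),
            )

    def test_parental_freq_sampling(self, rng):
        spec = FounderSpec(mean_freq=0.5, ld_level="high")
        p1, p2 = sample_parental_freqs(spec, 2000, rng)
        assert np.all(p1 >= p2 - 1e-12)  # coupling phase
        mean = (p1 + p2) / 2
        assert abs(mean.mean() - 0.5) < 0.02

    def test_ld_level_ordering(self, rng):
        # founder |Delta| increases with the configured LD level
        gm = _two_gene_map(0.05)
        mags = {}
        for level in ("low", "intermediate", "high"):
            spec = FounderSpec(mean_freq=0.5, ld_level=level)
            deltas = []
            r2 = np.random.default_rng(7)
            for _ in range(200):
                p1, p2 = sample_parental_freqs(spec, 2, r2)
                deltas.append(abs(founder_delta(p1[0], p2[0], p1[1], p2[1], 0.05)))
            mags[level] = np.mean(deltas)
        assert mags["low"] < mags["intermediate"] < mags["high"]


class TestGenerationAdvance:
    def test_zero_generations_identity(self, rng):
        gm = _two_gene_map(0.2)
        pop = found_ld_population(FounderSpec(N=100), gm, rng)
        same = advance_random_mating(pop, 0, rng)
        assert np.array_equal(same.haplotypes, pop.haplotypes)

    def test_random_mating_halves_unlinked_delta(self, rng):
        gm = _two_gene_map(0.5)
        N = 50000
        pop = found_ld_population(
            FounderSpec(N=N), gm, rng,
            p1=np.array([0.9, 0.9]), p2=np.array([0.1, 0.1]),
        )
        d0 = pop.empirical_delta(0, 1)
        pop1 = advance_random_mating(pop, 1, rng)
        se = np.sqrt(0.25**2 / (2 * N))
        assert abs(pop1.empirical_delta(0, 1) - d0 / 2) < 4 * se

    def test_selfing_F_and_heterozygosity(self, rng):
        gm = build_gene_map(1, 50.0, 3)
        N = 100000
        pop = sample_le_population(np.full(3, 0.5), N, gm, rng)
        pop10 = advance_selfing(pop, 10, rng)
        assert pop10.F == pytest.approx(1023 / 1024)
        het = np.mean(pop10.dosage() == 1, axis=0)
        expected = 2 * 0.5 * 0.5 * 0.5**10
        se = np.sqrt(expected / N)
        assert np.all(np.abs(het - expected) < 4 * se + 1e-4)

    def test_allele_frequency_conservation(self, rng):
        gm = build_gene_map(2, 80.0, 10)
        pop = found_ld_population(FounderSpec(N=20000), gm, rng)
        f0 = pop.allele_freqs()
        for advance in (advance_random_mating, advance_selfing):
            diffs = advance(pop, 3, rng).allele_freqs() - f0
            se = np.sqrt(f0 * (1 - f0) / (2 * 20000))
            # drift accumulates over 3 generations; allow 4 per-generation SEs
            assert np.all(np.abs(diffs) < 4 * np.sqrt(3) * se + 1e-3)

    def test_selfing_two_locus_matches_recursion(self, rng):
        r, n, N = 0.2, 3, 100000
        gm = _two_gene_map(r)
        pop = found_ld_population(
            FounderSpec(N=N), gm, rng,
            p1=np.array([0.8, 0.7]), p2=np.array([0.2, 0.3]),
        )
        d0 = founder_delta(0.8, 0.2, 0.7, 0.3, r)
        dist = TwoLocusDist.from_margins(0.5, 0.5, d0).self_generations(r, n)
        popn = advance_selfing(pop, n, rng)
        dos = popn.dosage()
        f = dist.f9()
        for i in range(3):
            for j in range(3):
                emp = np.mean((dos[:, 0] == i) & (dos[:, 1] == j))
                se = np.sqrt(f[i, j] * (1 - f[i, j]) / N)
                assert abs(emp - f[i, j]) < 4 * se + 1e-4


class TestFounderDensityLD:
    def test_higher_density_gives_higher_founder_r2(self, rng):
        # same parental dispersion: 1 gene/cM shows more LD than 1 gene/5 cM
        from qgvar.ld import ld_decay_summary

        spec = FounderSpec(mean_freq=0.5, ld_level="high")
        p1, p2 = sample_parental_freqs(spec, 40, rng)
        dense = build_gene_map(1, 39.0, 40)
        sparse = build_gene_map(1, 195.0, 40)
        r2 = {}
        for name, gm in (("dense", dense), ("sparse", sparse)):
            df, _ = ld_decay_summary(gm, p1, p2, "random", 1)
            r2[name] = np.nanmean(df["r2_0"])
        assert r2["dense"] > r2["sparse"]
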