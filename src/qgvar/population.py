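"""Individual-based forward simulation.

Individuals carry two haplotypes over the gene map (0/1 allele indicators;
1 is the trait-increasing allele).  Founder populations in LD arise from
crossing two linkage-equilibrium parental populations followed by one round
of random mating, which gives a Hardy-Weinberg population of unrelated
individuals with gametic LD Delta = [(1-2r)/4](p_a1-p_a2)(p_b1-p_b2) per
gene pair.  Generations then advance by random mating or selfing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome import GeneMap

__all__ = [
    "Population",
    "FounderSpec",
    "LD_LEVEL_DISPERSION",
    "sample_parental_freqs",
    "sample_le_population",
    "found_ld_population",
    "meiosis",
    "advance_random_mating",
    "advance_selfing",
    "genotypes_to_csv",
    "genotypes_to_vcf",
]

#: dispersion of per-locus parental frequencies around the target mean;
#: founder Delta scales with (p_a1 - p_a2)(p_b1 - p_b2), so a wide dispersion
#: of the two parental vectors yields high LD
LD_LEVEL_DISPERSION = {"high": 0.45, "intermediate": 0.25, "low": 0.1}


@dataclass
class Population:
    """A cohort of individuals over a gene map.

    haplotypes: (N, 2, L) array of 0/1 allele indicators;
    F: expected inbreeding coefficient (pedigree expectation, not realized);
    parental_freqs: per-locus frequency vectors of the two LE parental
    populations when the population descends from a founder cross.
    """

    haplotypes: np.ndarray
    gene_map: GeneMap
    F: float = 0.0
    generation: int = 0
    parental_freqs: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (N, 2, L)")
        if self.haplotypes.shape[2] != self.gene_map.n_genes:
            raise ValueError("haplotype length must equal the gene count")

    @property
    def size(self) -> int:
        return self.haplotypes.shape[0]

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def dosage(self) -> np.ndarray:
        """(N, L) count of the trait-increasing allele."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    def empirical_delta(self, i: int, j: int) -> float:
        """Gametic LD between two genes from the haplotype sample."""
        x = self.haplotypes[:, :, i].ravel().astype(float)
        y = self.haplotypes[:, :, j].ravel().astype(float)
        return float(np.mean(x * y) - x.mean() * y.mean())


@dataclass(frozen=True)
class FounderSpec:
    """Founder construction: mean allele frequency and LD level.

    ld_level selects the dispersion of the per-locus parental frequencies
    (see LD_LEVEL_DISPERSION); a custom dispersion may be given instead.
    """

    mean_freq: float = 0.5
    ld_level: str = "high"
    dispersion: float | None = None
    N: int = 5000

    def __post_init__(self) -> None:
        if not 0.0 < self.mean_freq < 1.0:
            raise ValueError("mean_freq must be in (0, 1)")
        if self.N < 2:
            raise ValueError("population size must be at least 2")
        if self.dispersion is None and self.ld_level not in LD_LEVEL_DISPERSION:
            raise ValueError(f"unknown LD level {self.ld_level!r}")

    @property
    def delta_dispersion(self) -> float:
        return (
            self.dispersion
            if self.dispersion is not None
            else LD_LEVEL_DISPERSION[self.ld_level]
        )


def sample_parental_freqs(
    spec: FounderSpec, n_loci: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus frequencies of the two LE parental populations.

    Parent 1 draws uniformly on [mean, mean + dispersion] and parent 2 on
    [mean - dispersion, mean], clipped to (0.02, 0.98) to keep every locus
    segregating.  Parent 1 systematically carries the higher frequency of
    the trait-increasing allele at every locus, so the founder cross is in
    coupling phase and the founder LD is predominantly positive; the
    dispersion controls the LD magnitude through (p_a1 - p_a2)(p_b1 - p_b2).
    """
    lo = spec.mean_freq - spec.delta_dispersion
    hi = spec.mean_freq + spec.delta_dispersion
    p1 = np.clip(rng.uniform(spec.mean_freq, hi, size=n_loci), 0.02, 0.98)
    p2 = np.clip(rng.uniform(lo, spec.mean_freq, size=n_loci), 0.02, 0.98)
    return p1, p2


def sample_le_population(
    freqs: np.ndarray, N: int, gene_map: GeneMap, rng: np.random.Generator
) -> Population:
    """HWE population in linkage equilibrium at the given per-locus freqs."""
    if N < 1:
        raise ValueError("population size must be positive")
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    hap = (rng.random((N, 2, gene_map.n_genes)) < freqs).astype(np.int8)
    return Population(haplotypes=hap, gene_map=gene_map)


def _gametes(
    parent_haps: np.ndarray, rec_adj: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete per row of ``parent_haps`` (n, 2, L).

    Recombination is Markovian along the flat gene order: a crossover occurs
    between adjacent genes with the Haldane fraction of their spacing, and
    with probability 0.5 across chromosome junctions, so any two genes
    recombine with the fraction of their map distance.
    """
    n, _, L = parent_haps.shape
    thresholds = np.concatenate([[0.5], rec_adj])  # random strand start
    cross = rng.random((n, L)) < thresholds
    source = np.cumsum(cross, axis=1) & 1
    return np.take_along_axis(parent_haps, source[:, None, :], axis=1)[:, 0, :]


def meiosis(
    individual_haplotypes: np.ndarray, gene_map: GeneMap, rng: np.random.Generator
) -> np.ndarray:
    """A single gamete (length L) from one individual's (2, L) haplotypes."""
    return _gametes(
        individual_haplotypes[None, :, :], gene_map.adjacent_recomb(), rng
    )[0]


def found_ld_population(
    spec: FounderSpec,
    gene_map: GeneMap,
    rng: np.random.Generator,
    p1: np.ndarray | None = None,
    p2: np.ndarray | None = None,
) -> Population:
    """Founder population in LD: cross of two LE populations + one round of
    random mating (Hardy-Weinberg, unrelated individuals)."""
    L = gene_map.n_genes
    if p1 is None or p2 is None:
        p1, p2 = sample_parental_freqs(spec, L, rng)
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if p1.shape != (L,) or p2.shape != (L,):
        raise ValueError("parental frequency vectors must match the gene count")
    N = spec.N
    # F1: one gamete from each LE parental population (LE gametes are
    # independent Bernoulli draws at the parental frequencies)
    f1 = np.empty((N, 2, L), dtype=np.int8)
    f1[:, 0, :] = rng.random((N, L)) < p1
    f1[:, 1, :] = rng.random((N, L)) < p2
    rec = gene_map.adjacent_recomb()
    mothers = rng.integers(N, size=N)
    fathers = _distinct_partners(mothers, N, rng)
    hap = np.empty((N, 2, L), dtype=np.int8)
    hap[:, 0, :] = _gametes(f1[mothers], rec, rng)
    hap[:, 1, :] = _gametes(f1[fathers], rec, rng)
    return Population(
        haplotypes=hap,
        gene_map=gene_map,
        F=0.0,
        generation=0,
        parental_freqs=(p1, p2),
    )


def _distinct_partners(
    mothers: np.ndarray, N: int, rng: np.random.Generator
) -> np.ndarray:
    fathers = rng.integers(N, size=mothers.size)
    clash = fathers == mothers
    while np.any(clash):
        fathers[clash] = rng.integers(N, size=int(clash.sum()))
        clash = fathers == mothers
    return fathers


def advance_random_mating(
    pop: Population, n: int, rng: np.random.Generator
) -> Population:
    """n generations of random crosses between distinct parents, constant N."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    hap = pop.haplotypes
    rec = pop.gene_map.adjacent_recomb()
    N = pop.size
    for _ in range(n):
        mothers = rng.integers(N, size=N)
        fathers = _distinct_partners(mothers, N, rng)
        nxt = np.empty_like(hap)
        nxt[:, 0, :] = _gametes(hap[mothers], rec, rng)
        nxt[:, 1, :] = _gametes(hap[fathers], rec, rng)
        hap = nxt
    return replace(
        pop, haplotypes=hap, F=0.0, generation=pop.generation + n
    )


def advance_selfing(pop: Population, n: int, rng: np.random.Generator) -> Population:
    """n generations of selfing: one offspring per parent (two independent
    meioses of the same individual); expected F goes from F to 1-(1-F)/2^n."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    hap = pop.haplotypes
    rec = pop.gene_map.adjacent_recomb()
    F = pop.F
    for _ in range(n):
        nxt = np.empty_like(hap)
        nxt[:, 0, :] = _gametes(hap, rec, rng)
        nxt[:, 1, :] = _gametes(hap, rec, rng)
        hap = nxt
        F = (1.0 + F) / 2.0
    return replace(pop, haplotypes=hap, F=F, generation=pop.generation + n)


def genotypes_to_csv(pop: Population, path: str) -> None:
    """Genotype matrix (individuals x genes, dosage 0/1/2) as CSV."""
    df = pd.DataFrame(
        pop.dosage(),
        columns=[f"gene_{i}" for i in range(pop.gene_map.n_genes)],
    )
    df.index.name = "individual"
    df.to_csv(path)


def genotypes_to_vcf(pop: Population, path: str) -> None:
    """Minimal VCF with genes as biallelic variants at cM-scaled positions."""
    chrom = pop.gene_map.chrom_of
    pos = np.round(pop.gene_map.pos_flat * 1e4).astype(int) + 1
    hap = pop.haplotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{i}" for i in range(pop.size))
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + samples + "\n"
        )
        for g in range(pop.gene_map.n_genes):
            gts = "\t".join(
                f"{hap[i, 0, g]}|{hap[i, 1, g]}" for i in range(pop.size)
            )
            fh.write(
                f"chr{chrom[g] + 1}\t{pos[g]}\tgene_{g}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )
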