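"""Genome layout and nonepistatic trait architecture.

A simulated genome is a set of chromosomes carrying biallelic genes at known
map positions (cM).  The trait side assigns each gene a homozygote
half-difference ``a`` and a dominance deviation ``d = a * (d/a)``, rescaled so
that the two extreme full homozygotes hit user-specified genotypic values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GeneMap",
    "GeneEffects",
    "EpistasisSettings",
    "TraitSpec",
    "build_gene_map",
    "haldane",
    "recombination_fraction",
    "assign_gene_effects",
    "sample_phenotypes",
    "error_variance",
]


def haldane(d: float | np.ndarray) -> float | np.ndarray:
    """Map distance (cM) to recombination fraction, Haldane (no interference).

    r = (1 - exp(-2d/100)) / 2.  ``d = inf`` (different chromosomes) gives
    exactly 0.5.  Negative distances are invalid.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    r = np.where(np.isinf(d), 0.5, r)
    return float(r) if r.ndim == 0 else r


# alias matching the operation name used elsewhere
recombination_fraction = haldane


@dataclass(frozen=True)
class GeneMap:
    """Gene positions (cM) on one or more chromosomes."""

    chrom_lengths: tuple[float, ...]
    positions: tuple[tuple[float, ...], ...]  # per chromosome, increasing

    def __post_init__(self) -> None:
        if len(self.chrom_lengths) != len(self.positions):
            raise ValueError("one position vector per chromosome required")
        for length, pos in zip(self.chrom_lengths, self.positions):
            if length <= 0:
                raise ValueError("chromosome length must be positive")
            arr = np.asarray(pos, dtype=float)
            if arr.size and (np.any(np.diff(arr) <= 0)):
                raise ValueError("positions must be strictly increasing")
            if arr.size and (arr[0] < 0 or arr[-1] > length):
                raise ValueError("positions must lie within [0, length]")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths)

    @property
    def n_genes(self) -> int:
        return sum(len(p) for p in self.positions)

    @property
    def chrom_of(self) -> np.ndarray:
        """Chromosome index of each gene, flat order."""
        return np.concatenate(
            [np.full(len(p), c, dtype=int) for c, p in enumerate(self.positions)]
        )

    @property
    def pos_flat(self) -> np.ndarray:
        return np.concatenate([np.asarray(p, float) for p in self.positions])

    def distance(self, i: int, j: int) -> float:
        """Map distance between genes (flat indices); inf across chromosomes."""
        chrom = self.chrom_of
        if chrom[i] != chrom[j]:
            return float("inf")
        pos = self.pos_flat
        return abs(pos[i] - pos[j])

    def recomb_between(self, i: int, j: int) -> float:
        return haldane(self.distance(i, j))

    def adjacent_recomb(self) -> np.ndarray:
        """Recombination fraction between consecutive genes in flat order.

        Length ``n_genes - 1``; the junction between two chromosomes is 0.5
        (independent assortment).
        """
        d = np.diff(self.pos_flat)
        boundary = np.diff(self.chrom_of) != 0
        d = np.where(boundary, np.inf, d)
        return haldane(d)


def build_gene_map(
    n_chrom: int, chrom_len: float, genes_per_chrom: int
) -> GeneMap:
    """Equally spaced genes spanning each chromosome (first gene at 0 cM)."""
    if n_chrom < 1 or genes_per_chrom < 2:
        raise ValueError("need at least one chromosome and two genes per chromosome")
    if chrom_len <= 0:
        raise ValueError("chromosome length must be positive")
    pos = tuple(np.linspace(0.0, chrom_len, genes_per_chrom))
    return GeneMap(
        chrom_lengths=tuple([float(chrom_len)] * n_chrom),
        positions=tuple([pos] * n_chrom),
    )


@dataclass(frozen=True)
class EpistasisSettings:
    """Digenic-epistasis block of a trait specification.

    type: one of the seven concrete types, "admixture", or None (no epistasis);
    pct_interacting: fraction of genes involved in pairwise interactions;
    ratio: V(I)/(V(A)+V(D)) controlling the epistatic-variance magnitude.
    """

    type: str | None = None
    pct_interacting: float = 0.0
    ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_interacting <= 1.0:
            raise ValueError("pct_interacting must be in [0, 1]")
        if self.ratio < 0:
            raise ValueError("ratio must be nonnegative")


@dataclass(frozen=True)
class TraitSpec:
    """Trait scaling: genotypic/phenotypic extremes, dominance, heritability."""

    g_min: float
    g_max: float
    p_min: float
    p_max: float
    mean_dominance: float = 0.6
    h2: float = 0.2
    epistasis: EpistasisSettings = field(default_factory=EpistasisSettings)

    def __post_init__(self) -> None:
        if self.g_max <= self.g_min:
            raise ValueError("g_max must exceed g_min")
        if not (self.p_min <= self.g_min and self.p_max >= self.g_max):
            raise ValueError("phenotypic bounds must enclose genotypic bounds")
        if not 0.0 < self.h2 <= 1.0:
            raise ValueError("broad-sense heritability must be in (0, 1]")


@dataclass(frozen=True)
class GeneEffects:
    """Per-gene additive effect a, dominance deviation d, and midpoint m."""

    a: np.ndarray
    d: np.ndarray
    m: np.ndarray

    @property
    def degree_of_dominance(self) -> np.ndarray:
        return self.d / self.a

    @property
    def n_genes(self) -> int:
        return self.a.size

    def nonepistatic_values(self) -> np.ndarray:
        """(n_genes, 3) genotypic values indexed by dosage 0/1/2: m-a, m+d, m+a."""
        return np.column_stack([self.m - self.a, self.m + self.d, self.m + self.a])


def assign_gene_effects(
    gene_map: GeneMap,
    spec: TraitSpec,
    rng: np.random.Generator,
    *,
    equal_a: bool = False,
    equal_dominance: bool = False,
) -> GeneEffects:
    """Sample per-gene effects and rescale to the configured extremes.

    Per-gene a > 0 is sampled (uniform on [0.5, 1.5], or constant when
    ``equal_a``) and rescaled so that the sum of (m + a) over genes equals
    ``g_max`` and the sum of (m - a) equals ``g_min``.  The degree of
    dominance is uniform on [0, 2 * mean_dominance] with positive sign
    (positive direction of dominance); d = a * degree.
    """
    n = gene_map.n_genes
    raw = np.ones(n) if equal_a else rng.uniform(0.5, 1.5, size=n)
    a = raw * (spec.g_max - spec.g_min) / (2.0 * raw.sum())
    m = np.full(n, (spec.g_max + spec.g_min) / (2.0 * n))
    if equal_dominance:
        dod = np.full(n, spec.mean_dominance)
    else:
        dod = rng.uniform(0.0, 2.0 * spec.mean_dominance, size=n)
    return GeneEffects(a=a, d=a * dod, m=m)


def sample_phenotypes(
    g_values: np.ndarray,
    error_var: float,
    p_min: float,
    p_max: float,
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> np.ndarray:
    """Phenotypes P = G + E with E ~ N(0, sigma2_E).

    Outliers are avoided by resampling the error term of any individual
    whose phenotype falls outside [p_min, p_max].
    """
    g = np.asarray(g_values, dtype=float)
    if error_var < 0:
        raise ValueError("error variance must be nonnegative")
    p = g + rng.normal(0.0, np.sqrt(error_var), size=g.shape)
    for _ in range(max_tries):
        bad = (p < p_min) | (p > p_max)
        if not np.any(bad):
            return p
        p[bad] = g[bad] + rng.normal(0.0, np.sqrt(error_var), size=int(bad.sum()))
    return np.clip(p, p_min, p_max)


def error_variance(genotypic_var: float, h2: float) -> float:
    """Environmental variance implied by a broad-sense heritability.

    sigma2_E = sigma2_G * (1 - H2) / H2.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("broad-sense heritability must be in (0, 1]")
    if genotypic_var < 0:
        raise ValueError("genotypic variance must be nonnegative")
    return genotypic_var * (1.0 - h2) / h2


def gene_map_to_table(gene_map: GeneMap, effects: GeneEffects, path: str) -> None:
    """Write the gene map and effects as a tab-separated table
    (chromosome, position_cM, a, d)."""
    import pandas as pd

    pd.DataFrame(
        {
            "chromosome": gene_map.chrom_of + 1,
            "position_cM": gene_map.pos_flat,
            "a": effects.a,
            "d": effects.d,
        }
    ).to_csv(path, sep="\t", index=False)
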