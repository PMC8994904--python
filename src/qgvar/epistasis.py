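"""Digenic epistasis: the seven classic types and epistatic grid sampling.

Each type is an equality pattern over the nine two-locus genotypic values
G_ij (i, j = dosage of the capital allele), yielding the classic F2
phenotypic ratios (9:7, 15:1, 12:3:1, 9:3:4, 13:3, 9:6:1, 9:3:3:1) when the
two loci segregate independently at frequency 1/2.

Because infinitely many grids satisfy a given pattern, the magnitude of the
epistatic deviations is controlled through the ratio V(I)/(V(A)+V(D)): the
epistatic value of the AABB genotype is sampled as I22 ~ N(0, V(I)) and the
grid construction (a documented stand-in for the original software's
unpublished rule) collapses each equality class onto the frequency-weighted
mean of its nonepistatic values, with the class containing AABB offset so
that its deviation from the nonepistatic value is exactly I22.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction

import numpy as np

from .decomposition import kempthorne_effects
from .ld import TwoLocusDist

__all__ = [
    "EpistasisType",
    "CONCRETE_TYPES",
    "EpistaticGrid",
    "EpistaticPairSpec",
    "epistasis_pattern",
    "f2_class_probabilities",
    "build_epistatic_grid",
    "assign_epistatic_network",
]


class EpistasisType(str, Enum):
    COMPLEMENTARY = "complementary"
    DUPLICATE = "duplicate"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    DOMINANT_AND_RECESSIVE = "dominant_and_recessive"
    DUPLICATE_CUMULATIVE = "duplicate_cumulative"
    NONEPISTATIC_INTERACTION = "nonepistatic_interaction"
    ADMIXTURE = "admixture"
    NONE = "none"


CONCRETE_TYPES: tuple[EpistasisType, ...] = (
    EpistasisType.COMPLEMENTARY,
    EpistasisType.DUPLICATE,
    EpistasisType.DOMINANT,
    EpistasisType.RECESSIVE,
    EpistasisType.DOMINANT_AND_RECESSIVE,
    EpistasisType.DUPLICATE_CUMULATIVE,
    EpistasisType.NONEPISTATIC_INTERACTION,
)

# cells written as (i, j) dosage pairs
_C = lambda *cells: frozenset(cells)  # noqa: E731

_PATTERNS: dict[EpistasisType, tuple[frozenset, ...]] = {
    EpistasisType.COMPLEMENTARY: (
        _C((2, 2), (2, 1), (1, 2), (1, 1)),
        _C((2, 0), (1, 0), (0, 2), (0, 1), (0, 0)),
    ),
    EpistasisType.DUPLICATE: (
        _C((2, 2), (2, 1), (2, 0), (1, 2), (1, 1), (1, 0), (0, 2), (0, 1)),
        _C((0, 0)),
    ),
    EpistasisType.DOMINANT: (
        _C((2, 2), (2, 1), (2, 0), (1, 2), (1, 1), (1, 0)),
        _C((0, 2), (0, 1)),
        _C((0, 0)),
    ),
    EpistasisType.RECESSIVE: (
        _C((2, 2), (2, 1), (1, 2), (1, 1)),
        _C((0, 2), (0, 1)),
        _C((2, 0), (1, 0), (0, 0)),
    ),
    EpistasisType.DOMINANT_AND_RECESSIVE: (
        _C((2, 2), (2, 1), (1, 2), (1, 1), (2, 0), (1, 0), (0, 0)),
        _C((0, 2), (0, 1)),
    ),
    EpistasisType.DUPLICATE_CUMULATIVE: (
        _C((2, 2), (2, 1), (1, 2), (1, 1)),
        _C((2, 0), (1, 0), (0, 2), (0, 1)),
        _C((0, 0)),
    ),
    EpistasisType.NONEPISTATIC_INTERACTION: (
        _C((2, 2), (2, 1), (1, 2), (1, 1)),
        _C((2, 0), (1, 0)),
        _C((0, 2), (0, 1)),
        _C((0, 0)),
    ),
}


def epistasis_pattern(etype: EpistasisType | str) -> tuple[frozenset, ...]:
    """Equality classes of the nine cells for a concrete epistasis type."""
    etype = EpistasisType(etype)
    if etype not in _PATTERNS:
        raise ValueError(
            f"{etype.value!r} is not a concrete type; resolve admixture/none first"
        )
    return _PATTERNS[etype]


def f2_class_probabilities(etype: EpistasisType | str) -> tuple[Fraction, ...]:
    """Exact F2 class probabilities (p = q = 1/2, unlinked, HWE, LE).

    Cell weights are (1, 2, 1)/4 per locus; each class probability is the sum
    over its cells, in exact rational arithmetic (all denominators 16).
    """
    w = (Fraction(1, 4), Fraction(2, 4), Fraction(1, 4))
    probs = tuple(
        sum((w[i] * w[j] for (i, j) in cls), Fraction(0))
        for cls in epistasis_pattern(etype)
    )
    assert sum(probs) == 1
    return probs


@dataclass
class EpistaticGrid:
    """3x3 genotypic values of an interacting pair with its pattern and I22."""

    values: np.ndarray
    etype: EpistasisType
    i22: float
    v_i: float
    pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3, 3):
            raise ValueError("grid must be 3x3")


def build_epistatic_grid(
    nonepistatic: np.ndarray,
    etype: EpistasisType | str,
    ratio: float,
    dist: TwoLocusDist,
    rng: np.random.Generator,
) -> EpistaticGrid:
    """Sample an epistatic grid for one pair with controlled V(I).

    Steps: (1) the pair's nonepistatic V(A) + V(D) is computed at the
    current genotype distribution; (2) V(I) = ratio * (V(A) + V(D));
    (3) I22 ~ N(0, V(I)); (4) each equality class of the type collapses to
    the distribution-weighted mean of its nonepistatic values, except the
    class containing AABB, which is set to the nonepistatic AABB value plus
    I22.  ratio = 0 returns the plain nonepistatic grid.
    """
    etype = EpistasisType(etype)
    nonepi = np.asarray(nonepistatic, dtype=float)
    if nonepi.shape != (3, 3):
        raise ValueError("nonepistatic grid must be 3x3")
    if ratio < 0:
        raise ValueError("ratio must be nonnegative")
    if ratio == 0 or etype is EpistasisType.NONE:
        return EpistaticGrid(values=nonepi.copy(), etype=EpistasisType.NONE,
                             i22=0.0, v_i=0.0)
    es = kempthorne_effects(dist, nonepi)
    comps = es.parametric_components(dist)
    v_ad = comps.variances["A"] + comps.variances["D"]
    v_i = ratio * v_ad
    i22 = float(rng.normal(0.0, np.sqrt(v_i)))
    f = dist.f9()
    grid = np.empty((3, 3))
    for cls in epistasis_pattern(etype):
        cells = sorted(cls)
        idx = tuple(np.array(c) for c in zip(*cells))
        if (2, 2) in cls:
            value = nonepi[2, 2] + i22
        else:
            w = f[idx]
            value = (
                float(np.average(nonepi[idx], weights=w))
                if w.sum() > 0
                else float(nonepi[idx].mean())
            )
        grid[idx] = value
    return EpistaticGrid(values=grid, etype=etype, i22=i22, v_i=v_i)


@dataclass(frozen=True)
class EpistaticPairSpec:
    """One interacting gene pair and its (resolved) epistasis type."""

    gene_i: int
    gene_j: int
    etype: EpistasisType


def assign_epistatic_network(
    n_genes: int,
    pct_interacting: float,
    etype: EpistasisType | str,
    rng: np.random.Generator,
) -> list[EpistaticPairSpec]:
    """Select interacting genes and pair them uniformly at random.

    floor(pct * n_genes) genes are drawn without replacement and paired so
    that every epistatic gene belongs to exactly one pair.  Under admixture
    each pair's type is drawn uniformly among the seven concrete types;
    otherwise all pairs share the given type.  Pairs may span chromosomes.
    """
    etype = EpistasisType(etype)
    if not 0.0 <= pct_interacting <= 1.0:
        raise ValueError("pct_interacting must be in [0, 1]")
    k = int(np.floor(pct_interacting * n_genes + 0.5))
    if k == 0:
        return []
    if k % 2:
        raise ValueError("the number of interacting genes must be even")
    genes = rng.choice(n_genes, size=k, replace=False)
    pairs = []
    for a, b in genes.reshape(-1, 2):
        t = (
            CONCRETE_TYPES[rng.integers(len(CONCRETE_TYPES))]
            if etype is EpistasisType.ADMIXTURE
            else etype
        )
        pairs.append(EpistaticPairSpec(int(a), int(b), t))
    return pairs
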