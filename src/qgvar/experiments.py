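"""Scenario runner: named experimental grid and trajectory computation.

A Scenario ties together the genome layout, founder specification, trait
scaling, epistasis settings and a generation scheme.  ``run_scenario``
simulates the founder, advances generations, and at each generation computes
the variance components from the parametric genetic values of the sampled
individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .decomposition import (
    COMPONENTS,
    EffectSet,
    GenomeEffects,
    genetic_values,
    kempthorne_effects,
    variance_components_from_sample,
)
from .epistasis import (
    EpistasisType,
    EpistaticGrid,
    EpistaticPairSpec,
    assign_epistatic_network,
    build_epistatic_grid,
)
from .genome import (
    EpistasisSettings,
    GeneMap,
    TraitSpec,
    assign_gene_effects,
    build_gene_map,
)
from .ld import (
    TwoLocusDist,
    delta_random_mating,
    founder_delta,
    gamete_freqs_from_margins,
    ld_decay_summary,
)
from .population import (
    FounderSpec,
    Population,
    advance_random_mating,
    advance_selfing,
    found_ld_population,
    sample_parental_freqs,
)

__all__ = [
    "Scenario",
    "TrajectoryResult",
    "TraitArchitecture",
    "run_scenario",
    "run_replicates",
    "paper_scenarios",
    "summarize_percent_changes",
    "epistatic_network_table",
]


def epistatic_network_table(arch: "TraitArchitecture") -> pd.DataFrame:
    """Interacting pairs with their type, sampled I22 and V(I)."""
    return pd.DataFrame(
        [
            {
                "gene_i": pr.spec.gene_i,
                "gene_j": pr.spec.gene_j,
                "type": pr.spec.etype.value,
                "I22": pr.grid.i22,
                "V_I": pr.grid.v_i,
            }
            for pr in arch.pairs
        ]
    )


@dataclass(frozen=True)
class Scenario:
    """One simulated experiment configuration."""

    name: str = "custom"
    n_chrom: int = 10
    chrom_len: float = 200.0
    genes_per_chrom: int = 40
    mean_freq: float = 0.5
    ld_level: str = "high"
    epistasis_type: str = "admixture"
    pct_interacting: float = 0.3
    ratio: float = 1.0
    scheme: str = "selfing"
    generations: int = 10
    N: int = 5000
    g_min: float = 30.0
    g_max: float = 160.0
    p_min: float = 10.0
    p_max: float = 180.0
    mean_dominance: float = 0.6
    h2: float = 0.2
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.scheme not in {"selfing", "random"}:
            raise ValueError("scheme must be 'selfing' or 'random'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def trait_spec(self) -> TraitSpec:
        return TraitSpec(
            g_min=self.g_min,
            g_max=self.g_max,
            p_min=self.p_min,
            p_max=self.p_max,
            mean_dominance=self.mean_dominance,
            h2=self.h2,
            epistasis=EpistasisSettings(
                type=None if self.epistasis_type == "none" else self.epistasis_type,
                pct_interacting=self.pct_interacting,
                ratio=self.ratio,
            ),
        )

    def founder_spec(self) -> FounderSpec:
        return FounderSpec(mean_freq=self.mean_freq, ld_level=self.ld_level, N=self.N)


@dataclass
class _Pair:
    spec: EpistaticPairSpec
    r: float
    delta0: float
    dist0: TwoLocusDist
    grid: EpistaticGrid
    effects: EffectSet


@dataclass
class TraitArchitecture:
    """Sampled genome + trait + epistatic network with parametric effects.

    Built once per run; the per-pair 36-parameter effect sets are solved at
    the founder allele frequencies (invariant over generations), while the
    per-generation genotype distributions supply the component means.
    """

    gene_map: GeneMap
    a: np.ndarray
    d: np.ndarray
    m: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    pairs: list[_Pair]

    @property
    def pbar(self) -> np.ndarray:
        return (self.p1 + self.p2) / 2.0

    @property
    def epistatic_mask(self) -> np.ndarray:
        mask = np.zeros(self.gene_map.n_genes, dtype=bool)
        for pr in self.pairs:
            mask[pr.spec.gene_i] = True
            mask[pr.spec.gene_j] = True
        return mask

    @classmethod
    def build(cls, s: Scenario, rng: np.random.Generator) -> "TraitArchitecture":
        gene_map = build_gene_map(s.n_chrom, s.chrom_len, s.genes_per_chrom)
        spec = s.trait_spec()
        eff = assign_gene_effects(gene_map, spec, rng)
        p1, p2 = sample_parental_freqs(s.founder_spec(), gene_map.n_genes, rng)
        pbar = (p1 + p2) / 2.0
        pairs: list[_Pair] = []
        if spec.epistasis.type is not None and spec.epistasis.pct_interacting > 0:
            network = assign_epistatic_network(
                gene_map.n_genes,
                spec.epistasis.pct_interacting,
                spec.epistasis.type,
                rng,
            )
            for ps in network:
                gi, gj = ps.gene_i, ps.gene_j
                r = gene_map.recomb_between(gi, gj)
                d0 = founder_delta(p1[gi], p2[gi], p1[gj], p2[gj], r)
                dist0 = TwoLocusDist.from_margins(pbar[gi], pbar[gj], d0)
                nonepi = np.add.outer(
                    np.array([eff.m[gi] - eff.a[gi], eff.m[gi] + eff.d[gi],
                              eff.m[gi] + eff.a[gi]]),
                    np.array([eff.m[gj] - eff.a[gj], eff.m[gj] + eff.d[gj],
                              eff.m[gj] + eff.a[gj]]),
                )
                grid = build_epistatic_grid(nonepi, ps.etype, spec.epistasis.ratio,
                                            dist0, rng)
                es = kempthorne_effects(dist0, grid.values)
                grid = replace(grid, pair=(gi, gj))
                pairs.append(_Pair(spec=ps, r=r, delta0=d0, dist0=dist0,
                                   grid=grid, effects=es))
        return cls(gene_map=gene_map, a=eff.a, d=eff.d, m=eff.m,
                   p1=p1, p2=p2, pairs=pairs)

    def genome_effects(self, scheme: str, gen: int) -> GenomeEffects:
        """Effect tables at a given generation of selfing or random mating."""
        F = (1.0 - 0.5**gen) if scheme == "selfing" else 0.0
        mask = self.epistatic_mask
        ne_idx = np.flatnonzero(~mask)
        p = self.pbar[ne_idx]
        q = 1.0 - p
        a = self.a[ne_idx]
        d = self.d[ne_idx]
        m = self.m[ne_idx]
        alpha = a + (q - p) * d
        # per-locus values indexed by dosage 0/1/2
        A_table = np.column_stack(
            [-2.0 * p * alpha, (q - p) * alpha, 2.0 * q * alpha]
        )
        D0 = np.column_stack([-2.0 * p * p * d, 2.0 * p * q * d, -2.0 * q * q * d])
        D_table = D0 + (2.0 * F * p * q * d)[:, None]
        M = m + (p - q) * a + 2.0 * p * q * d
        M_F = float(np.sum(M - 2.0 * F * p * q * d))
        pair_idx = np.zeros((len(self.pairs), 2), dtype=int)
        pair_tables = {c: np.zeros((len(self.pairs), 9)) for c in COMPONENTS}
        for k, pr in enumerate(self.pairs):
            pair_idx[k] = (pr.spec.gene_i, pr.spec.gene_j)
            if scheme == "selfing":
                dist = pr.dist0.self_generations(pr.r, gen)
            else:
                dist = TwoLocusDist.from_gamete_freqs(
                    gamete_freqs_from_margins(
                        *pr.dist0.allele_freqs(),
                        delta_random_mating(pr.delta0, pr.r, gen),
                    )
                )
            cv = pr.effects.centered_values(dist)
            for c in COMPONENTS:
                pair_tables[c][k] = cv[c].ravel()
            M_F += pr.effects.M_F(dist)
        return GenomeEffects(
            generation=gen,
            F=F,
            M_F=M_F,
            ne_idx=ne_idx,
            A_table=A_table,
            D_table=D_table,
            pair_idx=pair_idx,
            pair_tables=pair_tables,
        )


@dataclass
class TrajectoryResult:
    """Per-generation variance components of one scenario run."""

    components: pd.DataFrame
    scenario: Scenario
    seed: int
    ld: pd.DataFrame | None = None
    ld_mean_pct_change: float | None = None


def run_scenario(
    s: Scenario, seed: int | None = None, with_ld: bool = False
) -> TrajectoryResult:
    """Simulate one scenario trajectory; deterministic given the seed."""
    used_seed = s.seed if seed is None else seed
    rng = np.random.default_rng(used_seed)
    arch = TraitArchitecture.build(s, rng)
    pop = found_ld_population(
        s.founder_spec(), arch.gene_map, rng, p1=arch.p1, p2=arch.p2
    )
    rows = []
    for gen in range(s.generations + 1):
        ge = arch.genome_effects(s.scheme, gen)
        vals = genetic_values(pop, ge)
        vc = variance_components_from_sample(vals, F=ge.F, generation=gen)
        rows.append(vc.to_series())
        if gen < s.generations:
            if s.scheme == "selfing":
                pop = advance_selfing(pop, 1, rng)
            else:
                pop = advance_random_mating(pop, 1, rng)
    components = pd.DataFrame(rows).reset_index(drop=True)
    ld_df = mean_pct = None
    if with_ld:
        ld_df, mean_pct = ld_decay_summary(
            arch.gene_map,
            arch.p1,
            arch.p2,
            "random" if s.scheme == "random" else "selfing",
            s.generations,
            chromosome=0,
        )
    return TrajectoryResult(
        components=components,
        scenario=s,
        seed=used_seed,
        ld=ld_df,
        ld_mean_pct_change=mean_pct,
    )


def run_replicates(s: Scenario, seeds: Iterable[int]) -> pd.DataFrame:
    """Replicate means of the per-generation component table."""
    frames = [run_scenario(s, seed=sd).components for sd in seeds]
    stacked = pd.concat(frames, keys=range(len(frames)), names=["rep"])
    return stacked.groupby(level=1).mean()


def paper_scenarios(
    pct_values: tuple[float, ...] = (0.3, 1.0),
    schemes: tuple[str, ...] = ("random", "selfing"),
) -> list[Scenario]:
    """The named experimental grid.

    Four founder populations at one gene/5 cM (high-LD/0.5, low-LD/0.5,
    intermediate-LD/0.3 and /0.7), each crossed with the seven concrete
    epistasis types plus admixture at 30% and 100% interacting genes, ratio
    1, under 10 generations of selfing and of random mating.  A fifth
    high-LD/0.5 genome at one gene/cM (50 cM chromosomes) is included for LD
    characterization only (no epistasis).
    """
    founders = [
        ("high_0.5", 0.5, "high", 200.0),
        ("low_0.5", 0.5, "low", 200.0),
        ("intermediate_0.3", 0.3, "intermediate", 200.0),
        ("intermediate_0.7", 0.7, "intermediate", 200.0),
    ]
    etypes = [t.value for t in EpistasisType if t not in
              (EpistasisType.NONE,)]
    out = []
    for fname, freq, level, clen in founders:
        for et in etypes:
            for pct in pct_values:
                for scheme in schemes:
                    out.append(
                        Scenario(
                            name=f"{fname}/{et}/{int(pct * 100)}pct/{scheme}",
                            chrom_len=clen,
                            mean_freq=freq,
                            ld_level=level,
                            epistasis_type=et,
                            pct_interacting=pct,
                            scheme=scheme,
                        )
                    )
    out.append(
        Scenario(
            name="high_0.5_dense/ld_only",
            chrom_len=50.0,
            mean_freq=0.5,
            ld_level="high",
            epistasis_type="none",
            pct_interacting=0.0,
            scheme="random",
        )
    )
    return out


def summarize_percent_changes(tr: TrajectoryResult) -> pd.DataFrame:
    """Percent change of each component from generation 0 to each generation,
    plus the epistatic fraction per generation.

    Percent change is 100 (X_n - X_0) / X_0; a zero baseline yields NaN.
    """
    comp = tr.components
    if len(comp) < 2:
        raise ValueError("trajectory must span at least two generations")
    cols = [f"sigma2_{c}" for c in COMPONENTS] + ["sigma2_G"]
    base = comp[cols].iloc[0]
    pct = 100.0 * (comp[cols] - base) / base.where(base != 0, np.nan)
    pct.columns = [f"pct_change_{c}" for c in cols]
    pct.insert(0, "generation", comp["generation"].to_numpy())
    pct["epistatic_fraction"] = comp["epistatic_fraction"].to_numpy()
    return pct
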