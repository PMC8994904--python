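"""Variance decomposition under LD, inbreeding, and digenic epistasis.

Single-locus theory
-------------------
For a biallelic gene with effects (a, d) at frequency p, the average
substitution effect is alpha = a + (q - p)d.  In a population derived by
selfing (inbreeding coefficient F) the mean is M_F = M - 2Fpqd, the inbred
additive values are A^(n) = A^(0) + 4Fpqd, and the inbred dominance values
are D^(n) = D^(0) + 2Fpqd, where A^(0), D^(0) are the noninbred values.

Two-locus theory
----------------
The 36-parameter partition (alpha_i, delta_ij, and the four classes of
digenic interaction effects) is the saturated linear model over the nine
dosage cells, identified by frequency-weighted zero-sum restrictions on each
effect class.  The restriction weights are allele frequencies, which both
selfing and random mating leave invariant, so the effects themselves are the
noninbred linkage-equilibrium reference effects; inbreeding and LD enter
through the genotype distribution used to take expectations, variances and
covariances of the effect variables.  Component means (E(D), E(AA), ...) are
generally nonzero under inbreeding/LD; each component is centered by its
current mean so that E(G) = M_F at every generation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .ld import SelfingConstants, TwoLocusDist, selfing_constants

__all__ = [
    "COMPONENTS",
    "SingleLocusEffects",
    "cockerham_d1_d2",
    "single_locus_inbred_effects",
    "closed_form_two_locus_variances",
    "EffectSet",
    "kempthorne_effects",
    "GenomeEffects",
    "genetic_values",
    "VarianceComponents",
    "variance_components_from_sample",
]

COMPONENTS = ("A", "D", "AA", "AD", "DA", "DD")


# ---------------------------------------------------------------------------
# single locus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SingleLocusEffects:
    """Single-gene effects and genotype values in a selfed population.

    Value arrays are indexed by dosage of the capital allele (0, 1, 2).
    """

    p: float
    a: float
    d: float
    F: float
    m: float = 0.0

    @property
    def q(self) -> float:
        return 1.0 - self.p

    @property
    def alpha(self) -> float:
        """Average effect of an allelic substitution: a + (q - p)d."""
        return self.a + (self.q - self.p) * self.d

    @property
    def alpha_A(self) -> float:
        """Inbred-population average effect of allele A: q*alpha + 2Fpqd."""
        return self.q * self.alpha + 2.0 * self.F * self.p * self.q * self.d

    @property
    def alpha_a(self) -> float:
        return -self.p * self.alpha + 2.0 * self.F * self.p * self.q * self.d

    @property
    def M(self) -> float:
        """Noninbred population mean."""
        return self.m + (self.p - self.q) * self.a + 2.0 * self.p * self.q * self.d

    @property
    def M_F(self) -> float:
        """Inbred population mean: M - 2Fpqd."""
        return self.M - 2.0 * self.F * self.p * self.q * self.d

    @property
    def A0(self) -> np.ndarray:
        """Noninbred additive (breeding) values [aa, Aa, AA]."""
        al = self.alpha
        return np.array([-2.0 * self.p * al, (self.q - self.p) * al, 2.0 * self.q * al])

    @property
    def An(self) -> np.ndarray:
        """Inbred additive values: A^(0) + 4Fpqd."""
        return self.A0 + 4.0 * self.F * self.p * self.q * self.d

    @property
    def D0(self) -> np.ndarray:
        """Noninbred dominance deviations [aa, Aa, AA]."""
        p, q, d = self.p, self.q, self.d
        return np.array([-2.0 * p * p * d, 2.0 * p * q * d, -2.0 * q * q * d])

    @property
    def Dn(self) -> np.ndarray:
        """Inbred dominance values: D^(0) + 2Fpqd (zero mean in the inbred
        population, since E(D^(0)) = -2Fpqd)."""
        return self.D0 + 2.0 * self.F * self.p * self.q * self.d

    @property
    def genotype_values(self) -> np.ndarray:
        return np.array([self.m - self.a, self.m + self.d, self.m + self.a])

    @property
    def genotype_freqs(self) -> np.ndarray:
        """Inbred genotype frequencies [q^2 + Fpq, 2pq(1-F), p^2 + Fpq]."""
        p, q, F = self.p, self.q, self.F
        return np.array(
            [q * q + F * p * q, 2.0 * p * q * (1.0 - F), p * p + F * p * q]
        )


def single_locus_inbred_effects(
    p: float, a: float, d: float, F: float, m: float = 0.0
) -> SingleLocusEffects:
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must be in [0, 1]")
    if not 0.0 <= F <= 1.0:
        raise ValueError("inbreeding coefficient must be in [0, 1]")
    return SingleLocusEffects(p=p, a=a, d=d, F=F, m=m)


def cockerham_d1_d2(effects: list[SingleLocusEffects]) -> tuple[float, float]:
    """D1 (covariance of a and d) and D2 (variance of d) over loci."""
    d1 = sum(
        2.0 * e.p * e.q * (e.p - e.q) * e.alpha * e.d for e in effects
    )
    d2 = sum(
        4.0 * e.p * e.q * (e.p - e.q) ** 2 * e.d * e.d for e in effects
    )
    return float(d1), float(d2)


def closed_form_two_locus_variances(
    ea: SingleLocusEffects,
    eb: SingleLocusEffects,
    delta: float,
    r: float,
    n: int,
) -> tuple[float, float, float]:
    """Closed-form sigma2_A^(n), sigma2_D^(n), sigma_{A,D}^(n) for two linked
    genes after n generations of selfing from a founder in LD (no epistasis).

    ``delta`` is the founder gametic LD (generation -1 pool); r is the
    recombination fraction.  The inbreeding coefficients stored on the
    SingleLocusEffects inputs are ignored; F, c1 and c follow from (r, n).
    """
    sc: SelfingConstants = selfing_constants(r, n)
    F, c1, c = sc.F, sc.c1, sc.c
    pa, qa, pb, qb = ea.p, ea.q, eb.p, eb.q
    aa, ab = ea.alpha, eb.alpha
    da, db = ea.d, eb.d

    s2a = (1.0 + F) * (2.0 * pa * qa * aa**2 + 2.0 * pb * qb * ab**2) + 2.0 * (
        2.0 + c1 * (1.0 - 2.0 * r)
    ) * delta * aa * ab

    cn = c**n
    s2d = (
        (1.0 - F * F) * (4.0 * pa**2 * qa**2 * da**2 + 4.0 * pb**2 * qb**2 * db**2)
        + F
        * (
            4.0 * pa * qa * (pa - qa) ** 2 * da**2
            + 4.0 * pb * qb * (pb - qb) ** 2 * db**2
        )
        + 8.0
        * (
            (1.0 - F) * (cn - 1.0 + F) * pa * qa * pb * qb
            + (pa - qa)
            * (pb - qb)
            * ((1.0 - F) * cn - (1.0 - 2.0 * F) + c1 * (1.0 - 2.0 * r) / 2.0)
            * delta
            / 2.0
            + (1.0 - F) * cn * delta**2
        )
        * da
        * db
    )

    sad = 2.0 * F * (
        2.0 * pa * qa * (pa - qa) * aa * da + 2.0 * pb * qb * (pb - qb) * ab * db
    ) + (2.0 * F + c1 * (1.0 - 2.0 * r)) * delta * (
        (pb - qb) * aa * db + (pa - qa) * ab * da
    )
    return float(s2a), float(s2d), float(sad)


# ---------------------------------------------------------------------------
# Kempthorne 36-parameter decomposition of a two-locus grid
# ---------------------------------------------------------------------------

# parameter layout within beta (36,)
_SL_M = slice(0, 1)
_SL_A1 = slice(1, 3)    # alpha1: (A, a)
_SL_A2 = slice(3, 5)    # alpha2: (B, b)
_SL_D1 = slice(5, 8)    # delta1: (AA, Aa, aa)
_SL_D2 = slice(8, 11)   # delta2: (BB, Bb, bb)
_SL_AA = slice(11, 15)  # (alpha alpha)_{xk}: (AB, Ab, aB, ab)
_SL_AD = slice(15, 21)  # (alpha delta)_{x,kl}: x in (A,a) x (BB,Bb,bb)
_SL_DA = slice(21, 27)  # (delta alpha)_{ij,k}: (AA,Aa,aa) x (B,b)
_SL_DD = slice(27, 36)  # (delta delta)_{ij,kl}: (AA,Aa,aa) x (BB,Bb,bb)


def _allele_counts(dosage: int) -> np.ndarray:
    """[#capital, #lowercase] alleles for a dosage 0/1/2."""
    return np.array([dosage, 2 - dosage], dtype=float)


def _geno_onehot(dosage: int) -> np.ndarray:
    """One-hot over genotypes ordered (hom capital, het, hom lowercase)."""
    out = np.zeros(3)
    out[2 - dosage] = 1.0
    return out


def _design_matrix() -> np.ndarray:
    """9x36 incidence matrix of the saturated two-locus effect model.

    Rows follow cell order c = 3*i + j with i = #A alleles, j = #B alleles.
    """
    X = np.zeros((9, 36))
    for i in range(3):
        na = _allele_counts(i)
        ga = _geno_onehot(i)
        for j in range(3):
            nb = _allele_counts(j)
            gb = _geno_onehot(j)
            row = X[3 * i + j]
            row[_SL_M] = 1.0
            row[_SL_A1] = na
            row[_SL_A2] = nb
            row[_SL_D1] = ga
            row[_SL_D2] = gb
            row[_SL_AA] = np.outer(na, nb).ravel()
            row[_SL_AD] = np.outer(na, gb).ravel()
            row[_SL_DA] = np.outer(ga, nb).ravel()
            row[_SL_DD] = np.outer(ga, gb).ravel()
    return X


_X = _design_matrix()


def _restrictions(p_a: float, p_b: float) -> np.ndarray:
    """Kempthorne's zero-sum restrictions, weighted by allele frequencies.

    Every effect class sums to zero over either of its allelic indices with
    weights (p, q); dominance-type indices are summed over one allele of the
    genotype at a time.  Together with the incidence matrix these identify
    the 36 parameters exactly (the model saturates the nine cells).
    """
    wa = np.array([p_a, 1.0 - p_a])
    wb = np.array([p_b, 1.0 - p_b])
    rows: list[np.ndarray] = []

    def add(sl: slice, coef: np.ndarray) -> None:
        row = np.zeros(36)
        row[sl] = coef.ravel()
        rows.append(row)

    # genotype (x, y) -> genotype index: (A,A)->0, (A,a)/(a,A)->1, (a,a)->2
    def gidx(x: int, y: int) -> int:
        return x + y

    # alpha: sum_x p_x alpha_x = 0
    add(_SL_A1, wa)
    add(_SL_A2, wb)
    # delta: sum_x p_x delta_{xy} = 0 for each y
    for y in range(2):
        coef = np.zeros(3)
        for x in range(2):
            coef[gidx(x, y)] += wa[x]
        add(_SL_D1, coef)
    for y in range(2):
        coef = np.zeros(3)
        for x in range(2):
            coef[gidx(x, y)] += wb[x]
        add(_SL_D2, coef)
    # (alpha alpha): weighted zero sums over each allelic index
    for k in range(2):
        coef = np.zeros((2, 2))
        coef[:, k] = wa
        add(_SL_AA, coef)
    for x in range(2):
        coef = np.zeros((2, 2))
        coef[x, :] = wb
        add(_SL_AA, coef)
    # (alpha delta): over the alpha index for each genotype, and over one
    # allele of the genotype for each (x, k)
    for g in range(3):
        coef = np.zeros((2, 3))
        coef[:, g] = wa
        add(_SL_AD, coef)
    for x in range(2):
        for k in range(2):
            coef = np.zeros((2, 3))
            for l in range(2):
                coef[x, gidx(k, l)] += wb[l]
            add(_SL_AD, coef)
    # (delta alpha): symmetric
    for g in range(3):
        coef = np.zeros((3, 2))
        coef[g, :] = wb
        add(_SL_DA, coef)
    for y in range(2):
        for k in range(2):
            coef = np.zeros((3, 2))
            for x in range(2):
                coef[gidx(x, y), k] += wa[x]
            add(_SL_DA, coef)
    # (delta delta): over one allele of each genotype index
    for y in range(2):
        for g in range(3):
            coef = np.zeros((3, 3))
            for x in range(2):
                coef[gidx(x, y), g] += wa[x]
            add(_SL_DD, coef)
    for g in range(3):
        for k in range(2):
            coef = np.zeros((3, 3))
            for l in range(2):
                coef[g, gidx(k, l)] += wb[l]
            add(_SL_DD, coef)
    return np.array(rows)


@dataclass
class EffectSet:
    """Solved 36-parameter effect set for one gene pair.

    ``values[c]`` holds the (3, 3) per-cell value of component c (indexed by
    dosage i, j); these are the noninbred LE reference effect variables.
    ``means(dist)`` gives the component expectations under an arbitrary
    genotype distribution; centered values subtract those means.
    """

    beta: np.ndarray
    p_a: float
    p_b: float
    values: dict[str, np.ndarray]
    M: float

    @property
    def alpha1(self) -> np.ndarray:
        return self.beta[_SL_A1]

    @property
    def alpha2(self) -> np.ndarray:
        return self.beta[_SL_A2]

    @property
    def delta1(self) -> np.ndarray:
        return self.beta[_SL_D1]

    @property
    def delta2(self) -> np.ndarray:
        return self.beta[_SL_D2]

    @property
    def aa_effects(self) -> np.ndarray:
        return self.beta[_SL_AA].reshape(2, 2)

    @property
    def ad_effects(self) -> np.ndarray:
        return self.beta[_SL_AD].reshape(2, 3)

    @property
    def da_effects(self) -> np.ndarray:
        return self.beta[_SL_DA].reshape(3, 2)

    @property
    def dd_effects(self) -> np.ndarray:
        return self.beta[_SL_DD].reshape(3, 3)

    def fitted(self) -> np.ndarray:
        """(3, 3) reconstructed genotypic values (exact for a valid solve)."""
        g = np.full((3, 3), self.M)
        for comp in COMPONENTS:
            g = g + self.values[comp]
        return g

    def means(self, dist: TwoLocusDist) -> dict[str, float]:
        """E(A), E(D), E(AA), E(AD), E(DA), E(DD) under ``dist``."""
        f = dist.f9()
        return {c: float(np.sum(f * self.values[c])) for c in COMPONENTS}

    def M_F(self, dist: TwoLocusDist) -> float:
        """E(G) under ``dist``: M plus the component means."""
        return self.M + sum(self.means(dist).values())

    def centered_values(self, dist: TwoLocusDist) -> dict[str, np.ndarray]:
        mu = self.means(dist)
        return {c: self.values[c] - mu[c] for c in COMPONENTS}

    def parametric_components(self, dist: TwoLocusDist) -> "VarianceComponents":
        """Exact variances/covariances of the centered components under
        ``dist`` (enumeration over the nine cells)."""
        f = dist.f9().ravel()
        cv = self.centered_values(dist)
        mat = np.array([cv[c].ravel() for c in COMPONENTS])
        cov = (mat * f) @ mat.T
        g = self.fitted().ravel()
        var_g = float(np.sum(f * g * g) - np.sum(f * g) ** 2)
        variances = {c: float(cov[k, k]) for k, c in enumerate(COMPONENTS)}
        covariances = {
            (c1, c2): float(cov[k1, k2])
            for (k1, c1), (k2, c2) in combinations(enumerate(COMPONENTS), 2)
        }
        return VarianceComponents(
            variances=variances,
            covariances=covariances,
            sigma2_G=var_g,
            F=float("nan"),
            generation=dist.generation,
        )


def kempthorne_effects(dist: TwoLocusDist, grid: np.ndarray) -> EffectSet:
    """Solve the restricted weighted normal equations for a 3x3 grid.

    ``grid[i, j]`` is the genotypic value for dosages (i, j).  The saturated
    system (incidence matrix stacked on the restriction rows) reproduces the
    grid exactly; allele frequencies for the restriction weights come from
    ``dist``.  A fixed allele makes the partition undefined.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (3, 3):
        raise ValueError("grid must be 3x3")
    p_a, p_b = dist.allele_freqs()
    for name, p in (("first", p_a), ("second", p_b)):
        if not 1e-12 < p < 1.0 - 1e-12:
            raise ValueError(f"{name} locus has a fixed allele (p = {p})")
    y = grid.ravel()
    R = _restrictions(p_a, p_b)
    A = np.vstack([_X, R])
    b = np.concatenate([y, np.zeros(R.shape[0])])
    beta, *_ = np.linalg.lstsq(A, b, rcond=None)
    resid = np.max(np.abs(_X @ beta - y))
    scale = max(1.0, np.max(np.abs(y)))
    if resid > 1e-8 * scale:
        raise np.linalg.LinAlgError(
            f"restricted system failed to reproduce the grid (residual {resid:g})"
        )
    values: dict[str, np.ndarray] = {c: np.zeros((3, 3)) for c in COMPONENTS}
    for i in range(3):
        na = _allele_counts(i)
        ga = _geno_onehot(i)
        for j in range(3):
            nb = _allele_counts(j)
            gb = _geno_onehot(j)
            values["A"][i, j] = na @ beta[_SL_A1] + nb @ beta[_SL_A2]
            values["D"][i, j] = ga @ beta[_SL_D1] + gb @ beta[_SL_D2]
            values["AA"][i, j] = na @ beta[_SL_AA].reshape(2, 2) @ nb
            values["AD"][i, j] = na @ beta[_SL_AD].reshape(2, 3) @ gb
            values["DA"][i, j] = ga @ beta[_SL_DA].reshape(3, 2) @ nb
            values["DD"][i, j] = ga @ beta[_SL_DD].reshape(3, 3) @ gb
    return EffectSet(
        beta=beta, p_a=p_a, p_b=p_b, values=values, M=float(beta[0])
    )


# ---------------------------------------------------------------------------
# multilocus genetic values
# ---------------------------------------------------------------------------

@dataclass
class GenomeEffects:
    """Parametric effect tables for a whole genome at one generation.

    Nonepistatic loci contribute per-locus additive values A^(0) and inbred
    dominance values D^(n); each interacting pair contributes its six
    centered component values over the nine cells.  All components have
    parametric expectation zero at the stated generation, so the genotypic
    value of an individual is G = M_F + A + D + AA + AD + DA + DD.

    ne_idx: flat gene indices of nonepistatic loci;
    A_table, D_table: (len(ne_idx), 3) values indexed by dosage;
    pair_idx: (P, 2) flat gene indices of the interacting pairs;
    pair_tables: component name -> (P, 9) centered cell values, cell = 3i + j.
    """

    generation: int
    F: float
    M_F: float
    ne_idx: np.ndarray
    A_table: np.ndarray
    D_table: np.ndarray
    pair_idx: np.ndarray
    pair_tables: dict[str, np.ndarray]


def genetic_values(pop, effects: GenomeEffects) -> pd.DataFrame:
    """Per-individual genetic values A, D, AA, AD, DA, DD and G.

    ``pop`` is a Population whose generation must match the effect tables
    (stale effects raise).  G = M_F + A + D + AA + AD + DA + DD exactly.
    """
    if pop.generation != effects.generation:
        raise ValueError(
            f"effects computed for generation {effects.generation}, "
            f"population is at generation {pop.generation}"
        )
    dos = pop.dosage()
    N = dos.shape[0]
    out = {c: np.zeros(N) for c in COMPONENTS}
    if effects.ne_idx.size:
        d_ne = dos[:, effects.ne_idx].astype(np.intp)
        cols = np.arange(effects.ne_idx.size)[None, :]
        out["A"] += effects.A_table[cols, d_ne].sum(axis=1)
        out["D"] += effects.D_table[cols, d_ne].sum(axis=1)
    if effects.pair_idx.size:
        cell = (
            3 * dos[:, effects.pair_idx[:, 0]].astype(np.intp)
            + dos[:, effects.pair_idx[:, 1]].astype(np.intp)
        )
        cols = np.arange(effects.pair_idx.shape[0])[None, :]
        for c in COMPONENTS:
            out[c] += effects.pair_tables[c][cols, cell].sum(axis=1)
    df = pd.DataFrame(out)
    df["G"] = effects.M_F + df[list(COMPONENTS)].sum(axis=1)
    return df


# ---------------------------------------------------------------------------
# variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Six component variances, fifteen pairwise covariances, and sigma2_G."""

    variances: dict[str, float]
    covariances: dict[tuple[str, str], float]
    sigma2_G: float
    F: float = 0.0
    generation: int = 0

    @property
    def total(self) -> float:
        """Sum of variances + 2 * sum of covariances (equals sigma2_G)."""
        return sum(self.variances.values()) + 2.0 * sum(self.covariances.values())

    @property
    def epistatic_fraction(self) -> float:
        """(sigma2_AA + sigma2_AD + sigma2_DA + sigma2_DD) / sigma2_G."""
        epi = sum(self.variances[c] for c in ("AA", "AD", "DA", "DD"))
        return epi / self.sigma2_G if self.sigma2_G > 0 else float("nan")

    def to_series(self) -> pd.Series:
        out = {"generation": self.generation, "F": self.F}
        for c in COMPONENTS:
            out[f"sigma2_{c}"] = self.variances[c]
        for (c1, c2), v in self.covariances.items():
            out[f"cov_{c1}_{c2}"] = v
        out["sigma2_G"] = self.sigma2_G
        out["epistatic_fraction"] = self.epistatic_fraction
        return pd.Series(out)


def variance_components_from_sample(
    values: pd.DataFrame, F: float = 0.0, generation: int = 0
) -> VarianceComponents:
    """Empirical components from per-individual genetic values.

    ``values`` must have columns A, D, AA, AD, DA, DD and G with
    G = M_F + A + D + AA + AD + DA + DD per individual, so that
    Var(G) = sum of variances + 2 * sum of covariances holds algebraically.
    """
    if len(values) < 2:
        raise ValueError("need at least two individuals")
    mat = values[list(COMPONENTS)].to_numpy().T
    cov = np.cov(mat, ddof=1)
    variances = {c: float(cov[k, k]) for k, c in enumerate(COMPONENTS)}
    covariances = {
        (c1, c2): float(cov[k1, k2])
        for (k1, c1), (k2, c2) in combinations(enumerate(COMPONENTS), 2)
    }
    return VarianceComponents(
        variances=variances,
        covariances=covariances,
        sigma2_G=float(np.var(values["G"].to_numpy(), ddof=1)),
        F=F,
        generation=generation,
    )
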