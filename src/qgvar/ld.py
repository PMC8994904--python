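"""Parametric two-locus linkage-disequilibrium machinery.

Haplotypes of two biallelic loci (A/a, B/b) are indexed ``h = 2x + y`` with
``x, y`` = 1 for the capital allele, so 3 = AB, 2 = Ab, 1 = aB, 0 = ab.
Gametic frequency vectors are ordered ``[P_ab, P_aB, P_Ab, P_AB]``.

The phase-aware genotype of an individual is the unordered pair of its two
haplotypes: ten states, of which two are the double-heterozygote phases
AB/ab (coupling) and Ab/aB (repulsion).  Under selfing with linkage the two
phases have different dynamics, which is why the recursion is kept at ten
states even though genotypic values only distinguish the nine dosage cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .genome import GeneMap, haldane

__all__ = [
    "HAP_AB",
    "LDMetrics",
    "SelfingConstants",
    "TwoLocusDist",
    "founder_delta",
    "delta_random_mating",
    "gamete_freqs_from_margins",
    "ld_metrics",
    "selfing_constants",
    "selfing_transition_matrix",
    "ld_decay_summary",
]

HAP_ab, HAP_aB, HAP_Ab, HAP_AB = 0, 1, 2, 3

#: the ten unordered haplotype pairs (phase-aware genotypes)
STATES: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (0, 2), (0, 3), (1, 1),
    (1, 2), (1, 3), (2, 2), (2, 3), (3, 3),
)
STATE_COUPLING = STATES.index((0, 3))   # AB/ab
STATE_REPULSION = STATES.index((1, 2))  # Ab/aB


def _hap_alleles(h: int) -> tuple[int, int]:
    return h >> 1, h & 1


def founder_delta(
    p_a1: float, p_a2: float, p_b1: float, p_b2: float, r: float
) -> float:
    """Gametic LD of a population founded by crossing two LE populations.

    Delta = [(1 - 2r)/4] (p_a1 - p_a2)(p_b1 - p_b2): positive for coupling
    (parental frequency differences of equal sign), negative for repulsion.
    """
    return (1.0 - 2.0 * r) / 4.0 * (p_a1 - p_a2) * (p_b1 - p_b2)


def delta_random_mating(delta0: float, r: float, n: int) -> float:
    """LD after n generations of random mating: Delta_n = (1 - r)^n Delta_0."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    return (1.0 - r) ** n * delta0


def gamete_freqs_from_margins(p_a: float, p_b: float, delta: float) -> np.ndarray:
    """Haplotype frequency vector [ab, aB, Ab, AB] from allele freqs and Delta."""
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    freqs = np.array(
        [
            q_a * q_b + delta,
            q_a * p_b - delta,
            p_a * q_b - delta,
            p_a * p_b + delta,
        ]
    )
    if np.any(freqs < -1e-12):
        raise ValueError("Delta outside the feasible range for these frequencies")
    return np.clip(freqs, 0.0, None)


class LDMetrics(NamedTuple):
    delta: float
    r2: float
    dprime: float


def ld_metrics(gamete_freqs: np.ndarray) -> LDMetrics:
    """Delta, r^2 and D' from a haplotype frequency vector.

    At a fixed locus r^2 and D' are undefined and reported as NaN.
    """
    P = np.asarray(gamete_freqs, dtype=float)
    p_a = P[HAP_AB] + P[HAP_Ab]
    p_b = P[HAP_AB] + P[HAP_aB]
    q_a, q_b = 1.0 - p_a, 1.0 - p_b
    delta = P[HAP_AB] * P[HAP_ab] - P[HAP_Ab] * P[HAP_aB]
    denom = p_a * q_a * p_b * q_b
    if denom <= 0:
        return LDMetrics(delta, float("nan"), float("nan"))
    r2 = delta * delta / denom
    if delta > 0:
        dmax = min(p_a * q_b, q_a * p_b)
    else:
        dmax = min(p_a * p_b, q_a * q_b)
    dprime = delta / dmax if dmax > 0 else float("nan")
    return LDMetrics(delta, r2, dprime)


@dataclass(frozen=True)
class SelfingConstants:
    """F, c1 and c after n generations of selfing with recombination r."""

    F: float
    c1: float
    c: float


def selfing_constants(r: float, n: int) -> SelfingConstants:
    F = 1.0 - 0.5**n
    c1 = 2.0 * (1.0 - ((1.0 - 2.0 * r) / 2.0) ** n) / (1.0 + 2.0 * r)
    c = 1.0 - 2.0 * r * (1.0 - r)
    return SelfingConstants(F=F, c1=c1, c=c)


def _gamete_distribution(state: tuple[int, int], r: float) -> np.ndarray:
    """Meiosis gamete probabilities (length 4) of a phase-aware genotype."""
    h1, h2 = state
    x1, y1 = _hap_alleles(h1)
    x2, y2 = _hap_alleles(h2)
    out = np.zeros(4)
    out[h1] += (1.0 - r) / 2.0
    out[h2] += (1.0 - r) / 2.0
    out[2 * x1 + y2] += r / 2.0
    out[2 * x2 + y1] += r / 2.0
    return out


def selfing_transition_matrix(r: float) -> np.ndarray:
    """10x10 selfing transition matrix T[s, s'] over phase-aware genotypes.

    A selfed offspring is the unordered pair of two independent gametes of
    the same parent.
    """
    T = np.zeros((10, 10))
    index = {s: k for k, s in enumerate(STATES)}
    for k, state in enumerate(STATES):
        g = _gamete_distribution(state, r)
        for h1 in range(4):
            for h2 in range(4):
                key = (min(h1, h2), max(h1, h2))
                T[k, index[key]] += g[h1] * g[h2]
    return T


class TwoLocusDist:
    """Phase-aware two-locus genotype distribution (10 states)."""

    def __init__(self, probs: np.ndarray, generation: int = 0):
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (10,):
            raise ValueError("expected 10 state probabilities")
        if np.any(probs < -1e-12) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("state probabilities must be nonnegative and sum to 1")
        self.probs = np.clip(probs, 0.0, None)
        self.probs /= self.probs.sum()
        self.generation = generation

    @classmethod
    def from_gamete_freqs(cls, gamete_freqs: np.ndarray) -> "TwoLocusDist":
        """Random union of gametes (Hardy-Weinberg pairing, possibly in LD)."""
        P = np.asarray(gamete_freqs, dtype=float)
        if abs(P.sum() - 1.0) > 1e-9 or np.any(P < -1e-12):
            raise ValueError("gamete frequencies must be nonnegative and sum to 1")
        probs = np.zeros(10)
        index = {s: k for k, s in enumerate(STATES)}
        for h1 in range(4):
            for h2 in range(4):
                key = (min(h1, h2), max(h1, h2))
                probs[index[key]] += P[h1] * P[h2]
        return cls(probs, generation=0)

    @classmethod
    def from_margins(cls, p_a: float, p_b: float, delta: float) -> "TwoLocusDist":
        return cls.from_gamete_freqs(gamete_freqs_from_margins(p_a, p_b, delta))

    def haplotype_freqs(self) -> np.ndarray:
        """Marginal haplotype (gametic-pool) frequencies of the population."""
        out = np.zeros(4)
        for k, (h1, h2) in enumerate(STATES):
            out[h1] += self.probs[k] / 2.0
            out[h2] += self.probs[k] / 2.0
        return out

    def allele_freqs(self) -> tuple[float, float]:
        P = self.haplotype_freqs()
        return float(P[HAP_AB] + P[HAP_Ab]), float(P[HAP_AB] + P[HAP_aB])

    def f9(self) -> np.ndarray:
        """3x3 dosage-cell probabilities f[i, j], i = #A alleles, j = #B."""
        f = np.zeros((3, 3))
        for k, (h1, h2) in enumerate(STATES):
            x1, y1 = _hap_alleles(h1)
            x2, y2 = _hap_alleles(h2)
            f[x1 + x2, y1 + y2] += self.probs[k]
        return f

    def self_generations(self, r: float, n: int) -> "TwoLocusDist":
        """Distribution after n further generations of selfing."""
        if n < 0:
            raise ValueError("n must be nonnegative")
        T = selfing_transition_matrix(r)
        probs = self.probs @ np.linalg.matrix_power(T, n)
        return TwoLocusDist(probs, generation=self.generation + n)

    def metrics(self) -> LDMetrics:
        return ld_metrics(self.haplotype_freqs())


def ld_decay_summary(
    gene_map: GeneMap,
    p1: np.ndarray,
    p2: np.ndarray,
    scheme: str,
    n: int,
    chromosome: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Parametric per-pair LD decay table for one chromosome.

    For every ordered gene pair of the chromosome the founder Delta is the
    two-LE-parents crossing value; after n generations of random mating
    Delta_n = (1-r)^n Delta_0 at constant allele frequencies, and after n
    generations of selfing the gametic-pool haplotype frequencies come from
    the 10-state recursion.  Returns the per-pair table and the unweighted
    mean percent change of r^2 over pairs where r^2 at generation 0 is
    nonzero.
    """
    if scheme not in {"random", "selfing"}:
        raise ValueError("scheme must be 'random' or 'selfing'")
    sel = np.flatnonzero(gene_map.chrom_of == chromosome)
    if sel.size < 2:
        raise ValueError("need at least two genes on the chromosome")
    pos = gene_map.pos_flat[sel]
    p1 = np.asarray(p1, float)[sel]
    p2 = np.asarray(p2, float)[sel]
    pbar = (p1 + p2) / 2.0
    rows = []
    for u in range(sel.size):
        for v in range(u + 1, sel.size):
            d = pos[v] - pos[u]
            r = haldane(d)
            d0 = founder_delta(p1[u], p2[u], p1[v], p2[v], r)
            g0 = gamete_freqs_from_margins(pbar[u], pbar[v], d0)
            m0 = ld_metrics(g0)
            if scheme == "random":
                dn = delta_random_mating(d0, r, n)
                mn = ld_metrics(gamete_freqs_from_margins(pbar[u], pbar[v], dn))
            else:
                dist = TwoLocusDist.from_gamete_freqs(g0).self_generations(r, n)
                mn = ld_metrics(dist.haplotype_freqs())
            pct = (
                100.0 * (mn.r2 - m0.r2) / m0.r2
                if np.isfinite(m0.r2) and m0.r2 > 0
                else float("nan")
            )
            rows.append(
                {
                    "gene_i": int(sel[u]),
                    "gene_j": int(sel[v]),
                    "distance_cM": d,
                    "r": r,
                    "delta_0": d0,
                    "r2_0": m0.r2,
                    "dprime_0": m0.dprime,
                    "delta_n": mn.delta,
                    "r2_n": mn.r2,
                    "dprime_n": mn.dprime,
                    "pct_change_r2": pct,
                }
            )
    df = pd.DataFrame(rows)
    mean_pct = float(np.nanmean(df["pct_change_r2"].to_numpy()))
    return df, mean_pct
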