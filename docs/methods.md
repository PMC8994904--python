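# Methods

`qgvar` simulates quantitative-trait variation in populations of biallelic
genes and partitions the genotypic variance, generation by generation, into
additive, dominance, and digenic epistatic components under three jointly
acting forces: linkage disequilibrium (LD), inbreeding by selfing, and
digenic epistasis. This note records the model, the numerical choices, and
the limits of what the simulations can show.

## Model

### Genome and trait

A genome is `n_chrom` chromosomes of equal length (cM) carrying equally
spaced genes (first gene at position 0). Map distance converts to a
recombination fraction with Haldane's function, `r = (1 − e^(−2d/100))/2`,
with `r = 1/2` across chromosomes. No interference is modelled; because the
map function is Markovian, the recombination fraction between any two genes
equals the function of their map distance, which is what the closed-form
theory assumes.

Each gene has genotypic values `m − a`, `m + d`, `m + a` for 0, 1, 2 copies
of the trait-increasing allele. Per-gene `a > 0` is sampled (uniform on
[0.5, 1.5], then rescaled) so that the sums `Σ(m + a)` and `Σ(m − a)` equal
the configured maximum and minimum homozygote genotypic values; `m` is split
equally across genes. The degree of dominance `d/a` is uniform on
[0, 2 × mean] with positive sign, so the configured mean (default 0.6,
positive dominance) is the expectation. Defaults follow the simulated
grain-yield trait: extremes 160/30 g per plant, phenotypic bounds 180/10,
broad-sense heritability H² = 0.2. The error variance is
`σ²_E = σ²_G (1 − H²)/H²`; phenotypes outside the phenotypic bounds are
avoided by resampling the error term.

### Founder populations in LD

A founder is produced by crossing two linkage-equilibrium (LE) populations
and random-mating the F1 once, giving unrelated Hardy–Weinberg individuals
with gametic LD

    Δ_ab = [(1 − 2 r_ab)/4] (p_a1 − p_a2)(p_b1 − p_b2)

per gene pair (indices 1, 2 are the parental populations). Per-locus
parental frequencies are sampled uniformly with parent 1 on
[mean, mean + δ] and parent 2 on [mean − δ, mean], clipped to (0.02, 0.98).
Parent 1 therefore carries the higher frequency of every trait-increasing
allele, all crosses are in coupling phase, and the founder LD is
predominantly positive — the regime in which random mating erodes genetic
variance. Sampling both parents independently on the full interval was
considered and rejected: it yields founder Δ of random sign, whose
contributions to the genome-wide variances cancel, leaving the variance
trajectories nearly flat under random mating. The dispersion δ sets the LD
level: 0.45 (high), 0.25 (intermediate), 0.1 (low). This sampling scheme is
this package's own stand-in for an unpublished rule; only the implied Δ
formula above is exact.

### Generation advance

Random mating draws distinct parent pairs uniformly with replacement
(constant N, F = 0); gametic LD then decays as `Δ_n = (1 − r)^n Δ_0` at
constant allele frequencies. Selfing produces one offspring per parent from
two independent meioses, so the expected inbreeding coefficient follows
`F_n = 1 − (1/2)^n`. Neither scheme models selection, mutation, migration,
or overlapping generations.

### Two-locus distribution under selfing

Under selfing with linkage the two double-heterozygote phases (AB/ab vs
Ab/aB) have different dynamics, so the genotype distribution is tracked
over the ten unordered haplotype pairs. The selfing transition matrix
follows from each state's meiotic gamete distribution (parental haplotypes
with probability (1 − r)/2 each, recombinants r/2 each; offspring = two
independent gametes). The chain preserves allele frequencies exactly and
halves single-locus heterozygosity per generation; it is validated against
the forward simulator rather than against any printed table.

An exact consequence worth recording: the gametic-pool LD under selfing
converges to `Δ_∞/Δ_0 = 1/(1 + 2r)`, so unlinked pairs lose 75% of their
gametic r² and a 200 cM chromosome loses on average about 60% after ten
selfing generations. Published descriptions of selfing as leaving LD nearly
intact (a decrease around 14%) are not reproducible from any LD statistic
we examined on this model (gametic r², D′, initial-r²-weighted averages,
Burrows' composite disequilibrium with or without the (1 + F) correction);
the package reports the gametic-pool quantity, which is the measure the
variance theory is written in.

### Effect decomposition

For a gene pair with 3×3 genotypic values `G_ij`, the 36-parameter model

    G = M + α_i + α_j + α_k + α_l + δ_ij + δ_kl + (αα)·4 + (αδ)·2 + (δα)·2 + (δδ)

is saturated over the nine dosage cells once each effect class satisfies
zero-sum restrictions weighted by allele frequencies. Because both mating
schemes leave allele frequencies invariant, the effects are the noninbred
linkage-equilibrium reference effects, solved once per pair from the
stacked incidence/restriction system by least squares (the weight matrix of
genotype probabilities is immaterial for a saturated model). Inbreeding and
LD enter through the generation-n genotype distribution, under which the
effect variables acquire generally nonzero means:

- E(A) = 0 at any inbreeding level (allele frequencies do not change);
- E(D)^(n) = p_a q_a F (δ_AA − 2δ_Aa + δ_aa) + p_b q_b F (δ_BB − 2δ_Bb + δ_bb);
- E(AA) ≠ 0 only under LD; E(AD), E(DA) ≠ 0 only with inbreeding and
  unequal allele frequencies; E(DD) ≠ 0 only with inbreeding or LD.

Each component is centered by its current mean, so E(G) = M_F every
generation, with M_F = M − 2Fpqd summed over loci for the nonepistatic
part. Variances and covariances of the centered components under the exact
two-locus distribution reproduce the closed-form expressions for
σ²_A^(n), σ²_D^(n), σ_{A,D}^(n) (with the constants
c₁ = 2{1 − [(1 − 2r)/2]^n}/(1 + 2r) and c = 1 − 2r(1 − r)) to machine
precision; the tests pin this agreement at relative 1e−8 over 200 random
parameter draws, and the identity σ²_G = Σ variances + 2 Σ covariances is
algebraic.

For a multilocus genome, nonepistatic loci contribute per-locus additive
and dominance values from the single-locus marginal theory; each
interacting pair contributes all six component values from its own solved
effect set. Pairs spanning chromosomes use r = 1/2. Per-individual values
are evaluated on the simulated genotypes; the per-generation variance
components are sample variances/covariances over the N individuals
("parametric genetic values, empirical frequencies").

### Digenic epistasis

The seven types are equality patterns over the nine cells, reproducing the
F2 ratios 9:7, 15:1, 12:3:1, 9:3:4, 13:3, 9:6:1 and 9:3:3:1 exactly (tested
in rational arithmetic). Interacting genes are a configured fraction of the
genome, paired uniformly at random (each epistatic gene in exactly one
pair, pairs may span chromosomes); under admixture each pair draws its type
uniformly from the seven.

Infinitely many grids satisfy a given pattern, so the magnitude of the
epistatic deviations must be pinned down by convention. The package's rule:

1. compute the pair's nonepistatic V(A) + V(D) at the founder distribution;
2. set V(I) = ratio × (V(A) + V(D)) (default ratio 1) and sample
   I₂₂ ~ N(0, V(I));
3. collapse each equality class onto the founder-frequency-weighted mean of
   its nonepistatic values — the minimum-norm class-constant grid — except
   the class containing AABB, which is set to the nonepistatic AABB value
   plus I₂₂.

The equality pattern therefore holds to machine precision in every sampled
grid, and the AABB deviation is exactly the sampled I₂₂. With ratio = 0 the
plain nonepistatic grid is returned. This construction is a documented
stand-in for an unpublished rule, and it is the single largest source of
quantitative freedom in the whole pipeline: it fixes the absolute scale of
the epistatic variances. In our runs the epistatic-variance fraction of
σ²_G ranks across populations as expected (intermediate-LD/0.3 ≈ 3× the
high-LD/0.5 fraction; low-LD/0.5 between them; intermediate-LD/0.7
smallest) but sits at roughly half the published absolute level, and the
dominance-x-dominance variance retains somewhat more of its founder value
at complete inbreeding (≈ −70% rather than ≤ −76%). Two acceptance checks
tied to those absolute levels are left failing rather than adjusting the
template to meet them.

## Problem sizes and defaults

The study conditions are 400 genes on 10 chromosomes (200 cM for one
gene/5 cM; 50 cM for one gene/cM), N = 5000 individuals per generation, 10
generations, ratio 1, H² = 0.2, and 10 seed replicates for every
band-type comparison; trajectory statistics are evaluated on replicate
means. Monte-Carlo cross-validation tests use N = 50 000–200 000
individuals for two-gene checks and 3–4 standard-error tolerances. These
sizes run a full scenario in about a second; unit tests use smaller
genomes (2 chromosomes × 20 genes, N a few hundred) where only code paths,
not published quantities, are at stake.

## What the generator does and does not emulate

The synthetic populations have exactly the structure the closed-form theory
assumes: unlinked founders in Hardy–Weinberg proportions with the crossing
LD, no selection or mutation, equal gene spacing, and error-free genotypes.
Real populations violate most of these (variable gene density and effect
distributions, selection during inbreeding, nonrandom mating structure),
so passing tests demonstrate internal consistency of theory and simulator
— the closed forms, the recursion, and the forward simulation agree — not
that any particular crop population behaves this way.

## Known limitations

- Digenic epistasis only; no three-locus terms, no gene × environment, one
  trait.
- The epistatic-grid template is a stand-in (see above); absolute epistatic
  variance levels depend on it.
- The selfing LD summary is a gametic-pool quantity; composite
  (genotypic) disequilibrium is not implemented.
- Pedigree inbreeding F is the expectation 1 − (1/2)^n, not the realized
  identity-by-descent of each individual.
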