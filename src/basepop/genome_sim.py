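"""Diploid biallelic genomes: layout, initialisation, mutation, meiosis and burn-in.

The genome is a set of chromosomes of fixed genetic length carrying two
classes of evenly spaced biallelic loci:

* *non-marker* (neutral) loci, used to monitor genome-wide diversity, and
* *marker* loci (SNP-like), used to estimate relationships between
  candidates when optimising founder contributions.

Alleles are coded 0/1.  An individual's genotype is two haplotypes, each a
0/1 vector over all loci in genome order.  Meiosis follows a crossover
process with a Poisson(1) number of crossovers per Morgan, placed uniformly
without interference, and a uniformly chosen starting strand per chromosome.
Recurrent symmetric mutation (0 <-> 1) maintains polymorphism during the
burn-in that brings the founder population to mutation-drift equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Sequence

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "GenomeSpec",
    "PopulationState",
    "init_random_population",
    "mutate_cohort",
    "make_gamete",
    "cohort_gametes",
    "reproduce",
    "run_burnin",
    "equilibrium_heterozygosity",
]

MALE = 0
FEMALE = 1


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its preconditions."""


@dataclass(frozen=True)
class GenomeSpec:
    """Genome architecture.

    Parameters
    ----------
    n_chromosomes
        Number of chromosomes.
    chromosome_length
        Genetic length of each chromosome in Morgans.
    n_nonmarker_per_chrom
        Neutral (non-marker) loci per chromosome.
    n_marker_per_chrom
        Marker (SNP) loci per chromosome, interleaved with the neutral loci
        at evenly spaced ranks so that sparser marker panels are nested
        subsets of denser ones.
    mutation_rate
        Per-locus, per-generation probability of an allele flip (applied
        during the equilibrium burn-in only).
    """

    n_chromosomes: int = 20
    chromosome_length: float = 1.0
    n_nonmarker_per_chrom: int = 25_000
    n_marker_per_chrom: int = 100
    mutation_rate: float = 2.5e-3

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("need at least one chromosome")
        if self.n_nonmarker_per_chrom < 0 or self.n_marker_per_chrom < 0:
            raise ConfigurationError("locus counts must be non-negative")
        if self.n_loci_per_chrom < 1:
            raise ConfigurationError("need at least one locus per chromosome")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ConfigurationError("mutation rate must be in [0, 1)")
        if self.chromosome_length <= 0:
            raise ConfigurationError("chromosome length must be positive")

    @property
    def n_loci_per_chrom(self) -> int:
        return self.n_nonmarker_per_chrom + self.n_marker_per_chrom

    @property
    def n_loci(self) -> int:
        return self.n_chromosomes * self.n_loci_per_chrom

    @property
    def n_markers(self) -> int:
        return self.n_chromosomes * self.n_marker_per_chrom

    @cached_property
    def positions(self) -> np.ndarray:
        """Within-chromosome genetic positions (Morgans), strictly inside
        (0, chromosome_length), evenly spaced; identical for every
        chromosome."""
        t = self.n_loci_per_chrom
        return (np.arange(1, t + 1) / (t + 1)) * self.chromosome_length

    @cached_property
    def marker_mask(self) -> np.ndarray:
        """Boolean mask over all loci (genome order): True at marker loci."""
        t = self.n_loci_per_chrom
        m = self.n_marker_per_chrom
        mask_one = np.zeros(t, dtype=bool)
        if m > 0:
            ranks = ((np.arange(m) + 0.5) * t / m).astype(int)
            if len(np.unique(ranks)) != m:
                raise ConfigurationError("marker ranks collide; too many markers")
            mask_one[ranks] = True
        return np.tile(mask_one, self.n_chromosomes)

    @cached_property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(self.marker_mask)

    @cached_property
    def nonmarker_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.marker_mask)

    def marker_subset(self, n_markers: int) -> np.ndarray:
        """Global locus indices of an evenly spaced panel of ``n_markers``
        drawn from the available markers; panels are nested whenever one
        size divides the other."""
        total = self.n_markers
        if not 1 <= n_markers <= total:
            raise ConfigurationError(
                f"requested {n_markers} markers, {total} available"
            )
        pick = (np.arange(n_markers) * total) // n_markers
        return self.marker_indices[pick]

    def chrom_slices(self) -> list[slice]:
        t = self.n_loci_per_chrom
        return [slice(c * t, (c + 1) * t) for c in range(self.n_chromosomes)]


@dataclass
class PopulationState:
    """A cohort of diploid individuals.

    Attributes
    ----------
    ids
        Unique integer identifiers, shape ``(n,)``.
    sex
        0 = male, 1 = female, shape ``(n,)``.
    strain
        Strain label per individual (-1 when not applicable).
    sire, dam
        Parent ids (-1 for founders / untracked parents).
    haplotypes
        Allele array of shape ``(n, 2, n_loci)`` with values in {0, 1}.
    phenotype, bv
        Optional trait records, assigned once per individual by the trait
        machinery and carried unchanged thereafter.
    """

    ids: np.ndarray
    sex: np.ndarray
    strain: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    haplotypes: np.ndarray
    phenotype: np.ndarray | None = None
    bv: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == MALE)

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == FEMALE)

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele-1 dosage (0/1/2) per individual, optionally restricted to
        a locus index set."""
        if loci is None:
            return self.haplotypes.sum(axis=1, dtype=np.uint8)
        return self.haplotypes[:, :, loci].sum(axis=1, dtype=np.uint8)

    def subset(self, idx: np.ndarray) -> "PopulationState":
        return PopulationState(
            ids=self.ids[idx].copy(),
            sex=self.sex[idx].copy(),
            strain=self.strain[idx].copy(),
            sire=self.sire[idx].copy(),
            dam=self.dam[idx].copy(),
            haplotypes=self.haplotypes[idx].copy(),
            phenotype=None if self.phenotype is None else self.phenotype[idx].copy(),
            bv=None if self.bv is None else self.bv[idx].copy(),
        )

    @classmethod
    def concatenate(cls, pops: Sequence["PopulationState"]) -> "PopulationState":
        if not pops:
            raise ValueError("no populations to concatenate")
        phen = None
        bvs = None
        if all(p.phenotype is not None for p in pops):
            phen = np.concatenate([p.phenotype for p in pops])
        if all(p.bv is not None for p in pops):
            bvs = np.concatenate([p.bv for p in pops])
        out = cls(
            ids=np.concatenate([p.ids for p in pops]),
            sex=np.concatenate([p.sex for p in pops]),
            strain=np.concatenate([p.strain for p in pops]),
            sire=np.concatenate([p.sire for p in pops]),
            dam=np.concatenate([p.dam for p in pops]),
            haplotypes=np.concatenate([p.haplotypes for p in pops]),
            phenotype=phen,
            bv=bvs,
        )
        if len(np.unique(out.ids)) != out.n:
            raise ValueError("duplicate individual ids after concatenation")
        return out


def init_random_population(
    spec: GenomeSpec,
    n_males: int,
    n_females: int,
    rng: np.random.Generator | int,
    id_start: int = 0,
) -> PopulationState:
    """Create a cohort with alleles drawn independently per allele copy with
    probability 1/2, i.e. allele frequency 0.5 at every locus with
    Hardy-Weinberg and linkage equilibrium by construction."""
    if n_males < 1 or n_females < 1:
        raise ConfigurationError("need at least one individual of each sex")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    n = n_males + n_females
    haplos = rng.integers(0, 2, size=(n, 2, spec.n_loci), dtype=np.uint8)
    sex = np.concatenate(
        [np.full(n_males, MALE, dtype=np.int8), np.full(n_females, FEMALE, dtype=np.int8)]
    )
    return PopulationState(
        ids=np.arange(id_start, id_start + n, dtype=np.int64),
        sex=sex,
        strain=np.full(n, -1, dtype=np.int32),
        sire=np.full(n, -1, dtype=np.int64),
        dam=np.full(n, -1, dtype=np.int64),
        haplotypes=haplos,
    )


def mutate_cohort(
    pop: PopulationState, spec: GenomeSpec, rng: np.random.Generator
) -> PopulationState:
    """Apply recurrent symmetric mutation to a cohort, in place.

    The number of allele flips is Poisson with mean
    ``2 * n * n_chromosomes * mu * n_loci_per_chrom`` (every allele copy in
    the cohort mutates with probability ``mu``); targets are uniform over
    (individual, haplotype, locus) and a flip replaces allele ``a`` with
    ``1 - a``.  Returns the mutated cohort for convenience.
    """
    if pop.n == 0:
        raise ValueError("empty cohort")
    mean = 2.0 * pop.n * spec.n_chromosomes * spec.mutation_rate * spec.n_loci_per_chrom
    n_flips = rng.poisson(mean)
    if n_flips == 0:
        return pop
    flat = pop.haplotypes.reshape(-1)
    targets = rng.integers(0, flat.size, size=n_flips)
    # xor.at handles repeated targets as successive flips
    np.bitwise_xor.at(flat, targets, 1)
    return pop


def make_gamete(
    parent_haplotypes: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
    crossovers: Sequence[np.ndarray] | None = None,
    start: Sequence[int] | None = None,
    return_crossovers: bool = False,
):
    """Form one gamete from a parent's pair of haplotypes.

    Per chromosome, ``k ~ Poisson(chromosome_length)`` crossover points are
    placed uniformly (no interference); the gamete copies one haplotype and
    switches source at every point, starting from a strand chosen with
    probability 1/2.  ``crossovers``/``start`` override the random draws
    (one entry per chromosome), which pins down degenerate cases in tests.
    """
    if parent_haplotypes.shape[0] != 2:
        raise ValueError("parent must have exactly 2 haplotypes")
    gamete = np.empty(spec.n_loci, dtype=np.uint8)
    drawn: list[np.ndarray] = []
    for c, sl in enumerate(spec.chrom_slices()):
        if crossovers is None:
            k = rng.poisson(spec.chromosome_length)
            points = np.sort(rng.uniform(0.0, spec.chromosome_length, size=k))
        else:
            points = np.sort(np.asarray(crossovers[c], dtype=float))
        s = int(rng.integers(0, 2)) if start is None else int(start[c])
        src = (s + np.searchsorted(points, spec.positions)) % 2
        hap = parent_haplotypes[:, sl]
        gamete[sl] = np.where(src == 0, hap[0], hap[1])
        drawn.append(points)
    if return_crossovers:
        return gamete, drawn
    return gamete


def cohort_gametes(
    parent_haplotypes: np.ndarray, spec: GenomeSpec, rng: np.random.Generator
) -> np.ndarray:
    """Form one gamete from each of ``g`` parents' haplotype pairs, vectorised.

    Uses the interval representation of the crossover process: under a
    Poisson process of rate 1 per Morgan, the source strand switches between
    adjacent loci separated by ``d`` Morgans with probability
    ``(1 - exp(-2 d)) / 2`` (probability of an odd number of points in the
    interval), independently across intervals, and the starting strand is
    uniform.  This is exactly the locus-level law of :func:`make_gamete`
    (Haldane mapping), but costs one vectorised pass per chromosome.

    Parameters
    ----------
    parent_haplotypes
        Array of shape ``(g, 2, n_loci)``.

    Returns
    -------
    Array of shape ``(g, n_loci)``.
    """
    g = parent_haplotypes.shape[0]
    out = np.empty((g, spec.n_loci), dtype=np.uint8)
    lc = spec.n_loci_per_chrom
    # evenly spaced loci share one inter-locus distance; crossovers before
    # the first locus are absorbed by the uniform starting strand
    d = spec.positions[1] - spec.positions[0] if lc > 1 else 0.0
    n_intervals = g * (lc - 1)
    for sl in spec.chrom_slices():
        switches = np.zeros((g, lc), dtype=np.uint8)
        switches[:, 0] = rng.integers(0, 2, size=g, dtype=np.uint8)
        if n_intervals and d > 0:
            # the Poisson process over all (gamete, interval) cells: a
            # Poisson total placed uniformly, with parity toggling per cell
            k = rng.poisson(n_intervals * d)
            if k:
                flat = rng.integers(0, n_intervals, size=k)
                np.bitwise_xor.at(
                    switches, (flat // (lc - 1), flat % (lc - 1) + 1), 1
                )
        # uint8 cumsum wraps mod 256 (even), so parity is preserved
        src = np.bitwise_and(np.cumsum(switches, axis=1, dtype=np.uint8), 1)
        hap = parent_haplotypes[:, :, sl]
        out[:, sl] = np.where(src == 0, hap[:, 0, :], hap[:, 1, :])
    return out


def reproduce(
    parents: PopulationState,
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    offspring_sex: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
    id_start: int = 0,
    strain: int | np.ndarray = -1,
) -> PopulationState:
    """Produce an offspring cohort; one offspring per (sire, dam) entry."""
    sire_idx = np.asarray(sire_idx)
    dam_idx = np.asarray(dam_idx)
    if len(sire_idx) != len(dam_idx) or len(sire_idx) != len(offspring_sex):
        raise ValueError("sire/dam/sex arrays must have equal length")
    if np.any(parents.sex[sire_idx] != MALE) or np.any(parents.sex[dam_idx] != FEMALE):
        raise ValueError("sires must be male and dams female")
    n = len(sire_idx)
    paternal = cohort_gametes(parents.haplotypes[sire_idx], spec, rng)
    maternal = cohort_gametes(parents.haplotypes[dam_idx], spec, rng)
    haplos = np.stack([paternal, maternal], axis=1)
    strain_arr = (
        np.full(n, strain, dtype=np.int32)
        if np.isscalar(strain)
        else np.asarray(strain, dtype=np.int32)
    )
    return PopulationState(
        ids=np.arange(id_start, id_start + n, dtype=np.int64),
        sex=np.asarray(offspring_sex, dtype=np.int8),
        strain=strain_arr,
        sire=parents.ids[sire_idx].astype(np.int64),
        dam=parents.ids[dam_idx].astype(np.int64),
        haplotypes=haplos,
    )


def random_mating_generation(
    pop: PopulationState,
    n_males: int,
    n_females: int,
    spec: GenomeSpec,
    rng: np.random.Generator,
    id_start: int = 0,
    strain: int = -1,
) -> PopulationState:
    """One discrete generation of random mating: each offspring's sire (dam)
    is drawn uniformly with replacement from the current males (females)."""
    males = pop.males()
    females = pop.females()
    if len(males) == 0 or len(females) == 0:
        raise ConfigurationError("cannot mate: a sex class is empty")
    n = n_males + n_females
    sire_idx = males[rng.integers(0, len(males), size=n)]
    dam_idx = females[rng.integers(0, len(females), size=n)]
    sex = np.concatenate(
        [np.full(n_males, MALE, dtype=np.int8), np.full(n_females, FEMALE, dtype=np.int8)]
    )
    return reproduce(pop, sire_idx, dam_idx, sex, spec, rng, id_start, strain)


def run_burnin(
    spec: GenomeSpec,
    n: int,
    n_generations: int,
    rng: np.random.Generator | int,
) -> PopulationState:
    """Simulate the mutation-drift equilibrium population.

    Starting from a random (allele frequency 0.5) population of ``n``
    individuals with equal sexes, run ``n_generations`` discrete generations
    of random mating with constant size, applying recurrent mutation to each
    new cohort.  With enough generations, expected heterozygosity settles at
    the symmetric two-allele mutation-drift equilibrium (see
    :func:`equilibrium_heterozygosity`).

    Pedigree links are not tracked during burn-in (sire/dam stay -1): every
    later analysis treats the equilibrium population as unrelated founders.
    """
    if n % 2 != 0:
        raise ConfigurationError("burn-in population size must be even (equal sexes)")
    if n_generations < 0:
        raise ConfigurationError("number of generations must be >= 0")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    half = n // 2
    pop = init_random_population(spec, half, half, rng)
    for _ in range(n_generations):
        pop = random_mating_generation(pop, half, half, spec, rng)
        pop.sire[:] = -1
        pop.dam[:] = -1
        mutate_cohort(pop, spec, rng)
    return pop


def equilibrium_heterozygosity(pop_size: int, mutation_rate: float) -> float:
    """Expected heterozygosity at the symmetric two-allele mutation-drift
    equilibrium.

    Let ``Q`` be the probability that two allele copies drawn at random from
    the population are identical in state.  One generation of random mating
    in a population of ``2N`` allele copies with symmetric flip rate ``mu``
    gives the recursion::

        Q' = ((1-mu)^2 + mu^2) * (1/(2N) + (1 - 1/(2N)) Q)
             + 2 mu (1-mu) * (1 - 1/(2N)) * (1 - Q)

    (two copies either coalesce or not, then each mutates independently;
    identity survives if both or neither flipped).  The fixed point is linear
    in ``Q`` and expected heterozygosity is ``1 - Q*``.
    """
    if pop_size < 1:
        raise ConfigurationError("population size must be positive")
    a = (1.0 - mutation_rate) ** 2 + mutation_rate**2
    b = 2.0 * mutation_rate * (1.0 - mutation_rate)
    r = 1.0 / (2.0 * pop_size)
    # Q* = (a r + b (1-r)) / (1 - (a - b)(1 - r))
    q_star = (a * r + b * (1.0 - r)) / (1.0 - (a - b) * (1.0 - r))
    return 1.0 - q_star
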