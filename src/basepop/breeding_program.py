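"""Multi-generation phenotypic truncation selection from a base population.

Each generation the selected breeders are mated at random into monogamous
couples, every couple leaves a fixed number of offspring, and the top
candidates per sex on phenotype become the next generation's breeders.
With 100 couples x 10 offspring and 100 selected per sex the selected
proportion is 20%, a standardised selection intensity of about 1.4.

Tracked per generation (on the selected group): mean phenotype, mean
breeding value, additive variance, expected heterozygosity at the
non-marker loci, and genealogical inbreeding/coancestry with their rates,
taking the base-population founders as unrelated and non-inbred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genome_sim import (
    FEMALE,
    MALE,
    GenomeSpec,
    PopulationState,
    reproduce,
)
from .relatedness_metrics import expected_heterozygosity, rate
from .trait_model import TraitModel, phenotype_cohort

__all__ = [
    "BreedingConfig",
    "selection_intensity",
    "mate_randomly",
    "select_truncation",
    "run_program",
]


@dataclass(frozen=True)
class BreedingConfig:
    n_couples: int = 100
    offspring_per_couple: int = 10
    selected_per_sex: int = 100
    generations: int = 10

    def __post_init__(self) -> None:
        if min(
            self.n_couples,
            self.offspring_per_couple,
            self.selected_per_sex,
            self.generations,
        ) < 0:
            raise ValueError("breeding parameters must be non-negative")
        # offspring sexes alternate within family, so each sex class holds
        # n_couples * offspring_per_couple / 2 candidates
        if self.n_couples * self.offspring_per_couple < 2 * self.selected_per_sex:
            raise ValueError("not enough candidates to select from")

    @property
    def selected_proportion(self) -> float:
        return 2.0 * self.selected_per_sex / (self.n_couples * self.offspring_per_couple)


def selection_intensity(p: float) -> float:
    """Standardised selection differential for truncating the top fraction
    ``p`` of a normal distribution: ``i = phi(z) / p`` with ``z`` the
    truncation point."""
    if not 0.0 < p < 1.0:
        raise ValueError("selected proportion must be in (0, 1)")
    z = norm.ppf(1.0 - p)
    return float(norm.pdf(z) / p)


def mate_randomly(
    males: np.ndarray, females: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Uniform random perfect matching of males to females (monogamous
    couples).  Returns an array of shape (n_couples, 2) of the given
    indices."""
    males = np.asarray(males)
    females = np.asarray(females)
    if len(males) != len(females):
        raise ValueError("need equal numbers of males and females")
    return np.column_stack([rng.permutation(males), rng.permutation(females)])


def select_truncation(pop: PopulationState, n_per_sex: int) -> np.ndarray:
    """Top-n candidates per sex by phenotype; ties broken by ascending id."""
    if pop.phenotype is None:
        raise ValueError("candidates carry no phenotypes")
    keep = []
    for sex in (MALE, FEMALE):
        idx = np.flatnonzero(pop.sex == sex)
        if len(idx) < n_per_sex:
            raise ValueError("not enough candidates of a sex")
        order = np.lexsort((pop.ids[idx], -pop.phenotype[idx]))
        keep.append(idx[order[:n_per_sex]])
    return np.concatenate(keep)


def _offspring_kinship(
    parent_kin: np.ndarray, sire_pos: np.ndarray, dam_pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Kinship matrix of an offspring cohort from the parents' matrix.

    ``f(o, o') = (f(s,s') + f(s,d') + f(d,s') + f(d,d')) / 4`` for distinct
    offspring, and ``f(o, o) = (1 + F_o)/2`` with ``F_o = f(s, d)`` — the
    tabular method expressed as matrix indexing.
    """
    b = 0.5 * (parent_kin[sire_pos, :] + parent_kin[dam_pos, :])
    kin = 0.5 * (b[:, sire_pos] + b[:, dam_pos])
    inb = parent_kin[sire_pos, dam_pos]
    np.fill_diagonal(kin, 0.5 * (1.0 + inb))
    return kin, inb


def _mean_offdiag(kin: np.ndarray) -> float:
    n = kin.shape[0]
    return float((kin.sum() - np.trace(kin)) / (n * (n - 1)))


def run_program(
    base_pop: PopulationState,
    trait: TraitModel,
    spec: GenomeSpec,
    config: BreedingConfig,
    rng: np.random.Generator,
    v_e: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the breeding program and return (metrics, pedigree).

    The base population must carry phenotypes (founders keep the phenotypes
    assigned when their strains were expanded; they are not re-measured).
    Offspring phenotypes use a single program-level environmental variance:
    ``v_e`` if given, otherwise the mean of the founders' strain-calibrated
    values — cohorts mix strains, so a per-strain V_E no longer applies.

    Metrics rows cover generations 0..G, generation 0 being the selected
    founders themselves (pedigree F = f = 0 by the founder convention);
    rates are NaN at t = 0.
    """
    n_sel = config.selected_per_sex
    if len(base_pop.males()) != n_sel or len(base_pop.females()) != n_sel:
        raise ValueError("base population must hold selected_per_sex of each sex")
    if base_pop.phenotype is None:
        raise ValueError("base population must carry phenotypes")
    if v_e is None:
        if not trait.v_e_by_strain:
            raise ValueError("no environmental variance available")
        v_e = float(
            np.mean([trait.v_e_by_strain[int(s)] for s in base_pop.strain])
        )

    nonmarkers = spec.nonmarker_indices
    selected = base_pop
    n_tot = 2 * n_sel
    kin = np.zeros((n_tot, n_tot))
    np.fill_diagonal(kin, 0.5)
    inb = np.zeros(n_tot)

    ped_rows = [
        pd.DataFrame(
            {
                "id": selected.ids,
                "sire": -1,
                "dam": -1,
                "generation": 0,
            }
        )
    ]
    rows = []

    def record(t: int, pop: PopulationState, kin_m: np.ndarray, inb_v: np.ndarray):
        he = expected_heterozygosity(pop.dosages(nonmarkers))
        rows.append(
            {
                "generation": t,
                "phenotype_mean": float(pop.phenotype.mean()),
                "bv_mean": float(pop.bv.mean()),
                "v_a": float(pop.bv.var()),
                "he_nonmarker": he,
                "f_mean": _mean_offdiag(kin_m),
                "inbreeding_mean": float(inb_v.mean()),
            }
        )

    record(0, selected, kin, inb)
    next_id = int(base_pop.ids.max()) + 1

    for t in range(1, config.generations + 1):
        couples = mate_randomly(selected.males(), selected.females(), rng)
        k = config.offspring_per_couple
        sire_idx = np.repeat(couples[:, 0], k)
        dam_idx = np.repeat(couples[:, 1], k)
        # deterministic alternating sexes within family keep both sex
        # classes at exactly half the candidates
        fam_sex = np.tile(
            np.array([MALE] * (k // 2) + [FEMALE] * (k - k // 2), dtype=np.int8),
            config.n_couples,
        )
        offspring = reproduce(
            selected, sire_idx, dam_idx, fam_sex, spec, rng, next_id
        )
        next_id += offspring.n
        phenotype_cohort(offspring, trait, rng, v_e=v_e)
        ped_rows.append(
            pd.DataFrame(
                {
                    "id": offspring.ids,
                    "sire": offspring.sire,
                    "dam": offspring.dam,
                    "generation": t,
                }
            )
        )
        keep = select_truncation(offspring, n_sel)
        # positions of the kept offspring's parents within the previous
        # selected cohort drive the kinship recursion
        id_to_pos = {int(i): p for p, i in enumerate(selected.ids)}
        sire_pos = np.array([id_to_pos[int(s)] for s in offspring.sire[keep]])
        dam_pos = np.array([id_to_pos[int(d)] for d in offspring.dam[keep]])
        kin, inb = _offspring_kinship(kin, sire_pos, dam_pos)
        selected = offspring.subset(keep)
        record(t, selected, kin, inb)

    metrics = pd.DataFrame(rows)
    for col, out in (("f_mean", "delta_f"), ("inbreeding_mean", "delta_F")):
        series = metrics[col].to_numpy()
        metrics[out] = np.concatenate([[np.nan], rate(series)]) if len(series) > 1 else np.nan
    pedigree = pd.concat(ped_rows, ignore_index=True)
    return metrics, pedigree
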