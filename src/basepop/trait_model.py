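"""Additive polygenic trait: locus effects, phenotypes, breeding values.

The trait is controlled by ``n_sel`` additive "selective" loci drawn at
random from the whole genome (markers and non-markers alike).  An
individual's phenotype is

    P_j = mu_P + sum_i x_i a_i + e_j

where ``x_i`` is +1 / 0 / -1 for genotypes 11 / 01 / 00 at selective locus
``i``, ``a_i`` the additive effect, and ``e_j ~ N(0, V_E)`` an environmental
deviation.  Effects are sampled so that the expected additive variance in
the founding population equals ``V_A(0) = h2(0) * V_P(0)``; the
environmental variance is calibrated per strain at its founding so every
strain starts at the same heritability, and then kept constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_sim import GenomeSpec, PopulationState

__all__ = [
    "TraitModel",
    "sample_effects",
    "calibrate_ve",
    "phenotype_cohort",
    "additive_variance",
]


@dataclass
class TraitModel:
    """Trait architecture shared by all strains of one replicate."""

    selective_loci: np.ndarray  # locus indices, shape (n_sel,)
    effects: np.ndarray  # additive effects a_i, shape (n_sel,)
    trait_mean: float = 100.0
    v_p0: float = 30.0
    h2_0: float = 0.4
    v_e_by_strain: dict[int, float] = field(default_factory=dict)
    # genotype-score mean of the founding (pre-divergence) cohort; breeding
    # values are reported as deviations from it so unselected scenarios
    # start near 0
    bv_reference: float = 0.0

    @property
    def v_a0(self) -> float:
        return self.h2_0 * self.v_p0

    @property
    def n_sel(self) -> int:
        return len(self.selective_loci)

    def genotype_score(self, pop: PopulationState) -> np.ndarray:
        """Sum over selective loci of ``x_i a_i`` with x in {-1, 0, +1}."""
        x = pop.dosages(self.selective_loci).astype(np.float64) - 1.0
        return x @ self.effects

    def breeding_values(self, pop: PopulationState) -> np.ndarray:
        return self.genotype_score(pop) - self.bv_reference


def sample_effects(
    pop_at_founding: PopulationState,
    spec: GenomeSpec,
    rng: np.random.Generator,
    n_sel: int = 1000,
    trait_mean: float = 100.0,
    v_p0: float = 30.0,
    h2_0: float = 0.4,
) -> TraitModel:
    """Define the trait on the equilibrium population, once per replicate.

    Selective loci are drawn uniformly without replacement from all loci.
    Effects are i.i.d. Normal(0, V_A(0) / [2 p (1-p) n_sel]) where ``p`` is
    the mean allele-1 frequency across the chosen loci, so that the additive
    variance summed over loci is V_A(0) in expectation (LD covariances
    neglected).
    """
    if pop_at_founding.n < 1:
        raise ValueError("empty founding population")
    if not 1 <= n_sel <= spec.n_loci:
        raise ValueError("n_sel must be between 1 and the number of loci")
    loci = np.sort(rng.choice(spec.n_loci, size=n_sel, replace=False))
    v_a0 = h2_0 * v_p0
    p_bar = pop_at_founding.dosages(loci).mean() / 2.0
    if v_a0 > 0 and not 0.0 < p_bar < 1.0:
        raise ValueError("selective loci monomorphic: effect variance undefined")
    if v_a0 == 0.0:
        effects = np.zeros(n_sel)
    else:
        var_a = v_a0 / (2.0 * p_bar * (1.0 - p_bar) * n_sel)
        effects = rng.normal(0.0, np.sqrt(var_a), size=n_sel)
    trait = TraitModel(
        selective_loci=loci,
        effects=effects,
        trait_mean=trait_mean,
        v_p0=v_p0,
        h2_0=h2_0,
    )
    trait.bv_reference = float(trait.genotype_score(pop_at_founding).mean())
    return trait


def calibrate_ve(trait: TraitModel, strain_pop: PopulationState) -> TraitModel:
    """Fix a strain's environmental variance from the additive variance
    realised among its founders: ``V_E = V_A,strain(0) (1 - h2) / h2``.

    Stored in ``trait.v_e_by_strain`` and never recomputed, so heritability
    is exact at strain founding and drifts with V_A afterwards.
    """
    if strain_pop.n < 1:
        raise ValueError("empty strain")
    strain_ids = np.unique(strain_pop.strain)
    if len(strain_ids) != 1:
        raise ValueError("calibrate_ve expects a single-strain cohort")
    scores = trait.genotype_score(strain_pop)
    v_a_strain = float(scores.var())  # divisor n
    ratio = (1.0 - trait.h2_0) / trait.h2_0
    if v_a_strain == 0.0:
        warnings.warn(
            "strain has zero realised additive variance; "
            "falling back to the global V_A(0) for V_E calibration",
            stacklevel=2,
        )
        v_a_strain = trait.v_a0
    trait.v_e_by_strain[int(strain_ids[0])] = v_a_strain * ratio
    return trait


def phenotype_cohort(
    pop: PopulationState,
    trait: TraitModel,
    rng: np.random.Generator,
    v_e: float | None = None,
    store: bool = True,
) -> pd.DataFrame:
    """Assign phenotypes to a cohort and return one record per individual.

    ``v_e`` overrides the per-strain environmental variances (used by the
    breeding program where cohorts mix strains); otherwise every strain in
    the cohort must have a calibrated V_E.
    """
    scores = trait.genotype_score(pop)
    if v_e is not None:
        sd = np.full(pop.n, np.sqrt(v_e))
    else:
        sd = np.empty(pop.n)
        for s in np.unique(pop.strain):
            if int(s) not in trait.v_e_by_strain:
                raise KeyError(f"no calibrated V_E for strain {int(s)}")
            sd[pop.strain == s] = np.sqrt(trait.v_e_by_strain[int(s)])
    env = rng.normal(0.0, 1.0, size=pop.n) * sd
    phen = trait.trait_mean + scores + env
    bv = scores - trait.bv_reference
    if store:
        pop.phenotype = phen
        pop.bv = bv
    return pd.DataFrame(
        {
            "id": pop.ids,
            "sex": pop.sex,
            "strain": pop.strain,
            "genotype_score": scores,
            "environment": env,
            "phenotype": phen,
            "bv": bv,
        }
    )


def additive_variance(bv: np.ndarray) -> float:
    """Additive variance of a cohort: population variance (divisor n) of
    breeding values."""
    bv = np.asarray(bv, dtype=float)
    if bv.size < 2:
        raise ValueError("need at least two individuals")
    return float(bv.var())
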