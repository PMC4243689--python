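"""Create candidate strains and diverge them under drift or selection.

Ten strains are founded by sampling disjoint groups from the equilibrium
population.  Each strain then evolves for a fixed number of discrete,
mutation-free generations under one of three regimes:

* ``drift`` — random selection, size alone governs diversity loss;
* ``directional`` — truncation selection on phenotype within each sex,
  mimicking already-improved commercial strains;
* ``stabilizing`` — Gaussian viability selection toward an optimum,
  mimicking wild strains with local adaptations.

Afterwards every strain is expanded to 50 males + 50 females in one
generation of random mating, yielding the pool of candidates from which the
base population is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .genome_sim import (
    FEMALE,
    MALE,
    ConfigurationError,
    GenomeSpec,
    PopulationState,
    random_mating_generation,
    reproduce,
)
from .trait_model import TraitModel, phenotype_cohort

__all__ = [
    "StrainRegime",
    "ScenarioSpec",
    "load_scenario",
    "found_strains",
    "diverge_drift",
    "diverge_directional",
    "diverge_stabilizing",
    "diverge_strain",
    "gaussian_fitness",
    "expand_strain",
]

REGIMES = ("drift", "directional", "stabilizing")


@dataclass(frozen=True)
class StrainRegime:
    """Divergence rule for one strain."""

    strain_id: int
    regime: str
    n_males: int
    n_females: int
    n_selected_per_sex: int | None = None  # directional only
    p_opt: float | None = None  # stabilizing only
    omega2: float | None = None  # stabilizing only

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.n_males < 1 or self.n_females < 1:
            raise ConfigurationError("strain sizes must be positive")
        if self.regime == "directional":
            if self.n_selected_per_sex is None:
                raise ConfigurationError("directional regime needs n_selected_per_sex")
            if not 1 <= self.n_selected_per_sex <= min(self.n_males, self.n_females):
                raise ConfigurationError("n_selected_per_sex out of range")
        if self.regime == "stabilizing":
            if self.p_opt is None or self.omega2 is None:
                raise ConfigurationError("stabilizing regime needs p_opt and omega2")
            if self.omega2 <= 0:
                raise ConfigurationError("omega2 must be positive")


@dataclass
class ScenarioSpec:
    name: str
    regimes: list[StrainRegime]
    divergence_generations: int = 20
    expansion_per_sex: int = 50

    def __post_init__(self) -> None:
        ids = [r.strain_id for r in self.regimes]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate strain ids in scenario")

    @property
    def n_strains(self) -> int:
        return len(self.regimes)


def load_scenario(name_or_path: str | Path) -> ScenarioSpec:
    """Load a scenario preset by name (``drift``, ``selection``,
    ``stabilizing``, ``stabilizing_large``, ``mixed``, ``four_strains``) or
    from a YAML file with the same schema."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        ref = resources.files("basepop").joinpath("presets", f"{name_or_path}.yaml")
        try:
            raw = yaml.safe_load(ref.read_text())
        except FileNotFoundError:
            raise ConfigurationError(f"unknown scenario preset {name_or_path!r}")
    regimes = [StrainRegime(**entry) for entry in raw["strains"]]
    return ScenarioSpec(
        name=raw.get("name", str(name_or_path)),
        regimes=regimes,
        divergence_generations=int(raw.get("divergence_generations", 20)),
        expansion_per_sex=int(raw.get("expansion_per_sex", 50)),
    )


def found_strains(
    eq_pop: PopulationState,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    disjoint: bool = True,
) -> list[PopulationState]:
    """Sample each strain's founders at random from the equilibrium
    population, respecting per-sex sizes.  With ``disjoint=True`` (default)
    strains share no founders."""
    males = eq_pop.males()
    females = eq_pop.females()
    need_m = sum(r.n_males for r in scenario.regimes)
    need_f = sum(r.n_females for r in scenario.regimes)
    if disjoint and (need_m > len(males) or need_f > len(females)):
        raise ConfigurationError(
            "equilibrium population too small to found all strains disjointly"
        )
    pool_m = rng.permutation(males)
    pool_f = rng.permutation(females)
    strains = []
    off_m = off_f = 0
    for reg in scenario.regimes:
        if disjoint:
            take_m = pool_m[off_m : off_m + reg.n_males]
            take_f = pool_f[off_f : off_f + reg.n_females]
            off_m += reg.n_males
            off_f += reg.n_females
        else:
            if reg.n_males > len(males) or reg.n_females > len(females):
                raise ConfigurationError("not enough individuals of a sex")
            take_m = rng.choice(males, size=reg.n_males, replace=False)
            take_f = rng.choice(females, size=reg.n_females, replace=False)
        sub = eq_pop.subset(np.concatenate([take_m, take_f]))
        sub.strain[:] = reg.strain_id
        strains.append(sub)
    return strains


def gaussian_fitness(
    p: np.ndarray | float, p_opt: float, omega2: float
) -> np.ndarray | float:
    """Survival probability under stabilizing selection:
    ``W(P) = exp(-(P - P_opt)^2 / (2 omega^2))``."""
    if omega2 <= 0:
        raise ConfigurationError("omega2 must be positive")
    return np.exp(-((np.asarray(p, dtype=float) - p_opt) ** 2) / (2.0 * omega2))


def _next_id(pop: PopulationState, id_start: int | None) -> int:
    return int(pop.ids.max()) + 1 if id_start is None else id_start


def diverge_drift(
    strain: PopulationState,
    spec: GenomeSpec,
    gens: int,
    rng: np.random.Generator,
    trait: TraitModel | None = None,
    id_start: int | None = None,
) -> PopulationState:
    """Random selection: parents drawn uniformly with replacement within
    sex; constant per-sex size; no mutation."""
    n_m, n_f = len(strain.males()), len(strain.females())
    sid = int(strain.strain[0])
    nid = _next_id(strain, id_start)
    for _ in range(gens):
        strain = random_mating_generation(strain, n_m, n_f, spec, rng, nid, sid)
        nid += strain.n
        if trait is not None:
            phenotype_cohort(strain, trait, rng)
    return strain


def diverge_directional(
    strain: PopulationState,
    trait: TraitModel,
    spec: GenomeSpec,
    n_selected_per_sex: int,
    gens: int,
    rng: np.random.Generator,
    id_start: int | None = None,
) -> PopulationState:
    """Directional truncation selection: each generation keep the top
    ``n_selected_per_sex`` phenotypes within each sex (ties broken by id),
    then mate the survivors at random to restore the per-sex size."""
    n_m, n_f = len(strain.males()), len(strain.females())
    if n_selected_per_sex > min(n_m, n_f):
        raise ConfigurationError("cannot select more parents than available")
    sid = int(strain.strain[0])
    nid = _next_id(strain, id_start)
    if strain.phenotype is None:
        phenotype_cohort(strain, trait, rng)
    for _ in range(gens):
        keep = _top_per_sex(strain, n_selected_per_sex)
        parents = strain.subset(keep)
        strain = random_mating_generation(parents, n_m, n_f, spec, rng, nid, sid)
        nid += strain.n
        phenotype_cohort(strain, trait, rng)
    return strain


def _top_per_sex(pop: PopulationState, n_per_sex: int) -> np.ndarray:
    keep = []
    for sex in (MALE, FEMALE):
        idx = np.flatnonzero(pop.sex == sex)
        order = np.lexsort((pop.ids[idx], -pop.phenotype[idx]))
        keep.append(idx[order[:n_per_sex]])
    return np.concatenate(keep)


def diverge_stabilizing(
    strain: PopulationState,
    trait: TraitModel,
    spec: GenomeSpec,
    p_opt: float,
    omega2: float,
    gens: int,
    rng: np.random.Generator,
    id_start: int | None = None,
) -> PopulationState:
    """Stabilizing viability selection: candidates survive with probability
    ``W(P)``; survivors mate at random to restore the per-sex size.  If a
    sex class has no survivors, parents for that sex are sampled
    proportionally to ``W`` instead (acceptance would stall)."""
    n_m, n_f = len(strain.males()), len(strain.females())
    sid = int(strain.strain[0])
    nid = _next_id(strain, id_start)
    if strain.phenotype is None:
        phenotype_cohort(strain, trait, rng)
    for _ in range(gens):
        w = gaussian_fitness(strain.phenotype, p_opt, omega2)
        survive = rng.random(strain.n) < w
        parent_idx = []
        for sex in (MALE, FEMALE):
            sex_idx = np.flatnonzero((strain.sex == sex) & survive)
            if len(sex_idx) == 0:
                sex_all = np.flatnonzero(strain.sex == sex)
                ws = np.asarray(w)[sex_all]
                if ws.sum() == 0:
                    ws = np.ones_like(ws)
                probs = ws / ws.sum()
                sex_idx = rng.choice(sex_all, size=1, replace=True, p=probs)
            parent_idx.append(sex_idx)
        parents = strain.subset(np.concatenate(parent_idx))
        strain = random_mating_generation(parents, n_m, n_f, spec, rng, nid, sid)
        nid += strain.n
        phenotype_cohort(strain, trait, rng)
    return strain


def diverge_strain(
    strain: PopulationState,
    regime: StrainRegime,
    trait: TraitModel,
    spec: GenomeSpec,
    gens: int,
    rng: np.random.Generator,
    id_start: int | None = None,
) -> PopulationState:
    """Dispatch divergence according to the regime."""
    if regime.regime == "drift":
        return diverge_drift(strain, spec, gens, rng, trait, id_start)
    if regime.regime == "directional":
        return diverge_directional(
            strain, trait, spec, regime.n_selected_per_sex, gens, rng, id_start
        )
    return diverge_stabilizing(
        strain, trait, spec, regime.p_opt, regime.omega2, gens, rng, id_start
    )


def expand_strain(
    strain: PopulationState,
    spec: GenomeSpec,
    rng: np.random.Generator,
    trait: TraitModel | None = None,
    per_sex: int = 50,
    id_start: int | None = None,
) -> PopulationState:
    """Expand a strain to ``per_sex`` males and females in a single
    generation of random selection and mating; candidates receive their
    phenotypes here if a trait is given."""
    if len(strain.males()) == 0 or len(strain.females()) == 0:
        raise ConfigurationError("cannot expand: a sex class is empty")
    nid = _next_id(strain, id_start)
    sid = int(strain.strain[0])
    out = random_mating_generation(strain, per_sex, per_sex, spec, rng, nid, sid)
    if trait is not None:
        phenotype_cohort(out, trait, rng)
    return out
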