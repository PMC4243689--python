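"""Replicated factorial experiments over scenario x strategy x marker panel.

One replicate shares a single burn-in, trait and strain set across every
strategy and marker panel (paired design), so differences between
strategies are not confounded by the candidate pool.  Outputs are tidy
DataFrames: per-strain percentage contributions, base-population phenotype
and non-marker heterozygosity, and (optionally) per-generation breeding
metrics.

Two scale presets are provided.  ``full_plan`` carries the full-scale
simulation conditions (20 chromosomes x 25,000 non-marker loci, N = 1000, 1000
burn-in generations, 100 replicates); ``desk_plan`` is a reduced genome
(10 chromosomes, 200 non-marker + 500 marker loci each, N = 400, 150
burn-in generations) that runs in minutes while preserving the qualitative
behaviour of the strategies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .breeding_program import BreedingConfig, run_program
from .founder_optimizer import (
    AnnealSchedule,
    ContributionSolution,
    optimize_IC,
    optimize_IP,
    solve_strain_strategy,
    strategy_E,
)
from .genome_sim import GenomeSpec, PopulationState, run_burnin
from .relatedness_metrics import (
    expected_heterozygosity,
    molecular_coancestry,
    strain_mean_coancestry,
)
from .strain_builder import (
    ScenarioSpec,
    diverge_strain,
    expand_strain,
    found_strains,
    load_scenario,
)
from .trait_model import TraitModel, calibrate_ve, sample_effects

__all__ = ["ExperimentPlan", "desk_plan", "full_plan", "run_experiment", "summarize"]


@dataclass
class ExperimentPlan:
    scenarios: list[str] = field(default_factory=lambda: ["mixed"])
    strategies: list[str] = field(default_factory=lambda: ["E", "MC", "MP", "IC", "IP"])
    marker_numbers: list[int] | None = None  # None -> all available markers
    n_replicates: int = 10
    seed: int = 0
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    pop_size: int = 1000
    burnin_generations: int = 1000
    n_selective_loci: int = 1000
    n_per_sex: int = 100
    run_breeding: bool = False
    breeding: BreedingConfig = field(default_factory=BreedingConfig)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for s in self.strategies:
            if s not in ("E", "MC", "MP", "IC", "IP"):
                raise ValueError(f"unknown strategy {s!r}")
        if self.marker_numbers is not None:
            for m in self.marker_numbers:
                if not 1 <= m <= self.genome.n_markers:
                    raise ValueError("marker panel larger than available markers")


def full_plan(**overrides) -> ExperimentPlan:
    """Full-scale simulation conditions (slow; intended for cluster runs)."""
    base = ExperimentPlan(
        scenarios=["drift", "selection", "stabilizing", "mixed"],
        marker_numbers=[100, 1000, 100_000],
        n_replicates=100,
        genome=GenomeSpec(
            n_chromosomes=20,
            n_nonmarker_per_chrom=25_000,
            n_marker_per_chrom=5000,
            mutation_rate=2.5e-3,
        ),
        pop_size=1000,
        burnin_generations=1000,
        n_selective_loci=1000,
        run_breeding=True,
    )
    return replace(base, **overrides)


def desk_plan(**overrides) -> ExperimentPlan:
    """Reduced-scale conditions that preserve the qualitative behaviour.

    Genome of 10 chromosomes x (200 non-marker + 500 marker) loci; burn-in
    of 150 generations at N = 400 (enough for substantial linkage
    disequilibrium at the marker spacing used); 500 selective loci.  All
    downstream parameters (strain regimes, divergence length, candidate
    expansion, base-population size, breeding design) keep their full-scale
    values.
    """
    base = ExperimentPlan(
        scenarios=["mixed"],
        marker_numbers=None,
        n_replicates=10,
        genome=GenomeSpec(
            n_chromosomes=10,
            n_nonmarker_per_chrom=200,
            n_marker_per_chrom=500,
            mutation_rate=2.5e-3,
        ),
        pop_size=400,
        burnin_generations=150,
        n_selective_loci=500,
        schedule=AnnealSchedule().light(),
    )
    return replace(base, **overrides)


def _build_candidates(
    plan: ExperimentPlan,
    scenario: ScenarioSpec,
    rng: np.random.Generator,
) -> tuple[PopulationState, TraitModel]:
    """Burn-in, trait definition, strain founding/divergence/expansion."""
    pop = run_burnin(plan.genome, plan.pop_size, plan.burnin_generations, rng)
    trait = sample_effects(pop, plan.genome, rng, n_sel=plan.n_selective_loci)
    strains = found_strains(pop, scenario, rng)
    next_id = int(pop.ids.max()) + 1
    expanded = []
    for strain, regime in zip(strains, scenario.regimes):
        calibrate_ve(trait, strain)
        strain = diverge_strain(
            strain,
            regime,
            trait,
            plan.genome,
            scenario.divergence_generations,
            rng,
            id_start=next_id,
        )
        next_id = int(strain.ids.max()) + 1
        strain = expand_strain(
            strain,
            plan.genome,
            rng,
            trait,
            per_sex=scenario.expansion_per_sex,
            id_start=next_id,
        )
        next_id = int(strain.ids.max()) + 1
        expanded.append(strain)
    return PopulationState.concatenate(expanded), trait


def _solve_strategy(
    strategy: str,
    candidates: PopulationState,
    coancestry: np.ndarray,
    sol_e: ContributionSolution,
    plan: ExperimentPlan,
    rng: np.random.Generator,
) -> ContributionSolution:
    if strategy == "E":
        return sol_e
    if strategy in ("MC", "MP"):
        strain_ids, strain_f = strain_mean_coancestry(coancestry, candidates.strain)
        means = np.array(
            [candidates.phenotype[candidates.strain == s].mean() for s in strain_ids]
        )
        return solve_strain_strategy(
            candidates,
            coancestry,
            strategy,
            rng,
            n_per_sex=plan.n_per_sex,
            c_e=sol_e.group_coancestry if strategy == "MP" else None,
            phenotype_means=means if strategy == "MP" else None,
            strain_f=strain_f,
            strain_ids=strain_ids,
            schedule=plan.schedule,
        )
    if strategy == "IC":
        return optimize_IC(
            coancestry,
            candidates.sex,
            rng,
            n_per_sex=plan.n_per_sex,
            schedule=plan.schedule,
            init=sol_e.selected_idx,
        )
    return optimize_IP(
        coancestry,
        candidates.phenotype,
        candidates.sex,
        sol_e.group_coancestry,
        rng,
        n_per_sex=plan.n_per_sex,
        schedule=plan.schedule,
        init=sol_e.selected_idx,
    )


def run_replicate(
    plan: ExperimentPlan,
    scenario: ScenarioSpec,
    replicate: int,
    seed_seq: np.random.SeedSequence,
) -> dict[str, pd.DataFrame]:
    """One replicate: shared candidates, then every strategy x marker panel."""
    ss_build, ss_opt, ss_breed = seed_seq.spawn(3)
    rng_build = np.random.default_rng(ss_build)
    candidates, trait = _build_candidates(plan, scenario, rng_build)
    nonmarkers = plan.genome.nonmarker_indices
    marker_panels = (
        [plan.genome.n_markers] if plan.marker_numbers is None else plan.marker_numbers
    )

    base_rows = []
    contrib_rows = []
    gen_frames = []
    for n_markers in marker_panels:
        rng_opt = np.random.default_rng(ss_opt.spawn(1)[0])
        loci = plan.genome.marker_subset(n_markers)
        coan = molecular_coancestry(candidates.dosages(loci))
        sol_e = strategy_E(candidates, coan, rng_opt, n_per_sex=plan.n_per_sex)
        for strategy in plan.strategies:
            sol = _solve_strategy(strategy, candidates, coan, sol_e, plan, rng_opt)
            sel = candidates.subset(sol.selected_idx)
            he = expected_heterozygosity(sel.dosages(nonmarkers))
            base_rows.append(
                {
                    "scenario": scenario.name,
                    "strategy": strategy,
                    "markers": n_markers,
                    "replicate": replicate,
                    "phenotype_mean": float(sel.phenotype.mean()),
                    "bv_mean": float(sel.bv.mean()),
                    "v_a": float(sel.bv.var()),
                    "he_nonmarker_pct": 100.0 * he,
                    "marker_group_coancestry": sol.group_coancestry,
                    "c_e": sol.c_e if sol.c_e is not None else np.nan,
                    "feasible": sol.feasible,
                }
            )
            counts = np.array(
                [(sel.strain == s).sum() for s in np.unique(candidates.strain)]
            )
            for s, cnt in zip(np.unique(candidates.strain), counts):
                contrib_rows.append(
                    {
                        "scenario": scenario.name,
                        "strategy": strategy,
                        "markers": n_markers,
                        "replicate": replicate,
                        "strain": int(s),
                        "pct": 100.0 * cnt / counts.sum(),
                    }
                )
            if plan.run_breeding:
                rng_b = np.random.default_rng(ss_breed.spawn(1)[0])
                metrics, _ = run_program(
                    sel, trait, plan.genome, plan.breeding, rng_b
                )
                metrics.insert(0, "scenario", scenario.name)
                metrics.insert(1, "strategy", strategy)
                metrics.insert(2, "markers", n_markers)
                metrics.insert(3, "replicate", replicate)
                gen_frames.append(metrics)
    out = {
        "base": pd.DataFrame(base_rows),
        "contributions": pd.DataFrame(contrib_rows),
    }
    if gen_frames:
        out["generations"] = pd.concat(gen_frames, ignore_index=True)
    return out


def run_experiment(plan: ExperimentPlan, progress: bool = False) -> dict[str, pd.DataFrame]:
    """Run the full plan; returns tidy tables keyed ``base``,
    ``contributions`` and (when breeding is on) ``generations``."""
    results: dict[str, list[pd.DataFrame]] = {}
    for scen_idx, scen_name in enumerate(plan.scenarios):
        scenario = load_scenario(scen_name)
        for rep in range(plan.n_replicates):
            # one child sequence per (scenario, replicate), stable under
            # reordering of the loops
            ss = np.random.SeedSequence(
                entropy=plan.seed, spawn_key=(scen_idx, rep)
            )
            tables = run_replicate(plan, scenario, rep, ss)
            for key, df in tables.items():
                results.setdefault(key, []).append(df)
            if progress:
                print(f"[basepop] {scen_name} replicate {rep + 1}/{plan.n_replicates}")
    return {k: pd.concat(v, ignore_index=True) for k, v in results.items()}


def summarize(
    df: pd.DataFrame, group_cols: list[str], value_cols: list[str] | None = None
) -> pd.DataFrame:
    """Aggregate tidy metrics: mean, sample SD (0 when n = 1) and count per
    group, in deterministic group order."""
    if df.empty:
        raise ValueError("nothing to summarize")
    missing = [c for c in group_cols if c not in df.columns]
    if missing:
        raise KeyError(f"missing grouping columns: {missing}")
    if value_cols is None:
        value_cols = [
            c
            for c in df.columns
            if c not in group_cols and pd.api.types.is_numeric_dtype(df[c])
        ]
    g = df.groupby(group_cols, sort=True)[value_cols]
    mean = g.mean().add_suffix("_mean")
    sd = g.std(ddof=1).fillna(0.0).add_suffix("_sd")
    n = g.size().rename("n")
    return pd.concat([mean, sd, n], axis=1).reset_index()
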