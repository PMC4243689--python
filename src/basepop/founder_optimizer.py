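"""Optimal selection of base-population founders from candidate strains.

Five strategies choose 100 males + 100 females (configurable) from the
candidate pool:

* ``E``  — equal numbers sampled at random from each strain (reference);
* ``MC`` — strain proportions minimising the group coancestry
  ``c' F c`` built from strain-mean marker coancestries;
* ``MP`` — strain proportions maximising the mean strain phenotype
  ``c' P`` subject to ``c' F c <= C_E``;
* ``IC`` — individual 0/1 indicators minimising ``x' F x`` over the
  individual marker coancestry matrix, with exactly the required number
  selected per sex;
* ``IP`` — individual indicators maximising the summed phenotype subject to
  a group-coancestry cap at ``C_E``.

``C_E`` is the marker group coancestry realised by the strategy-E draw of
the same replicate, so the phenotype-driven strategies are benchmarked
against the same randomness.  All combinatorial searches use simulated
annealing; tiny instances are verifiable against exhaustive enumeration and
the continuous problems against closed forms / SLSQP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from .genome_sim import FEMALE, MALE, PopulationState
from .relatedness_metrics import group_coancestry

__all__ = [
    "AnnealSchedule",
    "ContributionSolution",
    "strategy_E",
    "optimize_MC",
    "optimize_MP",
    "optimize_IC",
    "optimize_IP",
    "round_contributions",
    "materialize_counts",
]

STRATEGIES = ("E", "MC", "MP", "IC", "IP")


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric-cooling simulated-annealing schedule.

    The initial temperature defaults to the standard deviation of the
    energy change over 100 random moves from the initial state; cooling is
    ``T_k = T0 * alpha**k`` with ``moves_per_temp`` proposals per level, and
    the search stops after ``patience`` consecutive levels without
    improvement of the best energy (or at ``max_temps``).
    """

    t0: float | None = None
    alpha: float = 0.995
    moves_per_temp: int = 200
    patience: int = 50
    restarts: int = 3
    max_temps: int = 4000

    def light(self) -> "AnnealSchedule":
        """A cheaper schedule for replicated experiments."""
        return replace(self, alpha=0.99, moves_per_temp=200, patience=40, restarts=1)


@dataclass
class ContributionSolution:
    """Outcome of a founder-selection strategy."""

    strategy: str
    selected_idx: np.ndarray  # positions within the candidate pool
    n_per_sex: int
    objective: float  # solver objective (see each strategy)
    group_coancestry: float  # marker group coancestry of the selected set
    c_e: float | None = None  # reference bound (MP/IP)
    feasible: bool = True
    proportions: np.ndarray | None = None  # MC/MP continuous solution
    counts: np.ndarray | None = None  # per-strain counts (E/MC/MP)
    strain_ids: np.ndarray | None = None

    def contributions_pct(self) -> np.ndarray | None:
        if self.counts is None:
            return None
        return 100.0 * self.counts / self.counts.sum()


# ---------------------------------------------------------------------------
# Strategy E


def strategy_E(
    candidates: PopulationState,
    coancestry: np.ndarray,
    rng: np.random.Generator,
    n_per_sex: int = 100,
) -> ContributionSolution:
    """Equal numbers from each strain, individuals sampled at random.

    Records the realised marker group coancestry of the chosen set as
    ``C_E``, the reference constraint level for MP and IP.
    """
    strain_ids = np.unique(candidates.strain)
    k = len(strain_ids)
    if (2 * n_per_sex) % k or n_per_sex % k:
        raise ValueError("strategy E needs the target sizes divisible by strain count")
    per_strain_sex = n_per_sex // k
    chosen = []
    for s in strain_ids:
        for sex in (MALE, FEMALE):
            pool = np.flatnonzero((candidates.strain == s) & (candidates.sex == sex))
            if len(pool) < per_strain_sex:
                raise ValueError(f"strain {s} short of candidates of sex {sex}")
            chosen.append(rng.choice(pool, size=per_strain_sex, replace=False))
    sel = np.sort(np.concatenate(chosen))
    g = group_coancestry(coancestry[np.ix_(sel, sel)])
    counts = np.full(k, 2 * per_strain_sex)
    return ContributionSolution(
        strategy="E",
        selected_idx=sel,
        n_per_sex=n_per_sex,
        objective=g,
        group_coancestry=g,
        counts=counts,
        proportions=counts / counts.sum(),
        strain_ids=strain_ids,
    )


# ---------------------------------------------------------------------------
# Continuous strain-proportion problems (MC, MP)


def _simplex_anneal(
    energy,
    k: int,
    rng: np.random.Generator,
    schedule: AnnealSchedule,
    init: np.ndarray | None = None,
    step: float = 0.5,
    t0_energy=None,
) -> tuple[np.ndarray, float]:
    """Anneal over the probability simplex with mass-transfer moves, then
    polish the best state by greedy transfers with decreasing step.

    ``t0_energy`` (default: ``energy``) sets the scale for the initial
    temperature; passing the unpenalised objective keeps constraint
    penalties from inflating T0.
    """
    scale_fn = energy if t0_energy is None else t0_energy
    best_c = np.full(k, 1.0 / k) if init is None else init.copy()
    best_e = energy(best_c)
    for _ in range(schedule.restarts):
        c = np.full(k, 1.0 / k) if init is None else init.copy()
        e = energy(c)
        # initial temperature from the spread of random-move deltas
        if schedule.t0 is None:
            base = scale_fn(c)
            deltas = []
            for _ in range(100):
                cc = _transfer(c, rng, step)
                deltas.append(scale_fn(cc) - base)
            t = float(np.std(deltas)) or 1.0
        else:
            t = schedule.t0
        cur_best = e
        stall = 0
        for _ in range(schedule.max_temps):
            improved = False
            for _ in range(schedule.moves_per_temp):
                cc = _transfer(c, rng, step)
                ee = energy(cc)
                de = ee - e
                if de <= 0 or rng.random() < np.exp(-de / t):
                    c, e = cc, ee
                    if e < cur_best - 1e-15:
                        cur_best = e
                        improved = True
                        if e < best_e:
                            best_e = e
                            best_c = c.copy()
            stall = 0 if improved else stall + 1
            if stall >= schedule.patience:
                break
            t *= schedule.alpha
    return _greedy_polish(energy, best_c, best_e)


def _greedy_polish(energy, c, e, steps=(0.1, 0.01, 1e-3, 1e-4)):
    """Deterministic descent: try fixed-size transfers between every ordered
    strain pair, keeping improvements, for a ladder of step sizes."""
    k = len(c)
    for step in steps:
        improved = True
        while improved:
            improved = False
            for i in range(k):
                if c[i] <= 0:
                    continue
                for j in range(k):
                    if j == i:
                        continue
                    delta = min(step, c[i])
                    cc = c.copy()
                    cc[i] -= delta
                    cc[j] += delta
                    ee = energy(cc)
                    if ee < e - 1e-15:
                        c, e = cc, ee
                        improved = True
    return c, e


def _transfer(c: np.ndarray, rng: np.random.Generator, step: float) -> np.ndarray:
    i, j = rng.integers(0, len(c), size=2)
    while j == i:
        j = rng.integers(0, len(c))
    # squaring biases toward fine moves so late annealing can settle
    delta = rng.random() ** 2 * step * c[i]
    out = c.copy()
    out[i] -= delta
    out[j] += delta
    return out


def optimize_MC(
    strain_coancestry: np.ndarray,
    rng: np.random.Generator,
    schedule: AnnealSchedule = AnnealSchedule(),
    method: str = "sa",
) -> tuple[np.ndarray, float]:
    """Strain proportions minimising ``c' F c`` on the simplex.

    Returns ``(c, objective)``; turning proportions into selected
    individuals is done by :func:`round_contributions` +
    :func:`materialize_counts`.
    """
    f = np.asarray(strain_coancestry, dtype=float)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError("strain coancestry must be square")
    if not np.allclose(f, f.T, atol=1e-10):
        raise ValueError("strain coancestry must be symmetric")
    k = f.shape[0]
    if method == "slsqp":
        res = minimize(
            lambda c: c @ f @ c,
            np.full(k, 1.0 / k),
            jac=lambda c: 2.0 * f @ c,
            bounds=[(0.0, 1.0)] * k,
            constraints=[{"type": "eq", "fun": lambda c: c.sum() - 1.0}],
            method="SLSQP",
        )
        return res.x, float(res.x @ f @ res.x)
    c, e = _simplex_anneal(lambda c: c @ f @ c, k, rng, schedule)
    return c, float(e)


def optimize_MP(
    strain_coancestry: np.ndarray,
    strain_means: np.ndarray,
    c_e: float,
    rng: np.random.Generator,
    schedule: AnnealSchedule = AnnealSchedule(),
    method: str = "sa",
) -> tuple[np.ndarray, float, bool]:
    """Strain proportions maximising ``c' P`` subject to ``c' F c <= C_E``.

    Infeasible bounds (C_E below the unconstrained minimum of ``c' F c``)
    fall back to the MC solution with a warning.  Returns
    ``(c, mean phenotype, feasible)``.  Ties in the objective are broken
    toward lower coancestry by a tiny secondary term.
    """
    f = np.asarray(strain_coancestry, dtype=float)
    p = np.asarray(strain_means, dtype=float)
    k = f.shape[0]
    c_mc, mc_obj = optimize_MC(f, rng, schedule, method=method)
    if mc_obj > c_e + 1e-9:
        warnings.warn(
            "coancestry restriction infeasible; returning the MC solution",
            stacklevel=2,
        )
        return c_mc, float(c_mc @ p), False
    lam = 1e6 * (np.ptp(p) + 1.0)
    tie = 1e-9 * (np.ptp(p) + 1.0)

    def energy(c):
        q = c @ f @ c
        return -(c @ p) + lam * max(0.0, q - c_e) + tie * q

    def objective_only(c):
        return -(c @ p)

    if method == "slsqp":
        res = minimize(
            lambda c: -(c @ p),
            c_mc,
            jac=lambda c: -p,
            bounds=[(0.0, 1.0)] * k,
            constraints=[
                {"type": "eq", "fun": lambda c: c.sum() - 1.0},
                {"type": "ineq", "fun": lambda c: c_e - c @ f @ c},
            ],
            method="SLSQP",
        )
        c = res.x
    else:
        c, _ = _simplex_anneal(
            energy, k, rng, schedule, init=c_mc, t0_energy=objective_only
        )
    feasible = bool(c @ f @ c <= c_e + 1e-9)
    return c, float(c @ p), feasible


def round_contributions(
    c: np.ndarray, total: int = 200, max_per_strain: np.ndarray | int | None = None
) -> np.ndarray:
    """Turn proportions into even per-strain counts summing to ``total``.

    Each count is the nearest even integer to ``total * c_i`` (halves round
    up); the residual is repaired in +/-2 steps by the largest-remainder
    rule (ties to the lowest strain index), optionally respecting per-strain
    availability caps (scalar or per-strain array).
    """
    c = np.asarray(c, dtype=float)
    if total % 2:
        raise ValueError("total must be even")
    if not np.isclose(c.sum(), 1.0, atol=1e-6):
        raise ValueError("proportions must sum to 1")
    cap = None if max_per_strain is None else np.broadcast_to(
        np.asarray(max_per_strain, dtype=float), c.shape
    )
    target = c * total
    counts = 2.0 * np.floor(target / 2.0 + 0.5)
    if cap is not None:
        if cap.sum() < total:
            raise ValueError("availability caps cannot supply the total")
        counts = np.minimum(counts, cap)
    while counts.sum() != total:
        remainder = target - counts
        if counts.sum() < total:
            cand = np.arange(len(c))
            if cap is not None:
                cand = cand[counts[cand] + 2 <= cap[cand]]
            i = cand[np.argmax(remainder[cand])]
            counts[i] += 2
        else:
            cand = np.flatnonzero(counts >= 2)
            i = cand[np.argmin(remainder[cand])]
            counts[i] -= 2
    return counts.astype(int)


def materialize_counts(
    candidates: PopulationState,
    strain_ids: np.ndarray,
    counts: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample ``counts[s]`` individuals (half per sex) at random from each
    strain; returns sorted positions within the candidate pool."""
    chosen = []
    for s, k in zip(strain_ids, counts):
        half = int(k) // 2
        if half == 0:
            continue
        for sex in (MALE, FEMALE):
            pool = np.flatnonzero((candidates.strain == s) & (candidates.sex == sex))
            if len(pool) < half:
                raise ValueError(f"strain {s} cannot supply {half} of sex {sex}")
            chosen.append(rng.choice(pool, size=half, replace=False))
    return np.sort(np.concatenate(chosen))


def solve_strain_strategy(
    candidates: PopulationState,
    coancestry: np.ndarray,
    strategy: str,
    rng: np.random.Generator,
    n_per_sex: int = 100,
    c_e: float | None = None,
    phenotype_means: np.ndarray | None = None,
    strain_f: np.ndarray | None = None,
    strain_ids: np.ndarray | None = None,
    schedule: AnnealSchedule = AnnealSchedule(),
    method: str = "sa",
) -> ContributionSolution:
    """Run MC or MP end to end: optimise proportions, round to even counts,
    sample individuals, and evaluate the realised group coancestry."""
    if strategy not in ("MC", "MP"):
        raise ValueError("strategy must be MC or MP")
    total = 2 * n_per_sex
    # availability caps: a strain can supply at most 2 * min(males, females)
    caps = np.array(
        [
            2
            * min(
                int(((candidates.strain == s) & (candidates.sex == MALE)).sum()),
                int(((candidates.strain == s) & (candidates.sex == FEMALE)).sum()),
            )
            for s in strain_ids
        ]
    )
    feasible = True
    if strategy == "MC":
        c, obj = optimize_MC(strain_f, rng, schedule, method)
    else:
        if c_e is None or phenotype_means is None:
            raise ValueError("MP needs c_e and phenotype means")
        c, obj, feasible = optimize_MP(
            strain_f, phenotype_means, c_e, rng, schedule, method
        )
    counts = round_contributions(c, total, max_per_strain=caps)
    sel = materialize_counts(candidates, strain_ids, counts, rng)
    g = group_coancestry(coancestry[np.ix_(sel, sel)])
    return ContributionSolution(
        strategy=strategy,
        selected_idx=sel,
        n_per_sex=n_per_sex,
        objective=float(obj),
        group_coancestry=g,
        c_e=c_e,
        feasible=feasible,
        proportions=c,
        counts=counts,
        strain_ids=strain_ids,
    )


# ---------------------------------------------------------------------------
# Individual subset problems (IC, IP)


def _subset_anneal(
    coancestry: np.ndarray,
    sexes: np.ndarray,
    n_per_sex: int,
    rng: np.random.Generator,
    schedule: AnnealSchedule,
    init: np.ndarray,
    phenotypes: np.ndarray | None = None,
    c_e: float | None = None,
):
    """Simulated annealing over same-sex swap moves.

    Minimises ``q = x' F x`` when ``phenotypes`` is None, otherwise
    maximises the summed phenotype under the penalised constraint
    ``q / total^2 <= c_e``.  The incremental bookkeeping keeps each
    proposal O(1) via the row-sum vector ``s_i = sum_{j in S} F_ij``.
    """
    f = np.asarray(coancestry, dtype=np.float64)
    n = f.shape[0]
    total = 2 * n_per_sex
    tot2 = float(total * total)
    maximize_phen = phenotypes is not None
    if maximize_phen:
        phen = np.asarray(phenotypes, dtype=np.float64)
        lam = 1e6 * (np.ptp(phen) + 1.0)

    def state_from(sel_idx):
        mask = np.zeros(n, dtype=bool)
        mask[sel_idx] = True
        s = f[:, sel_idx].sum(axis=1)
        q = float(s[sel_idx].sum())
        psum = float(phen[sel_idx].sum()) if maximize_phen else 0.0
        return mask, s, q, psum

    def energy(q, psum):
        if not maximize_phen:
            return q
        return -psum + lam * max(0.0, q / tot2 - c_e)

    def feasible(q):
        return (not maximize_phen) or q / tot2 <= c_e + 1e-9

    sex_arr = np.asarray(sexes)
    pools = {sx: np.flatnonzero(sex_arr == sx) for sx in (MALE, FEMALE)}
    for sx in (MALE, FEMALE):
        if (np.isin(init, pools[sx])).sum() != n_per_sex:
            raise ValueError("initial solution must have n_per_sex of each sex")

    best_sel = np.array(init, dtype=int)
    mask0, s0, q0, p0 = state_from(best_sel)
    best_e = energy(q0, p0)
    best_feasible_sel = best_sel.copy() if feasible(q0) else None
    best_feasible_e = best_e if feasible(q0) else np.inf

    for _ in range(schedule.restarts):
        mask, s, q, psum = state_from(init)
        # positional lists per sex for O(1) swaps
        sel_lists = {sx: [i for i in init if sex_arr[i] == sx] for sx in (MALE, FEMALE)}
        unsel_lists = {
            sx: [i for i in pools[sx] if not mask[i]] for sx in (MALE, FEMALE)
        }
        e = energy(q, psum)

        movable = [sx for sx in (MALE, FEMALE) if unsel_lists[sx]]
        if not movable:
            return best_sel, best_feasible_sel  # nothing to optimise

        def propose():
            sx = movable[0] if len(movable) == 1 else (
                MALE if rng.random() < 0.5 else FEMALE
            )
            sl, ul = sel_lists[sx], unsel_lists[sx]
            a = rng.integers(0, len(sl))
            b = rng.integers(0, len(ul))
            u, v = sl[a], ul[b]
            dq = 2.0 * (s[v] - s[u] - f[v, u]) + f[u, u] + f[v, v]
            dp = (phen[v] - phen[u]) if maximize_phen else 0.0
            return sx, a, b, u, v, dq, dp

        if schedule.t0 is None:
            # temperature from the raw objective spread; the constraint
            # penalty would otherwise inflate T0 by orders of magnitude
            deltas = []
            for _ in range(100):
                _, _, _, _, _, dq, dp = propose()
                deltas.append(dp if maximize_phen else dq)
            t = float(np.std(deltas)) or 1.0
        else:
            t = schedule.t0

        cur_best = e
        stall = 0
        for _ in range(schedule.max_temps):
            improved = False
            for _ in range(schedule.moves_per_temp):
                sx, a, b, u, v, dq, dp = propose()
                ee = energy(q + dq, psum + dp)
                de = ee - e
                if de <= 0 or rng.random() < np.exp(-de / t):
                    sel_lists[sx][a], unsel_lists[sx][b] = v, u
                    mask[u] = False
                    mask[v] = True
                    s += f[:, v] - f[:, u]
                    q += dq
                    psum += dp
                    e = ee
                    if e < cur_best - 1e-12:
                        cur_best = e
                        improved = True
                        if e < best_e:
                            best_e = e
                            best_sel = np.array(
                                sel_lists[MALE] + sel_lists[FEMALE], dtype=int
                            )
                        if maximize_phen and feasible(q) and -psum < best_feasible_e:
                            best_feasible_e = -psum
                            best_feasible_sel = np.array(
                                sel_lists[MALE] + sel_lists[FEMALE], dtype=int
                            )
            stall = 0 if improved else stall + 1
            if stall >= schedule.patience:
                break
            t *= schedule.alpha
    return best_sel, best_feasible_sel


def optimize_IC(
    coancestry: np.ndarray,
    sexes: np.ndarray,
    rng: np.random.Generator,
    n_per_sex: int = 100,
    schedule: AnnealSchedule = AnnealSchedule(),
    init: np.ndarray | None = None,
) -> ContributionSolution:
    """Select the subset (n_per_sex per sex) minimising ``x' F x``.

    When ``init`` is omitted the search starts from the first candidates of
    each sex; seeding with a strategy-E draw guarantees the result is never
    worse than E.
    """
    sexes = np.asarray(sexes)
    if init is None:
        init = np.concatenate(
            [np.flatnonzero(sexes == sx)[:n_per_sex] for sx in (MALE, FEMALE)]
        )
    sel, _ = _subset_anneal(coancestry, sexes, n_per_sex, rng, schedule, init)
    sel = np.sort(sel)
    g = group_coancestry(coancestry[np.ix_(sel, sel)])
    total = 2 * n_per_sex
    return ContributionSolution(
        strategy="IC",
        selected_idx=sel,
        n_per_sex=n_per_sex,
        objective=g * total * total,  # x'Fx
        group_coancestry=g,
    )


def optimize_IP(
    coancestry: np.ndarray,
    phenotypes: np.ndarray,
    sexes: np.ndarray,
    c_e: float,
    rng: np.random.Generator,
    n_per_sex: int = 100,
    schedule: AnnealSchedule = AnnealSchedule(),
    init: np.ndarray | None = None,
) -> ContributionSolution:
    """Select the subset maximising summed phenotype subject to a marker
    group-coancestry cap at ``C_E``.  Returns the best feasible solution
    found; if none is feasible, the best penalised solution is returned
    with ``feasible=False`` and a warning."""
    sexes = np.asarray(sexes)
    if init is None:
        init = np.concatenate(
            [np.flatnonzero(sexes == sx)[:n_per_sex] for sx in (MALE, FEMALE)]
        )
    best, best_feas = _subset_anneal(
        coancestry, sexes, n_per_sex, rng, schedule, init, phenotypes, c_e
    )
    feasible = best_feas is not None
    if not feasible:
        warnings.warn("no feasible IP solution found; returning best penalised")
        sel = np.sort(best)
    else:
        sel = np.sort(best_feas)
    g = group_coancestry(coancestry[np.ix_(sel, sel)])
    return ContributionSolution(
        strategy="IP",
        selected_idx=sel,
        n_per_sex=n_per_sex,
        objective=float(np.asarray(phenotypes)[sel].sum()),
        group_coancestry=g,
        c_e=c_e,
        feasible=feasible,
    )
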