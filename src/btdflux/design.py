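"""Evolutionary strain design: modification semantics, BPCY, SPEA2.

A *modification* scales the activity of a reaction or a gene relative to
the wildtype: factor 0 is a knockout, a factor below 1 under-expression
(the flux through the reaction is capped at that fraction of its wildtype
value), a factor above 1 over-expression (the flux magnitude is floored at
that multiple of wildtype).  Gene factors propagate to reactions through
the GPR rules (AND → min, OR → max).

A *design candidate* is a set of at most ``max_modifications`` such edits.
Candidates are scored by simulating the modified network — with pFBA,
LMOMA or MiMBL against the wildtype reference — and computing the
Biomass-Product Coupled Yield

    BPCY = growth × production / |substrate uptake|,

the classic strain-design objective coupling product secretion to growth.
The search is the Strength Pareto Evolutionary Algorithm 2 (SPEA2) over
the two objectives (BPCY, production rate), with an external
non-dominated archive, k-th-nearest-neighbour density estimation and
binary-tournament mating.  :func:`enumerate_designs` is the exhaustive
deterministic counterpart used as an oracle on small problems.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import Condition, MetabolicModel, apply_condition, evaluate_gpr
from .simulate import (
    FluxSolution,
    ReferenceState,
    lmoma,
    mimbl,
    pfba,
    reference_state,
)

__all__ = [
    "Modification",
    "DesignCandidate",
    "DesignResult",
    "OptimizerConfig",
    "DEFAULT_FACTOR_GRID",
    "apply_modification",
    "apply_candidate",
    "bpcy",
    "evaluate_candidate",
    "spea2_optimize",
    "enumerate_designs",
]

#: powers-of-two modification factors: 0 (knockout), 1/32 … 1/2
#: (under-expression) and 2 … 32 (over-expression)
DEFAULT_FACTOR_GRID: tuple[float, ...] = (
    0.0, 1 / 32, 1 / 16, 1 / 8, 1 / 4, 1 / 2, 2.0, 4.0, 8.0, 16.0, 32.0,
)


@dataclass(frozen=True)
class Modification:
    target_kind: str  # "reaction" | "gene"
    target_id: str
    factor: float

    def __post_init__(self) -> None:
        if self.target_kind not in ("reaction", "gene"):
            raise ValueError(f"unknown target kind {self.target_kind!r}")
        if self.factor < 0:
            raise ValueError("modification factor must be >= 0")

    def __str__(self) -> str:
        return f"{self.target_id} = {self.factor:g}"


@dataclass(frozen=True)
class DesignCandidate:
    """An immutable set of ≤ K modifications with unique targets."""

    modifications: tuple[Modification, ...] = ()

    def __post_init__(self) -> None:
        targets = [(m.target_kind, m.target_id) for m in self.modifications]
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate modification targets in candidate")
        ordered = tuple(sorted(self.modifications,
                               key=lambda m: (m.target_kind, m.target_id, m.factor)))
        object.__setattr__(self, "modifications", ordered)

    def __str__(self) -> str:
        return "; ".join(str(m) for m in self.modifications) or "wildtype"

    @property
    def key(self) -> tuple:
        return tuple((m.target_kind, m.target_id, m.factor) for m in self.modifications)


@dataclass
class DesignResult:
    candidate: DesignCandidate
    solution: FluxSolution
    growth: float
    production: float
    substrate_uptake: float
    bpcy: float
    feasible: bool


@dataclass
class OptimizerConfig:
    """SPEA2 settings; the defaults are the ones runs are reported with."""

    simulation_method: str = "pfba"  # pfba | lmoma | mimbl
    max_evaluations: int = 5000
    max_modifications: int = 2
    population_size: int = 100
    archive_size: int = 100
    crossover_probability: float = 0.7
    mutation_probability: float = 0.2
    factor_grid: tuple[float, ...] = DEFAULT_FACTOR_GRID
    seed: int = 0
    target_kind: str = "reaction"  # or "gene"
    targets: Optional[tuple[str, ...]] = None  # None = every eligible target

    def __post_init__(self) -> None:
        if self.simulation_method not in ("pfba", "lmoma", "mimbl"):
            raise ValueError(f"unknown simulation method {self.simulation_method!r}")
        if self.max_evaluations < self.population_size:
            raise ValueError("max_evaluations must be >= population_size")
        if 0.0 not in self.factor_grid or 1.0 in self.factor_grid:
            raise ValueError("factor grid must contain 0 and exclude 1")


# --------------------------------------------------------------------------
# modification semantics
# --------------------------------------------------------------------------

def _apply_reaction_factor(model: MetabolicModel, rid: str, factor: float,
                           wildtype_flux: float) -> None:
    rxn = model.get_reaction(rid)
    w = wildtype_flux
    if factor == 1.0:
        return
    if factor == 0.0:
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    elif factor < 1.0:
        # sign-preserving cap at a fraction of the wildtype flux
        rxn.lower_bound = min(0.0, factor * w)
        rxn.upper_bound = max(0.0, factor * w)
    else:
        # sign-preserving floor |v| >= factor·|w|, outer bound retained
        if w > 0:
            rxn.lower_bound = factor * w
            if rxn.lower_bound > rxn.upper_bound:
                model.infeasible_marker = (
                    f"over-expression floor {factor:g}x on {rid} exceeds upper bound"
                )
        elif w < 0:
            rxn.upper_bound = factor * w
            if rxn.upper_bound < rxn.lower_bound:
                model.infeasible_marker = (
                    f"over-expression floor {factor:g}x on {rid} exceeds lower bound"
                )
        # w == 0: flooring |v| >= 0 changes nothing


def apply_modification(
    model: MetabolicModel, reference: ReferenceState, mod: Modification
) -> MetabolicModel:
    """Return a copy of ``model`` with one modification's bounds applied.

    Reaction targets are re-bounded relative to their wildtype flux in
    ``reference``.  Gene targets propagate through every GPR that mentions
    the gene and then apply the resulting reaction-level factor.  An
    over-expression floor that cannot fit inside the reaction's original
    outer bound marks the returned model infeasible rather than raising.
    """
    out = model.copy()
    if mod.target_kind == "reaction":
        if not out.has_reaction(mod.target_id):
            raise KeyError(f"no reaction {mod.target_id!r} to modify")
        _apply_reaction_factor(out, mod.target_id, mod.factor,
                               reference.flux(mod.target_id))
        return out
    # gene target
    if mod.target_id not in out.genes:
        raise KeyError(f"no gene {mod.target_id!r} to modify")
    gene_factors = {mod.target_id: mod.factor}
    for rxn in out.reactions:
        if rxn.gpr is None or mod.target_id not in rxn.gpr.genes:
            continue
        factor = evaluate_gpr(rxn.gpr, gene_factors)
        _apply_reaction_factor(out, rxn.id, factor, reference.flux(rxn.id))
    return out


def apply_candidate(
    model: MetabolicModel, reference: ReferenceState, candidate: DesignCandidate
) -> MetabolicModel:
    out = model
    for mod in candidate.modifications:
        out = apply_modification(out, reference, mod)
    return out


def bpcy(growth: float, production: float, substrate_uptake: float) -> float:
    """Biomass-Product Coupled Yield: growth × production / |uptake|.

    ``substrate_uptake`` is the carbon-source exchange flux (≤ 0 for
    uptake); zero uptake yields a score of 0.
    """
    if substrate_uptake == 0.0:
        return 0.0
    return growth * production / abs(substrate_uptake)


_SIMULATORS = {"pfba": "pfba", "lmoma": "lmoma", "mimbl": "mimbl"}


def evaluate_candidate(
    model: MetabolicModel,
    reference: ReferenceState,
    candidate: DesignCandidate,
    method: str,
    product_id: str,
    substrate_id: str,
) -> DesignResult:
    """Simulate one candidate and score it.

    ``model`` must already carry the growth condition.  ``product_id`` and
    ``substrate_id`` are exchange-reaction ids; production is the product
    exchange flux, uptake the substrate exchange flux.
    """
    mutant = apply_candidate(model, reference, candidate)
    if mutant.infeasible_marker:
        sol = FluxSolution({r.id: 0.0 for r in mutant.reactions},
                           float("nan"), "infeasible", method)
    elif method == "pfba":
        sol = pfba(mutant)
    elif method == "lmoma":
        sol = lmoma(mutant, reference)
    elif method == "mimbl":
        sol = mimbl(mutant, reference)
    else:
        raise ValueError(f"unknown simulation method {method!r}")
    if not sol.optimal:
        return DesignResult(candidate, sol, 0.0, 0.0, 0.0, 0.0, feasible=False)
    growth = sol.fluxes[model.objective_reaction]
    production = sol.fluxes[product_id]
    uptake = sol.fluxes[substrate_id]
    return DesignResult(candidate, sol, growth, production, uptake,
                        bpcy(growth, production, uptake), feasible=True)


# --------------------------------------------------------------------------
# SPEA2
# --------------------------------------------------------------------------

def _default_targets(model: MetabolicModel, config: OptimizerConfig,
                     product_id: str, substrate_id: str) -> tuple[str, ...]:
    if config.target_kind == "gene":
        return tuple(sorted(model.genes))
    skip = {model.objective_reaction, product_id, substrate_id}
    return tuple(r.id for r in model.reactions if r.id not in skip)


def _dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] >= b[0] and a[1] >= b[1] and (a[0] > b[0] or a[1] > b[1])


def _spea2_fitness(objs: Sequence[tuple[float, float]]) -> np.ndarray:
    n = len(objs)
    strength = np.zeros(n)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and _dominates(objs[i], objs[j]):
                strength[i] += 1
                dominated_by[j].append(i)
    raw = np.array([sum(strength[i] for i in dominated_by[j]) for j in range(n)])
    pts = np.asarray(objs, dtype=float)
    if n > 1:
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        k = min(int(math.sqrt(n)), n - 1)
        sigma = np.sort(d, axis=1)[:, k - 1] if k >= 1 else np.zeros(n)
    else:
        sigma = np.zeros(n)
    density = 1.0 / (sigma + 2.0)
    return raw + density


def _truncate(indices: list[int], objs: Sequence[tuple[float, float]],
              size: int) -> list[int]:
    """SPEA2 archive truncation: repeatedly drop the most crowded member."""
    keep = list(indices)
    pts = np.asarray([objs[i] for i in keep], dtype=float)
    while len(keep) > size:
        m = len(keep)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        sorted_d = np.sort(d, axis=1)
        # lexicographic min over the sorted distance vectors
        victim = min(range(m), key=lambda i: tuple(sorted_d[i]))
        keep.pop(victim)
        pts = np.delete(pts, victim, axis=0)
    return keep


class _Search:
    """One seeded SPEA2 run (internal)."""

    def __init__(self, model: MetabolicModel, reference: ReferenceState,
                 config: OptimizerConfig, product_id: str, substrate_id: str,
                 targets: tuple[str, ...]):
        self.model = model
        self.reference = reference
        self.config = config
        self.product_id = product_id
        self.substrate_id = substrate_id
        self.targets = targets
        self.rng = np.random.default_rng(config.seed)
        self.cache: dict[tuple, DesignResult] = {}
        self.evaluations = 0

    # genotypes are fixed-length slot lists (Modification | None)
    def _random_mod(self) -> Modification:
        target = self.targets[int(self.rng.integers(len(self.targets)))]
        factor = self.config.factor_grid[int(self.rng.integers(len(self.config.factor_grid)))]
        return Modification(self.config.target_kind, target, factor)

    def _random_genotype(self) -> list[Optional[Modification]]:
        k = self.config.max_modifications
        return [self._random_mod() if self.rng.random() < 0.8 else None for _ in range(k)]

    @staticmethod
    def _to_candidate(genotype: Sequence[Optional[Modification]]) -> DesignCandidate:
        seen: dict[tuple[str, str], Modification] = {}
        for m in genotype:
            if m is not None:
                seen.setdefault((m.target_kind, m.target_id), m)
        return DesignCandidate(tuple(seen.values()))

    def evaluate(self, candidate: DesignCandidate) -> Optional[DesignResult]:
        if candidate.key in self.cache:
            return self.cache[candidate.key]
        if self.evaluations >= self.config.max_evaluations:
            return None
        self.evaluations += 1
        res = evaluate_candidate(self.model, self.reference, candidate,
                                 self.config.simulation_method,
                                 self.product_id, self.substrate_id)
        self.cache[candidate.key] = res
        return res

    def _vary(self, p1: Sequence[Optional[Modification]],
              p2: Sequence[Optional[Modification]]) -> list[Optional[Modification]]:
        k = self.config.max_modifications
        child: list[Optional[Modification]] = []
        do_cx = self.rng.random() < self.config.crossover_probability
        for i in range(k):
            if do_cx:
                child.append(p1[i] if self.rng.random() < 0.5 else p2[i])
            else:
                child.append(p1[i])
        for i in range(k):
            if self.rng.random() < self.config.mutation_probability:
                choice = self.rng.random()
                if child[i] is None or choice < 0.4:
                    child[i] = self._random_mod()
                elif choice < 0.7:
                    factor = self.config.factor_grid[
                        int(self.rng.integers(len(self.config.factor_grid)))]
                    child[i] = replace(child[i], factor=factor)
                else:
                    child[i] = None
        return child

    def run(self) -> list[DesignResult]:
        cfg = self.config
        if cfg.max_modifications == 0:
            wt = self.evaluate(DesignCandidate())
            return [wt] if wt is not None and wt.feasible else []
        population = [self._random_genotype() for _ in range(cfg.population_size)]
        archive: list[tuple[DesignCandidate, DesignResult]] = []
        # cached re-evaluations are free, so on small search spaces the
        # evaluation budget may never be exhausted; cap generations too
        max_generations = 2 * cfg.max_evaluations // max(1, cfg.population_size) + 10
        generation = 0
        while True:
            generation += 1
            evaluated: list[tuple[DesignCandidate, DesignResult]] = []
            seen_keys = set()
            for g in population:
                cand = self._to_candidate(g)
                res = self.evaluate(cand)
                if res is None:
                    break
                if cand.key not in seen_keys:
                    seen_keys.add(cand.key)
                    evaluated.append((cand, res))
            union = evaluated + [a for a in archive
                                 if a[0].key not in seen_keys]
            feasible = [(c, r) for c, r in union if r.feasible]
            if not feasible:
                archive = []
                if (self.evaluations >= cfg.max_evaluations
                        or generation >= max_generations):
                    warnings.warn("all evaluated candidates infeasible; empty archive")
                    return []
                population = [self._random_genotype() for _ in range(cfg.population_size)]
                continue
            objs = [(r.bpcy, r.production) for _, r in feasible]
            fitness = _spea2_fitness(objs)
            nondom = [i for i in range(len(feasible)) if fitness[i] < 1.0]
            if len(nondom) > cfg.archive_size:
                nondom = _truncate(nondom, objs, cfg.archive_size)
            elif len(nondom) < cfg.archive_size:
                dominated = sorted(
                    (i for i in range(len(feasible)) if fitness[i] >= 1.0),
                    key=lambda i: (fitness[i], feasible[i][0].key),
                )
                nondom = nondom + dominated[: cfg.archive_size - len(nondom)]
            archive = [feasible[i] for i in sorted(nondom)]
            if self.evaluations >= cfg.max_evaluations or generation >= max_generations:
                break
            # binary-tournament mating on archive fitness
            pool_objs = [(r.bpcy, r.production) for _, r in archive]
            pool_fit = _spea2_fitness(pool_objs)
            genos = [self._candidate_genotype(c) for c, _ in archive]

            def tournament() -> list[Optional[Modification]]:
                i = int(self.rng.integers(len(archive)))
                j = int(self.rng.integers(len(archive)))
                return genos[i] if pool_fit[i] <= pool_fit[j] else genos[j]

            population = [self._vary(tournament(), tournament())
                          for _ in range(cfg.population_size)]
        # final pareto filter on the archive
        objs = [(r.bpcy, r.production) for _, r in archive]
        front = [
            (c, r) for i, (c, r) in enumerate(archive)
            if not any(_dominates(objs[j], objs[i]) for j in range(len(archive)) if j != i)
        ]
        front.sort(key=lambda cr: (-cr[1].bpcy, -cr[1].production, cr[0].key))
        return [r for _, r in front]

    def _candidate_genotype(self, cand: DesignCandidate) -> list[Optional[Modification]]:
        k = self.config.max_modifications
        slots: list[Optional[Modification]] = list(cand.modifications)[:k]
        slots += [None] * (k - len(slots))
        return slots


def spea2_optimize(
    model: MetabolicModel,
    condition: Condition,
    product_id: str,
    substrate_id: str,
    config: OptimizerConfig,
    reference: Optional[ReferenceState] = None,
) -> list[DesignResult]:
    """SPEA2 search for modification sets maximising (BPCY, production).

    Returns the non-dominated archive as a list of feasible
    :class:`DesignResult`, best BPCY first.  The total number of candidate
    simulations never exceeds ``config.max_evaluations`` and identical
    seeds yield identical archives.  Raises if the wildtype itself cannot
    grow under ``condition``.
    """
    conditioned = apply_condition(model, condition)
    if reference is None:
        reference = reference_state(conditioned)
    for rid in (product_id, substrate_id):
        if not conditioned.has_reaction(rid):
            raise KeyError(f"no exchange {rid!r} in model")
    targets = (config.targets if config.targets is not None
               else _default_targets(conditioned, config, product_id, substrate_id))
    search = _Search(conditioned, reference, config, product_id, substrate_id,
                     tuple(targets))
    return search.run()


def enumerate_designs(
    model: MetabolicModel,
    condition: Condition,
    product_id: str,
    substrate_id: str,
    config: OptimizerConfig,
    reference: Optional[ReferenceState] = None,
    budget: int = 100_000,
) -> list[DesignResult]:
    """Exhaustive evaluation of every candidate with ≤ K modifications.

    The deterministic oracle for optimizer tests: all combinations of up
    to ``config.max_modifications`` distinct targets × factor-grid values,
    sorted by BPCY descending (ties broken by genotype).  Raises if the
    candidate count would exceed ``budget`` — restrict the target list.
    """
    from itertools import combinations, product as iproduct

    conditioned = apply_condition(model, condition)
    if reference is None:
        reference = reference_state(conditioned)
    targets = (config.targets if config.targets is not None
               else _default_targets(conditioned, config, product_id, substrate_id))
    grid = config.factor_grid
    k_max = config.max_modifications
    total = sum(
        math.comb(len(targets), k) * len(grid) ** k for k in range(k_max + 1)
    )
    if total > budget:
        raise ValueError(
            f"{total} candidates exceeds the enumeration budget {budget}; "
            "restrict the target list or the factor grid"
        )
    results: list[DesignResult] = []
    for k in range(k_max + 1):
        for combo in combinations(sorted(targets), k):
            for factors in iproduct(grid, repeat=k):
                cand = DesignCandidate(tuple(
                    Modification(config.target_kind, t, f)
                    for t, f in zip(combo, factors)
                ))
                results.append(evaluate_candidate(
                    conditioned, reference, cand, config.simulation_method,
                    product_id, substrate_id))
    results.sort(key=lambda r: (-r.bpcy, -r.production, r.candidate.key))
    return results
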