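"""Moran-like birth-death evolution of reactomes on a pan-reactome pool.

A constant-size population of functional reactomes (subsets of one
pan-reactome, all evaluated in a single fixed environment) evolves by
alternating two steps: a mutation attempt on a random individual (delete a
uniformly chosen present reaction, or insert a uniformly chosen absent pan
reaction; the change is kept only if the mutant remains functional) and a
birth-death replacement (one random individual is overwritten by a copy of
another).  There are no fitness differences among functional reactomes —
the process is neutral on the functional state space, so allele dynamics
are pure drift.

Deletions are proposed more often than insertions (``p_delete = 0.9`` by
default), making the dynamics loss-dominated.  This matters: insertions
can never be rejected (adding a reaction only relaxes the flux LP), so a
balanced 50/50 kernel drifts toward complete reactomes in which every
reaction sits near frequency one and the population carries no signature
of the environment.  Under reductive, loss-dominated evolution the
population instead hovers near minimal functional sets, and the evolved
reaction frequencies mirror the environment-specific panEFM frequencies —
the regime in which niche prediction from reaction content is possible.

Individuals are represented by their set of *deletable* reactions; the
biomass and exchange reactions are part of every reactome by construction.
Functionality uses the same cutoff as panEFM sampling: biomass flux above
1% of the pan-reactome's flux in the environment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np
import pandas as pd

from .network import Environment, GROWTH_EPS, MetabolicNetwork
from .sampling import DEFAULT_CUTOFF_FRAC, sample_panefm


@dataclass
class MoranState:
    """Population snapshot: sets of deletable reactions per individual."""

    pan: MetabolicNetwork
    environment: Environment
    population: List[FrozenSet[str]]
    iteration: int = 0
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC
    p_delete: float = 0.9
    p_mutation: float = 1.0
    _cutoff: float = field(default=0.0, repr=False)

    def __post_init__(self) -> None:
        ev = self.pan.evaluator()
        pan_flux = ev.biomass_flux(self.environment)
        if pan_flux <= GROWTH_EPS:
            raise ValueError("environment does not support growth of the pan-reactome")
        self._cutoff = self.cutoff_frac * pan_flux

    @property
    def size(self) -> int:
        return len(self.population)

    def is_functional(self, individual: FrozenSet[str]) -> bool:
        deletable = frozenset(self.pan.deletable_reaction_ids)
        deleted = deletable - individual
        return (
            self.pan.evaluator().biomass_flux(self.environment, deleted)
            > self._cutoff
        )

    def audit(self) -> bool:
        """True iff every individual in the population is functional."""
        return all(self.is_functional(ind) for ind in set(self.population))


@dataclass
class MoranResult:
    """Outcome of an evolution run."""

    state: MoranState
    types: Counter
    reaction_frequencies: pd.Series

    @property
    def distinct_types(self) -> List[FrozenSet[str]]:
        return sorted(self.types, key=lambda s: (len(s), sorted(s)))


def random_functional_reactome(
    pan: MetabolicNetwork,
    env: Environment,
    rng: np.random.Generator,
    inflate_p: float = 0.25,
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
) -> FrozenSet[str]:
    """A random functional subset of the pan-reactome's deletable reactions.

    A sampled panEFM is re-inflated with each absent reaction independently
    with probability ``inflate_p``, spanning sizes between minimal and full
    while guaranteeing functionality (adding reactions cannot break it).
    """
    efm = sample_panefm(pan, env, rng, cutoff_frac, record_usage=False)
    deletable = set(pan.deletable_reaction_ids)
    present = set(efm.reactions) & deletable
    for rid in sorted(deletable - present):
        if rng.random() < inflate_p:
            present.add(rid)
    return frozenset(present)


def moran_step(state: MoranState, rng: np.random.Generator) -> MoranState:
    """One mutation attempt followed by one birth-death replacement.

    Mutates ``state`` in place (and returns it): population size never
    changes and every individual stays functional.
    """
    pop = state.population
    n = len(pop)
    deletable = state.pan.deletable_reaction_ids
    # -- mutation (p_mutation < 1 leaves pure drift for calibration checks)
    if rng.random() < state.p_mutation:
        k = int(rng.integers(n))
        individual = pop[k]
        if rng.random() < state.p_delete:
            if individual:
                present = sorted(individual)
                rid = present[int(rng.integers(len(present)))]
                mutant = individual - {rid}
                if state.is_functional(mutant):
                    pop[k] = mutant
        else:
            absent = sorted(set(deletable) - individual)
            if absent:
                rid = absent[int(rng.integers(len(absent)))]
                # insertion relaxes the LP, so the mutant stays functional
                pop[k] = individual | {rid}
    # -- birth-death replacement
    i = int(rng.integers(n))
    j = int(rng.integers(n - 1))
    if j >= i:
        j += 1
    pop[j] = pop[i]
    state.iteration += 1
    return state


def moran_evolve(
    pan: MetabolicNetwork,
    env: Environment,
    n: int = 1000,
    iterations: int = 1_000_000,
    seed: int = 0,
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
    inflate_p: float = 0.25,
    p_delete: float = 0.9,
    initial: Optional[Sequence[FrozenSet[str]]] = None,
) -> MoranResult:
    """Evolve ``n`` random functional reactomes for ``iterations`` steps.

    Returns the distinct surviving reactome types with their counts and the
    per-reaction population frequency (over all pan reactions; biomass and
    exchange reactions are present in every individual by construction).
    """
    rng = np.random.default_rng(seed)
    if initial is None:
        population = [
            random_functional_reactome(pan, env, rng, inflate_p, cutoff_frac)
            for _ in range(n)
        ]
    else:
        population = [frozenset(ind) for ind in initial]
        if len(population) != n:
            raise ValueError("initial population size does not match n")
    state = MoranState(
        pan, env, population, cutoff_frac=cutoff_frac, p_delete=p_delete
    )
    for _ in range(iterations):
        moran_step(state, rng)
    counts = Counter(state.population)
    deletable = set(pan.deletable_reaction_ids)
    freq = {}
    for rid in pan.reactions:
        if rid in deletable:
            freq[rid] = sum(rid in ind for ind in state.population) / n
        else:
            freq[rid] = 1.0
    return MoranResult(state, counts, pd.Series(freq, dtype=float))


def realized_usage(
    reactomes: Sequence[FrozenSet[str]],
    pan: MetabolicNetwork,
    env: Environment,
    weights: Optional[Sequence[float]] = None,
    pfba: bool = False,
) -> pd.Series:
    """Fraction of (distinct) reactomes importing each external metabolite.

    Each reactome's usage is read off the biomass-optimal FBA solution of
    its subnetwork (parsimoniously refined when ``pfba``); ``weights``
    (e.g. type counts) turn the unweighted fraction into a
    population-weighted one.
    """
    ev = pan.evaluator()
    deletable = frozenset(pan.deletable_reaction_ids)
    if weights is None:
        weights = [1.0] * len(reactomes)
    if len(weights) != len(reactomes):
        raise ValueError("weights and reactomes length mismatch")
    total = float(sum(weights))
    mets = list(pan.external_metabolites)
    acc: Dict[str, float] = {m: 0.0 for m in mets}
    for ind, w in zip(reactomes, weights):
        deleted = deletable - frozenset(ind)
        usage = ev.solve(env, deleted, pfba=pfba).imported_metabolites
        for m in usage:
            acc[m] += w
    return pd.Series({m: acc[m] / total for m in mets}, dtype=float)
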