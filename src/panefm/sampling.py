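"""Sampling and enumeration of panEFMs (minimal functional reaction sets).

A panEFM is a subset of the pan-reactome that still produces biomass above a
cutoff (1% of the pan-reactome's own biomass flux in that environment) and
is minimal: deleting any single remaining reaction breaks functionality.
Sampling follows a single randomized greedy deletion sweep — each uniformly
random permutation of the deletable reactions yields one panEFM.  On small
networks all minimal sets can be enumerated exactly, which serves as the
oracle for the sampler.

The biomass reaction and exchange reactions are never deletion candidates:
removing an exchange would change the environment definition rather than
the reactome (a flag exists for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    Optional,
    Sequence,
    Set,
    Tuple,
)

import numpy as np
import pandas as pd

from .network import (
    GROWTH_EPS,
    Environment,
    FluxEvaluator,
    MetabolicNetwork,
)

#: Fraction of the pan-reactome's biomass flux a deletion must preserve.
DEFAULT_CUTOFF_FRAC = 0.01


@dataclass(frozen=True)
class PanEFM:
    """One minimal functional reaction set and its metabolite usage."""

    reactions: FrozenSet[str]
    environment_index: int = -1
    usage: FrozenSet[str] = frozenset()

    def __contains__(self, rid: str) -> bool:
        return rid in self.reactions

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass
class PanEFMCollection:
    """panEFMs sampled (or enumerated) per growth-supporting environment.

    ``samples`` maps environment index -> list of panEFMs; environments in
    which the pan-reactome cannot grow have no entry.  ``n_per_env`` is None
    for exhaustive (enumeration-based) collections, whose per-environment
    counts vary.
    """

    pan: MetabolicNetwork
    environments: Sequence[Environment]
    samples: Dict[int, List[PanEFM]] = field(default_factory=dict)
    n_per_env: Optional[int] = None
    seed: Optional[int] = None

    @property
    def environment_indices(self) -> List[int]:
        return sorted(self.samples)

    def all_panefms(self) -> List[PanEFM]:
        return [p for e in self.environment_indices for p in self.samples[e]]

    def distinct_sets(self) -> Set[FrozenSet[str]]:
        return {p.reactions for p in self.all_panefms()}


def _deletion_candidates(
    pan: MetabolicNetwork, include_exchanges: bool
) -> Tuple[str, ...]:
    if include_exchanges:
        return tuple(
            r for r in pan.reactions if r != pan.biomass_reaction_id
        )
    return pan.deletable_reaction_ids


def sample_panefm(
    pan: MetabolicNetwork,
    env: Environment,
    rng: np.random.Generator,
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
    include_exchanges: bool = False,
    environment_index: int = -1,
    record_usage: bool = True,
) -> PanEFM:
    """Draw one panEFM by a randomized greedy deletion sweep.

    Reactions are visited in a uniformly random order; each is deleted and
    the deletion is kept iff the remaining network's biomass flux strictly
    exceeds ``cutoff_frac`` times the pan-reactome's biomass flux in ``env``
    (otherwise the reaction is restored).  One full sweep returns a set that
    is minimal with respect to single deletions at the same cutoff.
    """
    ev = pan.evaluator()
    pan_flux = ev.biomass_flux(env)
    if pan_flux <= GROWTH_EPS:
        raise ValueError(
            f"environment {env.name or '?'} does not support growth of {pan.id}"
        )
    cutoff = cutoff_frac * pan_flux
    candidates = list(_deletion_candidates(pan, include_exchanges))
    order = rng.permutation(len(candidates))
    deleted: Set[str] = set()
    for k in order:
        rid = candidates[k]
        trial = frozenset(deleted | {rid})
        if ev.biomass_flux(env, trial) > cutoff:
            deleted.add(rid)
    kept = frozenset(set(pan.reactions) - deleted)
    usage: FrozenSet[str] = frozenset()
    if record_usage:
        usage = ev.solve(env, frozenset(deleted)).imported_metabolites
    return PanEFM(kept, environment_index, usage)


def growth_supporting_environments(
    network: MetabolicNetwork, environments: Sequence[Environment]
) -> List[int]:
    """Indices of environments where biomass flux exceeds ``GROWTH_EPS``."""
    ev = network.evaluator()
    return [
        i for i, env in enumerate(environments)
        if ev.biomass_flux(env) > GROWTH_EPS
    ]


def sample_collection(
    pan: MetabolicNetwork,
    environments: Sequence[Environment],
    n_per_env: int = 1000,
    seed: int = 0,
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
    include_exchanges: bool = False,
    record_usage: bool = True,
) -> PanEFMCollection:
    """``n_per_env`` independent panEFM draws per growth-supporting
    environment, with per-environment sub-seeds derived from ``seed``."""
    if n_per_env < 1:
        raise ValueError("n_per_env must be >= 1")
    environments = list(environments)
    coll = PanEFMCollection(pan, environments, n_per_env=n_per_env, seed=seed)
    children = np.random.SeedSequence(seed).spawn(len(environments))
    for i in growth_supporting_environments(pan, environments):
        rng = np.random.default_rng(children[i])
        coll.samples[i] = [
            sample_panefm(
                pan,
                environments[i],
                rng,
                cutoff_frac,
                include_exchanges,
                environment_index=i,
                record_usage=record_usage,
            )
            for _ in range(n_per_env)
        ]
    return coll


def enumerate_minimal_functional_sets(
    network: MetabolicNetwork,
    env: Environment,
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
    include_exchanges: bool = False,
    limit: int = 25,
) -> Set[FrozenSet[str]]:
    """All single-deletion-minimal functional reaction sets — exact.

    Depth-first search over deletion orders with memoization on the
    surviving set; every set reachable by functionality-preserving deletions
    from which no further deletion is possible is minimal (and every minimal
    set is reachable this way, because greedy deletion can always avoid
    touching the members of a target minimal set).  Only feasible on small
    networks; use the random sampler beyond ``limit`` deletable reactions.
    """
    candidates = _deletion_candidates(network, include_exchanges)
    if len(candidates) > limit:
        raise ValueError(
            f"{len(candidates)} deletable reactions exceed the enumeration "
            f"limit ({limit}); use sample_panefm / sample_collection instead"
        )
    ev = network.evaluator()
    pan_flux = ev.biomass_flux(env)
    if pan_flux <= GROWTH_EPS:
        return set()
    cutoff = cutoff_frac * pan_flux
    feasible_memo: Dict[FrozenSet[str], bool] = {}

    def feasible(deleted: FrozenSet[str]) -> bool:
        hit = feasible_memo.get(deleted)
        if hit is None:
            hit = ev.biomass_flux(env, deleted) > cutoff
            feasible_memo[deleted] = hit
        return hit

    minimal: Set[FrozenSet[str]] = set()
    seen: Set[FrozenSet[str]] = set()
    all_reactions = frozenset(network.reactions)

    stack: List[FrozenSet[str]] = [frozenset()]
    while stack:
        deleted = stack.pop()
        if deleted in seen:
            continue
        seen.add(deleted)
        children = [
            rid
            for rid in candidates
            if rid not in deleted and feasible(deleted | {rid})
        ]
        if not children:
            minimal.add(all_reactions - deleted)
        else:
            stack.extend(deleted | {rid} for rid in children)
    return minimal


def exhaustive_collection(
    pan: MetabolicNetwork,
    environments: Sequence[Environment],
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
    limit: int = 25,
    record_usage: bool = True,
) -> PanEFMCollection:
    """Collection holding *every* minimal set of every growth-supporting
    environment exactly once (the exhaustive counterpart of sampling)."""
    environments = list(environments)
    coll = PanEFMCollection(pan, environments, n_per_env=None)
    ev = pan.evaluator()
    for i in growth_supporting_environments(pan, environments):
        env = environments[i]
        sets = enumerate_minimal_functional_sets(
            pan, env, cutoff_frac, limit=limit
        )
        entry = []
        for s in sorted(sets, key=sorted):
            usage: FrozenSet[str] = frozenset()
            if record_usage:
                deleted = frozenset(set(pan.reactions) - s)
                usage = ev.solve(env, deleted).imported_metabolites
            entry.append(PanEFM(s, i, usage))
        coll.samples[i] = entry
    return coll


def audit_panefm(
    pan: MetabolicNetwork,
    env: Environment,
    panefm: PanEFM,
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
) -> bool:
    """Post-hoc check: functional, and minimal under single deletions."""
    ev = pan.evaluator()
    cutoff = cutoff_frac * ev.biomass_flux(env)
    deleted = frozenset(set(pan.reactions) - panefm.reactions)
    if ev.biomass_flux(env, deleted) <= cutoff:
        return False
    for rid in panefm.reactions:
        if rid == pan.biomass_reaction_id or pan.reactions[rid].is_exchange:
            continue
        if ev.biomass_flux(env, deleted | {rid}) > cutoff:
            return False
    return True


def reaction_presence_frame(collection: PanEFMCollection) -> pd.DataFrame:
    """Draw-level 0/1 membership matrix (rows = draws, cols = reactions),
    with a two-level index (environment index, draw number)."""
    rids = list(collection.pan.reactions)
    rows, index = [], []
    for e in collection.environment_indices:
        for k, p in enumerate(collection.samples[e]):
            rows.append([int(r in p.reactions) for r in rids])
            index.append((e, k))
    return pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["environment", "draw"]),
        columns=rids,
    )


def convergence_curve(
    pan: MetabolicNetwork,
    environments: Sequence[Environment],
    sizes: Sequence[int],
    seed_a: int,
    seed_b: int,
    cutoff_frac: float = DEFAULT_CUTOFF_FRAC,
) -> pd.DataFrame:
    """Reproducibility of mean reaction frequencies vs sample size.

    For each size ``s`` two independent collections of ``s`` panEFMs per
    environment are drawn with different seeds; their environment-averaged
    reaction-frequency vectors (over deletable reactions) are compared by
    Pearson correlation ("reproducibility") and mean squared error.
    """
    from .stats import reaction_frequency_matrix

    rows = []
    deletable = list(pan.deletable_reaction_ids)
    for s in sizes:
        means = []
        for seed in (seed_a, seed_b):
            coll = sample_collection(
                pan, environments, n_per_env=s, seed=seed,
                cutoff_frac=cutoff_frac, record_usage=False,
            )
            freq = reaction_frequency_matrix(coll)[deletable]
            means.append(freq.mean(axis=0).to_numpy())
        a, b = means
        if np.std(a) == 0 or np.std(b) == 0:
            r = 1.0 if np.allclose(a, b) else 0.0
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append((s, r, float(np.mean((a - b) ** 2))))
    return pd.DataFrame(rows, columns=["size", "reproducibility", "mse"])
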