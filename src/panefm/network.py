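"""Stoichiometric networks and their linear-programming evaluation.

The data model is a bipartite reaction/metabolite graph with flux bounds, a
set of exchange reactions that connect external metabolites to the
environment, and one designated biomass pseudo-reaction whose maximal flux
under steady state (flux balance analysis, FBA) is the growth proxy.

Sign conventions follow COBRA: negative stoichiometric coefficients are
consumed, an exchange reaction has stoichiometry ``{met: -1}`` so negative
exchange flux means import and positive flux means secretion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

import numpy as np
import pandas as pd

from . import _lp

#: Growth threshold operationalizing "biomass flux greater than zero with
#: five significant digits" (flux units: mmol gDW^-1 h^-1).
GROWTH_EPS = 1e-5

#: Numerical tolerance below which a flux (or a flux range in FVA) is zero.
FLUX_TOL = 1e-9

#: Default magnitude used for "unconstrained" bounds.
DEFAULT_BOUND = 1000.0

INTERNAL = "internal"
EXTERNAL = "external"


@dataclass(frozen=True)
class Metabolite:
    """A metabolite; compartment is derived from exchange-reaction contact."""

    id: str
    compartment: str = INTERNAL

    def __post_init__(self) -> None:
        if self.compartment not in (INTERNAL, EXTERNAL):
            raise ValueError(f"bad compartment {self.compartment!r} for {self.id}")


@dataclass(frozen=True)
class Reaction:
    """A reaction with signed stoichiometry (negative = consumed).

    ``has_gene_evidence`` is False for gap-filled reactions, i.e. reactions
    added to a draft model without support from the annotated genome.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    is_exchange: bool = False
    has_gene_evidence: bool = True

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if self.is_exchange and len(self.stoichiometry) != 1:
            raise ValueError(
                f"exchange reaction {self.id} must touch exactly one metabolite"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def exchange_metabolite(self) -> str:
        if not self.is_exchange:
            raise ValueError(f"{self.id} is not an exchange reaction")
        return next(iter(self.stoichiometry))


@dataclass(frozen=True)
class Environment:
    """Per-compound uptake bounds plus a binary oxygen state.

    ``uptake_bounds`` maps external metabolite ids to non-negative maximal
    import rates; compounds absent from the map cannot be imported.
    ``math.inf`` means unconstrained.  If ``oxygen_id`` is set, oxygen uptake
    is unconstrained when ``aerobic`` and zero otherwise, overriding any
    explicit entry.
    """

    uptake_bounds: Mapping[str, float]
    aerobic: bool = True
    oxygen_id: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        bounds = dict(self.uptake_bounds)
        for met, b in bounds.items():
            if math.isnan(b) or b < 0:
                raise ValueError(f"uptake bound for {met} must be >= 0, got {b}")
        object.__setattr__(self, "uptake_bounds", bounds)

    def bound(self, met_id: str) -> float:
        """Maximal import rate for ``met_id`` in this environment."""
        if self.oxygen_id is not None and met_id == self.oxygen_id:
            return math.inf if self.aerobic else 0.0
        return self.uptake_bounds.get(met_id, 0.0)

    def cache_key(self) -> Tuple:
        return (
            tuple(sorted(self.uptake_bounds.items())),
            self.aerobic,
            self.oxygen_id,
        )


@dataclass
class FluxSolution:
    """Outcome of one FBA solve."""

    biomass_flux: float
    exchange_fluxes: Dict[str, float]
    status: str
    fluxes: Dict[str, float] = field(default_factory=dict)

    @property
    def imported_metabolites(self) -> FrozenSet[str]:
        """External metabolites with import flux below ``-FLUX_TOL``."""
        return frozenset(
            m for m, v in self.exchange_fluxes.items() if v < -FLUX_TOL
        )


class MetabolicNetwork:
    """A stoichiometric network with a designated biomass reaction.

    Metabolite compartments are derived: a metabolite is external exactly
    when it is touched by an exchange reaction.  Iteration order over
    reactions and metabolites is deterministic (sorted by id).
    """

    def __init__(
        self,
        reactions: Iterable[Reaction],
        biomass_reaction_id: str,
        id: str = "network",
    ) -> None:
        self.id = id
        self.reactions: Dict[str, Reaction] = {}
        for rxn in reactions:
            if rxn.id in self.reactions:
                raise ValueError(f"duplicate reaction id {rxn.id}")
            self.reactions[rxn.id] = rxn
        self.reactions = dict(sorted(self.reactions.items()))
        if biomass_reaction_id not in self.reactions:
            raise ValueError(f"biomass reaction {biomass_reaction_id!r} not present")
        self.biomass_reaction_id = biomass_reaction_id
        external: Set[str] = set()
        for rxn in self.reactions.values():
            if rxn.is_exchange:
                external.add(rxn.exchange_metabolite)
        met_ids = sorted({m for r in self.reactions.values() for m in r.stoichiometry})
        self.metabolites: Dict[str, Metabolite] = {
            m: Metabolite(m, EXTERNAL if m in external else INTERNAL)
            for m in met_ids
        }
        self._evaluator: Optional["FluxEvaluator"] = None

    # -- basic introspection -------------------------------------------------

    @property
    def reaction_ids(self) -> Tuple[str, ...]:
        return tuple(self.reactions)

    @property
    def exchange_reactions(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions.values() if r.is_exchange}

    @property
    def external_metabolites(self) -> Tuple[str, ...]:
        return tuple(
            m for m, met in self.metabolites.items() if met.compartment == EXTERNAL
        )

    @property
    def deletable_reaction_ids(self) -> Tuple[str, ...]:
        """Reactions eligible for deletion: everything but biomass/exchanges."""
        return tuple(
            r
            for r in self.reactions
            if r != self.biomass_reaction_id and not self.reactions[r].is_exchange
        )

    def exchange_of(self, met_id: str) -> str:
        for rxn in self.reactions.values():
            if rxn.is_exchange and rxn.exchange_metabolite == met_id:
                return rxn.id
        raise KeyError(f"no exchange reaction for {met_id}")

    def __len__(self) -> int:
        return len(self.reactions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicNetwork):
            return NotImplemented
        if self.biomass_reaction_id != other.biomass_reaction_id:
            return False
        if set(self.reactions) != set(other.reactions):
            return False
        for rid, rxn in self.reactions.items():
            o = other.reactions[rid]
            if (
                rxn.stoichiometry != o.stoichiometry
                or rxn.lower_bound != o.lower_bound
                or rxn.upper_bound != o.upper_bound
                or rxn.is_exchange != o.is_exchange
                or rxn.has_gene_evidence != o.has_gene_evidence
            ):
                return False
        return True

    def evaluator(self) -> "FluxEvaluator":
        """Shared (cached) LP evaluator for this network."""
        if self._evaluator is None:
            self._evaluator = FluxEvaluator(self)
        return self._evaluator


class FluxEvaluator:
    """Repeated FBA/FVA on one network with cached LP state.

    Reaction deletions are applied as zeroed column bounds; results of
    growth queries are memoized per (environment, deleted set).
    """

    def __init__(self, network: MetabolicNetwork, big: float = DEFAULT_BOUND) -> None:
        self.network = network
        self.big = big
        met_index = {m: i for i, m in enumerate(network.metabolites)}
        entries: List[Tuple[int, int, float]] = []
        bounds: List[Tuple[float, float]] = []
        col_ids = list(network.reactions)
        for j, rid in enumerate(col_ids):
            rxn = network.reactions[rid]
            for met, coef in rxn.stoichiometry.items():
                entries.append((met_index[met], j, coef))
            bounds.append((rxn.lower_bound, rxn.upper_bound))
        self._base_bounds = list(bounds)
        self.lp = _lp.LinearProgram(len(met_index), col_ids, entries, bounds)
        self._biomass_col = self.lp.col_index[network.biomass_reaction_id]
        self.lp.set_objective(self._biomass_col, maximize=True)
        self._env_key: Optional[Tuple] = None
        self._disabled: FrozenSet[str] = frozenset()
        self._growth_cache: Dict[Tuple, float] = {}

    # -- state management ----------------------------------------------------

    def set_environment(self, env: Environment) -> None:
        key = env.cache_key()
        if key == self._env_key:
            return
        for rid, rxn in self.network.exchange_reactions.items():
            j = self.lp.col_index[rid]
            met = rxn.exchange_metabolite
            # the environment caps import magnitude; it never widens the
            # reaction's own bounds
            lb = max(rxn.lower_bound, -min(env.bound(met), self.big))
            ub = self._base_bounds[j][1]
            self._base_bounds[j] = (min(lb, ub), ub)
            if rid not in self._disabled:
                self.lp.set_bounds(j, min(lb, ub), ub)
        self._env_key = key

    def set_disabled(self, disabled: FrozenSet[str]) -> None:
        for rid in self._disabled - disabled:
            j = self.lp.col_index[rid]
            self.lp.set_bounds(j, *self._base_bounds[j])
        for rid in disabled - self._disabled:
            j = self.lp.col_index[rid]
            self.lp.set_bounds(j, 0.0, 0.0)
        self._disabled = frozenset(disabled)

    # -- queries -------------------------------------------------------------

    def biomass_flux(
        self, env: Environment, disabled: Iterable[str] = ()
    ) -> float:
        """Maximal biomass flux; 0.0 when the LP is infeasible."""
        disabled = frozenset(disabled)
        self.set_environment(env)
        key = (self._env_key, disabled)
        hit = self._growth_cache.get(key)
        if hit is not None:
            return hit
        self.set_disabled(disabled)
        self.lp.set_objective(self._biomass_col, maximize=True)
        status, value = self.lp.solve()
        if status == _lp.UNBOUNDED:
            raise RuntimeError(
                f"unbounded biomass flux in {self.network.id}: missing bound"
            )
        value = value if status == _lp.OPTIMAL else 0.0
        self._growth_cache[key] = value
        return value

    def solve(
        self, env: Environment, disabled: Iterable[str] = (), pfba: bool = False
    ) -> FluxSolution:
        """Deterministic biomass-optimal solution with the full flux vector.

        The simplex is restarted from the standard basis so the reported
        optimal vertex does not depend on previous solves.  With ``pfba``
        the flux vector is refined parsimoniously: total absolute flux is
        minimized at (numerically) fixed maximal biomass, removing the
        route-choice degeneracy of alternative optima.
        """
        disabled = frozenset(disabled)
        self.set_environment(env)
        self.set_disabled(disabled)
        self.lp.set_objective(self._biomass_col, maximize=True)
        status, value = self.lp.solve(fresh_basis=True)
        if status == _lp.UNBOUNDED:
            raise RuntimeError(
                f"unbounded biomass flux in {self.network.id}: missing bound"
            )
        if status != _lp.OPTIMAL:
            return FluxSolution(0.0, {}, _lp.INFEASIBLE)
        if pfba:
            fluxes = self._parsimonious_fluxes(value)
        else:
            cols = self.lp.column_values()
            fluxes = dict(zip(self.lp.col_ids, cols))
        exch = {
            rxn.exchange_metabolite: fluxes[rid]
            for rid, rxn in self.network.exchange_reactions.items()
            if rid not in disabled
        }
        self._growth_cache[(self._env_key, disabled)] = value
        return FluxSolution(value, exch, _lp.OPTIMAL, fluxes)

    def _parsimonious_fluxes(self, biomass_opt: float) -> Dict[str, float]:
        """Minimize total |flux| holding biomass at its optimum (via HiGHS
        with split auxiliary variables)."""
        from scipy.optimize import linprog
        from scipy.sparse import lil_matrix

        n = len(self.lp.col_ids)
        mets = list(self.network.metabolites)
        midx = {m: i for i, m in enumerate(mets)}
        S = lil_matrix((len(mets), 2 * n))
        bounds = []
        for j, rid in enumerate(self.lp.col_ids):
            rxn = self.network.reactions[rid]
            for m, c in rxn.stoichiometry.items():
                S[midx[m], j] = c
            lb, ub = self.lp.get_bounds(j)
            if j == self._biomass_col:
                lb = biomass_opt * (1.0 - 1e-9)
            bounds.append((max(lb, -self.big), min(ub, self.big)))
        # t_j >= |v_j| :  v - t <= 0  and  -v - t <= 0
        A_ub = lil_matrix((2 * n, 2 * n))
        for j in range(n):
            A_ub[j, j] = 1.0
            A_ub[j, n + j] = -1.0
            A_ub[n + j, j] = -1.0
            A_ub[n + j, n + j] = -1.0
        bounds += [(0.0, None)] * n
        c = np.concatenate([np.zeros(n), np.ones(n)])
        res = linprog(
            c,
            A_eq=S.tocsr(),
            b_eq=np.zeros(len(mets)),
            A_ub=A_ub.tocsr(),
            b_ub=np.zeros(2 * n),
            bounds=bounds,
            method="highs",
        )
        if res.status != 0:  # pragma: no cover - numerical safety net
            raise RuntimeError("parsimonious refinement failed")
        return dict(zip(self.lp.col_ids, res.x[:n]))

    def flux_range(
        self, env: Environment, reaction_id: str, disabled: Iterable[str] = ()
    ) -> Tuple[float, float]:
        """Min and max feasible flux of one reaction (biomass lower bound 0)."""
        disabled = frozenset(disabled)
        self.set_environment(env)
        self.set_disabled(disabled)
        j = self.lp.col_index[reaction_id]
        out = []
        for maximize in (False, True):
            self.lp.set_objective(j, maximize=maximize)
            status, value = self.lp.solve()
            if status == _lp.UNBOUNDED:
                value = math.copysign(self.big, 1 if maximize else -1)
            elif status != _lp.OPTIMAL:
                raise RuntimeError(
                    f"infeasible network {self.network.id} during FVA"
                )
            out.append(value)
        self.lp.set_objective(self._biomass_col, maximize=True)
        return out[0], out[1]


# -- module-level operations ------------------------------------------------


def fba(network: MetabolicNetwork, env: Environment) -> FluxSolution:
    """Flux balance analysis: maximize biomass flux in ``env``.

    Import magnitude of every exchange reaction is limited by the
    environment's uptake bound for its metabolite (compounds absent from the
    environment get bound 0).  Returns an infeasible solution with zero
    biomass flux when no steady state exists.
    """
    return network.evaluator().solve(env)


def is_functional(
    network: MetabolicNetwork, env: Environment, cutoff_flux: float = GROWTH_EPS
) -> bool:
    """True iff the maximal biomass flux strictly exceeds ``cutoff_flux``."""
    if cutoff_flux < 0:
        raise ValueError("cutoff_flux must be >= 0")
    return network.evaluator().biomass_flux(env) > cutoff_flux


def rich_environment_for(network: MetabolicNetwork) -> Environment:
    """Environment with every external metabolite of the network unconstrained."""
    return Environment(
        {m: math.inf for m in network.external_metabolites}, aerobic=True,
        name="rich",
    )


def fva_active_reactions(
    network: MetabolicNetwork,
    env: Optional[Environment] = None,
    tol: float = FLUX_TOL,
) -> Set[str]:
    """Reactions whose feasible flux range exceeds ``tol``.

    By default flux variability is assessed in the rich environment (all
    exchanges open) with the biomass lower bound at 0, so "active" means the
    reaction can carry flux at all rather than under one particular medium.
    """
    if env is None:
        env = rich_environment_for(network)
    ev = network.evaluator()
    if ev.biomass_flux(env) <= GROWTH_EPS:
        raise ValueError(f"network {network.id} is not functional in {env.name or 'env'}")
    active = set()
    for rid in network.reactions:
        lo, hi = ev.flux_range(env, rid)
        if hi - lo > tol or abs(hi) > tol or abs(lo) > tol:
            active.add(rid)
    return active


def fva_table(
    network: MetabolicNetwork, env: Optional[Environment] = None
) -> pd.DataFrame:
    """Per-reaction (min, max) feasible flux as a DataFrame."""
    if env is None:
        env = rich_environment_for(network)
    ev = network.evaluator()
    rows = []
    for rid in network.reactions:
        lo, hi = ev.flux_range(env, rid)
        rows.append((rid, lo, hi))
    return pd.DataFrame(rows, columns=["reaction", "minimum", "maximum"]).set_index(
        "reaction"
    )


def merge_pan_reactome(
    networks: Sequence[MetabolicNetwork], id: str = "pan"
) -> MetabolicNetwork:
    """Merge strain reactomes into a pan-reactome.

    Each reaction is added once (deduplicated by id; shared ids must have
    identical stoichiometry).  Bounds of shared reactions are merged to the
    widest interval and gene evidence is kept if any strain has it.  The
    biomass reaction must be shared by all inputs.  Exchange reactions are
    unioned, so every compound transported by any strain is exchangeable in
    the pan-reactome.
    """
    if not networks:
        raise ValueError("need at least one network to merge")
    biomass_ids = {n.biomass_reaction_id for n in networks}
    if len(biomass_ids) != 1:
        raise ValueError(f"differing biomass reactions: {sorted(biomass_ids)}")
    biomass_id = biomass_ids.pop()
    bm_stoich = {
        tuple(sorted(n.reactions[biomass_id].stoichiometry.items())) for n in networks
    }
    if len(bm_stoich) != 1:
        raise ValueError("biomass reaction stoichiometry differs between inputs")
    merged: Dict[str, Reaction] = {}
    for net in networks:
        for rid, rxn in net.reactions.items():
            if rid not in merged:
                merged[rid] = rxn
                continue
            prev = merged[rid]
            if prev.stoichiometry != rxn.stoichiometry:
                raise ValueError(f"conflicting stoichiometry for reaction {rid}")
            if prev.is_exchange != rxn.is_exchange:
                raise ValueError(f"conflicting exchange flag for reaction {rid}")
            merged[rid] = Reaction(
                rid,
                prev.stoichiometry,
                min(prev.lower_bound, rxn.lower_bound),
                max(prev.upper_bound, rxn.upper_bound),
                is_exchange=prev.is_exchange,
                has_gene_evidence=prev.has_gene_evidence or rxn.has_gene_evidence,
            )
    return MetabolicNetwork(merged.values(), biomass_id, id=id)


def subnetwork(
    network: MetabolicNetwork, keep: Iterable[str], id: Optional[str] = None
) -> MetabolicNetwork:
    """Restrict a network to ``keep`` (must include biomass); orphan
    metabolites are dropped implicitly."""
    keep = set(keep)
    unknown = keep - set(network.reactions)
    if unknown:
        raise KeyError(f"unknown reactions: {sorted(unknown)}")
    if network.biomass_reaction_id not in keep:
        raise ValueError("biomass reaction must be kept in a subnetwork")
    return MetabolicNetwork(
        [network.reactions[r] for r in sorted(keep)],
        network.biomass_reaction_id,
        id=id or f"{network.id}|sub{len(keep)}",
    )
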