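"""Synthetic fixtures: the toy pan-reactome, planted random pan-reactomes,
and synthetic abundance tables.

These generators are the package's no-download test surface.  The toy
pan-reactome is a 14-reaction network (unit stoichiometries, biomass built
from three precursors) in which five reactions are irreplaceable in every
environment while the rest belong to interchangeable routes whose
availability depends on which external metabolites are present.  The
random generator plants the same motifs — an essential backbone,
alternative pathway groups gated by distinct external metabolites, and
byproduct/export pairs — at configurable sizes with recorded ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .envball import presence_absence_environments, rich_environment
from .network import (
    Environment,
    MetabolicNetwork,
    Reaction,
)
from .sampling import enumerate_minimal_functional_sets

TOY_DATA = "toy_model_synthetic.tsv"


def _parse_stoichiometry(spec: str) -> Dict[str, float]:
    out: Dict[str, float] = {}
    for part in spec.split(";"):
        met, coef = part.split(":")
        out[met] = float(coef)
    return out


def exchange_reaction(met_id: str, lb: float = -1000.0, ub: float = 1000.0) -> Reaction:
    return Reaction(f"EX_{met_id}", {met_id: -1.0}, lb, ub, is_exchange=True)


def build_toy_model() -> MetabolicNetwork:
    """The 14-reaction toy pan-reactome plus biomass and exchanges.

    Reactions are read from the packaged table (a synthetic reconstruction
    of the original toy network, see the data file header); an exchange
    reaction is added for every external (``_e``) metabolite.  Environments
    for this network are presence/absence: a present compound is available
    at an unconstrained rate.
    """
    path = resources.files("panefm.data").joinpath(TOY_DATA)
    with path.open() as handle:
        table = pd.read_csv(handle, sep="\t", comment="#")
    reactions = [
        Reaction(
            row.reaction_id,
            _parse_stoichiometry(row.stoichiometry),
            float(row.lower_bound),
            float(row.upper_bound),
        )
        for row in table.itertuples()
    ]
    externals = sorted(
        {
            m
            for r in reactions
            for m in r.stoichiometry
            if m.endswith("_e")
        }
    )
    reactions.extend(exchange_reaction(m) for m in externals)
    return MetabolicNetwork(reactions, "biomass", id="toy_pan")


def toy_rich_environment() -> Environment:
    return rich_environment([f"M{k}_e" for k in range(1, 10)])


def toy_presence_absence_environments() -> List[Environment]:
    """All 512 presence/absence environments over the toy's nine compounds."""
    return presence_absence_environments([f"M{k}_e" for k in range(1, 10)])


def toy_strain_reactomes() -> List[MetabolicNetwork]:
    """Three functional strain reactomes whose union is the toy pan-reactome.

    Each strain carries the five universally required reactions plus one
    route to each interchangeable precursor; strains 1 and 2 share R8, so
    reaction frequencies across the three strains take values 1/3, 2/3 and 1.
    """
    toy = build_toy_model()
    strains = {
        "toy_strain_1": ["R1", "R10", "R8"],
        "toy_strain_2": ["R2", "R7", "R8"],
        "toy_strain_3": ["R3", "R4", "R6", "R11"],
    }
    core = ["R5", "R9", "R12", "R13", "R14", "biomass"]
    out = []
    for sid, extra in strains.items():
        rxns = [toy.reactions[r] for r in core + extra]
        touched = sorted(
            {
                m
                for r in rxns
                for m in r.stoichiometry
                if m.endswith("_e")
            }
        )
        rxns.extend(exchange_reaction(m) for m in touched)
        out.append(MetabolicNetwork(rxns, "biomass", id=sid))
    return out


# -- planted random pan-reactomes -------------------------------------------


@dataclass
class PlantedPanReactome:
    """A generated pan-reactome with recorded ground truth."""

    network: MetabolicNetwork
    essential: Set[str]
    alt_groups: List[List[str]]
    conditional: Dict[str, str]  # exporter reaction -> enabling external

    @property
    def compound_ids(self) -> List[str]:
        return sorted(self.network.external_metabolites)

    def rich_environment(self) -> Environment:
        return rich_environment(self.compound_ids)


def random_pan_reactome(
    n_precursors: int = 3,
    n_alt_routes: int = 3,
    n_conditional: int = 1,
    seed: int = 0,
) -> PlantedPanReactome:
    """Generate a pan-reactome with planted motifs.

    One biomass precursor is synthesized by ``n_alt_routes`` interchangeable
    single-step routes, each gated by its own external metabolite; every
    other precursor hangs off a linear essential backbone (length 1 or 2,
    seed-dependent) fed by a required external compound.  ``n_conditional``
    of the routes additionally produce a byproduct that must be exported
    through a dedicated exporter reaction (making the exporter's presence
    conditional on the route's enabling metabolite).  Ground truth (which
    reactions are always essential, the route groups, and the
    exporter-to-metabolite map) is recorded and checked by enumeration in
    the rich environment at construction time.
    """
    if min(n_precursors, n_alt_routes) < 1 or n_conditional < 0:
        raise ValueError("n_precursors, n_alt_routes >= 1; n_conditional >= 0")
    if n_conditional > n_alt_routes:
        raise ValueError("at most one byproduct motif per route")
    rng = np.random.default_rng(seed)
    reactions: List[Reaction] = []
    essential: Set[str] = set()
    externals: List[str] = []

    bm_stoich: Dict[str, float] = {}
    for i in range(1, n_precursors + 1):
        bm_stoich[f"P{i}"] = -1.0

    # backbone precursors (everything except precursor 1 when routes > 1)
    for i in range(2, n_precursors + 1):
        src = f"C{i}_e"
        externals.append(src)
        length = 1 + int(rng.integers(2))
        prev = src
        for step in range(1, length + 1):
            product = f"P{i}" if step == length else f"X{i}_{step}"
            rid = f"B{i}_{step}"
            reactions.append(Reaction(rid, {prev: -1.0, product: 1.0}))
            essential.add(rid)
            prev = product

    # alternative routes to precursor 1
    alt_groups: List[List[str]] = []
    conditional: Dict[str, str] = {}
    route_order = rng.permutation(n_alt_routes)
    for r in range(1, n_alt_routes + 1):
        gate = f"G{r}_e"
        externals.append(gate)
        rid = f"ALT{r}"
        group = [rid]
        stoich = {gate: -1.0, "P1": 1.0}
        if int(route_order[r - 1]) < n_conditional:
            waste = f"W{r}"
            stoich[waste] = 1.0
            exporter = f"EXP{r}"
            reactions.append(Reaction(exporter, {waste: -1.0, f"W{r}_e": 1.0}))
            externals.append(f"W{r}_e")
            conditional[exporter] = gate
            group.append(exporter)
        reactions.append(Reaction(rid, stoich))
        alt_groups.append(group)
    if n_alt_routes == 1:
        essential.update(alt_groups[0])
        alt_groups = []

    reactions.append(Reaction("biomass", bm_stoich))
    reactions.extend(exchange_reaction(m) for m in sorted(set(externals)))
    net = MetabolicNetwork(reactions, "biomass", id=f"planted[{seed}]")
    planted = PlantedPanReactome(net, essential, alt_groups, conditional)

    # construction-time audit in the rich environment
    sets = enumerate_minimal_functional_sets(net, planted.rich_environment())
    if not sets:
        raise RuntimeError("generated network is not functional in rich env")
    common = frozenset.intersection(*sets)
    if not planted.essential <= common:
        raise RuntimeError("planted essential reactions are not all essential")
    return planted


# -- synthetic abundance tables ----------------------------------------------


def synthetic_abundance_table(
    n_samples: int = 60,
    n_taxa: int = 12,
    n_biomes: int = 3,
    seed: int = 0,
    concentration: float = 50.0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Relative-abundance table with planted specialists and generalists.

    Each biome has its own expected community profile; generalist taxa get
    a positive expected abundance in every biome while each specialist is
    confined to a single home biome.  Sample compositions are Dirichlet
    draws around the biome profile (``concentration`` controls within-biome
    noise); rows sum to one.  Returns the samples x taxa table and a Series
    labelling each taxon ``"generalist"`` or ``"specialist"``.
    """
    if min(n_samples, n_taxa, n_biomes) < 2:
        raise ValueError("need at least 2 samples, taxa and biomes")
    rng = np.random.default_rng(seed)
    taxa = [f"t{k:03d}" for k in range(n_taxa)]
    n_gen = n_taxa // 2
    labels = pd.Series(
        ["generalist"] * n_gen + ["specialist"] * (n_taxa - n_gen), index=taxa
    )
    home = {
        taxa[k]: (k - n_gen) % n_biomes for k in range(n_gen, n_taxa)
    }
    base = np.zeros((n_biomes, n_taxa))
    for b in range(n_biomes):
        for k, t in enumerate(taxa):
            if labels[t] == "generalist":
                base[b, k] = rng.gamma(2.0, 1.0) + 0.2
            elif home[t] == b:
                base[b, k] = rng.gamma(2.0, 1.5) + 0.5
    base /= base.sum(axis=1, keepdims=True)
    rows = []
    sample_ids = []
    for s in range(n_samples):
        b = s % n_biomes
        alpha = base[b] * concentration
        profile = np.zeros(n_taxa)
        mask = alpha > 0
        profile[mask] = rng.dirichlet(alpha[mask])
        rows.append(profile)
        sample_ids.append(f"s{s:03d}_b{b}")
    table = pd.DataFrame(rows, index=sample_ids, columns=taxa)
    return table, labels
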