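"""Readers and writers for models, environments, and result matrices.

Models round-trip through SBML Level 3 (FBC, via cobrapy/libsbml) or a
plain JSON schema modelled on ModelSEED draft exports; gene evidence is
carried by gene-association annotations (an unannotated internal reaction
is treated as gap-filled).  Environments and frequency matrices are TSV;
panEFM collections are stored as a sparse draws x reactions presence
matrix in MatrixMarket format with TSV index files.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .envball import EnvironmentBall
from .network import Environment, MetabolicNetwork, Reaction
from .sampling import PanEFM, PanEFMCollection

PathLike = Union[str, Path]


# -- cobra conversion and SBML ----------------------------------------------


def to_cobra(network: MetabolicNetwork):
    """Convert to a cobrapy model (SBML export, external cross-checks)."""
    import cobra

    model = cobra.Model(network.id)
    mets = {
        m: cobra.Metabolite(
            m, compartment="e" if met.compartment == "external" else "c"
        )
        for m, met in network.metabolites.items()
    }
    rxns = []
    for rid, rxn in network.reactions.items():
        c = cobra.Reaction(
            rid, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound
        )
        rxns.append(c)
    model.add_reactions(rxns)
    for rid, rxn in network.reactions.items():
        c = model.reactions.get_by_id(rid)
        c.add_metabolites({mets[m]: v for m, v in rxn.stoichiometry.items()})
        if (
            rxn.has_gene_evidence
            and not rxn.is_exchange
            and rid != network.biomass_reaction_id
        ):
            c.gene_reaction_rule = f"G_{rid}"
    model.objective = network.biomass_reaction_id
    return model


def from_cobra(model, biomass_id: Optional[str] = None) -> MetabolicNetwork:
    """Build a network from a cobrapy model.

    Exchange reactions are single-metabolite boundary reactions (cobra's
    ``model.exchanges`` plus anything named ``EX_*``); a reaction named like
    an exchange but touching several metabolites is rejected.  Internal
    reactions without a gene association are flagged gap-filled.
    """
    if biomass_id is None:
        from cobra.util.solver import linear_reaction_coefficients

        candidates = sorted(
            r.id for r, c in linear_reaction_coefficients(model).items() if c
        )
        if len(candidates) != 1:
            raise ValueError(
                f"cannot infer biomass reaction from objective {candidates}"
            )
        biomass_id = candidates[0]
    exchange_ids = {r.id for r in model.exchanges}
    reactions = []
    for r in model.reactions:
        looks_exchange = r.id in exchange_ids or r.id.startswith("EX_")
        if looks_exchange and len(r.metabolites) != 1:
            raise ValueError(
                f"exchange reaction {r.id} touches {len(r.metabolites)} metabolites"
            )
        reactions.append(
            Reaction(
                r.id,
                {m.id: v for m, v in r.metabolites.items()},
                r.lower_bound,
                r.upper_bound,
                is_exchange=looks_exchange,
                has_gene_evidence=bool(r.genes)
                or looks_exchange
                or r.id == biomass_id,
            )
        )
    return MetabolicNetwork(reactions, biomass_id, id=model.id or "model")


def read_model(path: PathLike, format: str = "sbml") -> MetabolicNetwork:
    path = Path(path)
    if format == "sbml":
        import cobra

        return from_cobra(cobra.io.read_sbml_model(str(path)))
    if format == "model_json":
        return read_model_json(path)
    raise ValueError(f"unknown model format {format!r}")


def write_model(
    network: MetabolicNetwork, path: PathLike, format: str = "sbml"
) -> None:
    path = Path(path)
    if format == "sbml":
        import cobra

        cobra.io.write_sbml_model(to_cobra(network), str(path))
    elif format == "model_json":
        write_model_json(network, path)
    else:
        raise ValueError(f"unknown model format {format!r}")


# -- ModelSEED-style JSON ----------------------------------------------------


def read_model_json(path: PathLike) -> MetabolicNetwork:
    """Read the package's ModelSEED-style JSON schema.

    Expected top-level keys: ``id``, ``biomass`` (reaction id), and
    ``reactions`` — a list of objects with ``id``, ``stoichiometry`` (map
    metabolite -> signed coefficient), ``lower_bound``, ``upper_bound``,
    optional ``is_exchange`` and optional ``gapfilled`` flags.
    """
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model JSON {path}: {exc}") from exc
    reactions = []
    for entry in payload["reactions"]:
        try:
            reactions.append(
                Reaction(
                    entry["id"],
                    {m: float(v) for m, v in entry["stoichiometry"].items()},
                    float(entry.get("lower_bound", 0.0)),
                    float(entry.get("upper_bound", 1000.0)),
                    is_exchange=bool(entry.get("is_exchange", False)),
                    has_gene_evidence=not bool(entry.get("gapfilled", False)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(
                f"malformed reaction entry {entry.get('id', '?')!r}: {exc}"
            ) from exc
    return MetabolicNetwork(
        reactions, payload["biomass"], id=payload.get("id", "model")
    )


def write_model_json(network: MetabolicNetwork, path: PathLike) -> None:
    payload = {
        "id": network.id,
        "biomass": network.biomass_reaction_id,
        "reactions": [
            {
                "id": rid,
                "stoichiometry": rxn.stoichiometry,
                "lower_bound": rxn.lower_bound,
                "upper_bound": rxn.upper_bound,
                "is_exchange": rxn.is_exchange,
                "gapfilled": not rxn.has_gene_evidence,
            }
            for rid, rxn in network.reactions.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# -- environments ------------------------------------------------------------


def write_environment(env: Environment, path: PathLike) -> None:
    """Two-column TSV (compound_id, uptake_bound) with flag header lines."""
    lines = [f"# aerobic: {int(env.aerobic)}"]
    if env.oxygen_id is not None:
        lines.append(f"# oxygen_id: {env.oxygen_id}")
    lines.append("compound_id\tuptake_bound")
    for met, b in sorted(env.uptake_bounds.items()):
        lines.append(f"{met}\t{'inf' if math.isinf(b) else repr(b)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_environment(path: PathLike) -> Environment:
    aerobic = True
    oxygen_id = None
    bounds: Dict[str, float] = {}
    header_seen = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            key = key.strip()
            if key == "aerobic":
                aerobic = bool(int(value.strip()))
            elif key == "oxygen_id":
                oxygen_id = value.strip()
            continue
        if not header_seen:
            header_seen = True
            continue
        met, _, b = line.partition("\t")
        bounds[met] = float(b)
    return Environment(bounds, aerobic=aerobic, oxygen_id=oxygen_id,
                       name=Path(path).stem)


def write_ball(ball: EnvironmentBall, path: PathLike) -> None:
    ball.to_frame().to_csv(path, sep="\t", index_label="environment")


def read_ball(
    path: PathLike,
    oxygen_id: Optional[str] = None,
    water_id: Optional[str] = None,
) -> EnvironmentBall:
    frame = pd.read_csv(path, sep="\t", index_col="environment")
    compounds = [c for c in frame.columns if c not in ("aerobic", water_id)]
    envs = []
    for i, row in frame.iterrows():
        bounds = {c: float(row[c]) for c in compounds}
        if water_id is not None:
            bounds[water_id] = float(row[water_id])
        envs.append(
            Environment(
                bounds,
                aerobic=bool(row["aerobic"]),
                oxygen_id=oxygen_id,
                name=f"ball[{i}]",
            )
        )
    water_rate = (
        float(frame[water_id].iloc[0]) if water_id is not None else 1000.0
    )
    return EnvironmentBall(envs, compounds, seed=-1, water_id=water_id,
                           oxygen_id=oxygen_id, water_rate=water_rate)


# -- matrices and collections ------------------------------------------------


def write_matrix(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index_label="environment")


def read_matrix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="environment")


def write_collection(coll: PanEFMCollection, prefix: PathLike) -> None:
    """Write a collection as ``<prefix>.mtx`` (draws x reactions presence),
    ``<prefix>.usage.mtx`` (draws x external metabolites), and TSV indexes."""
    prefix = Path(prefix)
    rids = list(coll.pan.reactions)
    mets = list(coll.pan.external_metabolites)
    rid_pos = {r: j for j, r in enumerate(rids)}
    met_pos = {m: j for j, m in enumerate(mets)}
    efms = coll.all_panefms()
    pres = scipy.sparse.lil_matrix((len(efms), len(rids)), dtype=np.int8)
    usage = scipy.sparse.lil_matrix((len(efms), len(mets)), dtype=np.int8)
    env_of_draw = []
    for k, p in enumerate(efms):
        env_of_draw.append(p.environment_index)
        for r in p.reactions:
            pres[k, rid_pos[r]] = 1
        for m in p.usage:
            usage[k, met_pos[m]] = 1
    scipy.io.mmwrite(str(prefix) + ".mtx", pres.tocoo())
    scipy.io.mmwrite(str(prefix) + ".usage.mtx", usage.tocoo())
    pd.Series(env_of_draw, name="environment").to_csv(
        str(prefix) + ".draws.tsv", sep="\t", index_label="draw"
    )
    Path(str(prefix) + ".reactions.tsv").write_text("\n".join(rids) + "\n")
    Path(str(prefix) + ".metabolites.tsv").write_text("\n".join(mets) + "\n")


def read_collection(
    pan: MetabolicNetwork,
    environments: Sequence[Environment],
    prefix: PathLike,
) -> PanEFMCollection:
    prefix = Path(prefix)
    rids = Path(str(prefix) + ".reactions.tsv").read_text().split()
    mets = Path(str(prefix) + ".metabolites.tsv").read_text().split()
    pres = scipy.io.mmread(str(prefix) + ".mtx").tocsr()
    usage = scipy.io.mmread(str(prefix) + ".usage.mtx").tocsr()
    env_of_draw = pd.read_csv(
        str(prefix) + ".draws.tsv", sep="\t", index_col="draw"
    )["environment"].to_list()
    coll = PanEFMCollection(pan, list(environments))
    counts: Dict[int, int] = {}
    for k, e in enumerate(env_of_draw):
        row = pres[k].indices
        urow = usage[k].indices
        efm = PanEFM(
            frozenset(rids[j] for j in row),
            e,
            frozenset(mets[j] for j in urow),
        )
        coll.samples.setdefault(e, []).append(efm)
        counts[e] = counts.get(e, 0) + 1
    if counts and len(set(counts.values())) == 1:
        coll.n_per_env = next(iter(counts.values()))
    return coll
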