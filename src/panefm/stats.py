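"""Frequency matrices, environment-driven scores, and pan-genome summaries.

The central object is a frequency matrix: growth-supporting environments as
rows, features (reactions or external metabolites) as columns, entries in
[0, 1] giving how often the feature occurs in the panEFMs of that
environment.  Residuals against the column mean quantify how much an
environment shifts a feature away from its overall expectation; the
environment-driven score (EDS) is the per-feature standard deviation of
those residuals scaled by the largest such standard deviation, so EDS = 0
marks environment-independent features ("nature") and EDS near 1 marks the
most environment-driven one ("nutrition").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .network import Environment, MetabolicNetwork, fva_active_reactions
from .sampling import PanEFMCollection

#: Residual standard deviations below this are treated as exactly zero.
RESIDUAL_TOL = 1e-12


# -- frequency matrices ------------------------------------------------------


def reaction_frequency_matrix(collection: PanEFMCollection) -> pd.DataFrame:
    """Entry (e, r): fraction of environment ``e``'s panEFMs containing ``r``."""
    if not collection.samples:
        raise ValueError("empty panEFM collection")
    rids = list(collection.pan.reactions)
    rows = {}
    for e in collection.environment_indices:
        sets = [p.reactions for p in collection.samples[e]]
        rows[e] = [sum(r in s for s in sets) / len(sets) for r in rids]
    return pd.DataFrame.from_dict(rows, orient="index", columns=rids)


def metabolite_usage_matrix(collection: PanEFMCollection) -> pd.DataFrame:
    """Entry (e, m): fraction of environment ``e``'s panEFMs importing ``m``."""
    if not collection.samples:
        raise ValueError("empty panEFM collection")
    mets = list(collection.pan.external_metabolites)
    rows = {}
    for e in collection.environment_indices:
        usages = [p.usage for p in collection.samples[e]]
        rows[e] = [sum(m in u for u in usages) / len(usages) for m in mets]
    return pd.DataFrame.from_dict(rows, orient="index", columns=mets)


def metabolite_usage(
    panefm, pan: MetabolicNetwork, env: Environment, pfba: bool = False
) -> FrozenSet[str]:
    """External metabolites imported in the biomass-optimal solution of a
    panEFM subnetwork (exchange flux < -tolerance means import).

    ``pfba`` refines the solution parsimoniously (minimal total flux at
    fixed biomass), removing route-choice degeneracy in non-minimal
    networks."""
    deleted = frozenset(set(pan.reactions) - set(panefm.reactions))
    sol = pan.evaluator().solve(env, deleted, pfba=pfba)
    if sol.status != "optimal":
        raise ValueError("panEFM subnetwork is infeasible in this environment")
    return sol.imported_metabolites


# -- residuals and EDS -------------------------------------------------------


def residual_matrix(freq: pd.DataFrame) -> pd.DataFrame:
    """Per-environment frequency minus the column mean (column sums ~ 0)."""
    if len(freq) < 2:
        raise ValueError("need at least two environments to form residuals")
    return freq - freq.mean(axis=0)


def environment_driven_score(freq: pd.DataFrame) -> pd.Series:
    """EDS per feature: sd of residuals over environments, scaled by the
    maximum sd across features of the same matrix (population sd, ddof 0).

    Ranges over [0, 1]; identically-distributed features score 0, the
    feature with the largest residual spread scores exactly 1.  When no
    feature varies at all, every score is 0.
    """
    resid = residual_matrix(freq)
    sd = resid.std(axis=0, ddof=0)
    top = sd.max()
    if top <= RESIDUAL_TOL:
        return pd.Series(0.0, index=freq.columns)
    return sd / top


def significant_env_driven(
    freq: pd.DataFrame,
    n_per_env: int,
    alpha: float = 0.05,
) -> Set[str]:
    """Features whose across-environment variance exceeds sampling noise.

    Null: frequencies are binomial proportions from ``n_per_env`` draws at a
    common rate, so the residual variance is sd0^2 = p(1-p)/n_per_env with p
    estimated by the column mean.  The observed variance is compared to the
    null by a one-sided Z-test (normal approximation of the chi-square
    variance statistic), Benjamini-Hochberg adjusted at ``alpha``.
    """
    if n_per_env < 1:
        raise ValueError("n_per_env must be >= 1")
    n_env = len(freq)
    if n_env < 2:
        raise ValueError("need at least two environments")
    pvals = []
    for col in freq.columns:
        x = freq[col].to_numpy(float)
        pbar = x.mean()
        var0 = pbar * (1.0 - pbar) / n_per_env
        s2 = x.var(ddof=0)
        if var0 <= 0.0 or s2 <= 0.0:
            pvals.append(1.0)
            continue
        chi2 = n_env * s2 / var0
        z = (chi2 - (n_env - 1)) / math.sqrt(2.0 * (n_env - 1))
        pvals.append(float(sps.norm.sf(z)))
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return {c for c, rej in zip(freq.columns, reject) if rej}


# -- metabolite-reaction associations ---------------------------------------


@dataclass
class AssociationResult:
    """Pairwise Pearson association between metabolite usage and reaction
    frequency residuals (metabolites as rows, reactions as columns)."""

    correlation: pd.DataFrame
    p_value: pd.DataFrame
    adjusted_p: pd.DataFrame

    def significant_pairs(self, alpha: float = 0.05) -> List[tuple]:
        mask = self.adjusted_p < alpha
        return [
            (m, r)
            for m in self.correlation.index
            for r in self.correlation.columns
            if mask.at[m, r]
        ]


def metabolite_reaction_association(
    reaction_freq: pd.DataFrame,
    metabolite_freq: pd.DataFrame,
) -> AssociationResult:
    """Correlate reaction-frequency and metabolite-usage residuals.

    Pearson correlation over environments for every (metabolite, reaction)
    pair; features with (numerically) zero residuals are omitted.  P-values
    come from the exact t distribution of the correlation coefficient and
    are Benjamini-Hochberg adjusted over all retained pairs.
    """
    if not reaction_freq.index.equals(metabolite_freq.index):
        raise ValueError("environment rows of the two matrices do not match")
    n = len(reaction_freq)
    if n < 3:
        raise ValueError("need at least three environments for correlations")
    rf = residual_matrix(reaction_freq)
    mf = residual_matrix(metabolite_freq)
    rf = rf.loc[:, rf.std(axis=0, ddof=0) > RESIDUAL_TOL]
    mf = mf.loc[:, mf.std(axis=0, ddof=0) > RESIDUAL_TOL]
    if rf.empty or mf.empty:
        empty = pd.DataFrame(index=mf.columns, columns=rf.columns, dtype=float)
        return AssociationResult(empty, empty.copy(), empty.copy())
    a = mf.to_numpy(float)
    b = rf.to_numpy(float)
    a = (a - a.mean(0)) / a.std(0, ddof=0)
    b = (b - b.mean(0)) / b.std(0, ddof=0)
    corr = np.clip(a.T @ b / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = corr * np.sqrt((n - 2) / np.maximum(1.0 - corr**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    _, adj, _, _ = multipletests(p.ravel(), method="fdr_bh")
    mk = list(mf.columns)
    rk = list(rf.columns)
    return AssociationResult(
        pd.DataFrame(corr, index=mk, columns=rk),
        pd.DataFrame(p, index=mk, columns=rk),
        pd.DataFrame(adj.reshape(p.shape), index=mk, columns=rk),
    )


# -- natural frequencies and pan-genome summaries ----------------------------


def natural_reaction_frequencies(
    strain_networks: Sequence[MetabolicNetwork],
    pan: MetabolicNetwork,
    require_active: bool = True,
) -> pd.Series:
    """Frequency of each pan reaction across strain reactomes.

    Restricted to reactions with gene evidence (a strain counts as carrying
    a reaction only when its copy is not gap-filled) and, when
    ``require_active``, to reactions with non-zero flux variability in the
    pan-reactome's rich environment.  Reactions that are gap-filled in every
    strain are excluded from the result entirely.
    """
    if not strain_networks:
        raise ValueError("empty strain list")
    active = (
        fva_active_reactions(pan) if require_active else set(pan.reactions)
    )
    out = {}
    n = len(strain_networks)
    for rid in pan.reactions:
        if rid not in active:
            continue
        count = sum(
            1
            for s in strain_networks
            if rid in s.reactions and s.reactions[rid].has_gene_evidence
        )
        if count == 0:
            continue  # gap-filled everywhere (or absent): no gene evidence
        out[rid] = count / n
    return pd.Series(out, dtype=float)


@dataclass
class Partition:
    core: Set[str]
    shell: Set[str]
    cloud: Set[str]


def partition_core_shell_cloud(
    freq: Mapping[str, float], core: float = 0.98, cloud: float = 0.03
) -> Partition:
    """Partition features by frequency: core >= 98%, cloud <= 3%, shell between."""
    c, s, d = set(), set(), set()
    for f, v in dict(freq).items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"frequency of {f} outside [0, 1]: {v}")
        if v >= core:
            c.add(f)
        elif v <= cloud:
            d.add(f)
        else:
            s.add(f)
    return Partition(c, s, d)


def fluidity(
    sets: Sequence[Iterable[str]],
    max_pairs: Optional[int] = None,
    seed: int = 0,
) -> float:
    """Genome fluidity: mean over unordered pairs (k, l) of
    (U_k + U_l) / (M_k + M_l), U = elements unique to one set, M = set size.

    0 for identical sets, 1 for disjoint ones.  For large inputs,
    ``max_pairs`` random pairs are used instead of the full quadratic sweep.
    """
    sets = [frozenset(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if any(len(s) == 0 for s in sets):
        raise ValueError("empty set in input")
    n = len(sets)
    pairs = [(k, l) for k in range(n) for l in range(k + 1, n)]
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    total = 0.0
    for k, l in pairs:
        a, b = sets[k], sets[l]
        total += (len(a - b) + len(b - a)) / (len(a) + len(b))
    return total / len(pairs)


def diversity(freq: pd.DataFrame) -> float:
    """Average squared pairwise Euclidean distance between matrix rows."""
    x = np.asarray(freq, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least two rows")
    # sum over unordered pairs of ||x_k - x_l||^2, in closed form
    total = n * (x**2).sum() - (x.sum(axis=0) ** 2).sum()
    return float(total / (n * (n - 1) / 2.0))


def family_variables(
    collection: PanEFMCollection,
    strain_networks: Optional[Sequence[MetabolicNetwork]] = None,
    niche_breadth: Optional[float] = None,
    alpha: float = 0.05,
    fluidity_max_pairs: Optional[int] = 20000,
) -> pd.Series:
    """The pan-genome comparison variables for one family.

    Mirrors the standard panEFM/pan-reactome summary: diversity, fluidity,
    pan/size/core/shell/cloud of both the sampled panEFMs and the natural
    reactomes, metabolite-usage diversity, and the counts of significantly
    environment-driven reactions (EnvDReacs) and of metabolites associated
    with them (EnvDMetabs).  Strain-based entries are NaN when
    ``strain_networks`` is not given.
    """
    pan = collection.pan
    freq = reaction_frequency_matrix(collection)
    usage = metabolite_usage_matrix(collection)
    efms = collection.all_panefms()
    efm_sets = [p.reactions for p in efms]
    pooled = pd.Series(
        {r: sum(r in s for s in efm_sets) / len(efm_sets) for r in pan.reactions}
    )
    part_efm = partition_core_shell_cloud(pooled)
    eds = environment_driven_score(freq)
    n_per = collection.n_per_env or max(len(v) for v in collection.samples.values())
    env_driven = significant_env_driven(freq, n_per, alpha=alpha)
    assoc = metabolite_reaction_association(freq, usage)
    driven_reacs = [r for r in assoc.correlation.columns if eds.get(r, 0) > 0]
    envd_metabs = {
        m
        for m in assoc.correlation.index
        for r in driven_reacs
        if assoc.adjusted_p.at[m, r] < alpha
    }
    out = {
        "NicheBreadth": niche_breadth if niche_breadth is not None else np.nan,
        "diversity(panEFMs)": diversity(freq),
        "fluidity(panEFMs)": fluidity(
            efm_sets, max_pairs=fluidity_max_pairs
        ),
        "pan(panEFMs)": int((pooled > 0).sum()),
        "size(panEFMs)": float(np.mean([len(s) for s in efm_sets])),
        "core(panEFMs)": len(part_efm.core),
        "shell(panEFMs)": len(part_efm.shell),
        "cloud(panEFMs)": len(part_efm.cloud & set(pooled[pooled > 0].index)),
        "diversity(Metabs)": diversity(usage),
        "EnvDReacs": len(env_driven),
        "EnvDMetabs": len(envd_metabs),
    }
    if strain_networks:
        presence = pd.Series(
            {
                r: sum(r in s.reactions for s in strain_networks)
                / len(strain_networks)
                for r in pan.reactions
            }
        )
        part_nat = partition_core_shell_cloud(presence)
        out.update(
            {
                "pan(Reactomes)": len(pan.reactions),
                "size(Reactomes)": float(
                    np.mean([len(s.reactions) for s in strain_networks])
                ),
                "core(Reactomes)": len(part_nat.core),
                "shell(Reactomes)": len(part_nat.shell),
                "cloud(Reactomes)": len(part_nat.cloud),
            }
        )
    else:
        out.update(
            {
                "pan(Reactomes)": np.nan,
                "size(Reactomes)": np.nan,
                "core(Reactomes)": np.nan,
                "shell(Reactomes)": np.nan,
                "cloud(Reactomes)": np.nan,
            }
        )
    order = [
        "NicheBreadth",
        "diversity(panEFMs)", "fluidity(panEFMs)",
        "pan(panEFMs)", "pan(Reactomes)",
        "size(panEFMs)", "size(Reactomes)",
        "core(panEFMs)", "core(Reactomes)",
        "shell(panEFMs)", "shell(Reactomes)",
        "cloud(panEFMs)", "cloud(Reactomes)",
        "diversity(Metabs)", "EnvDReacs", "EnvDMetabs",
    ]
    return pd.Series({k: out[k] for k in order})


def variable_correlations(records: pd.DataFrame) -> pd.DataFrame:
    """Convenience: pairwise Pearson correlation (with BH-adjusted p) between
    family variable records (families as rows).  Returns a long-format frame
    with columns (var_a, var_b, r, p, adj_p)."""
    cols = [c for c in records.columns if records[c].notna().all()]
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r, p = sps.pearsonr(records[a], records[b])
            rows.append((a, b, r, p))
    frame = pd.DataFrame(rows, columns=["var_a", "var_b", "r", "p"])
    if len(frame):
        _, adj, _, _ = multipletests(frame["p"], method="fdr_bh")
        frame["adj_p"] = adj
    return frame
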