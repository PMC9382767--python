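"""Niche breadth of taxa from taxonomic relative-abundance profiles.

A taxon found only in compositionally similar samples is a specialist; one
spread across dissimilar communities is a generalist.  The score is the
mean pairwise sample distance over the samples where the taxon occurs,
with distance defined as 1/2 - rho/2 where rho is Spearman's rank
correlation between the full taxonomic profiles of the two samples.
"""

from __future__ import annotations

from typing import Union

import numpy as np
import pandas as pd
from scipy import stats as sps

#: A taxon is present in a sample at relative abundance >= 1/10,000.
PRESENCE_THRESHOLD = 1e-4


def validate_abundance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Samples x taxa relative abundances: non-negative, rows sum to <= 1."""
    values = table.to_numpy(float)
    if (values < 0).any():
        raise ValueError("negative abundances in table")
    if (values.sum(axis=1) > 1.0 + 1e-9).any():
        raise ValueError("some sample rows sum to more than 1")
    return table


def presence(
    table: pd.DataFrame, threshold: float = PRESENCE_THRESHOLD
) -> pd.DataFrame:
    """Boolean samples x taxa matrix: abundance >= threshold (inclusive)."""
    validate_abundance_table(table)
    return table >= threshold


def sample_distance(
    profile_a: Union[pd.Series, np.ndarray],
    profile_b: Union[pd.Series, np.ndarray],
) -> float:
    """1/2 - rho/2 over the full taxon vectors (ties get average ranks).

    0 for identical rank orders, 1 for exactly reversed ones.  Constant
    profiles have no defined rank correlation and raise.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must cover the same taxa")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant profile: Spearman correlation undefined")
    rho = sps.spearmanr(a, b).statistic
    return float(0.5 - rho / 2.0)


def niche_breadth(
    table: pd.DataFrame,
    taxon: str,
    threshold: float = PRESENCE_THRESHOLD,
) -> float:
    """Mean pairwise distance between all samples where ``taxon`` occurs."""
    validate_abundance_table(table)
    if taxon not in table.columns:
        raise KeyError(f"unknown taxon {taxon!r}")
    mask = table[taxon] >= threshold
    samples = table.loc[mask]
    if len(samples) < 2:
        raise ValueError(
            f"insufficient occurrences: {taxon} present in {len(samples)} sample(s)"
        )
    x = samples.to_numpy(float)
    # Spearman on ranks, vectorized over all pairs
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    if (np.ptp(ranks, axis=1) == 0).any():
        raise ValueError("constant profile among presence samples")
    z = (ranks - ranks.mean(axis=1, keepdims=True))
    z /= np.sqrt((z**2).sum(axis=1, keepdims=True))
    rho = np.clip(z @ z.T, -1.0, 1.0)
    n = len(x)
    iu = np.triu_indices(n, k=1)
    return float(np.mean(0.5 - rho[iu] / 2.0))


def niche_breadth_all(
    table: pd.DataFrame, threshold: float = PRESENCE_THRESHOLD
) -> pd.Series:
    """Niche breadth for every taxon with >= 2 presence samples."""
    out = {}
    for taxon in table.columns:
        try:
            out[taxon] = niche_breadth(table, taxon, threshold)
        except ValueError:
            out[taxon] = np.nan
    return pd.Series(out, dtype=float)
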