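"""Random growth environments ("environment ball").

Each environment draws relative compound concentrations from a flat
Dirichlet over the usable external compounds (so concentrations sum to one
and every composition is equally likely), anchors them to a constant water
uptake rate, and flips a fair coin for oxygen: aerobic environments have
unconstrained oxygen, anaerobic ones none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .network import DEFAULT_BOUND, Environment


@dataclass
class EnvironmentBall:
    """A batch of random environments over a fixed compound list."""

    environments: List[Environment]
    compound_ids: Sequence[str]
    seed: int
    water_id: Optional[str] = None
    oxygen_id: Optional[str] = None
    water_rate: float = DEFAULT_BOUND

    def __len__(self) -> int:
        return len(self.environments)

    def __iter__(self):
        return iter(self.environments)

    def __getitem__(self, i: int) -> Environment:
        return self.environments[i]

    def to_frame(self) -> pd.DataFrame:
        """Rows = environments, columns = compounds plus an ``aerobic`` flag."""
        rows = []
        for env in self.environments:
            row = {c: env.uptake_bounds.get(c, 0.0) for c in self.compound_ids}
            if self.water_id is not None:
                row[self.water_id] = env.uptake_bounds.get(self.water_id, 0.0)
            row["aerobic"] = int(env.aerobic)
            rows.append(row)
        return pd.DataFrame(rows)


def sample_environment_ball(
    compound_ids: Sequence[str],
    n_env: int = 1000,
    water_rate: float = DEFAULT_BOUND,
    seed: int = 0,
    water_id: Optional[str] = None,
    oxygen_id: Optional[str] = None,
) -> EnvironmentBall:
    """Sample ``n_env`` random environments.

    Compound ``i`` of environment ``e`` gets uptake bound ``c_i * water_rate``
    with ``c ~ Dirichlet(1, ..., 1)`` over ``compound_ids`` (which must
    exclude water and oxygen); water, when given, is fixed at ``water_rate``
    in every environment; each environment is independently aerobic with
    probability 1/2.  A single seeded generator drives both the Dirichlet
    draws and the oxygen coins, so results are reproducible for a fixed seed.
    """
    compound_ids = list(compound_ids)
    if len(set(compound_ids)) != len(compound_ids):
        raise ValueError("duplicate compound ids")
    for special in (water_id, oxygen_id):
        if special is not None and special in compound_ids:
            raise ValueError(f"{special} must not be in compound_ids")
    if n_env < 1:
        raise ValueError("n_env must be >= 1")
    rng = np.random.default_rng(seed)
    conc = rng.dirichlet(np.ones(len(compound_ids)), size=n_env)
    aerobic = rng.random(n_env) < 0.5
    envs = []
    for e in range(n_env):
        bounds = {c: float(conc[e, i]) * water_rate for i, c in enumerate(compound_ids)}
        if water_id is not None:
            bounds[water_id] = water_rate
        envs.append(
            Environment(
                bounds,
                aerobic=bool(aerobic[e]),
                oxygen_id=oxygen_id,
                name=f"ball[{e}]",
            )
        )
    return EnvironmentBall(
        envs, compound_ids, seed, water_id, oxygen_id, water_rate
    )


def rich_environment(
    compound_ids: Sequence[str], oxygen_id: Optional[str] = None
) -> Environment:
    """Environment with every listed compound unconstrained, aerobic."""
    return Environment(
        {c: math.inf for c in compound_ids},
        aerobic=True,
        oxygen_id=oxygen_id,
        name="rich",
    )


def presence_absence_environments(
    compound_ids: Sequence[str], oxygen_id: Optional[str] = None
) -> List[Environment]:
    """All 2^n environments defined by presence/absence of each compound.

    Present compounds are unconstrained, absent ones excluded — the
    environment semantics of networks whose stoichiometries are all one,
    where only availability (not rate) matters.  Enumeration order is
    deterministic: compound ids sorted, presence patterns in binary order.
    """
    compound_ids = sorted(compound_ids)
    n = len(compound_ids)
    if n > 20:
        raise ValueError(f"2^{n} environments is too many to enumerate")
    envs = []
    for mask in range(2**n):
        present = {
            compound_ids[i]: math.inf for i in range(n) if (mask >> i) & 1
        }
        envs.append(
            Environment(
                present, aerobic=True, oxygen_id=oxygen_id, name=f"pa[{mask}]"
            )
        )
    return envs
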