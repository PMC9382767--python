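"""Sampling an environment ball.

Random growth environments: compound uptake bounds are drawn from a flat
Dirichlet over the usable compounds (relative concentrations summing to 1,
anchored to a constant water uptake rate) and oxygen is a fair coin —
unconstrained when aerobic, zero when anaerobic.
"""

import numpy as np

import panefm as pf

compounds = [f"cpd{k:03d}" for k in range(20)]
ball = pf.sample_environment_ball(
    compounds, n_env=1000, water_rate=1000.0, seed=7,
    water_id="water", oxygen_id="oxygen",
)

frame = ball.to_frame()
conc = frame[compounds].to_numpy() / 1000.0
print(f"environments sampled: {len(ball)}")
print(f"per-environment concentration sums: {conc.sum(axis=1).round(9).min()}"
      f" .. {conc.sum(axis=1).round(9).max()}")
print(f"mean relative concentration per compound: {conc.mean():.4f}"
      f" (expected 1/{len(compounds)} = {1/len(compounds):.4f})")
print(f"aerobic fraction: {frame['aerobic'].mean():.3f} (expected 0.50)")
print(f"water bound constant at {frame['water'].iloc[0]:.0f} mmol/gDW/h")
print(
    "\nEach row is one candidate growth medium; uptake bounds feed the FBA "
    "exchange constraints when sampling panEFMs across environments."
)
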