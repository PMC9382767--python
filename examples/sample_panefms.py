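"""Random panEFM sampling and its convergence.

Draws minimal functional reaction sets by randomized greedy deletion, shows
that the sampler's support matches exhaustive enumeration on the toy
network, and demonstrates that a few hundred draws per environment already
reproduce the reaction-frequency profile.
"""

import numpy as np

import panefm as pf
from panefm import stats

toy = pf.build_toy_model()
rich = pf.toy_rich_environment()
rng = np.random.default_rng(11)

seen = set()
for _ in range(300):
    efm = pf.sample_panefm(toy, rich, rng)
    seen.add(efm.reactions)
enumerated = pf.enumerate_minimal_functional_sets(toy, rich)
print(f"distinct panEFMs in 300 draws: {len(seen)}"
      f" (enumeration finds {len(enumerated)}; support equal: {seen == enumerated})")

envs = pf.toy_presence_absence_environments()
grow = [envs[i] for i in pf.growth_supporting_environments(toy, envs)]
coll = pf.sample_collection(toy, grow[:30], n_per_env=100, seed=5)
freq = stats.reaction_frequency_matrix(coll)
print("\nreaction frequencies in the first five environments:")
print(freq[list(toy.deletable_reaction_ids)].head().round(2).to_string())

conv = pf.convergence_curve(toy, grow[:30], sizes=[10, 50, 200],
                            seed_a=1, seed_b=2)
print("\nconvergence of mean frequencies between independent collections:")
print(conv.round(4).to_string(index=False))
print(
    "\nreproducibility is the Pearson correlation between two independent "
    "samplings; it approaches 1 (and MSE approaches 0) well before 1000 "
    "draws per environment."
)
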