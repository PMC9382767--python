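"""Pan-genome style summary variables for one family.

Merges strain reactomes into a pan-reactome, samples panEFM collections,
and reports the standard comparison variables: diversity, fluidity,
pan/core/shell/cloud sizes for both panEFMs and natural reactomes, and the
counts of significantly environment-driven reactions and their associated
metabolites.
"""

import panefm as pf
from panefm import stats

strains = pf.toy_strain_reactomes()
pan = pf.merge_pan_reactome(strains, id="toy_family")
print(f"merged {len(strains)} strain reactomes into a pan-reactome of "
      f"{len(pan.deletable_reaction_ids)} reactions")

natural = stats.natural_reaction_frequencies(strains, pan)
print("\nnatural reaction frequencies (gene-supported, FVA-active):")
print(natural.round(3).to_string())

envs = pf.toy_presence_absence_environments()
grow = [envs[i] for i in pf.growth_supporting_environments(pan, envs)]
coll = pf.sample_collection(pan, grow[:60], n_per_env=100, seed=3)
record = stats.family_variables(coll, strains)
print("\nfamily summary variables:")
print(record.round(3).to_string())
print(
    "\ncore(panEFMs) counts reactions in at least 98% of all sampled "
    "panEFMs; EnvDReacs counts reactions whose frequency varies across "
    "environments beyond binomial sampling noise."
)
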