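# Methods

This note records the models implemented in `panefm`, the numerical and
design choices behind them, what the synthetic generators do and do not
emulate, and the package's known limitations.

## Networks and flux balance analysis

A metabolic network is a bipartite reaction/metabolite graph with signed
stoichiometry (negative = consumed), per-reaction flux bounds in
mmol gDW⁻¹ h⁻¹, a set of single-metabolite exchange reactions, and one
biomass pseudo-reaction.  A metabolite is *external* exactly when an
exchange reaction touches it.  Functionality is assessed by FBA: maximize
biomass flux v_bm subject to S·v = 0 and lb ≤ v ≤ ub.  COBRA sign
conventions apply: exchange flux < 0 is import, > 0 is secretion.

An environment is a map from external compounds to non-negative maximal
uptake rates (∞ = unconstrained, capped at the default bound of
1000 mmol gDW⁻¹ h⁻¹ inside the LP); oxygen, when designated, is ∞ under
aerobiosis and 0 otherwise.  The environment only *caps* import: it never
widens a reaction's own bounds, and secretion is unaffected.

Numerical constants:

* `GROWTH_EPS = 1e-5` — "growth" means biomass flux strictly above this
  (operationalizing positivity at five significant digits in flux units).
* `FLUX_TOL = 1e-9` — fluxes and FVA ranges below this are zero; imports
  are counted only below −1e-9.
* Residual standard deviations below `1e-12` are treated as exactly zero.

The LPs are solved with GLPK through a single persistent problem instance
per network; deletions and environment switches are column-bound updates,
so the simplex warm-starts and growth queries are memoized by
(environment, deleted set).  Objective values are vertex-independent, so
warm starts cannot change them; whenever a *flux vector* is reported (for
metabolite usage), the solve restarts from the standard basis so the
returned vertex is a deterministic function of the problem alone, not of
solver history.  Alternative optima still exist in principle (route choice
in non-minimal networks is degenerate); usage sets are therefore
deterministic but convention-dependent, which is why set-level outputs
(panEFM membership, usage sets under a fixed configuration) are the
reproducible quantities.  Tests cross-check FBA/FVA against an independent
scipy HiGHS formulation and against cobrapy.

Flux variability analysis runs per reaction (min and max over the feasible
region) in the rich environment — all exchanges open — with the biomass
lower bound at 0; "inactive" means the whole feasible range is within
tolerance of zero.  Reversible reactions are kept as single columns with
negative lower bounds.

## panEFM sampling and enumeration

One panEFM is produced by a single sweep over a uniformly random
permutation of the deletable reactions: each reaction is removed, and the
removal is kept iff the remaining network's biomass flux strictly exceeds
1% of the *pan-reactome's* flux in the same environment (recomputed per
environment, not a global constant).  A full sweep is minimal with respect
to single deletions at that cutoff, and no second pass is made.  The
biomass reaction is never a candidate; exchange reactions are excluded by
default because deleting an exchange changes the environment's definition
rather than the reactome (a flag enables them for sensitivity analysis).

On networks with at most 25 deletable reactions, all minimal functional
sets are enumerated exactly by depth-first search over deletion orders
with memoization on the surviving set; greedy deletion can always avoid
the members of any target minimal set, so every minimal set is reachable.
The sampler is validated against this enumeration in two ways: support
equality over many seeds, and distributional agreement with an independent
combinatorial simulator in which "functional" means "still contains at
least one known minimal set" (no LP involved).  Note the sampler's measure
over minimal sets is the permutation measure, not uniform over sets;
frequency expectations are always compared within one measure.

Collections store, for every growth-supporting environment, the sampled
panEFMs and their metabolite usage (the imports of the biomass-optimal
solution of the panEFM subnetwork).  The exhaustive collection (every
minimal set exactly once per environment) is the deterministic counterpart
used where exactness matters.

## Environment ball

Relative concentrations over the usable compounds (water and oxygen
excluded) are Dirichlet(α = 1) — every composition equally likely, summing
to one.  "Adjusted to a constant water uptake rate" is realized by fixing
water's bound at `water_rate` (default 1000 mmol gDW⁻¹ h⁻¹) and setting
compound i's bound to cᵢ·`water_rate`: a single anchor preserving the
relative-concentration semantics, configurable.  Whether water itself was
Dirichlet-scaled in comparable pipelines is not documented; fixing it is
the conservative reading of "constant".  One seeded generator drives both
the Dirichlet draws and the per-environment oxygen coin (p = 0.5), so a
ball is fully reproducible from its seed.

For networks with unit stoichiometries, rate does not matter — only
availability does — so the toy analyses use presence/absence environments:
each external compound either unconstrained or absent, enumerated
exhaustively (2ⁿ environments, deterministic order).

## EDS, significance, and associations

Frequency matrices have growth-supporting environments as rows and
features (reactions, or imported external metabolites) as columns, values
in [0, 1].  Residuals subtract the column mean; the EDS is the population
(ddof 0) standard deviation of a feature's residuals divided by the
*maximum* such standard deviation in the same matrix.  This is the reading
of "scaled standard deviation" that guarantees the advertised [0, 1] range
with a maximum of exactly 1 (scaling by a per-feature maximum residual
would not); when no feature varies, all scores are 0 and no division
occurs.

`significant_env_driven` tests, per feature, whether the across-environment
variance of frequencies exceeds pure sampling noise.  With n draws per
environment and a common rate p estimated by the column mean, the null
variance is σ₀² = p(1−p)/n; the statistic E·s²/σ₀² (E environments) is
compared to its χ²(E−1) null via the one-sided normal approximation
Z = (χ² − (E−1)) / √(2(E−1)), with Benjamini–Hochberg control at α = 0.05.
The per-feature binomial null was chosen over a z-score across the EDS
distribution because it is the natural no-environment-effect null given
the sampling design; its empirical false-discovery fraction is calibrated
in the tests (200 null features, n = 1000).  Features at frequency exactly
0 or 1 everywhere have zero variance and are never significant.

Associations are Pearson correlations, over environments, between
metabolite-usage and reaction-frequency residuals, for every pair whose
residual sd exceeds 1e-12 (centering makes this identical to correlating
the raw columns); p-values come from the exact t distribution and are BH
adjusted over all retained pairs.  A metabolite counts as
environment-driven-associated (EnvDMetabs) if at least one association
with an EDS > 0 reaction has adjusted p < 0.05.

## Pan-genome summaries

Natural reaction frequencies count, per pan reaction, the fraction of
strains carrying it *with gene evidence* (a gap-filled copy does not
count), restricted to reactions with non-zero flux variability in the
pan-reactome's rich environment; reactions gap-filled everywhere are
excluded entirely.  Core/shell/cloud thresholds are ≥ 98% / (3%, 98%) /
≤ 3%.  For panEFM-side partitions the same thresholds apply to frequency
over all sampled panEFMs pooled across environments, with the cloud
restricted to reactions appearing in at least one panEFM (reactions that
never enter any panEFM are not "present in up to 3%" — they are absent).
Fluidity is the mean over unordered pairs of (Uₖ + Uₗ)/(Mₖ + Mₗ) (unique
elements over summed sizes, 0 = identical, 1 = disjoint), computed over a
seeded subsample of pairs beyond 20 000 pairs.  Diversity is the average
squared pairwise Euclidean distance between matrix rows, evaluated in
closed form.

## Elastic-net niche model

Each metabolite is fit as an independent elastic net sharing one set of
5-fold CV splits (independent-per-target matches standard multi-output
practice and parallelizes trivially; the choice of joint vs independent is
otherwise open).  The grid is L1 ratio ∈ {0.1, 0.5, 0.9} with a 50-point
regularization path; inputs are standardized per feature (mean/scale
computed on the full training matrix); predictions are affine in the
frequency vector and clipped to [0, 1] since usages are proportions.
Held-out r per metabolite is computed by cross-validated prediction at the
selected hyperparameters on the same folds.  Constant targets get
intercept-only models with undefined (NaN) held-out r.  The persisted
model stores the feature order; prediction is invariant to input ordering
and missing features default to frequency 0 with a warning.

## Moran process

The population (default N = 1000; desk-scale runs use N = 200) evolves by
strictly alternating mutation and replacement events.  Mutation picks a
random individual, then with probability `p_delete` proposes deleting a
uniformly chosen present reaction (kept only if the mutant stays
functional at the same 1%-of-pan-flux cutoff as panEFM sampling) and
otherwise proposes inserting a uniformly chosen absent pan reaction
(always functional, since adding a column can only relax the LP).
Replacement copies one random individual over another (i ≠ j), keeping N
constant.  The process is neutral among functional reactomes; with
mutation disabled it reduces to classic drift, and the single-lineage
fixation probability 1/N is verified in the tests.

`p_delete` defaults to 0.9.  This is a deliberate, load-bearing choice:
because insertions can never be rejected while deletions can, a balanced
50/50 kernel drifts toward complete reactomes — every reaction near
frequency 1, no environmental signature, and no ability to predict the
niche from the evolved frequencies.  Under loss-dominated proposals the
population hovers near minimal functional sets, evolved frequencies mirror
the environment-specific panEFM frequencies, and the elastic net recovers
the realized usage (r ≈ 0.98 on the toy validation).  The ratio is
configurable; 0.5 reproduces the inflationary regime for anyone who wants
to study it.  A corollary worth stating: a reaction whose substrates are
absent is never load-bearing (it appears in no minimal set and carries no
flux), but it persists at a low mutation–drift equilibrium frequency
rather than vanishing — gain/loss neutrality does not purge neutral cargo.

Initial "random functional reactomes" are sampled panEFMs re-inflated with
each absent reaction independently with probability 0.25, spanning sizes
between minimal and full while guaranteeing functionality.  "Types that
persisted" are the distinct reaction sets in the final population;
realized usage is the (optionally count-weighted) fraction of types whose
biomass-optimal solution imports each metabolite.

## Synthetic generators

* **Toy pan-reactome** (`build_toy_model`): 14 unit-stoichiometry reactions
  plus a biomass reaction consuming M10_i, M11_i and M12_i, and exchanges
  for nine external compounds.  The shipped reaction table is a synthetic
  reconstruction (the original table was not redistributable) constrained
  by the network's described architecture — three interchangeable routes
  to the precursor M8_i ({R8}, {R7}, {R6, R11}, gated by M9_e, M8_e and
  M6_e + M7_e), a byproduct M2 exported by R10, and five universally
  essential reactions — and validated against the three published summary
  counts: exactly 9 minimal functional sets in the rich environment,
  exactly 208 growth-supporting presence/absence environments, and
  {R5, R9, R12, R13, R14} required everywhere.  All three are asserted in
  the test suite.  Three strain reactomes whose union is the pan-reactome
  are provided for the merging and natural-frequency examples.
* **Planted pan-reactomes** (`random_pan_reactome`): an essential backbone
  per precursor (chain length 1–2, seed-dependent), one precursor served
  by n interchangeable routes each gated by its own external compound, and
  byproduct/export motifs whose exporter is conditional on its route's
  enabling metabolite.  Ground truth (essential set, route groups,
  conditional map) is recorded and re-verified by enumeration at
  construction.  Networks stay ≤ ~25 reactions so exhaustive verification
  is feasible.
* **Abundance tables** (`synthetic_abundance_table`): per-biome expected
  community profiles with half the taxa generalists (positive expected
  abundance in every biome) and half specialists (confined to one home
  biome); samples are Dirichlet draws around the biome profile
  (concentration 50 controls within-biome noise), rows summing to one.

What these emulate — and what they do not: the generators reproduce the
*combinatorial* structure that drives the statistics (alternative routes,
conditional byproducts, biome-structured communities) at sizes where exact
enumeration is possible.  They do not emulate genome-scale network density,
currency-metabolite coupling, correlated compound availability, realistic
rank-abundance distributions, or compositional noise from sequencing.
Passing tests therefore demonstrate correctness of the machinery and the
claimed statistical behaviour at desk scale, not performance claims on
real genome-scale reconstructions.

## Problem sizes

Defaults mirror the full-scale design (1000 environments, 1000 panEFMs per
environment, N = 1000, 10⁶ Moran iterations).  The shipped analyses,
tests and the acceptance script run the toy system at sizes chosen for
interactive turnaround on one CPU: the exhaustive 208-environment
collection, 200 panEFMs per environment for training matrices, Moran
populations of 200 for 10⁵ iterations, 500-seed sampler/enumeration
comparisons on 20 planted networks, and 100-replicate niche-breadth
simulations.  Convergence of reaction frequencies is explicitly measured
(two independent collections, Pearson r ≥ 0.99 at 200 draws per
environment), which is what justifies the reduced sampling depth.

## Known limitations

* panEFMs are deletion-minimal functional sets, not elementary flux modes
  in the classical double-description sense; no claim is made about the
  full EFM lattice.
* No thermodynamic, enzyme-cost or protein-allocation constraints; the
  Moran process has no fitness differences among functional reactomes and
  no gene-acquisition costs or transfer barriers.
* Usage sets inherit LP degeneracy conventions (see above); comparisons
  across solver configurations should use set-level or frequency-level
  outputs.
* The niche-breadth input contract assumes an already-curated abundance
  table (comparable taxonomic profiles, adequate read depth); no curation
  of survey data is performed.
* SBML support covers Level 3 FBC as written by cobrapy; the JSON model
  format is the package's own documented schema, accepted alongside SBML.
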