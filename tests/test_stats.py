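"""Frequency matrices, EDS, associations, and pan-genome summary variables."""

import itertools

import numpy as np
import pandas as pd
import pytest

import panefm as pf
from panefm import stats
from panefm.network import Reaction, MetabolicNetwork
from panefm.sampling import PanEFM, PanEFMCollection

ESSENTIALS = {"R5", "R9", "R12", "R13", "R14"}


@pytest.fixture(scope="module")
def toy_matrices(toy_exhaustive):
    freq = stats.reaction_frequency_matrix(toy_exhaustive)
    usage = stats.metabolite_usage_matrix(toy_exhaustive)
    return freq, usage


class TestFrequencyMatrices:
    def test_values_are_proportions(self, toy_matrices):
        freq, usage = toy_matrices
        assert ((freq >= 0) & (freq <= 1)).all().all()
        assert ((usage >= 0) & (usage <= 1)).all().all()

    def test_universal_reactions_have_frequency_one(self, toy_matrices):
        freq, _ = toy_matrices
        for rid in ESSENTIALS | {"biomass"}:
            assert (freq[rid] == 1.0).all()

    def test_single_draw_collection_is_binary(self, toy, rich):
        coll = pf.sample_collection(toy, [rich], n_per_env=1, seed=8)
        freq = stats.reaction_frequency_matrix(coll)
        assert freq.isin([0.0, 1.0]).all().all()

    def test_sampled_frequencies_match_enumeration_measure(self, toy, rich, rng):
        """Rich-environment frequencies from 1000 draws agree with the
        expectation under the sampler's permutation measure, estimated by an
        independent combinatorial simulation."""
        from conftest import greedy_oracle

        deletable = set(toy.deletable_reaction_ids)
        mins = [
            s & deletable
            for s in pf.enumerate_minimal_functional_sets(toy, rich)
        ]
        n_sim = 30_000
        counts = {r: 0 for r in deletable}
        for _ in range(n_sim):
            s = greedy_oracle(mins, deletable, rng)
            for r in s:
                counts[r] += 1
        expected = {r: c / n_sim for r, c in counts.items()}
        coll = pf.sample_collection(toy, [rich], n_per_env=1000, seed=17)
        freq = stats.reaction_frequency_matrix(coll).iloc[0]
        for r in deletable:
            p = expected[r]
            se = np.sqrt(p * (1 - p) / 1000 + p * (1 - p) / n_sim + 1e-12)
            assert abs(freq[r] - p) < 4 * se + 1e-3, r

    def test_absent_compound_never_used(self, toy, pa_envs, toy_exhaustive):
        usage = stats.metabolite_usage_matrix(toy_exhaustive)
        for e in toy_exhaustive.environment_indices[:50]:
            env = pa_envs[e]
            for met in usage.columns:
                if env.bound(met) == 0.0:
                    assert usage.at[e, met] == 0.0

    def test_panefm_with_r8_uses_m9(self, toy, rich, toy_minimal_sets):
        for efm_set in toy_minimal_sets:
            if "R8" in efm_set:
                usage = stats.metabolite_usage(
                    PanEFM(efm_set), toy, rich
                )
                assert "M9_e" in usage


class TestResiduals:
    def test_constant_column_has_zero_residuals(self):
        F = pd.DataFrame({"a": [0.5, 0.5, 0.5], "b": [0.0, 0.5, 1.0]})
        R = stats.residual_matrix(F)
        assert (R["a"] == 0).all()

    def test_two_row_arithmetic(self):
        F = pd.DataFrame({"x": [0.0, 1.0]})
        R = stats.residual_matrix(F)
        assert list(R["x"]) == [-0.5, 0.5]

    def test_column_sums_are_zero(self, toy_matrices):
        freq, _ = toy_matrices
        sums = stats.residual_matrix(freq).sum(axis=0)
        assert np.allclose(sums, 0.0, atol=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            stats.residual_matrix(pd.DataFrame({"a": [1.0]}))


class TestEDS:
    def test_toy_environment_independent_reactions_score_zero(self, toy_matrices):
        freq, _ = toy_matrices
        eds = stats.environment_driven_score(freq)
        for rid in ESSENTIALS:
            assert eds[rid] == 0.0

    def test_remaining_toy_reactions_are_environment_driven(self, toy, toy_matrices):
        freq, _ = toy_matrices
        eds = stats.environment_driven_score(freq)
        driven = set(toy.deletable_reaction_ids) - ESSENTIALS
        assert (eds[sorted(driven)] > 0).all()

    def test_max_variance_feature_scores_exactly_one(self, toy_matrices):
        freq, _ = toy_matrices
        eds = stats.environment_driven_score(freq)
        assert eds.max() == pytest.approx(1.0)

    def test_all_constant_matrix_scores_zero_without_dividing(self):
        F = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 0.0]})
        assert (stats.environment_driven_score(F) == 0).all()

    def test_eds_range(self, toy_matrices):
        freq, usage = toy_matrices
        for M in (freq, usage):
            eds = stats.environment_driven_score(M)
            assert ((eds >= 0) & (eds <= 1)).all()


class TestSignificance:
    def test_constant_zero_or_one_features_never_significant(self):
        F = pd.DataFrame({"all0": [0.0] * 20, "all1": [1.0] * 20})
        assert stats.significant_env_driven(F, n_per_env=1000) == set()

    def test_alternating_signal_is_detected(self, rng):
        n_env, n_per = 40, 1000
        signal = np.where(np.arange(n_env) % 2 == 0, 0.1, 0.9)
        noisy = rng.binomial(n_per, signal) / n_per
        null = rng.binomial(n_per, 0.5, size=n_env) / n_per
        F = pd.DataFrame({"signal": noisy, "null": null})
        hits = stats.significant_env_driven(F, n_per_env=n_per)
        assert "signal" in hits

    def test_empirical_fdr_under_null(self, rng):
        """With no environment effect at all, essentially nothing should be
        rejected (BH at 0.05 over 200 pure-noise features)."""
        n_env, n_per, n_feat = 100, 1000, 200
        p = rng.uniform(0.2, 0.8, size=n_feat)
        F = pd.DataFrame(
            rng.binomial(n_per, np.tile(p, (n_env, 1))) / n_per,
            columns=[f"f{k}" for k in range(n_feat)],
        )
        hits = stats.significant_env_driven(F, n_per_env=n_per)
        assert len(hits) / n_feat <= 0.05


class TestAssociations:
    def test_toy_signs_around_r8(self, toy_matrices):
        freq, usage = toy_matrices
        assoc = stats.metabolite_reaction_association(freq, usage)
        assert assoc.correlation.at["M9_e", "R8"] > 0
        for m in ("M6_e", "M7_e", "M8_e"):
            assert assoc.correlation.at[m, "R8"] < 0

    def test_self_derived_copy_correlates_perfectly(self):
        x = np.linspace(0, 1, 30)
        Fr = pd.DataFrame({"r": x})
        Fm = pd.DataFrame({"m": x})
        assoc = stats.metabolite_reaction_association(Fr, Fm)
        assert assoc.correlation.at["m", "r"] == pytest.approx(1.0)

    def test_independent_columns_have_small_mean_correlation(self, rng):
        n = 500
        Fr = pd.DataFrame(rng.uniform(size=(n, 8)), columns=list("abcdefgh"))
        Fm = pd.DataFrame(rng.uniform(size=(n, 6)), columns=list("uvwxyz"))
        assoc = stats.metabolite_reaction_association(Fr, Fm)
        assert np.abs(assoc.correlation.to_numpy()).mean() < 0.1

    def test_constant_features_are_omitted(self, toy_matrices):
        freq, usage = toy_matrices
        assoc = stats.metabolite_reaction_association(freq, usage)
        assert "R5" not in assoc.correlation.columns
        assert "M5_e" not in assoc.correlation.index

    def test_row_mismatch_rejected(self):
        Fr = pd.DataFrame({"r": [0.1, 0.2, 0.3]})
        Fm = pd.DataFrame({"m": [0.1, 0.2, 0.3]}, index=[5, 6, 7])
        with pytest.raises(ValueError, match="rows"):
            stats.metabolite_reaction_association(Fr, Fm)


class TestNaturalFrequencies:
    def test_toy_strain_hand_count(self, strains, toy):
        freq = stats.natural_reaction_frequencies(strains, toy)
        # shared by all three / by strains 1+2 / by exactly one strain
        assert freq["R5"] == 1.0
        assert freq["R8"] == pytest.approx(2 / 3)
        assert freq["R7"] == pytest.approx(1 / 3)
        assert set(freq.round(6).unique()) <= {
            round(1 / 3, 6), round(2 / 3, 6), 1.0
        }

    def test_gap_filled_everywhere_reaction_excluded(self, toy):
        gapfilled = [
            MetabolicNetwork(
                [
                    Reaction(
                        rid,
                        rxn.stoichiometry,
                        rxn.lower_bound,
                        rxn.upper_bound,
                        is_exchange=rxn.is_exchange,
                        has_gene_evidence=(rid != "R8"),
                    )
                    for rid, rxn in s.reactions.items()
                ],
                "biomass",
                id=s.id,
            )
            for s in pf.toy_strain_reactomes()
        ]
        freq = stats.natural_reaction_frequencies(gapfilled, toy)
        assert "R8" not in freq.index

    def test_empty_strain_list_rejected(self, toy):
        with pytest.raises(ValueError):
            stats.natural_reaction_frequencies([], toy)


class TestPartition:
    def test_all_ones_is_all_core(self):
        part = stats.partition_core_shell_cloud({"a": 1.0, "b": 1.0})
        assert part.core == {"a", "b"} and not part.shell and not part.cloud

    def test_threshold_arithmetic(self):
        part = stats.partition_core_shell_cloud({"a": 1.0, "b": 0.5, "c": 0.01})
        assert (part.core, part.shell, part.cloud) == ({"a"}, {"b"}, {"c"})

    def test_is_a_true_partition(self, rng):
        freq = {f"f{k}": float(v) for k, v in enumerate(rng.uniform(size=50))}
        part = stats.partition_core_shell_cloud(freq)
        assert part.core | part.shell | part.cloud == set(freq)
        assert not (part.core & part.shell or part.shell & part.cloud
                    or part.core & part.cloud)


class TestFluidityAndDiversity:
    def test_fluidity_limits(self):
        assert stats.fluidity([{"a", "b"}, {"a", "b"}]) == 0.0
        assert stats.fluidity([{"a", "b"}, {"c", "d"}]) == 1.0
        assert stats.fluidity([{"a", "b"}, {"b", "c"}]) == pytest.approx(0.5)

    def test_fluidity_matches_brute_force(self, rng):
        sets = [
            frozenset(rng.choice(20, size=rng.integers(3, 9), replace=False))
            for _ in range(12)
        ]
        expected = np.mean(
            [
                (len(a - b) + len(b - a)) / (len(a) + len(b))
                for a, b in itertools.combinations(sets, 2)
            ]
        )
        assert stats.fluidity(sets) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            stats.fluidity([set(), {"a"}])

    def test_diversity_examples(self):
        same = pd.DataFrame([[0.3, 0.7], [0.3, 0.7]])
        assert stats.diversity(same) == 0.0
        corners = pd.DataFrame([[0.0, 0.0], [1.0, 1.0]])
        assert stats.diversity(corners) == pytest.approx(2.0)

    def test_diversity_matches_double_loop(self, rng):
        X = pd.DataFrame(rng.uniform(size=(15, 6)))
        brute = np.mean(
            [
                ((X.iloc[k] - X.iloc[l]) ** 2).sum()
                for k, l in itertools.combinations(range(15), 2)
            ]
        )
        assert stats.diversity(X) == pytest.approx(brute)


class TestFamilyVariables:
    def test_toy_record(self, toy, strains, toy_exhaustive):
        record = stats.family_variables(toy_exhaustive, strains)
        assert record["pan(Reactomes)"] == len(toy.reactions)
        assert record["pan(panEFMs)"] <= record["pan(Reactomes)"]
        # reactions in every panEFM of every environment are core
        pooled_core_expected = ESSENTIALS | {"biomass"}
        freq = stats.reaction_frequency_matrix(toy_exhaustive)
        eds = stats.environment_driven_score(freq)
        coll_sets = [p.reactions for p in toy_exhaustive.all_panefms()]
        for rid in pooled_core_expected:
            assert all(rid in s for s in coll_sets)
        assert record["EnvDReacs"] >= 0
        assert record["diversity(panEFMs)"] > 0
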