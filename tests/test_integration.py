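import numpy as np
import pytest

from gemtide.integration import (
    bray_curtis_matrix,
    null_importance_distribution,
    ordinate_2d,
    prune_to_condition,
    rank_distinguishing_reactions,
    sample_condition,
    shared_reactions,
)
from gemtide.network import FluxSampleSet, pfba
from gemtide.synth import make_toy_model, simulate_tpm
from gemtide.tailoring import ConditionConstraints, apply_condition_constraints


@pytest.fixture(scope="module")
def constrained_model():
    model, _ = make_toy_model()
    cc = ConditionConstraints(
        consumed_metabolites={"glc_e", "o2_e", "gln_e", "ala_e", "ser_e", "fa_e"}
    )
    out, report = apply_condition_constraints(model, cc)
    assert report.feasible
    return out


def uniform_tpm(model, value=100.0):
    return {g.id: value for g in model.genes}


def sample_set(label, reactions, matrix, seed=None):
    return FluxSampleSet(label, list(reactions), np.asarray(matrix, float), seed)


class TestPruning:
    def test_suppressed_respiration_route_is_pruned(self, constrained_model):
        tpm = dict(zip(*simulate_tpm(constrained_model, "oxphos_b", seed=1)[["gene", "tpm"]].T.values))
        pruned, report = prune_to_condition(constrained_model, tpm, condition_label="treat")
        assert "OXPHOS_B" in report.pruned_reactions
        assert "OXPHOS_A" in report.kept_reactions
        tpm = dict(zip(*simulate_tpm(constrained_model, "oxphos_a", seed=1)[["gene", "tpm"]].T.values))
        _, report = prune_to_condition(constrained_model, tpm, condition_label="alt")
        assert "OXPHOS_A" in report.pruned_reactions
        assert "OXPHOS_B" in report.kept_reactions

    def test_objective_retention_at_default_fraction(self, constrained_model):
        parent_opt = constrained_model.slim_optimize()
        tpm = dict(zip(*simulate_tpm(constrained_model, "oxphos_b", seed=2)[["gene", "tpm"]].T.values))
        pruned, report = prune_to_condition(constrained_model, tpm)
        assert report.objective_retained_fraction >= 0.9 - 1e-6
        assert pruned.slim_optimize() >= 0.9 * parent_opt - 1e-6

    def test_uniform_tpm_equals_pfba_support(self, constrained_model):
        _, report = prune_to_condition(constrained_model, uniform_tpm(constrained_model))
        sol = pfba(constrained_model, objective_fraction=0.9)
        pfba_support = {rid for rid, v in sol.fluxes.items() if abs(v) > 1e-9}
        assert report.kept_reactions == pfba_support

    def test_kept_and_pruned_partition_parent(self, constrained_model):
        tpm = dict(zip(*simulate_tpm(constrained_model, "oxphos_b", seed=3)[["gene", "tpm"]].T.values))
        _, report = prune_to_condition(constrained_model, tpm)
        parent = {r.id for r in constrained_model.reactions}
        assert report.kept_reactions | report.pruned_reactions == parent
        assert not report.kept_reactions & report.pruned_reactions

    def test_infeasible_fraction_raises(self, constrained_model):
        with pytest.raises(ValueError):
            prune_to_condition(constrained_model, uniform_tpm(constrained_model), objective_fraction=1.5)


class TestConditionSampling:
    def test_objective_fraction_active_in_all_samples(self, constrained_model):
        tpm = dict(zip(*simulate_tpm(constrained_model, "oxphos_b", seed=4)[["gene", "tpm"]].T.values))
        pruned, _ = prune_to_condition(constrained_model, tpm)
        optimum = pruned.slim_optimize()
        samples = sample_condition(pruned, n=20, seed=9, thinning=50)
        idx = samples.reaction_ids.index("ATPM")
        assert np.all(samples.samples[:, idx] >= 0.9 * optimum - 1e-6)

    def test_seeded_reproducibility(self, constrained_model):
        tpm = uniform_tpm(constrained_model)
        pruned, _ = prune_to_condition(constrained_model, tpm)
        s1 = sample_condition(pruned, n=10, seed=21, thinning=50)
        s2 = sample_condition(pruned, n=10, seed=21, thinning=50)
        assert np.array_equal(s1.samples, s2.samples)


class TestSharedReactions:
    def test_identical_sets_full_intersection(self):
        a = sample_set("a", ["R1", "R2"], [[1, 2]])
        b = sample_set("b", ["R2", "R1"], [[3, 4]])
        assert shared_reactions([a, b]) == ["R1", "R2"]

    def test_disjoint_sets_empty(self):
        a = sample_set("a", ["R1"], [[1]])
        b = sample_set("b", ["R2"], [[2]])
        assert shared_reactions([a, b]) == []

    def test_three_way_intersection_ordered(self):
        a = sample_set("a", ["A", "B", "C"], [[1, 2, 3]])
        b = sample_set("b", ["B", "C", "D"], [[1, 2, 3]])
        c = sample_set("c", ["C", "B"], [[1, 2]])
        assert shared_reactions([a, b, c]) == ["B", "C"]


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        a = sample_set("a", ["R1", "R2"], [[1, 2], [1, 2]])
        b = sample_set("b", ["R1", "R2"], [[1, 2]])
        distances, _ = bray_curtis_matrix([a, b])
        assert distances[0, 1] == pytest.approx(0.0)

    def test_disjoint_support_is_one(self):
        a = sample_set("a", ["R1", "R2"], [[1, 0]])
        b = sample_set("b", ["R1", "R2"], [[0, 5]])
        distances, _ = bray_curtis_matrix([a, b])
        assert distances[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        a = sample_set("a", ["R1", "R2"], [[1, 2]])
        b = sample_set("b", ["R1", "R2"], [[3, 0]])
        distances, _ = bray_curtis_matrix([a, b])
        assert distances[0, 1] == pytest.approx(2.0 / 3.0)

    def test_negative_fluxes_enter_as_magnitudes(self):
        a = sample_set("a", ["R1", "R2"], [[-1, 2]])
        b = sample_set("b", ["R1", "R2"], [[1, -2]])
        distances, _ = bray_curtis_matrix([a, b])
        assert distances[0, 1] == pytest.approx(0.0)

    def test_matrix_properties(self):
        rng = np.random.default_rng(2)
        a = sample_set("a", ["R1", "R2", "R3"], rng.uniform(0, 5, (6, 3)))
        b = sample_set("b", ["R1", "R2", "R3"], rng.uniform(0, 5, (6, 3)))
        distances, labels = bray_curtis_matrix([a, b])
        assert distances.shape == (12, 12) and len(labels) == 12
        assert np.allclose(distances, distances.T)
        assert np.allclose(np.diag(distances), 0.0)
        assert distances.min() >= 0 and distances.max() <= 1

    def test_all_zero_pair_defined_as_zero(self):
        a = sample_set("a", ["R1"], [[0.0], [0.0]])
        b = sample_set("b", ["R1"], [[0.0]])
        distances, _ = bray_curtis_matrix([a, b])
        assert np.all(distances == 0.0)


class TestOrdination:
    def test_equilateral_configuration(self):
        distances = np.ones((3, 3)) - np.eye(3)
        coords, stress = ordinate_2d(distances, seed=0)
        embedded = [
            np.linalg.norm(coords[i] - coords[j]) for i, j in [(0, 1), (0, 2), (1, 2)]
        ]
        assert max(embedded) / min(embedded) < 1.05

    def test_duplicated_point_coincident(self):
        distances = np.array(
            [[0, 0, 1, 1], [0, 0, 1, 1], [1, 1, 0, 0.5], [1, 1, 0.5, 0]], float
        )
        coords, _ = ordinate_2d(distances, seed=1)
        scale = np.abs(coords).max()
        assert np.linalg.norm(coords[0] - coords[1]) < 0.05 * scale

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            ordinate_2d(np.zeros((2, 2)), seed=0)

    def test_more_restarts_never_worse(self):
        rng = np.random.default_rng(4)
        points = rng.normal(0, 1, (8, 4))
        from scipy.spatial.distance import pdist, squareform

        distances = squareform(pdist(points))
        _, stress1 = ordinate_2d(distances, seed=5, n_restarts=1)
        _, stress8 = ordinate_2d(distances, seed=5, n_restarts=8)
        assert stress8 <= stress1 + 1e-12


def planted_sample_sets(seed, n=25, n_features=12, shift=4.0):
    """Two conditions identical except one reaction with disjoint flux ranges."""
    rng = np.random.default_rng(seed)
    reactions = [f"R{i:02d}" for i in range(n_features)]
    base_a = rng.normal(5, 1, (n, n_features))
    base_b = rng.normal(5, 1, (n, n_features))
    base_b[:, 3] += shift  # R03 is the planted divergent reaction
    return [
        sample_set("ctrl", reactions, np.abs(base_a), seed),
        sample_set("drug", reactions, np.abs(base_b), seed),
    ]


class TestFeatureRanking:
    def test_planted_divergent_reaction_ranks_first(self):
        sets = planted_sample_sets(seed=10)
        ranking = rank_distinguishing_reactions(sets, seed=0)
        assert ranking.top == "R03"

    def test_rf_and_smd_agree_on_clean_separation(self):
        sets = planted_sample_sets(seed=11, shift=8.0)
        rf = rank_distinguishing_reactions(sets, seed=1, method="rf")
        smd = rank_distinguishing_reactions(sets, seed=1, method="smd")
        assert rf.top == smd.top == "R03"

    def test_identical_distributions_within_null_envelope(self):
        sets = planted_sample_sets(seed=12, shift=0.0)
        ranking = rank_distinguishing_reactions(sets, seed=2, method="smd")
        null = null_importance_distribution(sets, seed=3, method="smd", n_null=30)
        assert ranking.features[0][1] <= np.quantile(null, 0.95)

    def test_seeded_full_ranking_reproducible(self):
        sets = planted_sample_sets(seed=13)
        r1 = rank_distinguishing_reactions(sets, seed=4)
        r2 = rank_distinguishing_reactions(sets, seed=4)
        assert r1.features == r2.features

    def test_single_label_rejected(self):
        sets = planted_sample_sets(seed=14)
        sets[1].condition_label = sets[0].condition_label
        with pytest.raises(ValueError, match="two condition labels"):
            rank_distinguishing_reactions(sets, seed=0)

    def test_too_few_samples_rejected(self):
        a = sample_set("a", ["R1"], [[1.0]] * 3)
        b = sample_set("b", ["R1"], [[2.0]] * 8)
        with pytest.raises(ValueError, match="fewer than 5"):
            rank_distinguishing_reactions([a, b], seed=0)
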