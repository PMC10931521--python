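import itertools

import numpy as np
import pandas as pd
import pytest

from gemtide.metabolomics import (
    AbundanceMatrix,
    bh_adjust,
    classify_metabolites,
    filter_missing,
    impute_half_min,
    mann_whitney,
    normalize,
)
from gemtide.synth import simulate_abundances
from .oracles import bh_oracle, mwu_exact_oracle


def make_matrix(values, groups=None, stage="raw"):
    frame = pd.DataFrame(values)
    if groups is None:
        # first column doubles as the blank sample; grouping is irrelevant
        # for the stage-level tests using this helper
        cols = list(frame.columns)
        groups = {c: ("blank" if str(c).startswith("b") or c == cols[0] else "cond")
                  for c in cols}
    return AbundanceMatrix(values=frame, sample_groups=groups, blank_group="blank", stage=stage)


def ten_sample_matrix(missing_per_row):
    cols = [f"b{i}" for i in range(3)] + [f"s{i}" for i in range(7)]
    data = {}
    rng = np.random.default_rng(0)
    for met, n_missing in missing_per_row.items():
        row = rng.uniform(10, 100, 10)
        row[:n_missing] = np.nan
        data[met] = row
    return make_matrix(pd.DataFrame(data, index=cols).T)


class TestFilterMissing:
    def test_strictly_greater_than_60_percent_removed(self):
        matrix = ten_sample_matrix({"gone": 7, "kept_boundary": 6, "complete": 0})
        out = filter_missing(matrix)
        assert list(out.values.index) == ["kept_boundary", "complete"]
        assert out.stage == "filtered"

    def test_no_missing_all_retained(self):
        matrix = ten_sample_matrix({"a": 0, "b": 0})
        assert len(filter_missing(matrix).values) == 2

    def test_threshold_configurable(self):
        matrix = ten_sample_matrix({"half": 5})
        assert len(filter_missing(matrix, max_missing_fraction=0.4).values) == 0


class TestImputation:
    def test_half_minimum_rule(self):
        matrix = make_matrix({"s1": [np.nan], "s2": [4.0], "s3": [8.0]}, stage="filtered")
        out = impute_half_min(matrix)
        assert list(out.values.iloc[0]) == [2.0, 4.0, 8.0]

    def test_two_sample_case(self):
        matrix = make_matrix({"s1": [np.nan], "s2": [10.0]}, stage="filtered")
        assert list(impute_half_min(matrix).values.iloc[0]) == [5.0, 10.0]

    def test_complete_rows_untouched(self):
        matrix = make_matrix({"s1": [3.0], "s2": [9.0]}, stage="filtered")
        assert list(impute_half_min(matrix).values.iloc[0]) == [3.0, 9.0]

    def test_all_missing_row_rejected(self):
        matrix = make_matrix({"s1": [np.nan], "s2": [np.nan]}, stage="filtered")
        with pytest.raises(ValueError, match="no observed values"):
            impute_half_min(matrix)

    def test_requires_filtered_stage(self):
        matrix = make_matrix({"s1": [1.0], "s2": [2.0]})
        with pytest.raises(ValueError, match="filtered"):
            impute_half_min(matrix)


class TestNormalize:
    def test_log2_mean_centering_closed_form(self):
        matrix = make_matrix({"s1": [1.0], "s2": [8.0]}, stage="imputed")
        out = normalize(matrix, log_base=2, center="mean")
        assert list(out.values.iloc[0]) == pytest.approx([-1.5, 1.5])

    def test_geometric_progression(self):
        b = 3.0
        matrix = make_matrix({"s1": [1.0], "s2": [b], "s3": [b * b]}, stage="imputed")
        out = normalize(matrix, log_base=b)
        assert list(out.values.iloc[0]) == pytest.approx([-1.0, 0.0, 1.0])

    def test_constant_row_becomes_zero(self):
        matrix = make_matrix({"s1": [5.0], "s2": [5.0]}, stage="imputed")
        assert list(normalize(matrix).values.iloc[0]) == pytest.approx([0.0, 0.0])

    def test_median_centering_option(self):
        matrix = make_matrix({"s1": [1.0], "s2": [2.0], "s3": [16.0]}, stage="imputed")
        out = normalize(matrix, center="median")
        assert sorted(out.values.iloc[0])[1] == pytest.approx(0.0)

    def test_renormalizing_is_guarded(self):
        matrix = make_matrix({"s1": [1.0], "s2": [8.0]}, stage="imputed")
        out = normalize(matrix)
        with pytest.raises(ValueError, match="already normalized"):
            normalize(out)

    def test_nonpositive_values_rejected(self):
        matrix = make_matrix({"s1": [0.0], "s2": [8.0]}, stage="imputed")
        with pytest.raises(ValueError, match="positive"):
            normalize(matrix)


class TestMannWhitney:
    def test_canonical_separation_example(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6], mode="exact")
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_degenerate_constant_data(self):
        _, p = mann_whitney([5, 5, 5], [5, 5, 5], mode="exact")
        assert p == 1.0

    def test_label_swap_symmetry(self):
        x, y = [1.0, 3.0, 7.0], [2.0, 2.0, 9.0]
        assert mann_whitney(x, y, mode="exact")[1] == pytest.approx(
            mann_whitney(y, x, mode="exact")[1]
        )

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_matches_bruteforce_enumeration(self):
        """200 random small-sample vectors (with ties) match the oracle."""
        rng = np.random.default_rng(31)
        for _ in range(200):
            n_x, n_y = rng.integers(1, 6), rng.integers(1, 6)
            x = rng.integers(0, 6, n_x).astype(float)
            y = rng.integers(0, 6, n_y).astype(float)
            u_impl, p_impl = mann_whitney(x, y, mode="exact")
            u_oracle, p_oracle = mwu_exact_oracle(x, y)
            assert u_impl == pytest.approx(u_oracle)
            assert p_impl == pytest.approx(p_oracle)

    def test_exact_floor_at_n3(self):
        """With 3 vs 3 and no ties the smallest exact two-sided p is 0.1."""
        best = min(
            mann_whitney(list(combo), [v for v in range(6) if v not in combo], mode="exact")[1]
            for combo in itertools.combinations(range(6), 3)
        )
        assert best == pytest.approx(0.1)

    def test_asymptotic_mode_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 8), rng.normal(1.0, 1, 8)
        _, p_exact = mann_whitney(x, y, mode="exact")
        _, p_asym = mann_whitney(x, y, mode="asymptotic")
        assert p_asym == pytest.approx(p_exact, abs=0.05)


class TestBHAdjust:
    def test_stepup_closed_form_example(self):
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_all_equal_p_unchanged(self):
        assert list(bh_adjust([0.2, 0.2, 0.2])) == pytest.approx([0.2, 0.2, 0.2])

    def test_matches_closed_form_oracle_and_order_invariance(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 40)
        q = bh_adjust(p)
        assert q == pytest.approx(bh_oracle(p))
        assert np.all(q >= p - 1e-12)
        perm = rng.permutation(40)
        assert q[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_fewer_discoveries_at_stricter_alpha(self):
        rng = np.random.default_rng(6)
        q = bh_adjust(rng.uniform(0, 0.5, 50))
        assert (q < 0.05).sum() <= (q < 0.1).sum()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


@pytest.fixture(scope="module")
def classified():
    matrix, truth = simulate_abundances(seed=0)
    matrix = normalize(impute_half_min(filter_missing(matrix)))
    results = classify_metabolites(matrix, [("treat", "control")])
    return {r.metabolite: r for r in results}, truth


class TestClassification:
    def test_planted_uptake_is_consumed_only_and_lower_in_treatment(self, classified):
        results, _ = classified
        glucose = results["glucose"]
        assert glucose.class_label == "consumed_only"
        assert glucose.vs_blank["treat"][0] == "consumed"
        assert glucose.vs_blank["control"][0] == "consumed"
        assert glucose.treatment_vs_control[("treat", "control")][0] == "lower"

    def test_planted_secretion_is_produced(self, classified):
        results, _ = classified
        assert results["lactate"].class_label == "produced_or_consumed"
        assert results["lactate"].vs_blank["treat"][0] == "produced"

    def test_treatment_only_secretion(self, classified):
        results, _ = classified
        deoxyuridine = results["2-deoxyuridine"]
        assert deoxyuridine.vs_blank["treat"][0] == "produced"
        assert deoxyuridine.vs_blank["control"][0] == "unchanged"
        assert deoxyuridine.class_label == "produced_or_consumed"

    def test_differential_without_blank_significance(self, classified):
        results, _ = classified
        erythritol = results["erythritol"]
        assert erythritol.class_label == "differential_without_blank_significance"
        assert erythritol.treatment_vs_control[("treat", "control")][0] == "higher"

    def test_neutral_metabolite_unchanged(self, classified):
        results, _ = classified
        assert results["ethylmalonate"].class_label == "unchanged"

    def test_planted_truth_recovered(self, classified):
        results, truth = classified
        for met, planted in truth.planted_metabolites.items():
            for group, expected in planted.items():
                assert results[met].vs_blank[group][0] == expected, (met, group)

    def test_unknown_condition_label_rejected(self):
        matrix, _ = simulate_abundances(seed=0)
        matrix = normalize(impute_half_min(filter_missing(matrix)))
        with pytest.raises(KeyError, match="nope"):
            classify_metabolites(matrix, [("nope", "control")])

    def test_requires_normalized_stage(self):
        matrix, _ = simulate_abundances(seed=0)
        with pytest.raises(ValueError, match="normalized"):
            classify_metabolites(matrix, [("treat", "control")])
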