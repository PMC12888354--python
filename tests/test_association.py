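"""Mixed-type association statistics and matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fanet.association import (
    MissingPolicy,
    build_matrix,
    cramers_v,
    eta_squared,
    pearson_r,
    prune_collinear,
)
from fanet.synthetic import (
    CategoricalMarginal,
    CohortTable,
    NormalMarginal,
    VariableSpec,
)

from conftest import matrix_from_array


# --- elementary statistics ------------------------------------------------


@pytest.mark.parametrize(
    "x,y,expected",
    [((1, 2, 3), (1, 2, 3), 1.0),
     ((1, 2, 3), (3, 2, 1), -1.0),
     ((1, 2, 3, 4), (1, 3, 2, 4), 0.8)],  # hand: cov=1, sd^2=5/3 each
)
def test_pearson_examples(x, y, expected):
    assert pearson_r(x, y) == pytest.approx(expected)


def test_pearson_undefined_cases():
    assert np.isnan(pearson_r((1, 1, 1), (1, 2, 3)))  # zero variance
    assert np.isnan(pearson_r((1, 2), (1, 2)))  # too few pairs
    # pairwise deletion: NaNs removed before computing
    assert pearson_r((1, 2, 3, np.nan), (1, 2, 3, 9)) == pytest.approx(1.0)


def test_pearson_standardized_equals_mean_of_products(rng):
    for _ in range(20):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        zx = (x - x.mean()) / x.std()
        zy = (y - y.mean()) / y.std()
        assert abs(pearson_r(x, y) - np.mean(zx * zy)) < 1e-12


def test_cramers_v_published_2x2_and_degenerate():
    # food addiction by sex contingency from the cohort description
    v = cramers_v([[8, 34], [16, 35]])
    assert v == pytest.approx(0.140, abs=5e-4)
    assert cramers_v([[10, 0], [0, 10]]) == pytest.approx(1.0)
    assert cramers_v([[5, 5], [5, 5]]) == pytest.approx(0.0)
    assert np.isnan(cramers_v([[5, 5], [0, 0]]))  # degenerate margin


def test_cramers_v_label_permutation_invariant(rng):
    t = rng.integers(1, 30, size=(3, 4))
    base = cramers_v(t)
    assert cramers_v(t[::-1]) == pytest.approx(base)
    assert cramers_v(t[:, ::-1]) == pytest.approx(base)
    assert cramers_v(t.T) == pytest.approx(base)


@pytest.mark.parametrize(
    "x,g,expected",
    [((1, 1, 2, 2), ("a", "a", "b", "b"), 1.0),
     ((1, 2, 1, 2), ("a", "a", "b", "b"), 0.0),
     ((1, 2, 3, 4), ("a", "a", "b", "b"), 0.8)],  # SSb=4, SStot=5
)
def test_eta_squared_examples(x, g, expected):
    assert eta_squared(x, g) == pytest.approx(expected)


def test_eta_squared_undefined_cases():
    assert np.isnan(eta_squared((1, 2, 3), ("a", "a", "a")))  # one group
    assert np.isnan(eta_squared((2, 2, 2, 2), ("a", "a", "b", "b")))  # no variance


# --- matrix assembly ------------------------------------------------------


def tiny_cohort(with_missing=False):
    df = pd.DataFrame({
        "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "y": [2.0, 1.0, 4.0, 3.0, 6.0, 5.0],
        "flag": ["no", "yes", "no", "yes", "no", "yes"],
    })
    if with_missing:
        df.loc[0, "x"] = np.nan
        df.loc[2, "flag"] = np.nan
    specs = [
        VariableSpec("x", "continuous", NormalMarginal(3.5, 1.9)),
        VariableSpec("y", "continuous", NormalMarginal(3.5, 1.9)),
        VariableSpec("flag", "binary", CategoricalMarginal(("no", "yes"), (0.5, 0.5))),
    ]
    return CohortTable(df, specs)


def test_build_matrix_method_dispatch():
    m = build_matrix(tiny_cohort())
    assert m.method.loc["x", "y"] == "pearson"
    assert m.method.loc["x", "flag"] == "eta_squared"
    assert m.method.loc["y", "flag"] == "eta_squared"


def test_build_matrix_symmetric_unit_diagonal(study_cohort):
    m = build_matrix(study_cohort)
    v = m.values.to_numpy()
    assert np.array_equal(v, v.T)
    assert np.allclose(np.diag(v), 1.0)
    # bounded entries per method
    for i, a in enumerate(m.variables):
        for b in m.variables[i + 1:]:
            val, meth = m.values.loc[a, b], m.method.loc[a, b]
            if np.isnan(val):
                continue
            assert -1 <= val <= 1
            if meth in ("cramers_v", "eta_squared"):
                assert val >= 0


def test_policies_are_noops_without_missing():
    complete = tiny_cohort()
    results = [
        build_matrix(complete, policy=MissingPolicy(cont, flag))
        for cont in ("complete_case", "listwise", "mean_impute")
        for flag in (True, False)
    ]
    for r in results[1:]:
        pd.testing.assert_frame_equal(r.values, results[0].values)


def test_binary_zero_fill_and_pairwise_n():
    cohort = tiny_cohort(with_missing=True)
    m = build_matrix(cohort, policy=MissingPolicy("complete_case", True))
    # binary missing filled with reference category -> full n for flag pairs
    assert m.n_used.loc["y", "flag"] == 6
    # continuous missing handled pairwise
    assert m.n_used.loc["x", "y"] == 5
    m2 = build_matrix(cohort, policy=MissingPolicy("complete_case", False))
    assert m2.n_used.loc["y", "flag"] == 5


def test_all_missing_column_rejected():
    cohort = tiny_cohort()
    cohort.data["x"] = np.nan
    with pytest.raises(ValueError, match="no observed values"):
        build_matrix(cohort)


def test_sqrt_eta_switch():
    plain = build_matrix(tiny_cohort())
    root = build_matrix(tiny_cohort(), sqrt_eta=True)
    assert root.values.loc["x", "flag"] == pytest.approx(
        np.sqrt(plain.values.loc["x", "flag"])
    )


# --- collinearity pruning -------------------------------------------------


def test_prune_single_violating_pair():
    m = matrix_from_array([[1, 0.95, 0.2], [0.95, 1, 0.3], [0.2, 0.3, 1]])
    pruned, removed = prune_collinear(m, 0.90)
    assert len(removed) == 1
    assert removed[0][0] == "B"  # larger mean |association| to others
    v = pruned.abs_values().to_numpy()
    np.fill_diagonal(v, 0)
    assert v.max() < 0.90


def test_prune_no_violation_unchanged():
    m = matrix_from_array([[1, 0.5, 0.1], [0.5, 1, 0.2], [0.1, 0.2, 1]])
    pruned, removed = prune_collinear(m)
    assert removed == []
    assert pruned.variables == m.variables


def test_prune_mutual_triple_keeps_at_most_one():
    m = matrix_from_array(
        [[1, 0.95, 0.92, 0.1],
         [0.95, 1, 0.91, 0.1],
         [0.92, 0.91, 1, 0.1],
         [0.1, 0.1, 0.1, 1]]
    )
    pruned, removed = prune_collinear(m)
    survivors = set(pruned.variables) & {"A", "B", "C"}
    assert len(survivors) <= 1
    assert "D" in pruned.variables


def test_prune_idempotent(rng):
    for _ in range(10):
        a = rng.uniform(-1, 1, (6, 6))
        vals = np.clip((a + a.T) / 2, -1, 1)
        np.fill_diagonal(vals, 1.0)
        m = matrix_from_array(vals)
        once, _ = prune_collinear(m)
        twice, removed_again = prune_collinear(once)
        assert removed_again == []
        assert twice.variables == once.variables
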