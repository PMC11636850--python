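"""The coefficient itself: tallies, difference functions, alpha, oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kalpha import (
    DegenerateDataError,
    MetricDomainError,
    METRICS,
    ReliabilityMatrix,
    UndefinedAlphaError,
    build_rates_by_units,
    compute_alpha,
    delta_squared,
    extract_categories,
    pairwise_alpha_oracle,
)


def mat(*rows):
    return ReliabilityMatrix.from_rows(rows)


class TestCategories:
    def test_worked_example_categories(self, example_matrix):
        assert extract_categories(example_matrix).values == (1, 2, 3, 4, 5)

    def test_single_category(self):
        assert extract_categories(mat([7, 7], [7, 7])).values == (7,)

    def test_unpairable_rating_defines_no_category(self):
        m = mat([1, 2], [9, None])
        assert extract_categories(m).values == (1, 2)

    def test_no_pairable_data(self):
        with pytest.raises(DegenerateDataError):
            extract_categories(mat([1, None], [None, 2]))


class TestRatesByUnits:
    def test_worked_example_totals(self, example_matrix):
        rbu = build_rates_by_units(
            example_matrix, extract_categories(example_matrix)
        )
        assert rbu.n_total == 40
        # the all-distinct unit tallies one rating in each of categories 1-4
        assert rbu.n_uc[5].tolist() == [1, 1, 1, 1, 0]
        # the single-rating unit is recorded but excluded from marginals
        assert rbu.n_u[11] == 1
        assert rbu.n_c.sum() == 40

    def test_complete_toy_totals(self, toy_matrix):
        rbu = build_rates_by_units(toy_matrix, extract_categories(toy_matrix))
        assert rbu.n_u.tolist() == [4, 4, 4, 4, 4]
        assert rbu.n_total == 20


class TestDeltaSquared:
    def test_nominal_identity_and_mismatch(self):
        assert delta_squared("nominal", 3, 3) == 0.0
        assert delta_squared("nominal", 3, 5) == 1.0

    def test_interval_is_squared_difference(self):
        assert delta_squared("interval", 2, 5) == 9.0

    def test_ratio_is_squared_relative_difference(self):
        assert delta_squared("ratio", 1, 3) == 0.25
        assert delta_squared("ratio", 0, 0) == 0.0

    def test_ratio_rejects_negative_categories(self):
        with pytest.raises(MetricDomainError):
            delta_squared("ratio", -1, 3)

    def test_ordinal_counts_ratings_between_ranks(self):
        # marginals n_1 = 2, n_2 = 4, n_3 = 2: delta(1,3) = (8 - 2)^2 = 36
        m = mat([1, 1], [2, 2], [2, 2], [3, 3])
        rbu = build_rates_by_units(m, extract_categories(m))
        assert rbu.n_c.tolist() == [2, 4, 2]
        assert delta_squared("ordinal", 1, 3, rbu) == 36.0
        assert delta_squared("ordinal", 3, 1, rbu) == 36.0
        assert delta_squared("ordinal", 2, 2, rbu) == 0.0

    def test_unknown_metric(self):
        with pytest.raises(ValueError, match="unknown metric"):
            delta_squared("angular", 1, 2)


class TestComputeAlpha:
    def test_worked_example_nominal(self, example_matrix):
        res = compute_alpha(example_matrix, "nominal")
        assert round(res.alpha, 3) == 0.743
        assert res.alpha == 1.0 - res.do_term / res.de_term
        assert res.summary.n_pairable == res.rates_by_units.n_total == 40

    def test_complete_toy_nominal_matches_frozen_oracle_value(self, toy_matrix):
        # value frozen from pairwise_alpha_oracle before the main build
        assert compute_alpha(toy_matrix, "nominal").alpha == pytest.approx(
            0.8503937007874016, abs=1e-12
        )

    def test_perfect_agreement_gives_one_for_every_metric(self):
        m = mat([1, 1], [2, 2], [3, 3])
        for metric in METRICS:
            res = compute_alpha(m, metric)
            assert res.alpha == 1.0
            assert res.do_term == 0.0

    def test_single_category_is_undefined(self):
        with pytest.raises(UndefinedAlphaError) as exc:
            compute_alpha(mat([5, 5], [5, 5]), "nominal")
        assert exc.value.uniform
        assert exc.value.summary.n_pairable == 4

    def test_systematic_disagreement_is_negative(self):
        m = mat([1, 2], [1, 2])
        assert compute_alpha(m, "nominal").alpha == pytest.approx(-0.5)

    def test_no_pairable_data_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            compute_alpha(mat([1, None], [None, 2]), "interval")

    def test_ratio_domain_violation_propagates(self):
        with pytest.raises(MetricDomainError):
            compute_alpha(mat([-1, 2], [3, 3]), "ratio")


# ---------------------------------------------------------------------------
# property tests against the brute-force pairwise oracle

small_matrices = st.integers(2, 4).flatmap(
    lambda w: st.lists(
        st.lists(
            st.one_of(st.none(), st.integers(0, 2)), min_size=w, max_size=w
        ),
        min_size=1,
        max_size=5,
    )
)


@settings(max_examples=200, derandomize=True)
@given(rows=small_matrices, metric=st.sampled_from(METRICS))
def test_alpha_matches_pairwise_enumeration(rows, metric):
    """Tally-based alpha equals brute-force pair enumeration, or both
    reject the input with the same typed error."""
    m = ReliabilityMatrix.from_rows(rows)
    try:
        expected = pairwise_alpha_oracle(m, metric)
    except (DegenerateDataError, UndefinedAlphaError) as err:
        with pytest.raises(type(err)):
            compute_alpha(m, metric)
        return
    assert compute_alpha(m, metric).alpha == pytest.approx(expected, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(rows=small_matrices, metric=st.sampled_from(METRICS), seed=st.integers(0, 999))
def test_alpha_invariant_under_permutations(rows, metric, seed):
    m = ReliabilityMatrix.from_rows(rows)
    try:
        base = compute_alpha(m, metric).alpha
    except (DegenerateDataError, UndefinedAlphaError):
        return
    rng = np.random.default_rng(seed)
    shuffled_rows = [list(m.cells[i]) for i in rng.permutation(m.n_items)]
    cols = rng.permutation(m.n_raters)
    permuted = ReliabilityMatrix.from_rows(
        [[row[j] for j in cols] for row in shuffled_rows]
    )
    assert compute_alpha(permuted, metric).alpha == pytest.approx(base, abs=1e-12)


@settings(max_examples=100, derandomize=True)
@given(rows=small_matrices, a=st.sampled_from([-2, -1, 2, 3]), b=st.integers(-5, 5))
def test_interval_alpha_is_affine_invariant(rows, a, b):
    """Rescaling rates r -> a*r + b leaves interval alpha unchanged."""
    m = ReliabilityMatrix.from_rows(rows)
    try:
        base = compute_alpha(m, "interval").alpha
    except (DegenerateDataError, UndefinedAlphaError):
        return
    rescaled = ReliabilityMatrix.from_rows(
        [[None if v is None else a * v + b for v in row] for row in m.cells]
    )
    assert compute_alpha(rescaled, "interval").alpha == pytest.approx(base, abs=1e-9)


binary_matrices = st.integers(2, 4).flatmap(
    lambda w: st.lists(
        st.lists(
            st.one_of(st.none(), st.integers(0, 1)), min_size=w, max_size=w
        ),
        min_size=2,
        max_size=6,
    )
)


@settings(max_examples=100, derandomize=True)
@given(rows=binary_matrices)
def test_binary_metrics_coincide(rows):
    """With two categories {0, 1} the nominal, interval and ratio alphas
    are identical: the difference functions differ by a constant factor
    that cancels in Do/De."""
    m = ReliabilityMatrix.from_rows(rows)
    try:
        nominal = compute_alpha(m, "nominal").alpha
    except (DegenerateDataError, UndefinedAlphaError):
        return
    if len(extract_categories(m)) != 2:
        return
    assert compute_alpha(m, "interval").alpha == pytest.approx(nominal, abs=1e-12)
    assert compute_alpha(m, "ratio").alpha == pytest.approx(nominal, abs=1e-12)


@settings(max_examples=150, derandomize=True)
@given(rows=small_matrices, metric=st.sampled_from(METRICS))
def test_alpha_never_exceeds_one(rows, metric):
    m = ReliabilityMatrix.from_rows(rows)
    try:
        res = compute_alpha(m, metric)
    except (DegenerateDataError, UndefinedAlphaError):
        return
    assert res.alpha <= 1.0
    assert res.do_term >= 0.0
    assert res.de_term > 0.0


def test_summary_pairable_count_equals_tally_total(example_matrix, toy_missing_matrix):
    """n.. computed by the tally equals n_pairable from the file summary."""
    for m in (example_matrix, toy_missing_matrix):
        res = compute_alpha(m, "nominal")
        assert res.rates_by_units.n_total == res.summary.n_pairable
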