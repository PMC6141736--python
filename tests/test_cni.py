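"""CNI tree algebra, ML fitting, and nested G² tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moralcni import (
    CniCounts,
    CniParams,
    EqualAcrossGroups,
    FixParameter,
    aggregate_counts,
    category_probabilities,
    fit_ml,
    generate_study,
    GeneratorConfig,
    moment_inversion,
)
from moralcni import test_group_equality as group_equality_test
from moralcni import test_parameter_reference as parameter_reference_test
from moralcni.io_types import ValidationError

from _oracle import grid_equality_fit, grid_fit
from conftest import exact_counts, random_counts

unit = st.floats(0.0, 1.0, allow_nan=False)


# --- tree algebra ----------------------------------------------------------


@pytest.mark.parametrize(
    "params,expected",
    [
        ((1.0, 0.4, 0.7), (1, 0, 1, 0)),        # consequences fully drive
        ((0.0, 0.0, 0.5), (0.5, 0.5, 0.5, 0.5)),  # pure coin flip
        ((0.2, 0.3, 0.6), (0.424, 0.224, 0.664, 0.464)),  # hand enumeration
    ],
)
def test_category_probabilities_worked_examples(params, expected):
    assert category_probabilities(CniParams(*params)) == pytest.approx(expected)


@given(c=unit, n=unit, i=unit)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_category_probabilities_structure(c, n, i):
    """Outputs are probabilities; p1-p2 = C; the 1-df constraint p3-p1 = p4-p2."""
    p = category_probabilities(CniParams(c, n, i))
    assert ((0 <= p) & (p <= 1)).all()
    assert p[0] - p[1] == pytest.approx(c, abs=1e-12)
    assert p[2] - p[0] == pytest.approx(p[3] - p[1], abs=1e-12)


@pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (0.5, 1.2, 0.5)])
def test_out_of_range_parameters_rejected(bad):
    with pytest.raises(ValueError):
        category_probabilities(bad)


# --- moment inversion ------------------------------------------------------


def test_moment_inversion_worked_examples():
    res = moment_inversion((0.424, 0.224, 0.664, 0.464))
    assert res.in_range
    assert res.params.C == pytest.approx(0.2, abs=1e-12)
    assert res.params.N == pytest.approx(0.3, abs=1e-12)
    assert res.params.I == pytest.approx(0.6, abs=1e-12)

    coin = moment_inversion((0.5, 0.5, 0.5, 0.5))
    assert (coin.params.C, coin.params.N, coin.params.I) == (0.0, 0.0, 0.5)

    boundary = moment_inversion((1.0, 0.0, 1.0, 0.0))
    assert boundary.params.C == 1.0
    assert not boundary.in_range  # N, I undefined at C = 1


@given(c=st.floats(0.01, 0.95), n=st.floats(0.01, 0.95), i=st.floats(0.01, 0.99))
@settings(max_examples=150, deadline=None, derandomize=True)
def test_moment_inversion_inverts_the_tree(c, n, i):
    res = moment_inversion(category_probabilities(CniParams(c, n, i)))
    assert res.in_range
    assert res.params.C == pytest.approx(c, abs=1e-9)
    assert res.params.N == pytest.approx(n, abs=1e-9)
    assert res.params.I == pytest.approx(i, abs=1e-9)


# --- count aggregation -----------------------------------------------------


def test_aggregate_counts_sums_and_doubles(battery):
    from moralcni.io_types import Participant, ResponseDataset, ResponseRecord

    p1 = Participant("a", 20, 0, 10)
    records = [ResponseRecord("a", it.item_id, 1) for it in battery]
    one = aggregate_counts(ResponseDataset(battery, [p1], records))[0]
    assert np.array_equal(one.n_action, [6, 6, 6, 6])
    assert np.array_equal(one.n_inaction, [0, 0, 0, 0])

    p2 = Participant("b", 20, 0, 10)
    records2 = records + [ResponseRecord("b", it.item_id, 1) for it in battery]
    two = aggregate_counts(ResponseDataset(battery, [p1, p2], records2))[0]
    assert np.array_equal(two.n_action, 2 * one.n_action)


def test_aggregate_counts_cell_totals_at_study_scale():
    study = generate_study(GeneratorConfig(n_participants=197, seed=6))
    counts = aggregate_counts(study.dataset)[0]
    assert np.array_equal(counts.totals, [1182, 1182, 1182, 1182])  # 197*6


def test_aggregate_counts_empty_group_rejected(small_study):
    with pytest.raises(ValidationError, match="no responses"):
        aggregate_counts(small_study.dataset, {"nobody": "g1"})


# --- maximum likelihood ----------------------------------------------------


def test_fit_recovers_exact_model_counts():
    fit = fit_ml(exact_counts(CniParams(0.2, 0.3, 0.6)))
    est = fit.params["all"]
    assert est.C == pytest.approx(0.2, abs=1e-4)
    assert est.N == pytest.approx(0.3, abs=1e-4)
    assert est.I == pytest.approx(0.6, abs=1e-4)
    assert fit.g2 < 1e-6
    assert fit.df == 1


def test_two_group_free_fit_has_two_df():
    a = exact_counts(CniParams(0.2, 0.3, 0.6), group="low")
    b = exact_counts(CniParams(0.25, 0.3, 0.5), group="high")
    fit = fit_ml([a, b])
    assert fit.df == 2
    assert fit.n_free == 6
    assert fit.params["high"].I == pytest.approx(0.5, abs=1e-4)


def test_fixed_value_constraint_honoured():
    counts = exact_counts(CniParams(0.2, 0.3, 0.6))
    fit = fit_ml(counts, [FixParameter("I", 0.5)])
    assert fit.params["all"].I == 0.5
    assert fit.n_free == 2
    assert fit.g2 > 0


def test_equality_constraint_shares_parameter():
    a = exact_counts(CniParams(0.2, 0.3, 0.7), group="a")
    b = exact_counts(CniParams(0.2, 0.3, 0.5), group="b")
    fit = fit_ml([a, b], [EqualAcrossGroups("I")])
    assert fit.n_free == 5
    assert fit.params["a"].I == pytest.approx(fit.params["b"].I, abs=1e-9)
    # shared I lands between the generating values
    assert 0.5 < fit.params["a"].I < 0.7


def test_fit_matches_grid_oracle_on_random_tables():
    rng = np.random.default_rng(42)
    for _ in range(5):
        counts = random_counts(rng)
        fit = fit_ml(counts)
        (oc, on, oi), _ = grid_fit(counts)
        assert fit.params["g"].C == pytest.approx(oc, abs=0.01)
        assert fit.params["g"].N == pytest.approx(on, abs=0.01)
        assert fit.params["g"].I == pytest.approx(oi, abs=0.01)


def test_empty_cell_rejected():
    with pytest.raises(ValidationError, match="empty design cell"):
        fit_ml(CniCounts(np.zeros(4), np.zeros(4)))


def test_wald_cis_bracket_estimates():
    fit = fit_ml(exact_counts(CniParams(0.2, 0.3, 0.6)))
    for name in ("C", "N", "I"):
        lo, hi = fit.ci95["all"][name]
        est = getattr(fit.params["all"], name)
        assert lo < est < hi
        assert 0.0 <= lo and hi <= 1.0


def test_profile_cis_close_to_wald_in_regular_case():
    fit_w = fit_ml(exact_counts(CniParams(0.3, 0.3, 0.5)))
    fit_p = fit_ml(exact_counts(CniParams(0.3, 0.3, 0.5)), profile_ci=True)
    for name in ("C", "N", "I"):
        wlo, whi = fit_w.ci95["all"][name]
        plo, phi = fit_p.ci95["all"][name]
        assert plo == pytest.approx(wlo, abs=5e-3)
        assert phi == pytest.approx(whi, abs=5e-3)


# --- nested tests ----------------------------------------------------------


def test_reference_test_null_is_small_and_violation_large():
    rng = np.random.default_rng(7)
    params = CniParams(0.3, 0.25, 0.5)
    p = category_probabilities(params)
    totals = np.full(4, 6000)
    actions = rng.binomial(totals, p).astype(float)
    counts = CniCounts(actions, totals - actions, group="all")
    near = parameter_reference_test(counts, "I", 0.5)
    far = parameter_reference_test(counts, "I", 0.0)
    assert near.df == 1
    assert near.statistic < far.statistic
    assert far.p_value < 1e-6


def test_reference_test_matches_grid_oracle():
    rng = np.random.default_rng(8)
    counts = random_counts(rng)
    t = parameter_reference_test(counts, "C", 0.0)
    _, ll_free = grid_fit(counts)
    _, ll_con = grid_fit(counts, fixed={"C": 0.0})
    assert t.statistic == pytest.approx(2 * (ll_free - ll_con), abs=0.05)


def test_reference_outside_unit_interval_rejected():
    counts = exact_counts(CniParams(0.2, 0.3, 0.6))
    with pytest.raises(ValueError):
        parameter_reference_test(counts, "C", 1.5)


def test_group_equality_zero_for_identical_tables():
    a = exact_counts(CniParams(0.2, 0.3, 0.6), group="a")
    b = exact_counts(CniParams(0.2, 0.3, 0.6), group="b")
    for param in ("C", "N", "I"):
        t = group_equality_test([a, b], param)
        assert t.df == 1
        assert t.statistic == pytest.approx(0.0, abs=1e-6)


def test_group_equality_detects_true_difference():
    rng = np.random.default_rng(9)
    totals = np.full(4, 6000)
    tables = []
    for g, i_val in (("low", 0.4), ("high", 0.6)):
        p = category_probabilities(CniParams(0.2, 0.3, i_val))
        act = rng.binomial(totals, p).astype(float)
        tables.append(CniCounts(act, totals - act, group=g))
    t_i = group_equality_test(tables, "I")
    assert t_i.p_value < 1e-6
    for param in ("C", "N"):
        assert group_equality_test(tables, param).statistic < 12.0


def test_group_equality_matches_grid_oracle():
    rng = np.random.default_rng(10)
    a = random_counts(rng, group="a")
    b = random_counts(rng, group="b")
    free = fit_ml([a, b])
    for param in ("C", "N", "I"):
        t = group_equality_test([a, b], param, fit_free=free)
        (_, _), ll_con = grid_equality_fit(a, b, param)
        _, ll_a = grid_fit(a)
        _, ll_b = grid_fit(b)
        assert t.statistic == pytest.approx(2 * (ll_a + ll_b - ll_con), abs=0.05)


def test_group_equality_requires_two_groups():
    counts = exact_counts(CniParams(0.2, 0.3, 0.6))
    with pytest.raises(ValueError, match="two groups"):
        group_equality_test([counts], "I")
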