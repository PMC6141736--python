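"""Choice scoring, t-test, correlation, hierarchical regression, α, median split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moralcni import (
    GeneratorConfig,
    choice_scores,
    cronbach_alpha,
    generate_study,
    hierarchical_regression,
    median_split,
    one_sample_t,
    pearson_r,
)
from moralcni.classical_stats import NEUTRAL_CHOICE_POINT
from moralcni.io_types import (
    Participant,
    ResponseDataset,
    ResponseRecord,
    ValidationError,
)
from moralcni.pd_model import Congruence, classify_congruence


def _choice_dataset(battery, incong_responses):
    p = Participant("p1", 20, 0, 10)
    records = []
    k = 0
    for it in battery:
        if classify_congruence(it) is Congruence.INCONGRUENT:
            records.append(ResponseRecord("p1", it.item_id, incong_responses[k]))
            k += 1
        else:
            records.append(ResponseRecord("p1", it.item_id, 0))
    return ResponseDataset(battery, [p], records)


@pytest.mark.parametrize(
    "responses,expected",
    [
        ([1] * 6, 6),
        ([0] * 6, 0),
        ([1, 1, 0, 1, 0, 0], NEUTRAL_CHOICE_POINT),
    ],
)
def test_choice_score_counts_incongruent_actions(battery, responses, expected):
    scores = choice_scores(_choice_dataset(battery, responses))
    assert scores[0].score == expected
    assert scores[0].complete


def test_one_sample_t_worked_examples():
    centered = one_sample_t([2, 3, 4], 3)
    assert centered["t"] == 0.0
    assert centered["cohen_d"] == 0.0

    shifted = one_sample_t([4, 5, 6], 3)
    assert shifted["t"] == pytest.approx(2 / (1 / np.sqrt(3)), abs=1e-9)
    assert shifted["df"] == 2

    with pytest.raises(ValueError):
        one_sample_t([5], 3)
    with pytest.raises(ValueError):
        one_sample_t([5, 5, 5], 3)


def test_pearson_r_worked_examples():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson_r(x, x)[0] == pytest.approx(1.0)
    assert pearson_r(x, [-v for v in x])[0] == pytest.approx(-1.0)
    r, p = pearson_r(x, [1.0, 3.0, 2.0, 4.0])
    assert r == pytest.approx(0.8, abs=1e-12)
    assert 0 < p < 1
    with pytest.raises(ValueError):
        pearson_r(x, [1.0, 1.0, 1.0, 1.0])


@given(
    scale=st.floats(0.1, 50),
    shift=st.floats(-100, 100),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_pearson_r_affine_invariance(scale, shift, seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=20)
    y = rng.normal(size=20)
    r1, _ = pearson_r(x, y)
    r2, _ = pearson_r(scale * x + shift, y)
    assert r2 == pytest.approx(r1, abs=1e-8)
    assert pearson_r(y, x)[0] == pytest.approx(r1, abs=1e-12)


# --- hierarchical regression -----------------------------------------------

# 6-observation worked fixture: betas checked against a normal-equations
# solution computed independently inside the test.
_FIXTURE = pd.DataFrame(
    {
        "y": [2.0, 4.0, 5.0, 4.0, 7.0, 9.0],
        "x1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "x2": [0.0, 1.0, 0.0, 1.0, 0.0, 1.0],
        "x3": [3.0, 1.0, 4.0, 1.0, 5.0, 2.0],
    }
)


def _normal_equations_betas(data, outcome, predictors):
    z = (data - data.mean()) / data.std(ddof=1)
    X = np.column_stack([np.ones(len(z))] + [z[c].to_numpy() for c in predictors])
    y = z[outcome].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    r2 = 1 - resid @ resid / (y @ y)
    return beta[1:], r2


def test_hierarchical_regression_matches_normal_equations():
    res = hierarchical_regression(_FIXTURE, "y", [["x1", "x2"], ["x3"]])
    for block, predictors in zip(res.blocks, (["x1", "x2"], ["x1", "x2", "x3"])):
        betas, r2 = _normal_equations_betas(_FIXTURE, "y", predictors)
        assert block.r2 == pytest.approx(r2, abs=1e-10)
        for name, b in zip(predictors, betas):
            assert block.betas[name] == pytest.approx(b, abs=1e-10)
    assert res.blocks[1].delta_r2 == pytest.approx(
        res.blocks[1].r2 - res.blocks[0].r2, abs=1e-14
    )
    assert res.blocks[1].df1 == 1
    assert res.blocks[1].df2 == len(_FIXTURE) - 3 - 1


def test_regression_degenerate_cases():
    data = _FIXTURE.assign(ycopy=_FIXTURE["x1"] * 2 + 1)
    res = hierarchical_regression(data, "ycopy", [["x1"], ["x2"]])
    assert res.blocks[0].r2 == pytest.approx(1.0, abs=1e-12)
    assert res.blocks[1].delta_r2 == pytest.approx(0.0, abs=1e-10)

    rng = np.random.default_rng(0)
    noise = pd.DataFrame(
        {
            "y": rng.normal(size=2000),
            "x1": rng.normal(size=2000),
            "x2": rng.normal(size=2000),
        }
    )
    res = hierarchical_regression(noise, "y", [["x1"], ["x2"]])
    assert res.blocks[1].r2 < 0.01


def test_regression_collinearity_reported():
    data = _FIXTURE.assign(x1dup=_FIXTURE["x1"])
    with pytest.raises(ValidationError, match="collinear"):
        hierarchical_regression(data, "y", [["x1", "x1dup"]])


def test_regression_too_few_rows():
    with pytest.raises(ValidationError, match="too few"):
        hierarchical_regression(_FIXTURE.head(3), "y", [["x1", "x2"], ["x3"]])


# --- Cronbach's alpha -------------------------------------------------------


def test_cronbach_alpha_cases():
    rng = np.random.default_rng(1)
    col = rng.normal(size=200)
    assert cronbach_alpha(np.column_stack([col, col])) == pytest.approx(1.0)

    uncorrelated = rng.normal(size=(5000, 10))
    assert abs(cronbach_alpha(uncorrelated)) < 0.1

    fixture = np.array([[1.0, 2.0, 2.0], [2.0, 3.0, 2.0], [4.0, 5.0, 3.0]])
    k = 3
    expected = k / (k - 1) * (
        1 - fixture.var(axis=0, ddof=1).sum() / fixture.sum(axis=1).var(ddof=1)
    )
    assert cronbach_alpha(fixture) == pytest.approx(expected, abs=1e-12)

    with pytest.raises(ValueError):
        cronbach_alpha(np.ones((5, 3)))
    with pytest.raises(ValueError):
        cronbach_alpha(np.ones((1, 3)))


# --- median split -----------------------------------------------------------


def test_median_split_rule_and_stats():
    split = median_split({f"p{i}": float(v) for i, v in enumerate([1, 2, 3, 4, 5])})
    assert split.median == 3.0
    assert split.sizes == {"high": 2, "low": 3}
    highs = [p for p, g in split.assignment.items() if g == "high"]
    assert sorted(highs) == ["p3", "p4"]

    two = median_split({"a": 1.0, "b": 2.0})
    assert two.sizes == {"high": 1, "low": 1}

    with pytest.raises(ValidationError, match="degenerate"):
        median_split({"a": 2.0, "b": 2.0, "c": 2.0})


def test_median_split_partitions_and_orders():
    rng = np.random.default_rng(5)
    scores = {f"p{i}": float(v) for i, v in enumerate(rng.integers(10, 40, 51))}
    split = median_split(scores)
    assert split.sizes["high"] + split.sizes["low"] == 51
    high_vals = [scores[p] for p, g in split.assignment.items() if g == "high"]
    low_vals = [scores[p] for p, g in split.assignment.items() if g == "low"]
    assert min(high_vals) > max(low_vals)


def test_stress_choice_correlation_sign_under_inaction_link():
    """A positive stress→inaction link lowers utilitarian choice scores."""
    rs = []
    for seed in range(5):
        study = generate_study(
            GeneratorConfig(n_participants=400, seed=seed, beta_I=0.4)
        )
        stress = [p.pss_total for p in study.dataset.participants]
        scores = [s.score for s in choice_scores(study.dataset)]
        rs.append(pearson_r(stress, scores)[0])
    assert np.mean(rs) < 0
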