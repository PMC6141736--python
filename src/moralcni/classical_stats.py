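"""Classical questionnaire statistics: choice scores, correlations,
one-sample t, hierarchical regression with ΔR², Cronbach's α, median split.

The *choice score* is the traditional moral-dilemma outcome: the number of
action ("yes") judgments among a participant's six incongruent items
(proscriptive norm, benefits > costs), on a 0–6 scale with neutral point 3.
Although such scores are often described as item averages, the 0–6 count is
the scale on which the neutral point of 3 and the reported means live, so
the count is what this module computes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_types import ResponseDataset, ValidationError
from .pd_model import Congruence, classify_congruence

__all__ = [
    "ChoiceScore",
    "RegressionBlock",
    "RegressionResult",
    "MedianSplit",
    "choice_scores",
    "one_sample_t",
    "pearson_r",
    "hierarchical_regression",
    "cronbach_alpha",
    "median_split",
]

NEUTRAL_CHOICE_POINT = 3


@dataclass(frozen=True)
class ChoiceScore:
    participant_id: str
    score: int          # count of action responses on incongruent items, 0..6
    complete: bool      # had all 6 incongruent responses


def choice_scores(dataset: ResponseDataset) -> list[ChoiceScore]:
    """0–6 utilitarian choice score per participant (incongruent items)."""
    incong = {
        it.item_id
        for it in dataset.battery
        if classify_congruence(it) is Congruence.INCONGRUENT
    }
    frame = dataset.to_frame()
    sub = frame[frame["item_id"].isin(incong)]
    grouped = sub.groupby("participant_id")["response"].agg(["sum", "count"])
    out = []
    for p in dataset.participants:
        if p.participant_id not in grouped.index:
            raise ValidationError(
                f"participant {p.participant_id} has no incongruent responses"
            )
        row = grouped.loc[p.participant_id]
        out.append(
            ChoiceScore(p.participant_id, int(row["sum"]), row["count"] == len(incong))
        )
    return out


def one_sample_t(values: Sequence[float], mu: float) -> dict:
    """One-sample t-test with Cohen's d = |mean − mu| / sd."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample t requires n >= 2")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    res = stats.ttest_1samp(x, mu)
    return {
        "mean": float(x.mean()),
        "sd": float(sd),
        "mu": float(mu),
        "t": float(res.statistic),
        "df": int(x.size - 1),
        "p_value": float(res.pvalue),
        "cohen_d": float(abs(x.mean() - mu) / sd),
        "n": int(x.size),
    }


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-tailed t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("pearson_r requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("degenerate variance")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RegressionBlock:
    predictors: tuple[str, ...]         # cumulative predictor set
    added: tuple[str, ...]
    betas: dict[str, float]             # standardized coefficients
    r2: float
    delta_r2: float
    f_change: float
    df1: int
    df2: int
    p_change: float


@dataclass
class RegressionResult:
    outcome: str
    n: int
    blocks: list[RegressionBlock] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "n": self.n,
            "blocks": [
                {
                    "predictors": list(b.predictors),
                    "beta": b.betas,
                    "R2": b.r2,
                    "delta_R2": b.delta_r2,
                    "F_change": b.f_change,
                    "df": [b.df1, b.df2],
                    "p_change": b.p_change,
                }
                for b in self.blocks
            ],
        }


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValidationError(f"column {s.name!r} has zero variance")
    return (s - s.mean()) / sd


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    blocks: Sequence[Sequence[str]],
) -> RegressionResult:
    """OLS per cumulative predictor block with standardized β and ΔR².

    The outcome and every predictor (including 0/1-coded ones) are z-scored
    before fitting, so the coefficients are the conventional standardized
    betas.  The F test for each block's ΔR² uses df1 = number of added
    predictors and df2 = n − k − 1 of the larger model.
    """
    cols = [outcome] + [c for blk in blocks for c in blk]
    sub = data[cols].dropna()
    n = len(sub)
    total_preds = sum(len(b) for b in blocks)
    if n <= total_preds + 1:
        raise ValidationError("too few observations for the predictor count")
    z = sub.apply(_zscore)

    result = RegressionResult(outcome=outcome, n=n)
    r2_prev = 0.0
    cumulative: list[str] = []
    for blk in blocks:
        cumulative = cumulative + list(blk)
        X = z[cumulative].to_numpy()
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValidationError(
                f"collinear predictors among {cumulative}", columns=cumulative
            )
        model = sm.OLS(z[outcome].to_numpy(), sm.add_constant(X)).fit()
        r2 = float(model.rsquared)
        delta = r2 - r2_prev
        df1 = len(blk)
        df2 = n - len(cumulative) - 1
        if 1.0 - r2 <= 0:
            f_change, p_change = math.inf, 0.0
        else:
            f_change = (delta / df1) / ((1.0 - r2) / df2)
            p_change = float(stats.f.sf(f_change, df1, df2))
        result.blocks.append(
            RegressionBlock(
                predictors=tuple(cumulative),
                added=tuple(blk),
                betas={c: float(b) for c, b in zip(cumulative, model.params[1:])},
                r2=r2,
                delta_r2=delta,
                f_change=float(f_change),
                df1=df1,
                df2=df2,
                p_change=p_change,
            )
        )
        r2_prev = r2
    return result


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's α = k/(k−1)·(1 − Σ item variances / total variance)."""
    X = np.asarray(item_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need >= 2 participants and >= 2 items")
    k = X.shape[1]
    item_var = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of total scores")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


@dataclass
class MedianSplit:
    median: float
    assignment: dict[str, str]          # participant_id -> "high" | "low"
    group_stats: dict[str, dict]        # n, mean, sd per group

    @property
    def sizes(self) -> dict[str, int]:
        return {g: s["n"] for g, s in self.group_stats.items()}


def median_split(scores: Mapping[str, float]) -> MedianSplit:
    """Dichotomize at the sample median: strictly above → high, else low."""
    if len(scores) < 2:
        raise ValueError("median split requires n >= 2")
    vals = np.array(list(scores.values()), dtype=float)
    if np.ptp(vals) == 0:
        raise ValidationError("median split degenerate: all values identical")
    med = float(np.median(vals))
    assignment = {
        pid: ("high" if v > med else "low") for pid, v in scores.items()
    }
    stats_out = {}
    for g in ("high", "low"):
        gv = np.array([scores[p] for p, lab in assignment.items() if lab == g])
        stats_out[g] = {
            "n": int(gv.size),
            "mean": float(gv.mean()) if gv.size else math.nan,
            "sd": float(gv.std(ddof=1)) if gv.size > 1 else math.nan,
        }
    if stats_out["high"]["n"] == 0 or stats_out["low"]["n"] == 0:
        raise ValidationError("median split degenerate: one group empty")
    return MedianSplit(median=med, assignment=assignment, group_stats=stats_out)
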