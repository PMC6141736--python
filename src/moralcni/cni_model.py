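"""CNI multinomial processing tree: likelihood, ML fitting, and G² tests.

The CNI model decomposes binary moral-dilemma judgments into three latent
processes, evaluated in a fixed order.  With probability C the response is
driven by *consequences* (act iff benefits exceed costs); otherwise, with
probability N, by the moral *norm* (act iff the norm prescribes action);
otherwise a general *inaction* preference applies (do not act with
probability I).  For the four design cells, ordered canonically as

    1. proscriptive norm, benefits > costs
    2. proscriptive norm, benefits < costs
    3. prescriptive norm, benefits > costs
    4. prescriptive norm, benefits < costs

the action probabilities are::

    p1 = C + (1-C)(1-N)(1-I)
    p2 =     (1-C)(1-N)(1-I)
    p3 = C + (1-C)N + (1-C)(1-N)(1-I)
    p4 =     (1-C)N + (1-C)(1-N)(1-I)

Counts are pooled over participants within a group (the convention of
aggregate MPT software), giving a product-binomial likelihood over the
four cells per group.  Fitting maximizes that likelihood by bounded
quasi-Newton with multiple starts; inference uses the likelihood-ratio
statistic G² against the saturated model and ΔG² between nested models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .io_types import Consequences, Norm, ResponseDataset, ValidationError

__all__ = [
    "PARAM_NAMES",
    "CELL_ORDER",
    "CniParams",
    "CniCounts",
    "CniFit",
    "NestedModelTest",
    "FixParameter",
    "EqualAcrossGroups",
    "FitError",
    "category_probabilities",
    "category_jacobian",
    "aggregate_counts",
    "moment_inversion",
    "fit_ml",
    "test_parameter_reference",
    "test_group_equality",
]

PARAM_NAMES = ("C", "N", "I")

#: Canonical (norm, consequences) order used for every 4-vector in this module.
CELL_ORDER: tuple[tuple[Norm, Consequences], ...] = (
    (Norm.PROSCRIPTIVE, Consequences.BENEFITS_EXCEED_COSTS),
    (Norm.PROSCRIPTIVE, Consequences.COSTS_EXCEED_BENEFITS),
    (Norm.PRESCRIPTIVE, Consequences.BENEFITS_EXCEED_COSTS),
    (Norm.PRESCRIPTIVE, Consequences.COSTS_EXCEED_BENEFITS),
)

_EPS = 1e-12
_BOUNDARY_TOL = 1e-4


class FitError(RuntimeError):
    """Raised when the optimizer fails to converge from every start."""


@dataclass(frozen=True)
class CniParams:
    """The three CNI process probabilities, each in [0, 1]."""

    C: float
    N: float
    I: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name}={v} outside [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.C, self.N, self.I], dtype=float)


@dataclass
class CniCounts:
    """Pooled action/inaction counts for the 4 design cells of one group.

    ``n_action[k]`` / ``n_inaction[k]`` follow :data:`CELL_ORDER`.  Counts
    may be non-integral (e.g. expected counts used for exact-recovery
    checks); the product-binomial likelihood does not require integers.
    """

    n_action: np.ndarray
    n_inaction: np.ndarray
    group: str = "all"

    def __post_init__(self):
        self.n_action = np.asarray(self.n_action, dtype=float)
        self.n_inaction = np.asarray(self.n_inaction, dtype=float)
        if self.n_action.shape != (4,) or self.n_inaction.shape != (4,):
            raise ValueError("counts must have one entry per design cell (4)")
        if (self.n_action < 0).any() or (self.n_inaction < 0).any():
            raise ValueError("negative counts")

    @property
    def totals(self) -> np.ndarray:
        return self.n_action + self.n_inaction

    def proportions(self) -> np.ndarray:
        totals = self.totals
        if (totals <= 0).any():
            raise ValueError(f"group {self.group!r}: empty design cell")
        return self.n_action / totals


def category_probabilities(params: CniParams | Sequence[float]) -> np.ndarray:
    """Action probability in each of the 4 cells (canonical order)."""
    if isinstance(params, CniParams):
        c, n, i = params.C, params.N, params.I
    else:
        c, n, i = params
        if not all(0.0 <= v <= 1.0 for v in (c, n, i)):
            raise ValueError("parameters must lie in [0, 1]")
    q = (1 - c) * (1 - n) * (1 - i)  # neither process drives and no inaction
    p = np.array([c + q, q, c + (1 - c) * n + q, (1 - c) * n + q])
    return np.clip(p, 0.0, 1.0)  # guard float roundoff at the boundary


def category_jacobian(theta: Sequence[float]) -> np.ndarray:
    """4x3 matrix of d(cell probability)/d(C, N, I)."""
    c, n, i = theta
    dq = np.array([-(1 - n) * (1 - i), -(1 - c) * (1 - i), -(1 - c) * (1 - n)])
    jac = np.tile(dq, (4, 1))
    jac[0] += np.array([1.0, 0.0, 0.0])
    jac[2] += np.array([1.0 - n, 1.0 - c, 0.0])
    jac[3] += np.array([-n, 1.0 - c, 0.0])
    return jac


def aggregate_counts(
    dataset: ResponseDataset,
    grouping: Mapping[str, str] | None = None,
) -> list[CniCounts]:
    """Pool responses into per-group 4x2 count tables (sufficient statistic).

    ``grouping`` maps participant_id to a group label; ``None`` pools
    everyone into a single group ``"all"``.  Cell totals may differ when
    responses are missing.
    """
    frame = dataset.to_frame()
    if grouping is None:
        groups = {"all": {p.participant_id for p in dataset.participants}}
    else:
        groups: dict[str, set[str]] = {}
        for pid, g in grouping.items():
            groups.setdefault(str(g), set()).add(pid)
    cell_index = {
        (norm.value, cons.value): k for k, (norm, cons) in enumerate(CELL_ORDER)
    }
    out = []
    for label in sorted(groups):
        sub = frame[frame["participant_id"].isin(groups[label])]
        if sub.empty:
            raise ValidationError(f"group {label!r} has no responses")
        n_action = np.zeros(4)
        n_inaction = np.zeros(4)
        agg = sub.groupby(["norm", "consequences"])["response"].agg(["sum", "count"])
        for (norm, cons), row in agg.iterrows():
            k = cell_index[(norm, cons)]
            n_action[k] = row["sum"]
            n_inaction[k] = row["count"] - row["sum"]
        out.append(CniCounts(n_action, n_inaction, group=label))
    return out


@dataclass
class MomentInversionResult:
    params: CniParams
    in_range: bool
    raw: tuple[float, float, float]


def moment_inversion(proportions: Sequence[float]) -> MomentInversionResult:
    """Solve the tree equations for (C, N, I) from the 4 cell proportions.

    Exact on model-consistent proportions; used as an analytic oracle and as
    a fitting initializer.  Out-of-range or near-singular solutions (C or N
    close to 1) are clipped and flagged so callers fall back to ML.
    """
    p1, p2, p3, p4 = (float(p) for p in proportions)
    if not all(0.0 <= p <= 1.0 for p in (p1, p2, p3, p4)):
        raise ValueError("proportions must lie in [0, 1]")
    c = p1 - p2
    in_range = 0.0 <= c <= 1.0
    if 1.0 - c < 1e-9:
        n_raw = math.nan
        i_raw = math.nan
        in_range = False
    else:
        n_raw = (p3 - p1) / (1.0 - c)
        if 1.0 - n_raw < 1e-9:
            i_raw = math.nan
            in_range = False
        else:
            i_raw = 1.0 - p2 / ((1.0 - c) * (1.0 - n_raw))
    raw = (c, n_raw, i_raw)
    clipped = tuple(
        0.5 if math.isnan(v) else min(1.0, max(0.0, v)) for v in raw
    )
    in_range = in_range and all(
        not math.isnan(v) and 0.0 <= v <= 1.0 for v in raw
    )
    return MomentInversionResult(CniParams(*clipped), in_range, raw)


# ---------------------------------------------------------------------------
# Constraints and free-parameter mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixParameter:
    """Fix one parameter to a value, in one group or (group=None) all groups."""

    parameter: str
    value: float
    group: str | None = None

    def __post_init__(self):
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"reference value {self.value} outside [0, 1]")


@dataclass(frozen=True)
class EqualAcrossGroups:
    """Constrain one parameter to a common value across all groups."""

    parameter: str

    def __post_init__(self):
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")


class _ParamMap:
    """Maps the free-parameter vector x to the full per-group theta matrix."""

    def __init__(self, groups: Sequence[str], constraints: Sequence):
        self.groups = list(groups)
        G = len(self.groups)
        fixed = np.full((G, 3), np.nan)
        shared = [False] * 3
        for con in constraints:
            j = PARAM_NAMES.index(con.parameter)
            if isinstance(con, FixParameter):
                if con.group is None:
                    fixed[:, j] = con.value
                else:
                    fixed[self.groups.index(con.group), j] = con.value
            elif isinstance(con, EqualAcrossGroups):
                shared[j] = True
            else:
                raise TypeError(f"unknown constraint {con!r}")
        # assign a free-vector index to every non-fixed slot
        self.index = np.full((G, 3), -1, dtype=int)
        self.fixed = fixed
        labels: list[str] = []
        k = 0
        for j in range(3):
            if shared[j]:
                if np.isnan(fixed[:, j]).any():
                    for g in range(G):
                        if np.isnan(fixed[g, j]):
                            self.index[g, j] = k
                    labels.append(PARAM_NAMES[j])
                    k += 1
            else:
                for g in range(G):
                    if np.isnan(fixed[g, j]):
                        self.index[g, j] = k
                        labels.append(
                            PARAM_NAMES[j] if G == 1
                            else f"{PARAM_NAMES[j]}[{self.groups[g]}]"
                        )
                        k += 1
        self.n_free = k
        self.labels = labels

    def theta(self, x: np.ndarray) -> np.ndarray:
        G = len(self.groups)
        th = self.fixed.copy()
        for g in range(G):
            for j in range(3):
                if self.index[g, j] >= 0:
                    th[g, j] = x[self.index[g, j]]
        return th

    def x_from_theta(self, theta: np.ndarray) -> np.ndarray:
        x = np.empty(self.n_free)
        for g in range(len(self.groups)):
            for j in range(3):
                if self.index[g, j] >= 0:
                    x[self.index[g, j]] = theta[g, j]
        return x


# ---------------------------------------------------------------------------
# Likelihood, fitting, inference
# ---------------------------------------------------------------------------


def _group_loglik_grad(theta_g: np.ndarray, counts: CniCounts):
    p = category_probabilities(tuple(theta_g))
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    a, b = counts.n_action, counts.n_inaction
    ll = float(a @ np.log(pc) + b @ np.log1p(-pc))
    w = a / pc - b / (1.0 - pc)
    grad = category_jacobian(theta_g).T @ w
    return ll, grad


def _loglik(x: np.ndarray, pmap: _ParamMap, counts_list: Sequence[CniCounts]):
    theta = pmap.theta(x)
    ll = 0.0
    grad = np.zeros(pmap.n_free)
    for g, counts in enumerate(counts_list):
        ll_g, grad_g = _group_loglik_grad(theta[g], counts)
        ll += ll_g
        for j in range(3):
            k = pmap.index[g, j]
            if k >= 0:
                grad[k] += grad_g[j]
    return ll, grad


def _saturated_loglik(counts_list: Sequence[CniCounts]) -> float:
    ll = 0.0
    for counts in counts_list:
        t = counts.totals
        for obs in (counts.n_action, counts.n_inaction):
            mask = obs > 0
            ll += float(obs[mask] @ np.log(obs[mask] / t[mask]))
    return ll


@dataclass
class CniFit:
    """Result of one (possibly constrained) multi-group CNI fit."""

    params: dict[str, CniParams]
    loglik: float
    g2: float
    df: int
    p_value: float
    se: dict[str, dict[str, float | None]]
    ci95: dict[str, dict[str, tuple[float, float] | None]]
    constraints: tuple
    n_free: int
    converged: bool
    boundary: bool
    groups: tuple[str, ...] = ()
    counts: list[CniCounts] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "params": {g: {n: getattr(p, n) for n in PARAM_NAMES}
                       for g, p in self.params.items()},
            "loglik": self.loglik,
            "G2": self.g2,
            "df": self.df,
            "p_value": self.p_value,
            "se": self.se,
            "ci95": self.ci95,
            "n_free_parameters": self.n_free,
            "boundary": self.boundary,
        }


def _hessian(x_hat, pmap, counts_list, step=1e-5):
    """Observed information: central finite differences of the analytic
    score, with one-sided steps at the box boundary."""
    k = len(x_hat)
    H = np.zeros((k, k))
    for j in range(k):
        hi = min(x_hat[j] + step, 1.0)
        lo = max(x_hat[j] - step, 0.0)
        xp = x_hat.copy(); xp[j] = hi
        xm = x_hat.copy(); xm[j] = lo
        _, gp = _loglik(xp, pmap, counts_list)
        _, gm = _loglik(xm, pmap, counts_list)
        H[j] = -(gp - gm) / (hi - lo)
    return 0.5 * (H + H.T)


def _profile_ci(x_hat, ll_hat, pmap, counts_list, free_idx, level=0.95):
    """Profile-likelihood CI: invert ΔG² = chi2(1) quantile by bisection."""
    crit = stats.chi2.ppf(level, 1) / 2.0  # on the loglik scale

    def profile(v):
        sub = [c for c in range(pmap.n_free) if c != free_idx]

        def negll(xs):
            x = np.empty(pmap.n_free)
            x[free_idx] = v
            x[sub] = xs
            ll, grad = _loglik(x, pmap, counts_list)
            return -ll, -grad[sub]

        if not sub:
            ll, _ = _loglik(np.array([v]), pmap, counts_list)
            return ll
        x0 = x_hat[sub]
        res = optimize.minimize(negll, x0, jac=True, method="L-BFGS-B",
                                bounds=[(0.0, 1.0)] * len(sub))
        return -res.fun

    def solve(lo, hi, target_at_hi):
        # profile(hi side) crosses ll_hat - crit between lo and hi
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if profile(mid) > ll_hat - crit:
                lo, hi = (mid, hi) if target_at_hi else (lo, mid)
            else:
                lo, hi = (lo, mid) if target_at_hi else (mid, hi)
        return 0.5 * (lo + hi)

    v_hat = x_hat[free_idx]
    lo = 0.0 if profile(0.0) > ll_hat - crit else solve(0.0, v_hat, target_at_hi=False)
    hi = 1.0 if profile(1.0) > ll_hat - crit else solve(v_hat, 1.0, target_at_hi=True)
    return lo, hi


def fit_ml(
    counts: CniCounts | Sequence[CniCounts],
    constraints: Sequence = (),
    *,
    n_restarts: int = 10,
    seed: int = 0,
    profile_ci: bool = False,
    tol: float = 1e-10,
) -> CniFit:
    """Maximum-likelihood CNI fit on pooled counts, optionally constrained.

    Maximizes the product-binomial log-likelihood over the free parameters
    in [0,1] with L-BFGS-B, starting from the moment-inversion solution plus
    ``n_restarts`` random starts.  Returns estimates, G² against the
    saturated model (df = 4·n_groups − n_free), and Wald 95% CIs from the
    observed information (profile-likelihood CIs when ``profile_ci``).
    """
    counts_list = [counts] if isinstance(counts, CniCounts) else list(counts)
    if not counts_list:
        raise ValueError("no count tables supplied")
    for c in counts_list:
        if (c.totals <= 0).any():
            raise ValidationError(f"group {c.group!r}: empty design cell")
    groups = [c.group for c in counts_list]
    if len(set(groups)) != len(groups):
        raise ValueError("duplicate group labels")
    pmap = _ParamMap(groups, constraints)

    def negll(x):
        ll, grad = _loglik(x, pmap, counts_list)
        return -ll, -grad

    starts: list[np.ndarray] = []
    if pmap.n_free:
        theta0 = np.empty((len(groups), 3))
        for g, c in enumerate(counts_list):
            theta0[g] = moment_inversion(c.proportions()).params.as_array()
        starts.append(np.clip(pmap.x_from_theta(theta0), 0.02, 0.98))
        rng = np.random.default_rng(seed)
        starts.extend(rng.uniform(0.02, 0.98, size=(n_restarts, pmap.n_free)))

    best = None
    any_success = False
    bounds = [(0.0, 1.0)] * pmap.n_free
    for x0 in starts:
        res = optimize.minimize(
            negll, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        any_success = any_success or res.success
        if best is None or res.fun < best.fun:
            best = res
    if pmap.n_free == 0:
        x_hat = np.empty(0)
        ll_hat, _ = _loglik(x_hat, pmap, counts_list)
        converged = True
    else:
        if best is None or not any_success:
            raise FitError("optimizer failed to converge from every start")
        x_hat = best.x
        ll_hat = -best.fun
        converged = True

    theta_hat = pmap.theta(x_hat)
    g2 = max(0.0, 2.0 * (_saturated_loglik(counts_list) - ll_hat))
    df = 4 * len(groups) - pmap.n_free
    p_value = float(stats.chi2.sf(g2, df)) if df > 0 else math.nan
    boundary = bool(
        pmap.n_free
        and ((x_hat < _BOUNDARY_TOL) | (x_hat > 1.0 - _BOUNDARY_TOL)).any()
    )

    se_x = np.full(pmap.n_free, np.nan)
    if pmap.n_free:
        H = _hessian(x_hat, pmap, counts_list)
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            se_x = np.where(d > 0, np.sqrt(np.maximum(d, 0.0)), np.nan)
        except np.linalg.LinAlgError:
            pass

    z = stats.norm.ppf(0.975)
    se: dict[str, dict] = {}
    ci95: dict[str, dict] = {}
    params: dict[str, CniParams] = {}
    for g, label in enumerate(groups):
        vals = np.clip(theta_hat[g], 0.0, 1.0)
        params[label] = CniParams(*vals)
        se[label] = {}
        ci95[label] = {}
        for j, name in enumerate(PARAM_NAMES):
            k = pmap.index[g, j]
            if k < 0:
                se[label][name] = None
                ci95[label][name] = None
            else:
                if profile_ci:
                    lo, hi = _profile_ci(x_hat, ll_hat, pmap, counts_list, k)
                    se[label][name] = float(se_x[k]) if np.isfinite(se_x[k]) else None
                else:
                    s = se_x[k]
                    se[label][name] = float(s) if np.isfinite(s) else None
                    lo = vals[j] - z * s if np.isfinite(s) else math.nan
                    hi = vals[j] + z * s if np.isfinite(s) else math.nan
                ci95[label][name] = (
                    float(max(0.0, lo)), float(min(1.0, hi))
                ) if math.isfinite(lo) and math.isfinite(hi) else None

    return CniFit(
        params=params, loglik=ll_hat, g2=g2, df=df, p_value=p_value,
        se=se, ci95=ci95, constraints=tuple(constraints),
        n_free=pmap.n_free, converged=converged, boundary=boundary,
        groups=tuple(groups), counts=counts_list,
    )


@dataclass
class NestedModelTest:
    """ΔG² likelihood-ratio test between nested CNI fits."""

    parameter: str
    statistic: float
    df: int
    p_value: float
    fit_unconstrained: CniFit
    fit_constrained: CniFit
    description: str = ""

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "delta_G2": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "description": self.description,
        }


def _nested_test(fit_free: CniFit, fit_con: CniFit, parameter: str,
                 description: str) -> NestedModelTest:
    df = fit_free.n_free - fit_con.n_free
    if df <= 0:
        raise ValueError("constrained model is not nested with fewer parameters")
    delta = max(0.0, fit_con.g2 - fit_free.g2)
    return NestedModelTest(
        parameter=parameter, statistic=delta, df=df,
        p_value=float(stats.chi2.sf(delta, df)),
        fit_unconstrained=fit_free, fit_constrained=fit_con,
        description=description,
    )


def test_parameter_reference(
    counts: CniCounts | Sequence[CniCounts],
    parameter: str,
    reference: float,
    *,
    fit_free: CniFit | None = None,
    **fit_kwargs,
) -> NestedModelTest:
    """Test one parameter against a reference value (e.g. C vs 0, I vs 0.5).

    ΔG² = G²(parameter fixed at the reference in every group) − G²(free);
    df = number of parameters removed, one per group.
    """
    counts_list = [counts] if isinstance(counts, CniCounts) else list(counts)
    if fit_free is None:
        fit_free = fit_ml(counts_list, **fit_kwargs)
    fit_con = fit_ml(
        counts_list,
        list(fit_free.constraints) + [FixParameter(parameter, reference)],
        **fit_kwargs,
    )
    return _nested_test(
        fit_free, fit_con, parameter,
        f"{parameter} vs reference {reference}",
    )


def test_group_equality(
    counts: Sequence[CniCounts],
    parameter: str,
    *,
    fit_free: CniFit | None = None,
    **fit_kwargs,
) -> NestedModelTest:
    """Test whether one parameter is equal across two groups (df = 1)."""
    counts_list = list(counts)
    if len(counts_list) != 2:
        raise ValueError("group-equality test requires exactly two groups")
    if fit_free is None:
        fit_free = fit_ml(counts_list, **fit_kwargs)
    fit_con = fit_ml(
        counts_list,
        list(fit_free.constraints) + [EqualAcrossGroups(parameter)],
        **fit_kwargs,
    )
    return _nested_test(
        fit_free, fit_con, parameter,
        f"{parameter} equal across groups "
        f"({counts_list[0].group} vs {counts_list[1].group})",
    )
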