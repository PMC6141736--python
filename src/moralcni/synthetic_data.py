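"""Synthetic study generator with CNI-governed responses and ground truth.

No raw data from the chronic-stress moral-judgment study were deposited, so
analyses run on simulated datasets that emulate its design: ~197
undergraduates aged 18–22 (mean 19.49, SD 0.83), about 34.5% male,
10-item Perceived Stress Scale totals with mean 26.51, SD 5.33 and
item-level Cronbach's α near 0.80, each judging a 24-item dilemma battery.

Binary responses are generated from per-participant CNI parameters.  Each
participant i receives (C_i, N_i, I_i) on the logit scale::

    logit(P_i) = logit(P0) + beta_P · z_i + eps_i,   eps_i ~ N(0, sd_between)

where z_i is the participant's standardized stress score, so a positive
``beta_I`` makes higher chronic stress raise the general inaction
preference — the qualitative mechanism the analysis is designed to detect.
Baseline parameters default to the pooled estimates the analysis itself
produces on real data of this kind (C0=0.131, N0=0.145, I0=0.451); the
stress effect sizes are illustrative, since no generative values exist to
anchor them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cni_model import CELL_ORDER, CniCounts, CniParams, category_probabilities
from .io_types import (
    Consequences,
    DilemmaItem,
    Norm,
    Participant,
    ResponseDataset,
    ResponseRecord,
)

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "SimulatedStudy",
    "default_battery",
    "generate_participants",
    "realize_parameters",
    "generate_responses",
    "generate_study",
    "simulate_model_true_counts",
]

_BASE_DILEMMAS = (
    "transplant", "torture", "abduction", "immune_deficiency",
    "border_control", "assisted_suicide",
)

_PSS_ITEMS = 10


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study; defaults are the emulated design."""

    n_participants: int = 197
    seed: int = 0
    age_mean: float = 19.49
    age_sd: float = 0.83
    age_min: int = 18
    age_max: int = 22
    prop_male: float = 0.345
    pss_mean: float = 26.51
    pss_sd: float = 5.33
    pss_item_level: bool = True
    target_alpha: float = 0.80
    C0: float = 0.131
    N0: float = 0.145
    I0: float = 0.451
    beta_C: float = 0.0
    beta_N: float = 0.0
    beta_I: float = 0.2
    between_subject_sd: float = 0.3

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name in ("prop_male", "target_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        for name in ("age_sd", "pss_sd", "between_subject_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("C0", "N0", "I0"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(
                    f"{name}={v} must lie strictly in (0, 1): the logit link "
                    "is undefined at the boundary"
                )

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Per-participant generating state, for parameter-recovery checks."""

    participant_ids: list[str]
    stress_z: np.ndarray
    C: np.ndarray
    N: np.ndarray
    I: np.ndarray
    group: list[str]  # "high"/"low" after a median split on stress

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "stress_z": self.stress_z,
                "C": self.C,
                "N": self.N,
                "I": self.I,
                "group": self.group,
            }
        )


@dataclass
class SimulatedStudy:
    dataset: ResponseDataset
    truth: GroundTruth
    config: GeneratorConfig


def default_battery() -> list[DilemmaItem]:
    """The 24-item full-factorial battery (6 base dilemmas x 2 x 2).

    Item texts are not modeled; items carry placeholder labels and the
    design-cell metadata that the models operate on.
    """
    items = []
    for base in _BASE_DILEMMAS:
        for norm in Norm:
            for cons in Consequences:
                norm_tag = "pro" if norm is Norm.PROSCRIPTIVE else "pre"
                cons_tag = "bgc" if cons is Consequences.BENEFITS_EXCEED_COSTS else "cgb"
                items.append(
                    DilemmaItem(
                        item_id=f"{base}_{norm_tag}_{cons_tag}",
                        base_dilemma=base,
                        norm=norm,
                        consequences=cons,
                    )
                )
    return items


def _truncated_rounded_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Rejection-sample a normal, round, keep values landing in [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = np.round(rng.normal(mean, sd, size=2 * (size - filled)))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out.astype(int)


def _discretized_moments(m: float, sigma: float):
    """Mean, variance, and location sensitivity of clip(round(N(m, σ)), 0, 4).

    The sensitivity dE/dm linearizes how the observed item mean moves with
    a latent location shift; it attenuates latent covariances after
    discretization.
    """
    from scipy.stats import norm

    edges = np.array([-np.inf, 0.5, 1.5, 2.5, 3.5, np.inf])
    cats = np.arange(5.0)
    cdf = norm.cdf((edges - m) / sigma)
    probs = np.diff(cdf)
    mean = float(cats @ probs)
    var = float((cats - mean) ** 2 @ probs)
    pdf_inner = norm.pdf((edges[1:-1] - m) / sigma) / sigma
    # dP(c)/dm telescopes to pdf differences; dE/dm = sum over inner edges
    sens = float(np.sum(pdf_inner))  # = Σ_c c·(pdf_{c-1/2} − pdf_{c+1/2})
    return mean, var, sens


def _pss_item_model(config: GeneratorConfig):
    """Latent mean, loading, and residual SD of the one-factor PSS model.

    Items are Gaussian with a shared factor, then rounded and clipped to
    the 0–4 scale.  The latent moments are calibrated by fixed-point
    iteration against the exact discretized-normal moments so that the
    *observed* items hit the target total mean, total SD, and expected
    Cronbach's α (inter-item correlations are attenuated by the squared
    location sensitivity of the discretization).
    """
    k = _PSS_ITEMS
    a = config.target_alpha
    rho = a / (k - a * (k - 1))          # target observed inter-item correlation
    var_target = config.pss_sd**2 / (k * (1 + (k - 1) * rho))
    mean_target = config.pss_mean / k

    m = mean_target
    sigma = float(np.sqrt(var_target))
    lam2 = rho * var_target
    for _ in range(40):
        mean_d, var_d, sens = _discretized_moments(m, sigma)
        m += (mean_target - mean_d) / max(sens, 1e-6)
        sigma *= float(np.sqrt(max(var_target, 1e-9) / max(var_d, 1e-9)))
        lam2 = rho * var_d / max(sens, 1e-6) ** 2   # cov_obs ≈ sens²·λ²
    lam2 = min(lam2, 0.95 * sigma**2)
    resid_var = sigma**2 - lam2
    return float(m), float(np.sqrt(lam2)), float(np.sqrt(resid_var))


def generate_participants(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[Participant], np.ndarray]:
    """Draw the participant table; returns it with the stress z-scores.

    Ages are rounded truncated normals on [age_min, age_max]; gender is
    Bernoulli(prop_male) coded 1 = male.  PSS data are either rounded
    truncated-normal totals on [0, 40] or, with ``pss_item_level``, ten
    one-factor item scores clipped to 0..4 whose sum is the total.
    The returned z-scores standardize the totals within the sample.
    """
    n = config.n_participants
    ids = [f"p{i + 1:04d}" for i in range(n)]
    ages = _truncated_rounded_normal(
        rng, config.age_mean, config.age_sd, config.age_min, config.age_max, n
    )
    genders = (rng.random(n) < config.prop_male).astype(int)
    if config.pss_item_level:
        item_mean, lam, resid_sd = _pss_item_model(config)
        factor = rng.normal(size=(n, 1))
        raw = (
            item_mean
            + lam * factor
            + resid_sd * rng.normal(size=(n, _PSS_ITEMS))
        )
        items = np.clip(np.round(raw), 0, 4).astype(int)
        totals = items.sum(axis=1)
    else:
        items = None
        totals = _truncated_rounded_normal(
            rng, config.pss_mean, config.pss_sd, 0, 40, n
        )
    participants = [
        Participant(
            participant_id=ids[i],
            age=int(ages[i]),
            gender=int(genders[i]),
            pss_total=int(totals[i]),
            pss_items=tuple(int(v) for v in items[i]) if items is not None else None,
        )
        for i in range(n)
    ]
    sd = totals.std(ddof=1)
    z = (totals - totals.mean()) / sd if sd > 0 else np.zeros(n)
    return participants, z


def realize_parameters(
    stress_z: np.ndarray,
    config: GeneratorConfig,
    rng: np.random.Generator,
    participant_ids: Sequence[str] | None = None,
) -> GroundTruth:
    """Per-participant (C_i, N_i, I_i) via the logit stress link."""
    z = np.asarray(stress_z, dtype=float)
    n = z.size
    if participant_ids is None:
        participant_ids = [f"p{i + 1:04d}" for i in range(n)]
    realized = {}
    for name, base, beta in (
        ("C", config.C0, config.beta_C),
        ("N", config.N0, config.beta_N),
        ("I", config.I0, config.beta_I),
    ):
        eps = rng.normal(0.0, config.between_subject_sd, size=n)
        realized[name] = expit(logit(base) + beta * z + eps)
    med = np.median(z)
    group = ["high" if v > med else "low" for v in z]
    return GroundTruth(
        participant_ids=list(participant_ids),
        stress_z=z,
        C=realized["C"],
        N=realized["N"],
        I=realized["I"],
        group=group,
    )


def generate_responses(
    battery: Sequence[DilemmaItem],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[ResponseRecord]:
    """Independent Bernoulli judgments from each participant's CNI tree."""
    cell_index = {
        (norm, cons): k for k, (norm, cons) in enumerate(CELL_ORDER)
    }
    records = []
    for i, pid in enumerate(truth.participant_ids):
        probs = category_probabilities((truth.C[i], truth.N[i], truth.I[i]))
        for item in battery:
            p = probs[cell_index[item.cell]]
            records.append(
                ResponseRecord(pid, item.item_id, int(rng.random() < p))
            )
    return records


def generate_study(
    config: GeneratorConfig,
    battery: Sequence[DilemmaItem] | None = None,
) -> SimulatedStudy:
    """Full reproducible simulated study (same seed ⇒ identical dataset)."""
    rng = np.random.default_rng(config.seed)
    battery = list(battery) if battery is not None else default_battery()
    participants, z = generate_participants(config, rng)
    truth = realize_parameters(
        z, config, rng, [p.participant_id for p in participants]
    )
    responses = generate_responses(battery, truth, rng)
    return SimulatedStudy(
        dataset=ResponseDataset(battery, participants, responses),
        truth=truth,
        config=config,
    )


def simulate_model_true_counts(
    params: CniParams,
    n_participants: int,
    rng: np.random.Generator,
    *,
    responses_per_cell: int = 6,
    group: str = "all",
) -> CniCounts:
    """Pooled counts drawn exactly from the CNI category probabilities.

    This is the model-true regime (no between-participant heterogeneity):
    each cell total is ``n_participants * responses_per_cell`` and actions
    are binomial at the analytic probabilities.  Used for calibration and
    recovery studies.
    """
    probs = category_probabilities(params)
    totals = np.full(4, n_participants * responses_per_cell)
    actions = rng.binomial(totals, probs)
    return CniCounts(actions.astype(float), (totals - actions).astype(float), group=group)
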