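"""Process-dissociation (PD) decomposition of moral-dilemma judgments.

PD separates utilitarian (U) and deontological (D) response inclinations
using only the proscriptive-norm dilemmas.  Dilemmas where the action's
benefits exceed its costs pit the two principles against each other
(*incongruent*); dilemmas where costs exceed benefits align them
(*congruent*).  From each participant's proportions of "unacceptable"
judgments the parameters follow algebraically::

    U = p_unacc(congruent) - p_unacc(incongruent)
    D = p_unacc(incongruent) / (1 - U)        (undefined when U = 1)

so that p_unacc(congruent) = U + (1-U)·D and p_unacc(incongruent) = (1-U)·D.
U and D are z-standardized across participants before regression analyses.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io_types import Consequences, DilemmaItem, Norm, ResponseDataset

__all__ = ["Congruence", "PdScores", "classify_congruence", "pd_parameters",
           "score_participants"]


class Congruence(enum.Enum):
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"
    EXCLUDED = "excluded"


def classify_congruence(item: DilemmaItem) -> Congruence:
    """PD trial type of a battery item; prescriptive items are excluded."""
    if item.norm is not Norm.PROSCRIPTIVE:
        return Congruence.EXCLUDED
    if item.consequences is Consequences.BENEFITS_EXCEED_COSTS:
        return Congruence.INCONGRUENT
    return Congruence.CONGRUENT


def pd_parameters(p_unacc_cong: float, p_unacc_incong: float) -> tuple[float, float | None]:
    """(U, D) from the two unacceptability proportions; D is None at U = 1."""
    if not (0.0 <= p_unacc_cong <= 1.0 and 0.0 <= p_unacc_incong <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    u = p_unacc_cong - p_unacc_incong
    if u >= 1.0:
        return u, None
    return u, p_unacc_incong / (1.0 - u)


@dataclass
class PdScores:
    participant_id: str
    p_unacc_congruent: float
    p_unacc_incongruent: float
    U: float
    D: float | None
    U_z: float = math.nan
    D_z: float = math.nan

    @property
    def d_defined(self) -> bool:
        return self.D is not None


def score_participants(dataset: ResponseDataset) -> list[PdScores]:
    """Per-participant PD scores with z-standardized U and D columns.

    Unacceptability proportions are computed over each participant's
    congruent and incongruent items (6 of each in a complete battery).
    Participants lacking both trial types are excluded with a warning;
    participants with U = 1 keep an undefined D and are dropped pairwise
    from the D standardization pool (D values outside [0, 1] that arise
    from sampling noise are retained, not clipped).
    """
    congruence = {it.item_id: classify_congruence(it) for it in dataset.battery}
    frame = dataset.to_frame().copy()
    frame["trial"] = frame["item_id"].map(lambda i: congruence[i].value)
    frame = frame[frame["trial"] != Congruence.EXCLUDED.value]
    acc = (
        frame.groupby(["participant_id", "trial"])["response"].mean().unstack()
    )
    scores: list[PdScores] = []
    for p in dataset.participants:
        pid = p.participant_id
        row = acc.loc[pid] if pid in acc.index else None
        if (
            row is None
            or "congruent" not in row or "incongruent" not in row
            or math.isnan(row.get("congruent", math.nan))
            or math.isnan(row.get("incongruent", math.nan))
        ):
            warnings.warn(
                f"participant {pid} lacks congruent and/or incongruent "
                "responses; excluded from PD scoring",
                stacklevel=2,
            )
            continue
        p_cong = 1.0 - float(row["congruent"])
        p_incong = 1.0 - float(row["incongruent"])
        u, d = pd_parameters(p_cong, p_incong)
        scores.append(PdScores(pid, p_cong, p_incong, u, d))

    if not scores:
        return scores
    u_vals = np.array([s.U for s in scores])
    d_vals = np.array([s.D for s in scores if s.d_defined])
    u_mean = u_vals.mean()
    u_sd = u_vals.std(ddof=1) if u_vals.size > 1 else math.nan
    d_mean = d_vals.mean() if d_vals.size else math.nan
    d_sd = d_vals.std(ddof=1) if d_vals.size > 1 else math.nan
    for s in scores:
        s.U_z = (s.U - u_mean) / u_sd if u_sd and u_sd > 0 else math.nan
        if s.d_defined and d_sd and d_sd > 0:
            s.D_z = (s.D - d_mean) / d_sd
    return scores
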