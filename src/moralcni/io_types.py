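"""Domain types, CSV readers/writers, and validation.

The data model mirrors a standard moral-dilemma battery design: 24 items
formed by crossing 6 base dilemmas with a norm factor (proscriptive norm
prohibiting action vs. prescriptive norm prescribing it) and a consequence
factor (benefits of action exceeding its costs or not).  Responses are
binary acceptability judgments (1 = action judged acceptable), and
participants carry age, gender, and Perceived Stress Scale (PSS) data.

All tabular I/O is plain CSV (comma-separated, UTF-8, header required).
Every malformed input raises :class:`ValidationError`; readers never return
a partially validated dataset.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ValidationError",
    "Norm",
    "Consequences",
    "DilemmaItem",
    "Participant",
    "ResponseRecord",
    "ResponseDataset",
    "read_battery",
    "write_battery",
    "read_participants",
    "write_participants",
    "read_responses",
    "write_responses",
    "write_report",
    "read_report",
    "render_text_report",
]


class ValidationError(ValueError):
    """Raised for any malformed battery, participant, or response input.

    Carries an optional ``details`` mapping (e.g. the offending design cell
    or CSV row number) for structured error handling.
    """

    def __init__(self, message: str, **details):
        super().__init__(message)
        self.details = details


class Norm(enum.Enum):
    PROSCRIPTIVE = "proscriptive"
    PRESCRIPTIVE = "prescriptive"


class Consequences(enum.Enum):
    BENEFITS_EXCEED_COSTS = "benefits_exceed_costs"
    COSTS_EXCEED_BENEFITS = "costs_exceed_benefits"


def _parse_enum(cls, value, *, column: str, row: int):
    try:
        return cls(str(value).strip().lower())
    except ValueError:
        allowed = ", ".join(m.value for m in cls)
        raise ValidationError(
            f"unknown {column} value {value!r} in row {row} (allowed: {allowed})",
            column=column,
            row=row,
            value=value,
        ) from None


@dataclass(frozen=True)
class DilemmaItem:
    """One battery item, identified by its design cell, not its text."""

    item_id: str
    base_dilemma: str
    norm: Norm
    consequences: Consequences

    @property
    def cell(self) -> tuple[Norm, Consequences]:
        return (self.norm, self.consequences)


@dataclass(frozen=True)
class Participant:
    """A participant with demographics and PSS stress data.

    Gender is coded 1 = male, 0 = female.  ``pss_items`` holds the ten
    0-4 Likert item scores when item-level data exist; ``pss_total`` is
    always the 0-40 summed stress score.
    """

    participant_id: str
    age: int
    gender: int
    pss_total: int
    pss_items: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.age < 0:
            raise ValidationError(f"participant {self.participant_id}: negative age")
        if self.gender not in (0, 1):
            raise ValidationError(
                f"participant {self.participant_id}: gender must be 0 or 1"
            )
        if not 0 <= self.pss_total <= 40:
            raise ValidationError(
                f"participant {self.participant_id}: PSS total {self.pss_total} outside 0..40"
            )
        if self.pss_items is not None:
            if len(self.pss_items) != 10:
                raise ValidationError(
                    f"participant {self.participant_id}: expected 10 PSS items"
                )
            if any(not 0 <= v <= 4 for v in self.pss_items):
                raise ValidationError(
                    f"participant {self.participant_id}: PSS item outside 0..4"
                )
            if sum(self.pss_items) != self.pss_total:
                raise ValidationError(
                    f"participant {self.participant_id}: PSS total "
                    f"{self.pss_total} != item sum {sum(self.pss_items)}"
                )


@dataclass(frozen=True)
class ResponseRecord:
    """One binary judgment: 1 = action judged acceptable ('yes'), 0 = 'no'."""

    participant_id: str
    item_id: str
    response: int

    def __post_init__(self):
        if self.response not in (0, 1):
            raise ValidationError(
                f"response for ({self.participant_id}, {self.item_id}) "
                f"must be 0 or 1, got {self.response}"
            )


@dataclass
class ResponseDataset:
    """Participants x items binary judgments joined to battery metadata."""

    battery: list[DilemmaItem]
    participants: list[Participant]
    responses: list[ResponseRecord]
    _frame: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    @property
    def items_by_id(self) -> dict[str, DilemmaItem]:
        return {it.item_id: it for it in self.battery}

    @property
    def participants_by_id(self) -> dict[str, Participant]:
        return {p.participant_id: p for p in self.participants}

    def completeness(self) -> dict[str, int]:
        """Number of answered items per participant."""
        counts = {p.participant_id: 0 for p in self.participants}
        for r in self.responses:
            counts[r.participant_id] += 1
        return counts

    @property
    def complete(self) -> bool:
        n_items = len(self.battery)
        return all(c == n_items for c in self.completeness().values())

    def to_frame(self) -> pd.DataFrame:
        """Long-format responses merged with item metadata (cached)."""
        if self._frame is None:
            items = pd.DataFrame(
                {
                    "item_id": [it.item_id for it in self.battery],
                    "norm": [it.norm.value for it in self.battery],
                    "consequences": [it.consequences.value for it in self.battery],
                }
            )
            resp = pd.DataFrame(
                {
                    "participant_id": [r.participant_id for r in self.responses],
                    "item_id": [r.item_id for r in self.responses],
                    "response": [r.response for r in self.responses],
                }
            )
            self._frame = resp.merge(items, on="item_id", how="left")
        return self._frame

    def participant_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": [p.participant_id for p in self.participants],
                "age": [p.age for p in self.participants],
                "gender": [p.gender for p in self.participants],
                "pss_total": [p.pss_total for p in self.participants],
            }
        )


# ---------------------------------------------------------------------------
# Battery I/O
# ---------------------------------------------------------------------------

_BATTERY_COLUMNS = ["item_id", "base_dilemma", "norm", "consequences"]


def _read_csv(path, required: Sequence[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        if isinstance(exc, FileNotFoundError):
            raise
        raise ValidationError(f"empty {what}", path=str(path)) from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{what} CSV missing required column(s): {', '.join(missing)}",
            missing=missing,
        )
    if df.empty:
        raise ValidationError(f"empty {what}", path=str(path))
    return df


def read_battery(path) -> list[DilemmaItem]:
    """Read and validate a 24-item dilemma battery CSV.

    The battery must contain exactly one item per (base dilemma x norm x
    consequences) combination: 24 items, 6 per (norm x consequences) cell.
    """
    df = _read_csv(path, _BATTERY_COLUMNS, "battery")
    items: list[DilemmaItem] = []
    seen_ids: set[str] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        item_id = str(row.item_id).strip()
        if item_id in seen_ids:
            raise ValidationError(f"duplicate item_id {item_id!r}", item_id=item_id)
        seen_ids.add(item_id)
        items.append(
            DilemmaItem(
                item_id=item_id,
                base_dilemma=str(row.base_dilemma).strip(),
                norm=_parse_enum(Norm, row.norm, column="norm", row=row_no),
                consequences=_parse_enum(
                    Consequences, row.consequences, column="consequences", row=row_no
                ),
            )
        )
    validate_battery(items)
    return items


def validate_battery(items: Sequence[DilemmaItem]) -> None:
    """Enforce the full-factorial battery design (6 items per cell)."""
    if not items:
        raise ValidationError("empty battery")
    combos: dict[tuple, list[str]] = {}
    for it in items:
        combos.setdefault((it.base_dilemma, it.norm, it.consequences), []).append(
            it.item_id
        )
    dup = {k: v for k, v in combos.items() if len(v) > 1}
    if dup:
        (base, norm, cons), ids = next(iter(dup.items()))
        raise ValidationError(
            f"multiple items ({', '.join(ids)}) for combination "
            f"({base}, {norm.value}, {cons.value})"
        )
    for norm in Norm:
        for cons in Consequences:
            n = sum(1 for it in items if it.cell == (norm, cons))
            if n != 6:
                raise ValidationError(
                    f"design cell ({norm.value}, {cons.value}) has {n} items, expected 6",
                    cell=(norm.value, cons.value),
                    count=n,
                )
    bases = {it.base_dilemma for it in items}
    if len(bases) != 6:
        raise ValidationError(
            f"battery has {len(bases)} base dilemmas, expected 6", bases=sorted(bases)
        )


def write_battery(items: Sequence[DilemmaItem], path) -> None:
    pd.DataFrame(
        {
            "item_id": [it.item_id for it in items],
            "base_dilemma": [it.base_dilemma for it in items],
            "norm": [it.norm.value for it in items],
            "consequences": [it.consequences.value for it in items],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Participant I/O
# ---------------------------------------------------------------------------

_PSS_ITEM_COLS = [f"pss{i}" for i in range(1, 11)]


def read_participants(path, gender_map: Mapping[str, int] | None = None) -> list[Participant]:
    """Read the participant covariate table.

    Required columns: ``participant_id``, ``age``, ``gender``, and either
    ``pss_total`` or the ten item columns ``pss1..pss10`` (in which case the
    total is recomputed from the items).  ``gender_map`` optionally maps raw
    gender codes to the canonical 1 = male / 0 = female coding.
    """
    df = _read_csv(path, ["participant_id", "age", "gender"], "participant table")
    has_items = all(c in df.columns for c in _PSS_ITEM_COLS)
    if not has_items and "pss_total" not in df.columns:
        raise ValidationError(
            "participant table needs either pss_total or columns pss1..pss10"
        )
    out: list[Participant] = []
    seen: set[str] = set()
    for row_no, row in df.iterrows():
        pid = str(row["participant_id"]).strip()
        if pid in seen:
            raise ValidationError(f"duplicate participant_id {pid!r}")
        seen.add(pid)
        raw_gender = str(row["gender"]).strip()
        if gender_map is not None:
            if raw_gender not in gender_map:
                raise ValidationError(
                    f"participant {pid}: gender {raw_gender!r} not in gender_map"
                )
            gender = int(gender_map[raw_gender])
        else:
            try:
                gender = int(raw_gender)
            except ValueError:
                raise ValidationError(
                    f"participant {pid}: non-integer gender {raw_gender!r} "
                    "(supply gender_map for non 0/1 codings)"
                ) from None
        try:
            age = int(row["age"])
        except ValueError:
            raise ValidationError(f"participant {pid}: non-integer age") from None
        if has_items:
            try:
                items = tuple(int(row[c]) for c in _PSS_ITEM_COLS)
            except ValueError:
                raise ValidationError(f"participant {pid}: non-integer PSS item") from None
            total = sum(items)
        else:
            items = None
            try:
                total = int(row["pss_total"])
            except ValueError:
                raise ValidationError(f"participant {pid}: non-integer pss_total") from None
        out.append(
            Participant(
                participant_id=pid, age=age, gender=gender,
                pss_total=total, pss_items=items,
            )
        )
    return out


def write_participants(participants: Sequence[Participant], path) -> None:
    data: dict[str, list] = {
        "participant_id": [p.participant_id for p in participants],
        "age": [p.age for p in participants],
        "gender": [p.gender for p in participants],
        "pss_total": [p.pss_total for p in participants],
    }
    if all(p.pss_items is not None for p in participants):
        for j, col in enumerate(_PSS_ITEM_COLS):
            data[col] = [p.pss_items[j] for p in participants]  # type: ignore[index]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Response I/O
# ---------------------------------------------------------------------------


def read_responses(
    path,
    battery: Sequence[DilemmaItem],
    participants: Sequence[Participant],
) -> ResponseDataset:
    """Read long-format responses and cross-reference them.

    Missing responses are allowed (the dataset's ``complete`` flag reports
    them); orphan ids, duplicates, and non-binary responses are errors.
    """
    df = _read_csv(path, ["participant_id", "item_id", "response"], "response table")
    known_items = {it.item_id for it in battery}
    known_pids = {p.participant_id for p in participants}
    records: list[ResponseRecord] = []
    seen: set[tuple[str, str]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        pid = str(row.participant_id).strip()
        iid = str(row.item_id).strip()
        raw = str(row.response).strip()
        if raw not in ("0", "1"):
            raise ValidationError(
                f"row {row_no}: response must be 0 or 1, got {raw!r}", row=row_no
            )
        if pid not in known_pids:
            raise ValidationError(f"row {row_no}: unknown participant_id {pid!r}", row=row_no)
        if iid not in known_items:
            raise ValidationError(f"row {row_no}: unknown item_id {iid!r}", row=row_no)
        key = (pid, iid)
        if key in seen:
            raise ValidationError(
                f"row {row_no}: duplicate response for participant {pid!r}, item {iid!r}",
                row=row_no,
            )
        seen.add(key)
        records.append(ResponseRecord(pid, iid, int(raw)))
    return ResponseDataset(list(battery), list(participants), records)


def write_responses(dataset: ResponseDataset, path) -> None:
    pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in dataset.responses],
            "item_id": [r.item_id for r in dataset.responses],
            "response": [r.response for r in dataset.responses],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------


def _jsonable(obj):
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, float) and obj != obj:  # NaN -> null
        return None
    return obj


def write_report(results: Mapping, path) -> None:
    """Write pipeline results as JSON, plus a human-readable .txt sibling."""
    if not results:
        raise ValidationError("nothing to report")
    path = Path(path)
    payload = _jsonable(dict(results))
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    path.with_suffix(".txt").write_text(render_text_report(payload))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def _render(obj, indent: int, lines: list[str]) -> None:
    pad = "  " * indent
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}{k}:")
                _render(v, indent + 1, lines)
            else:
                lines.append(f"{pad}{k}: {v}")
    elif isinstance(obj, list):
        for v in obj:
            if isinstance(v, (dict, list)):
                lines.append(f"{pad}-")
                _render(v, indent + 1, lines)
            else:
                lines.append(f"{pad}- {v}")
    else:
        lines.append(f"{pad}{obj}")


def render_text_report(results: Mapping) -> str:
    lines: list[str] = ["Moral-judgment analysis report", "=" * 30]
    _render(dict(results), 0, lines)
    return "\n".join(lines) + "\n"
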