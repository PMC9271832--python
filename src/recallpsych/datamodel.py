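"""Shared data model and tabular I/O.

The canonical exchange format is a tidy long table with one row per
participant x visit x story x item x recall condition holding a binary
``correct`` score.  Wide 50-column layouts are converted on read.  Dates
are accepted as ISO-8601 or decimal years and carried internally as
decimal years, matching how visit-to-scan gaps are reported (in years).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("recallpsych")

__all__ = [
    "STORIES",
    "CONDITIONS",
    "N_ITEMS_PER_STORY",
    "RESPONSE_COLUMNS",
    "all_item_keys",
    "to_decimal_year",
    "read_responses",
    "write_responses",
    "read_participants",
    "write_participants",
    "classify_amyloid",
    "select_lm_visit",
    "validate_dataset",
    "ValidationReport",
]

STORIES = ("A", "B")
CONDITIONS = ("immediate", "delayed")
N_ITEMS_PER_STORY = 25

#: canonical column order of the long response table
RESPONSE_COLUMNS = ["participant_id", "visit", "visit_date", "story", "item", "condition", "correct"]

_KEY_COLUMNS = ["participant_id", "visit", "story", "item", "condition"]


def all_item_keys() -> list[tuple[str, int]]:
    """The 50 (story, index) idea-unit keys, story-major order."""
    return [(s, i) for s in STORIES for i in range(1, N_ITEMS_PER_STORY + 1)]


def to_decimal_year(value) -> float:
    """Convert an ISO-8601 date string, date object, or decimal year to a decimal year."""
    if isinstance(value, (int, float, np.integer, np.floating)):
        out = float(value)
        if not np.isfinite(out):
            raise ValueError(f"non-finite date value {value!r}")
        return out
    if isinstance(value, _dt.datetime):
        value = value.date()
    if isinstance(value, str):
        value = _dt.date.fromisoformat(value.strip())
    if isinstance(value, _dt.date):
        start = _dt.date(value.year, 1, 1)
        length = (_dt.date(value.year + 1, 1, 1) - start).days
        return value.year + (value - start).days / length
    raise ValueError(f"cannot interpret {value!r} as a date")


# ---------------------------------------------------------------------------
# response table I/O


def _coerce_responses(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns and c != "visit_date"]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    df = df.copy()
    if "visit_date" not in df.columns:
        df["visit_date"] = np.nan
    else:
        df["visit_date"] = [
            np.nan if pd.isna(v) else to_decimal_year(v) for v in df["visit_date"]
        ]

    n_before = len(df)
    df = df.dropna(subset=["correct"])
    n_dropped = n_before - len(df)
    if n_dropped:
        log.warning("%s: dropped %d row(s) with missing 'correct'", source, n_dropped)

    correct = pd.to_numeric(df["correct"], errors="coerce")
    bad = correct.isna() | ~correct.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(
            f"{source}: 'correct' must be 0 or 1; offending data row {row} "
            f"(value {df['correct'].iloc[row - 1]!r})"
        )
    df["correct"] = correct.astype(np.int8)
    df["participant_id"] = df["participant_id"].astype(str)
    df["visit"] = pd.to_numeric(df["visit"]).astype(int)
    df["item"] = pd.to_numeric(df["item"]).astype(int)
    df["story"] = df["story"].astype(str).str.strip().str.upper()
    df["condition"] = df["condition"].astype(str).str.strip().str.lower()

    if (df["visit"] < 1).any():
        raise ValueError(f"{source}: visit numbers must be >= 1")
    if not df["story"].isin(STORIES).all():
        bad_story = sorted(set(df["story"]) - set(STORIES))
        raise ValueError(f"{source}: unknown story label(s) {bad_story}; expected A or B")
    if not df["item"].between(1, N_ITEMS_PER_STORY).all():
        raise ValueError(f"{source}: item index outside 1..{N_ITEMS_PER_STORY}")
    if not df["condition"].isin(CONDITIONS).all():
        bad_cond = sorted(set(df["condition"]) - set(CONDITIONS))
        raise ValueError(f"{source}: unknown condition(s) {bad_cond}")

    dup = df.duplicated(subset=_KEY_COLUMNS, keep=False)
    if dup.any():
        first = df.loc[dup, _KEY_COLUMNS].iloc[0].to_dict()
        raise ValueError(f"{source}: duplicate response record(s), first key {first}")
    return df[RESPONSE_COLUMNS].reset_index(drop=True)


def read_responses(
    path: str | Path, schema: Mapping[str, str] | None = None, sep: str | None = None
) -> pd.DataFrame:
    """Read a tidy item-response table from delimited text.

    Parameters
    ----------
    path
        CSV or TSV file (delimiter sniffed unless ``sep`` is given).
    schema
        Optional mapping from canonical column names to the file's column
        names, e.g. ``{"participant_id": "subj"}``.

    Returns
    -------
    DataFrame with columns ``participant_id, visit, visit_date, story,
    item, condition, correct``, validated: correct in {0,1}, no duplicate
    (participant, visit, story, item, condition) keys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    if schema:
        rename = {v: k for k, v in schema.items()}
        df = df.rename(columns=rename)
    return _coerce_responses(df, source=str(path))


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    """Write a response table as CSV with the canonical column order."""
    out = _coerce_responses(df)
    out.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# participant table I/O


def read_participants(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read the participant table (one row per participant).

    Expected columns: ``participant_id`` plus optionally ``dvr``,
    ``pet_date`` and covariates.  ``amyloid_status`` is recomputed from
    DVR when both are present and must agree.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    return _coerce_participants(df, source=str(path))


def _coerce_participants(df: pd.DataFrame, source: str = "<memory>") -> pd.DataFrame:
    if "participant_id" not in df.columns:
        raise ValueError(f"{source}: missing required column 'participant_id'")
    df = df.copy()
    df["participant_id"] = df["participant_id"].astype(str)
    if df["participant_id"].duplicated().any():
        raise ValueError(f"{source}: duplicate participant_id")
    if "dvr" not in df.columns:
        df["dvr"] = np.nan
    df["dvr"] = pd.to_numeric(df["dvr"], errors="coerce")
    if "pet_date" in df.columns:
        df["pet_date"] = [np.nan if pd.isna(v) else to_decimal_year(v) for v in df["pet_date"]]
    else:
        df["pet_date"] = np.nan
    derived = [
        "unknown" if pd.isna(d) else classify_amyloid(d) for d in df["dvr"]
    ]
    if "amyloid_status" in df.columns:
        stated = df["amyloid_status"].astype(str).str.lower()
        for i, (s, d) in enumerate(zip(stated, derived)):
            if s in ("positive", "negative") and d != "unknown" and s != d:
                raise ValueError(
                    f"{source}: participant {df['participant_id'].iloc[i]} has "
                    f"amyloid_status={s!r} inconsistent with dvr={df['dvr'].iloc[i]}"
                )
        df["amyloid_status"] = [
            s if s in ("positive", "negative") else d for s, d in zip(stated, derived)
        ]
    else:
        df["amyloid_status"] = derived
    return df.reset_index(drop=True)


def write_participants(df: pd.DataFrame, path: str | Path) -> None:
    _coerce_participants(df).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# cohort preparation


def classify_amyloid(dvr: float, threshold: float = 1.19) -> str:
    """Dichotomize a global PiB DVR value.

    Returns ``"positive"`` iff ``dvr`` is strictly greater than
    ``threshold`` (a DVR exactly at the threshold is negative).
    """
    dvr = float(dvr)
    if not np.isfinite(dvr) or dvr <= 0:
        raise ValueError(f"dvr must be a positive finite number, got {dvr}")
    return "positive" if dvr > threshold else "negative"


def select_lm_visit(
    visit_dates: Sequence[tuple[int, float]], pet_date, tie_break: str = "earlier"
) -> int:
    """Pick the memory-assessment visit closest in time to a PET scan.

    Parameters
    ----------
    visit_dates
        Sequence of ``(visit, date)`` pairs; dates as ISO strings or
        decimal years.
    pet_date
        The PET scan date.
    tie_break
        ``"earlier"`` (default) or ``"later"``: which visit wins when two
        are equidistant from the scan.
    """
    if len(visit_dates) == 0:
        raise ValueError("visit_dates must contain at least one (visit, date) pair")
    if tie_break not in ("earlier", "later"):
        raise ValueError(f"tie_break must be 'earlier' or 'later', got {tie_break!r}")
    pet = to_decimal_year(pet_date)
    pairs = [(int(v), to_decimal_year(d)) for v, d in visit_dates]
    pairs.sort(key=lambda p: p[1], reverse=(tie_break == "later"))
    best_visit, _ = min(pairs, key=lambda p: abs(p[1] - pet))
    return best_visit


@dataclass
class ValidationReport:
    """Report-only dataset audit; flags issues without mutating anything."""

    incomplete: list[dict] = field(default_factory=list)
    orphan_participants: list[str] = field(default_factory=list)
    taxonomy_gaps: list[tuple[str, int]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.incomplete or self.orphan_participants or self.taxonomy_gaps)

    def summary(self) -> str:
        return (
            f"incomplete item sets: {len(self.incomplete)}; "
            f"orphan participants: {len(self.orphan_participants)}; "
            f"taxonomy gaps: {len(self.taxonomy_gaps)}"
        )


def validate_dataset(
    responses: pd.DataFrame,
    participants: pd.DataFrame | None = None,
    taxonomy=None,
) -> ValidationReport:
    """Audit a dataset for completeness without modifying it.

    Flags (participant, visit, condition, story) cells with fewer than 25
    item responses, responses whose participant is absent from the
    participant table, and idea units missing from the taxonomy.
    """
    report = ValidationReport()
    counts = responses.groupby(
        ["participant_id", "visit", "condition", "story"], sort=True
    ).size()
    for key, n in counts.items():
        if n < N_ITEMS_PER_STORY:
            pid, visit, condition, story = key
            report.incomplete.append(
                {
                    "participant_id": pid,
                    "visit": int(visit),
                    "condition": condition,
                    "story": story,
                    "n_items": int(n),
                }
            )
    if participants is not None:
        known = set(participants["participant_id"].astype(str))
        orphans = sorted(set(responses["participant_id"].astype(str)) - known)
        report.orphan_participants.extend(orphans)
    if taxonomy is not None:
        covered = set(taxonomy.category_map)
        report.taxonomy_gaps.extend(k for k in all_item_keys() if k not in covered)
    if not report.ok:
        log.warning("dataset validation: %s", report.summary())
    return report
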