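"""Classical item indices and their decompositions.

Item *difficulty* is the proportion of respondents recalling an idea
unit (higher = easier).  Item *discrimination* is the corrected
item-total correlation: the Pearson correlation between an item's binary
score and the rest-score (the respondent's total over the remaining
items), a point-biserial by construction.  Indices are computed per
visit and recall condition, optionally stratified by a participant
grouping (e.g. amyloid status), then decomposed by story, lexical
category and serial position, and differenced across recall conditions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datamodel import CONDITIONS, all_item_keys
from .taxonomy import ItemTaxonomy, assign_serial_position

log = logging.getLogger("recallpsych")

__all__ = [
    "difficulty_index",
    "discrimination_index",
    "corrected_item_total",
    "compute_index_table",
    "average_over_visits",
    "aggregate_indices",
    "condition_differences",
]


def difficulty_index(responses: np.ndarray) -> float:
    """Proportion correct of a non-empty binary response vector."""
    arr = np.asarray(responses, dtype=float)
    if arr.size == 0:
        raise ValueError("difficulty_index requires at least one response")
    if not np.isin(arr, (0.0, 1.0)).all():
        raise ValueError("responses must be binary 0/1")
    return float(arr.mean())


def corrected_item_total(matrix: np.ndarray) -> np.ndarray:
    """Corrected item-total correlation for every column of a binary matrix.

    Column ``j`` is correlated with the rest-score (row total excluding
    column ``j``).  Entries are NaN where either side has zero variance —
    an undefined discrimination is flagged as missing, never coerced to 0.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("matrix must be 2-D with at least 2 items")
    n = x.shape[0]
    if n < 3:
        raise ValueError(f"discrimination requires at least 3 participants, got {n}")
    total = x.sum(axis=1, keepdims=True)
    rest = total - x
    xc = x - x.mean(axis=0)
    rc = rest - rest.mean(axis=0)
    cov = (xc * rc).sum(axis=0)
    var_x = (xc**2).sum(axis=0)
    var_r = (rc**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_x * var_r)
    r[(var_x <= 0) | (var_r <= 0)] = np.nan
    return r


def discrimination_index(matrix: np.ndarray, item_col: int) -> float:
    """Corrected item-total correlation of one column; NaN when undefined."""
    return float(corrected_item_total(matrix)[item_col])


def _index_block(
    sub: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Indices for one (visit, condition, group) slice of the long table."""
    wide = sub.pivot_table(
        index="participant_id", columns=["story", "item"], values="correct", aggfunc="first"
    )
    # difficulty: over participants with a non-missing response to that item
    difficulty = wide.mean(axis=0)
    n_resp = wide.notna().sum(axis=0)

    # discrimination: complete-case within the rest-score scope
    disc = pd.Series(np.nan, index=wide.columns)
    if config.rest_score_scope == "per_story":
        scopes = [[c for c in wide.columns if c[0] == s] for s in ("A", "B")]
    else:
        scopes = [list(wide.columns)]
    for cols in scopes:
        if len(cols) < 2:
            continue
        block = wide[cols].dropna(axis=0, how="any")
        if len(block) < 3:
            log.warning("discrimination skipped: %d complete case(s) in scope", len(block))
            continue
        disc[cols] = corrected_item_total(block.to_numpy())

    lo, hi = config.difficulty_acceptable
    out = pd.DataFrame(
        {
            "story": [c[0] for c in wide.columns],
            "item": [c[1] for c in wide.columns],
            "difficulty": difficulty.to_numpy(),
            "discrimination": disc.to_numpy(),
            "n_respondents": n_resp.to_numpy(),
        }
    )
    out = out[out["n_respondents"] > 0]
    out["qc_difficulty_ok"] = (out["difficulty"] >= lo) & (out["difficulty"] <= hi)
    out["qc_discrimination_ok"] = out["discrimination"] >= config.discrimination_floor
    out.loc[out["discrimination"].isna(), "qc_discrimination_ok"] = False
    return out


def compute_index_table(
    responses: pd.DataFrame,
    grouping: pd.Series | dict | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-item difficulty and discrimination, stratified.

    Parameters
    ----------
    responses
        Tidy response table (see :mod:`recallpsych.datamodel`).
    grouping
        Optional participant partition (``participant_id -> label``,
        e.g. amyloid status); unmapped participants are dropped from the
        stratified table.  ``None`` puts everyone in group ``"all"``.
    config
        Acceptability bands and the rest-score scope.

    Returns
    -------
    One row per (story, item, condition, visit, group) with columns
    ``difficulty``, ``discrimination`` (NaN when undefined),
    ``n_respondents`` and the two QC flags.
    """
    if config is None:
        config = AnalysisConfig()
    df = responses.copy()
    if grouping is None:
        df["group"] = "all"
    else:
        gmap = grouping if isinstance(grouping, dict) else grouping.to_dict()
        df["group"] = df["participant_id"].map(gmap)
        n_unmapped = int(df["group"].isna().sum())
        if n_unmapped:
            log.warning("compute_index_table: dropping %d response(s) without a group", n_unmapped)
            df = df.dropna(subset=["group"])

    blocks = []
    for (visit, condition, group), sub in df.groupby(["visit", "condition", "group"], sort=True):
        n_participants = sub["participant_id"].nunique()
        if n_participants < 3:
            log.warning(
                "group %r at visit %s/%s has %d participant(s) < 3; skipped",
                group, visit, condition, n_participants,
            )
            continue
        block = _index_block(sub, config)
        block.insert(2, "condition", condition)
        block.insert(3, "visit", visit)
        block.insert(4, "group", group)
        blocks.append(block)
    if not blocks:
        raise ValueError("no stratum had enough participants to compute indices")
    table = pd.concat(blocks, ignore_index=True)
    return table.sort_values(
        ["group", "condition", "visit", "story", "item"], ignore_index=True
    )


def average_over_visits(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of per-visit indices per (item, condition, group).

    Visits are weighted equally regardless of how many participants
    contributed to each; undefined discriminations are excluded from
    their item's mean.
    """
    grouped = table.groupby(["group", "condition", "story", "item"], sort=True)
    out = grouped.agg(
        difficulty=("difficulty", "mean"),
        discrimination=("discrimination", "mean"),
        n_visits=("visit", "nunique"),
        n_respondents=("n_respondents", "sum"),
    ).reset_index()
    out["visit"] = "all"
    return out


def _with_strata(table: pd.DataFrame, taxonomy: ItemTaxonomy) -> pd.DataFrame:
    tax = taxonomy.as_frame()
    return table.merge(tax, on=["story", "item"], how="left", validate="many_to_one")


_STRATUM_COLUMN = {
    "story": "story",
    "lexical_category": "category",
    "serial_position": "serial_position",
}


def aggregate_indices(
    table: pd.DataFrame, by: str, taxonomy: ItemTaxonomy | None = None
) -> pd.DataFrame:
    """Item-level mean(SD) of both indices per stratum.

    ``by`` is one of ``"story"``, ``"lexical_category"``,
    ``"serial_position"``.  The item is the unit of analysis: strata are
    summarized by the unweighted mean and SD over member items' index
    values (so the mean of stratum means generally differs from the
    grand mean when strata are unbalanced).  SD is the sample SD
    (ddof=1), 0 for a single-item stratum.
    """
    if by not in _STRATUM_COLUMN:
        raise ValueError(f"by must be one of {sorted(_STRATUM_COLUMN)}, got {by!r}")
    if taxonomy is None:
        taxonomy = ItemTaxonomy(
            {k: "unused" for k in all_item_keys()}, label="positions-only"
        )
    df = _with_strata(table, taxonomy)
    col = _STRATUM_COLUMN[by]

    def _sd(v: pd.Series) -> float:
        v = v.dropna()
        return 0.0 if len(v) <= 1 else float(v.std(ddof=1))

    rows = []
    for (group, condition, visit, stratum), sub in df.groupby(
        ["group", "condition", "visit", col], sort=True
    ):
        if sub.empty:
            continue
        n_undef = int(sub["discrimination"].isna().sum())
        if n_undef:
            log.info("aggregate %s=%s: %d undefined discrimination(s) excluded", by, stratum, n_undef)
        rows.append(
            {
                "group": group,
                "condition": condition,
                "visit": visit,
                by: stratum,
                "n_items": len(sub),
                "difficulty_mean": float(sub["difficulty"].mean()),
                "difficulty_sd": _sd(sub["difficulty"]),
                "discrimination_mean": float(sub["discrimination"].mean()),
                "discrimination_sd": _sd(sub["discrimination"]),
            }
        )
    return pd.DataFrame(rows)


def condition_differences(table: pd.DataFrame) -> pd.DataFrame:
    """Paired immediate-vs-delayed index differences per (item, visit, group).

    Sign conventions follow the reporting direction of each index:
    ``diff_difficulty`` is immediate minus delayed (positive = harder at
    delay) and ``diff_discrimination`` is delayed minus immediate
    (positive = more discriminating at delay).  ``plot_difficulty_change``
    carries the plotted convention (delayed minus immediate, negative =
    harder at delay).  Rows missing either condition are omitted with a
    warning.
    """
    piv = table.pivot_table(
        index=["group", "visit", "story", "item"],
        columns="condition",
        values=["difficulty", "discrimination"],
        aggfunc="first",
    )
    missing = piv.isna().all(axis=1)
    have_both = pd.Series(True, index=piv.index)
    for cond in CONDITIONS:
        if ("difficulty", cond) not in piv.columns:
            raise ValueError(f"condition {cond!r} absent from index table")
        have_both &= piv[("difficulty", cond)].notna()
    n_drop = int((~have_both | missing).sum())
    if n_drop:
        log.warning("condition_differences: %d item row(s) missing a condition; omitted", n_drop)
    piv = piv[have_both]
    out = piv.index.to_frame(index=False)
    out["diff_difficulty"] = (
        piv[("difficulty", "immediate")] - piv[("difficulty", "delayed")]
    ).to_numpy()
    out["plot_difficulty_change"] = -out["diff_difficulty"]
    out["diff_discrimination"] = (
        piv[("discrimination", "delayed")] - piv[("discrimination", "immediate")]
    ).to_numpy()
    out["serial_position"] = [assign_serial_position(i) for i in out["item"]]
    return out
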