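"""Group contrasts: Cliff's delta, assumption-gated tests, amyloid suite.

Cliff's delta is the nonparametric effect size
``P(X > Y) - P(X < Y)`` over all cross-group pairs, graded
negligible / small / medium / large at |d| = 0.147 / 0.33 / 0.474.
Two-group location tests are chosen by assumption gates: Shapiro-Wilk
normality and (for unpaired contrasts) Brown-Forsythe variance
homogeneity select the parametric branch (independent or paired t-test);
otherwise the Mann-Whitney U or Wilcoxon signed-rank test is used.

The amyloid contrast suite reproduces the Tables-4/5 style analysis:
item indices are computed separately for the amyloid-positive and
-negative groups at the PET-matched visit, then paired *by item* within
each recall condition and item subset (story, lexical category, serial
position, overall).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datamodel import CONDITIONS
from .taxonomy import CATEGORIES, SERIAL_POSITIONS, ItemTaxonomy, assign_serial_position

log = logging.getLogger("recallpsych")

__all__ = [
    "cliffs_delta",
    "delta_magnitude",
    "choose_test",
    "compare_groups",
    "ComparisonResult",
    "amyloid_contrast_suite",
]

MAGNITUDES = ("negligible", "small", "medium", "large")


def cliffs_delta(x, y) -> float:
    """Exact Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y).

    Ties contribute zero.  Computed by full sign enumeration over the
    n_x * n_y ordered pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("cliffs_delta requires two non-empty samples")
    signs = np.sign(x[:, None] - y[None, :])
    return float(signs.sum() / (x.size * y.size))


def delta_magnitude(delta: float, thresholds: tuple[float, float, float] = (0.147, 0.33, 0.474)) -> str:
    """Magnitude label of a Cliff's delta under half-open |d| bands.

    ``[0, t1)`` negligible, ``[t1, t2)`` small, ``[t2, t3)`` medium,
    ``[t3, 1]`` large.
    """
    if not np.isfinite(delta) or abs(delta) > 1.0:
        raise ValueError(f"delta must lie in [-1, 1], got {delta}")
    t1, t2, t3 = thresholds
    d = abs(delta)
    if d < t1:
        return "negligible"
    if d < t2:
        return "small"
    if d < t3:
        return "medium"
    return "large"


@dataclass(frozen=True)
class AssumptionReport:
    """Outcomes of the normality / variance-homogeneity gates."""

    normality_p_x: float | None = None
    normality_p_y: float | None = None
    normality_p_diff: float | None = None
    variance_p: float | None = None
    normal_ok: bool = False
    variance_ok: bool = True

    @property
    def parametric_ok(self) -> bool:
        return self.normal_ok and self.variance_ok


def choose_test(x, y, paired: bool = False, assumption_alpha: float = 0.05):
    """Select the location test for a two-group contrast.

    Unpaired: independent t-test iff both samples pass Shapiro-Wilk
    normality *and* Brown-Forsythe homogeneity at ``assumption_alpha``;
    otherwise Mann-Whitney U.  Paired: paired t-test iff the pairwise
    differences pass Shapiro-Wilk; otherwise Wilcoxon signed-rank.

    Returns ``(test_name, AssumptionReport)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if x.size < 3:
            raise ValueError("paired contrast requires at least 3 pairs")
        d = x - y
        if np.ptp(d) == 0 and d[0] == 0:
            raise ValueError("degenerate paired data: all differences are zero")
        if np.ptp(d) == 0:
            # constant nonzero difference: Shapiro undefined; not normal-testable
            report = AssumptionReport(normality_p_diff=np.nan, normal_ok=False)
            return "wilcoxon_signed_rank", report
        p_diff = float(stats.shapiro(d).pvalue)
        ok = p_diff > assumption_alpha
        report = AssumptionReport(normality_p_diff=p_diff, normal_ok=ok)
        return ("t_paired" if ok else "wilcoxon_signed_rank"), report

    if x.size < 3 or y.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("degenerate data: both samples are constant")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        report = AssumptionReport(normal_ok=False, variance_ok=False)
        return "mann_whitney", report
    p_x = float(stats.shapiro(x).pvalue)
    p_y = float(stats.shapiro(y).pvalue)
    p_var = float(stats.levene(x, y, center="median").pvalue)  # Brown-Forsythe
    normal_ok = p_x > assumption_alpha and p_y > assumption_alpha
    variance_ok = p_var > assumption_alpha
    report = AssumptionReport(
        normality_p_x=p_x, normality_p_y=p_y, variance_p=p_var,
        normal_ok=normal_ok, variance_ok=variance_ok,
    )
    return ("t_independent" if normal_ok and variance_ok else "mann_whitney"), report


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group (or paired) contrast with effect size and assumptions."""

    contrast_label: str
    n_x: int
    n_y: int
    mean_x: float
    sd_x: float
    mean_y: float
    sd_y: float
    test_used: str
    statistic: float
    p_value: float
    cliffs_delta: float
    magnitude: str
    assumptions: AssumptionReport

    def to_dict(self) -> dict:
        d = {
            "contrast": self.contrast_label,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "mean_x": self.mean_x,
            "sd_x": self.sd_x,
            "mean_y": self.mean_y,
            "sd_y": self.sd_y,
            "test": self.test_used,
            "statistic": self.statistic,
            "p": self.p_value,
            "cliffs_delta": self.cliffs_delta,
            "magnitude": self.magnitude,
            "normal_ok": self.assumptions.normal_ok,
            "variance_ok": self.assumptions.variance_ok,
        }
        return d


def _rank_test_method(n_min: int, values: np.ndarray) -> str:
    has_ties = len(np.unique(values)) < values.size
    return "exact" if (n_min <= 25 and not has_ties) else "asymptotic"


def compare_groups(
    x, y, paired: bool = False, config: AnalysisConfig | None = None,
    label: str = "",
) -> ComparisonResult:
    """Run the assumption-gated two-sided test and Cliff's delta.

    Cliff's delta is always computed on ``(x, y)`` in that argument
    order, so a first group with smaller values yields a negative delta,
    regardless of which hypothesis test is selected.
    """
    if config is None:
        config = AnalysisConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    test, report = choose_test(x, y, paired=paired, assumption_alpha=config.assumption_alpha)
    if test == "t_independent":
        res = stats.ttest_ind(x, y)
    elif test == "mann_whitney":
        method = _rank_test_method(min(x.size, y.size), np.concatenate([x, y]))
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    elif test == "t_paired":
        res = stats.ttest_rel(x, y)
    else:  # wilcoxon_signed_rank
        d = x - y
        d = d[d != 0]
        method = _rank_test_method(d.size, np.abs(d))
        res = stats.wilcoxon(x, y, alternative="two-sided", method=method, correction=True)
    delta = cliffs_delta(x, y)
    return ComparisonResult(
        contrast_label=label,
        n_x=int(x.size),
        n_y=int(y.size),
        mean_x=float(x.mean()),
        sd_x=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        mean_y=float(y.mean()),
        sd_y=float(y.std(ddof=1)) if y.size > 1 else 0.0,
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        cliffs_delta=delta,
        magnitude=delta_magnitude(delta, config.magnitude_thresholds),
        assumptions=report,
    )


def _item_subsets(taxonomy: ItemTaxonomy) -> list[tuple[str, set]]:
    subsets: list[tuple[str, set]] = [("overall", set(taxonomy.category_map))]
    for story in ("A", "B"):
        subsets.append((f"story_{story}", {k for k in taxonomy.category_map if k[0] == story}))
    for cat in CATEGORIES:
        subsets.append((f"category_{cat}", set(taxonomy.items_in_category(cat))))
    for pos in SERIAL_POSITIONS:
        subsets.append((f"position_{pos}", set(taxonomy.items_in_position(pos))))
    return subsets


def amyloid_contrast_suite(
    index_table: pd.DataFrame,
    taxonomy: ItemTaxonomy,
    config: AnalysisConfig | None = None,
    index_types: tuple[str, ...] = ("difficulty", "discrimination"),
) -> pd.DataFrame:
    """Amyloid-positive vs -negative contrasts over item subsets.

    ``index_table`` must carry per-item indices for groups ``"positive"``
    and ``"negative"`` at a single visit (the PET-matched one).  For each
    recall condition, index type and item subset (overall, each story,
    each lexical category, each serial position — 2 x 10 contrasts per
    index type) the member items' index values are paired across the two
    groups and compared with ``compare_groups(paired=True)``, with the
    amyloid-positive group as the first argument (so "harder for
    amyloid-positive" shows as negative delta).  An unpaired variant of
    every contrast is also emitted (``variant`` column); the paired rows
    are the primary analysis.  Subsets with fewer than 3 defined item
    pairs are reported descriptively without a test.
    """
    if config is None:
        config = AnalysisConfig()
    groups = set(index_table["group"].unique())
    if not {"positive", "negative"} <= groups:
        raise ValueError(
            f"index_table must contain both amyloid groups, found {sorted(groups)}"
        )
    rows = []
    for index_type in index_types:
        piv = index_table.pivot_table(
            index=["condition", "story", "item"], columns="group",
            values=index_type, aggfunc="first",
        )
        for condition in CONDITIONS:
            for subset_label, members in _item_subsets(taxonomy):
                sel = [
                    (condition, s, i)
                    for (s, i) in sorted(members)
                    if (condition, s, i) in piv.index
                ]
                sub = piv.loc[sel].dropna(subset=["positive", "negative"])
                xs = sub["positive"].to_numpy()
                ys = sub["negative"].to_numpy()
                base = {
                    "index_type": index_type,
                    "condition": condition,
                    "subset": subset_label,
                    "n_items": len(sub),
                }
                if len(sub) < 3:
                    log.warning(
                        "subset %s/%s/%s has %d item pair(s) < 3: descriptive only",
                        index_type, condition, subset_label, len(sub),
                    )
                    rows.append(
                        base | {
                            "variant": "descriptive",
                            "mean_pos": float(xs.mean()) if len(sub) else np.nan,
                            "mean_neg": float(ys.mean()) if len(sub) else np.nan,
                        }
                    )
                    continue
                for variant, paired in (("paired", True), ("unpaired", False)):
                    try:
                        res = compare_groups(
                            xs, ys, paired=paired, config=config,
                            label=f"{index_type}:{condition}:{subset_label}",
                        )
                    except ValueError as exc:
                        log.warning("contrast %s (%s) failed: %s", base, variant, exc)
                        continue
                    rows.append(
                        base | {
                            "variant": variant,
                            "mean_pos": res.mean_x,
                            "sd_pos": res.sd_x,
                            "mean_neg": res.mean_y,
                            "sd_neg": res.sd_y,
                            "test": res.test_used,
                            "statistic": res.statistic,
                            "p": res.p_value,
                            "cliffs_delta": res.cliffs_delta,
                            "magnitude": res.magnitude,
                            "significant": res.p_value < config.alpha,
                        }
                    )
    out = pd.DataFrame(rows)
    # Holm-adjusted p within each (index_type, variant) family, secondary column
    out["p_holm"] = np.nan
    for (_, _), idx in out.groupby(["index_type", "variant"]).groups.items():
        ps = out.loc[idx, "p"].dropna()
        if len(ps):
            order = ps.sort_values().index
            m = len(order)
            # Holm step-down: running max of (m - rank) * p, capped at 1
            vals = ps[order].to_numpy() * (m - np.arange(m))
            out.loc[order, "p_holm"] = np.minimum(1.0, np.maximum.accumulate(vals))
    return out
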