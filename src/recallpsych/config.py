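"""Analysis configuration.

All cut-points used by the pipeline live here: the amyloid-PET DVR
dichotomization threshold, the classical acceptability bands for item
difficulty and discrimination, the significance levels, and the Cliff's
delta magnitude thresholds (negligible / small / medium / large).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Constants and options shared across the analysis stages.

    Parameters
    ----------
    dvr_threshold
        Global PiB DVR value strictly above which a participant is
        classified amyloid positive.
    difficulty_acceptable
        Closed interval of acceptable item difficulty (proportion correct).
    discrimination_floor
        Minimum acceptable corrected item-total correlation.
    alpha
        Significance level for the primary hypothesis tests.
    assumption_alpha
        Significance level for the normality / variance-homogeneity gates
        that select parametric vs nonparametric tests.
    magnitude_thresholds
        Strictly increasing |delta| cut-points separating negligible,
        small, medium and large effect sizes.
    tie_break
        Which visit wins when two visits are equidistant from the PET
        scan date: ``"earlier"`` or ``"later"``.
    rest_score_scope
        ``"combined"`` computes the discrimination rest-score over all 50
        items of both stories; ``"per_story"`` restricts it to the item's
        own 25-item story.
    min_group_size
        Amyloid group size below which a prominent warning is issued.
    """

    dvr_threshold: float = 1.19
    difficulty_acceptable: tuple[float, float] = (0.2, 0.8)
    discrimination_floor: float = 0.2
    alpha: float = 0.05
    assumption_alpha: float = 0.05
    magnitude_thresholds: tuple[float, float, float] = (0.147, 0.33, 0.474)
    seed: int = 0
    tie_break: str = "earlier"
    rest_score_scope: str = "combined"
    min_group_size: int = 20

    def __post_init__(self) -> None:
        lo, mid, hi = self.magnitude_thresholds
        if not (0.0 < lo < mid < hi < 1.0):
            raise ValueError(
                "magnitude_thresholds must be strictly increasing in (0, 1), "
                f"got {self.magnitude_thresholds}"
            )
        for name in ("alpha", "assumption_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.tie_break not in ("earlier", "later"):
            raise ValueError(f"tie_break must be 'earlier' or 'later', got {self.tie_break!r}")
        if self.rest_score_scope not in ("combined", "per_story"):
            raise ValueError(
                f"rest_score_scope must be 'combined' or 'per_story', got {self.rest_score_scope!r}"
            )
        a, b = self.difficulty_acceptable
        if not 0.0 <= a < b <= 1.0:
            raise ValueError(f"difficulty_acceptable must be a subinterval of [0,1], got {(a, b)}")

    def to_dict(self) -> dict:
        return {
            f.name: list(v) if isinstance(v := getattr(self, f.name), tuple) else v
            for f in fields(self)
        }


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML or JSON file.

    Unknown keys raise; list-valued fields are coerced to tuples.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("difficulty_acceptable", "magnitude_thresholds"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return AnalysisConfig(**raw)
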