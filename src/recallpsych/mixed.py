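"""Repeated-measures models of item indices.

Two model families back the visit-level repeated-measures analyses:

* :func:`fit_index_model` — index ~ story + lexical_category +
  serial_position with a random intercept per item across visits,
  fitted on the logit scale with a Gaussian likelihood (indices clipped
  to [eps, 1-eps] first; discrimination values in [-1, 1] are mapped to
  (0, 1) via (r+1)/2 before the transform).  Omnibus factor tests are
  Wald F-tests with between-within denominator degrees of freedom (the
  factors vary between items, so the item count — not the observation
  count — carries the information; a naive likelihood-ratio chi-square
  is anticonservative at this design size).  Per-coefficient intervals
  are Wald.
* :func:`condition_change_model` — the paired immediate-minus-delayed
  index differences modelled on the natural scale as intercept + story
  version with a per-item random intercept, answering whether the mean
  change differs from zero and between stories.

With a single visit there is no repetition to absorb, so both degrade
to ordinary fixed-effects least squares with a logged note; the random
intercept variance is then reported as 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

import statsmodels.api as sm
import statsmodels.formula.api as smf

from .taxonomy import CATEGORIES, SERIAL_POSITIONS, ItemTaxonomy, assign_serial_position

log = logging.getLogger("recallpsych")

__all__ = ["ModelFit", "Contrast", "fit_index_model", "posthoc_pairwise", "condition_change_model"]

_CLIP_EPS = 0.005

_FACTORS = {
    "story": ("story", "A", ("A", "B")),
    "lexical_category": ("category", "proper_name", CATEGORIES),
    "serial_position": ("position", "primacy", SERIAL_POSITIONS),
}


@dataclass
class Contrast:
    """One pairwise difference of factor-level marginal means."""

    label: str
    estimate: float
    se: float
    p_value: float
    p_tukey: float

    def reversed(self) -> "Contrast":
        a, b = self.label.split(" vs ")
        return Contrast(f"{b} vs {a}", -self.estimate, self.se, self.p_value, self.p_tukey)


@dataclass
class ModelFit:
    """A fitted repeated-measures model with omnibus tests and diagnostics."""

    response: str
    condition: str
    family: str
    formula: str
    n_obs: int
    coefficients: dict  # term -> (estimate, ci_low, ci_high, p)
    omnibus: dict  # factor -> p_value (likelihood-ratio)
    random_intercept_variance: float
    converged: bool
    log_likelihood: float
    df_resid: float
    note: str = ""
    posthoc: list = field(default_factory=list)
    _params: np.ndarray | None = None
    _param_names: list | None = None
    _cov: np.ndarray | None = None
    _factor_levels: dict = field(default_factory=dict)

    def coefficient_table(self) -> pd.DataFrame:
        rows = [
            {"term": t, "estimate": e, "ci_low": lo, "ci_high": hi, "p": p}
            for t, (e, lo, hi, p) in self.coefficients.items()
        ]
        return pd.DataFrame(rows)

    def to_report(self) -> dict:
        return {
            "response": self.response,
            "condition": self.condition,
            "family": self.family,
            "formula": self.formula,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "log_likelihood": self.log_likelihood,
            "random_intercept_variance": self.random_intercept_variance,
            "note": self.note,
            "coefficients": {
                t: {"estimate": e, "ci_low": lo, "ci_high": hi, "p": p}
                for t, (e, lo, hi, p) in self.coefficients.items()
            },
            "omnibus": dict(self.omnibus),
            "posthoc": [
                {
                    "contrast": c.label,
                    "estimate": c.estimate,
                    "se": c.se,
                    "p": c.p_value,
                    "p_tukey": c.p_tukey,
                }
                for c in self.posthoc
            ],
        }


def _transform_response(values: np.ndarray, response: str, family: str) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if response == "discrimination":
        v = (v + 1.0) / 2.0  # [-1, 1] -> (0, 1)
    if family == "logit_gaussian":
        v = logit(np.clip(v, _CLIP_EPS, 1.0 - _CLIP_EPS))
    elif family == "identity_gaussian":
        pass
    else:
        raise ValueError(f"unknown family {family!r}")
    return v


def _prepare(table: pd.DataFrame, taxonomy: ItemTaxonomy, response: str) -> pd.DataFrame:
    df = table.copy()
    df["category"] = [taxonomy.category_map[(s, i)] for s, i in zip(df["story"], df["item"])]
    df["position"] = [assign_serial_position(i) for i in df["item"]]
    df["item_id"] = df["story"].astype(str) + df["item"].astype(str)
    df = df.dropna(subset=[response])
    return df


def _fit(formula: str, data: pd.DataFrame, mixed: bool):
    """Fit the (REML) mixed or OLS model; returns (result, converged)."""
    if mixed:
        model = smf.mixedlm(formula, data=data, groups=data["item_id"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=True, method="lbfgs")
                if not res.converged:
                    res = model.fit(reml=True, method="cg")
            except (np.linalg.LinAlgError, ValueError):
                res = model.fit(reml=True, method="powell")
        return res, bool(res.converged)
    res = smf.ols(formula, data=data).fit()
    return res, True


def _wald_f(beta: np.ndarray, cov: np.ndarray, names: list, prefix: str, ddf: float) -> float:
    """Wald F-test that all coefficients of one factor are zero."""
    idx = [i for i, n in enumerate(names) if n.startswith(prefix)]
    if not idx or ddf <= 0:
        return float("nan")
    b = beta[idx]
    V = cov[np.ix_(idx, idx)]
    f_stat = float(b @ np.linalg.solve(V, b)) / len(idx)
    return float(stats.f.sf(f_stat, len(idx), ddf))


def fit_index_model(
    table: pd.DataFrame,
    taxonomy: ItemTaxonomy,
    response: str = "difficulty",
    condition: str = "",
    family: str = "logit_gaussian",
) -> ModelFit:
    """Fit index ~ story + lexical_category + serial_position, item random intercept.

    ``table`` holds one row per item x visit with columns ``story``,
    ``item``, ``visit`` and the response column (``difficulty`` or
    ``discrimination``).  Reference levels are story A, proper_name and
    primacy.  With fewer than two distinct visits the model degrades to
    ordinary least squares (random-intercept variance 0, note logged);
    non-convergence is flagged in the result, never silently replaced.
    """
    df = _prepare(table, taxonomy, response)
    if df.empty:
        raise ValueError("no usable rows for the index model")
    df["z"] = _transform_response(df[response].to_numpy(), response, family)

    terms, factor_dfs = [], {}
    for factor, (col, ref, levels) in _FACTORS.items():
        present = [l for l in levels if l in set(df[col])]
        if len(present) < 2:
            log.warning("factor %s has a single level; omitted from the model", factor)
            continue
        terms.append(f"C({col}, Treatment('{ref}'))")
        factor_dfs[factor] = len(present) - 1
    formula = "z ~ " + (" + ".join(terms) if terms else "1")

    n_visits = df["visit"].nunique()
    mixed = n_visits >= 2
    note = "" if mixed else "single visit: degraded to a fixed-effects (OLS) fit"
    if note:
        log.info(note)
    res, converged = _fit(formula, df, mixed)

    fe_names = list(res.fe_params.index) if mixed else list(res.params.index)
    params = np.asarray(res.params)[: len(fe_names)]
    cov = np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)]
    ci = res.conf_int()
    coefficients = {}
    for name in fe_names:
        est = float(res.params[name])
        lo, hi = float(ci.loc[name, 0]), float(ci.loc[name, 1])
        p = float(res.pvalues[name])
        coefficients[name] = (est, lo, hi, p)

    # between-within denominator df: the factors vary between items
    n_units = df["item_id"].nunique() if mixed else len(df)
    ddf = float(n_units - len(fe_names))
    omnibus = {}
    for factor in factor_dfs:
        col, _ref, _ = _FACTORS[factor]
        omnibus[factor] = _wald_f(params, cov, fe_names, f"C({col},", ddf)

    re_var = float(np.asarray(res.cov_re)[0, 0]) if mixed else 0.0
    fit = ModelFit(
        response=response,
        condition=condition,
        family=family,
        formula=formula,
        n_obs=len(df),
        coefficients=coefficients,
        omnibus=omnibus,
        random_intercept_variance=re_var,
        converged=converged,
        log_likelihood=float(res.llf),
        df_resid=ddf,
        note=note,
        _params=params,
        _param_names=fe_names,
        _cov=cov,
        _factor_levels={
            f: [l for l in _FACTORS[f][2] if l in set(df[_FACTORS[f][0]])] for f in factor_dfs
        },
    )
    for factor in factor_dfs:
        fit.posthoc.extend(posthoc_pairwise(fit, factor))
    return fit


def _level_vector(fit: ModelFit, factor: str, level: str) -> np.ndarray:
    """Indicator vector picking the treatment-coded coefficient of a level."""
    col, ref, _ = _FACTORS[factor]
    vec = np.zeros(len(fit._param_names))
    if level == ref:
        return vec
    key = f"C({col}, Treatment('{ref}'))[T.{level}]"
    if key not in fit._param_names:
        raise KeyError(f"coefficient {key} not in model")
    vec[fit._param_names.index(key)] = 1.0
    return vec


def posthoc_pairwise(fit: ModelFit, factor: str) -> list[Contrast]:
    """All pairwise level differences of marginal means for one factor.

    In this additive treatment-coded model a difference of marginal
    means equals the difference of the levels' coefficients.  Unadjusted
    Wald p-values are primary (matching unadjusted post-hoc reporting);
    a Tukey studentized-range adjusted p is emitted as a secondary
    column.  Estimates are on the model's (transformed) scale.
    """
    if factor not in _FACTORS:
        raise ValueError(f"unknown factor {factor!r}")
    levels = fit._factor_levels.get(factor, [])
    if len(levels) < 2:
        return []
    out = []
    k = len(levels)
    for i in range(k):
        for j in range(i + 1, k):
            c = _level_vector(fit, factor, levels[i]) - _level_vector(fit, factor, levels[j])
            est = float(c @ fit._params)
            se = float(np.sqrt(c @ fit._cov @ c))
            if se == 0:
                p = p_tk = 1.0
            else:
                tstat = est / se
                p = float(2.0 * stats.t.sf(abs(tstat), fit.df_resid))
                p_tk = float(stats.studentized_range.sf(abs(tstat) * np.sqrt(2.0), k, fit.df_resid))
            out.append(Contrast(f"{levels[i]} vs {levels[j]}", est, se, p, min(1.0, p_tk)))
    return out


def condition_change_model(
    differences: pd.DataFrame,
    response: str = "diff_difficulty",
) -> ModelFit:
    """Model of paired immediate-vs-delayed differences: intercept + story.

    Fits ``difference ~ story`` (reference story A) with a per-item
    random intercept across visits, on the natural index scale.  The
    intercept tests whether the mean change differs from zero; the story
    coefficient tests whether the change differs between story versions.
    """
    df = differences.copy().dropna(subset=[response])
    if df.empty:
        raise ValueError("no usable rows for the condition-change model")
    df["item_id"] = df["story"].astype(str) + df["item"].astype(str)
    df["z"] = df[response].astype(float)

    if float(np.ptp(df["z"])) == 0.0 and float(df["z"].iloc[0]) == 0.0:
        # all differences identically zero: trivial fit, nothing to estimate
        coefs = {"Intercept": (0.0, 0.0, 0.0, 1.0)}
        if df["story"].nunique() > 1:
            coefs["C(story, Treatment('A'))[T.B]"] = (0.0, 0.0, 0.0, 1.0)
        return ModelFit(
            response=response, condition="", family="identity_gaussian",
            formula="z ~ C(story, Treatment('A'))", n_obs=len(df),
            coefficients=coefs, omnibus={}, random_intercept_variance=0.0,
            converged=True, log_likelihood=np.inf, df_resid=float(len(df) - len(coefs)),
            note="degenerate: all differences are exactly zero",
        )

    has_story = df["story"].nunique() > 1
    formula = "z ~ C(story, Treatment('A'))" if has_story else "z ~ 1"
    mixed = df["visit"].nunique() >= 2
    note = "" if mixed else "single visit: degraded to a fixed-effects (OLS) fit"
    res, converged = _fit(formula, df, mixed)

    fe_names = list(res.fe_params.index) if mixed else list(res.params.index)
    params = np.asarray(res.params)[: len(fe_names)]
    cov = np.asarray(res.cov_params())[: len(fe_names), : len(fe_names)]
    ci = res.conf_int()
    coefficients = {
        name: (
            float(res.params[name]),
            float(ci.loc[name, 0]),
            float(ci.loc[name, 1]),
            float(res.pvalues[name]),
        )
        for name in fe_names
    }
    n_units = df["item_id"].nunique() if mixed else len(df)
    ddf = float(n_units - len(fe_names))
    omnibus = {}
    if has_story:
        omnibus["story"] = _wald_f(params, cov, fe_names, "C(story,", ddf)
    return ModelFit(
        response=response, condition="", family="identity_gaussian",
        formula=formula, n_obs=len(df), coefficients=coefficients, omnibus=omnibus,
        random_intercept_variance=float(np.asarray(res.cov_re)[0, 0]) if mixed else 0.0,
        converged=converged, log_likelihood=float(res.llf),
        df_resid=ddf, note=note,
    )
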