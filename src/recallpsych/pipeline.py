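"""End-to-end orchestration of the two analysis aims.

Aim 1 (full cohort): per-visit and cross-visit item indices, story /
lexical-category / serial-position aggregates, paired immediate-minus-
delayed differences with their intercept + story-version model, and the
repeated-measures index models per recall condition and index type.

Aim 2 (PET subsample): per-participant PET-matched visit selection, DVR
dichotomization, per-group item indices, and the amyloid contrast suite
over stories, categories and serial positions.

All outputs are plain delimited text plus a JSON run manifest; a fixed
seed makes the whole bundle byte-for-byte reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .datamodel import (
    CONDITIONS,
    classify_amyloid,
    select_lm_visit,
    validate_dataset,
    write_participants,
    write_responses,
)
from .inference import amyloid_contrast_suite
from .mixed import condition_change_model, fit_index_model
from .psychometrics import (
    aggregate_indices,
    average_over_visits,
    compute_index_table,
    condition_differences,
)
from .simulate import generate_cohort, paper_like_params, with_overrides
from .taxonomy import ItemTaxonomy, default_taxonomy

log = logging.getLogger("recallpsych")

__all__ = ["run_simulate", "run_aim1", "run_aim2", "run_all"]

_FLOAT_FMT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def _write_json(obj, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_default) + "\n")
    return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _manifest(outdir: Path, config: AnalysisConfig, inputs: dict, outputs: list[Path], seed=None):
    manifest = {
        "config": config.to_dict(),
        "seed": seed,
        "inputs": {k: _digest(Path(v)) for k, v in inputs.items() if Path(v).exists()},
        "outputs": sorted(str(p.relative_to(outdir)) for p in outputs),
    }
    _write_json(manifest, outdir / "manifest.json")


def run_simulate(outdir: str | Path, seed: int = 0, n: int = 1141, visits: int = 7,
                 params=None) -> dict[str, Path]:
    """Generate the default synthetic cohort and write it to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = paper_like_params(n_participants=n, n_visits=visits, seed=seed)
    else:
        params = with_overrides(params, seed=seed)
    responses, participants, truth = generate_cohort(params)
    paths = {
        "responses": outdir / "responses.csv",
        "participants": outdir / "participants.csv",
        "truth_abilities": outdir / "truth_abilities.csv",
        "truth_expected": outdir / "truth_expected.csv",
        "truth_params": outdir / "truth_params.json",
    }
    write_responses(responses, paths["responses"])
    write_participants(participants, paths["participants"])
    _write_csv(truth.abilities, paths["truth_abilities"])
    _write_csv(truth.expected, paths["truth_expected"])
    _write_json(
        {
            "n_participants": params.n_participants,
            "n_visits": params.n_visits,
            "ability_sd": params.ability_sd,
            "visit_noise_sd": params.visit_noise_sd,
            "delay_shift": params.delay_shift,
            "amyloid_prevalence": params.amyloid_prevalence,
            "dvr_spread": params.dvr_spread,
            "pet_fraction": params.pet_fraction,
            "seed": params.seed,
            "item_slopes": {f"{s}:{i}": v for (s, i), v in sorted(params.item_slopes.items())},
            "item_locations": {f"{s}:{i}": v for (s, i), v in sorted(params.item_locations.items())},
            "amyloid_effects": {f"{c}:{d}": v for (c, d), v in sorted(params.amyloid_effects.items())},
        },
        paths["truth_params"],
    )
    return paths


def run_aim1(
    responses: pd.DataFrame,
    taxonomy: ItemTaxonomy | None = None,
    config: AnalysisConfig | None = None,
    outdir: str | Path = "aim1_out",
) -> dict:
    """Full-cohort indices, condition differences and repeated-measures models."""
    taxonomy = taxonomy or default_taxonomy()
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = validate_dataset(responses, taxonomy=taxonomy)
    if report.taxonomy_gaps:
        raise ValueError(f"dataset validation failed: {report.summary()}")

    table = compute_index_table(responses, config=config)
    cross = average_over_visits(table)
    diffs = condition_differences(table)

    outputs = [
        _write_csv(table, outdir / "indices_by_visit.csv"),
        _write_csv(cross, outdir / "indices_cross_visit.csv"),
        _write_csv(diffs, outdir / "condition_differences.csv"),
    ]
    for by in ("story", "lexical_category", "serial_position"):
        outputs.append(_write_csv(aggregate_indices(table, by, taxonomy),
                                  outdir / f"aggregate_by_{by}.csv"))

    models = {}
    for response in ("difficulty", "discrimination"):
        change = condition_change_model(
            diffs, response="diff_difficulty" if response == "difficulty" else "diff_discrimination"
        )
        models[f"condition_change_{response}"] = change
        for condition in CONDITIONS:
            sub = table[table["condition"] == condition]
            fit = fit_index_model(sub, taxonomy, response=response, condition=condition)
            models[f"index_model_{response}_{condition}"] = fit
    report_obj = {name: m.to_report() for name, m in sorted(models.items())}
    outputs.append(_write_json(report_obj, outdir / "model_reports.json"))

    coef_rows = []
    for name, m in sorted(models.items()):
        for term, (est, lo, hi, p) in m.coefficients.items():
            coef_rows.append(
                {"model": name, "term": term, "estimate": est, "ci_low": lo, "ci_high": hi, "p": p}
            )
    outputs.append(_write_csv(pd.DataFrame(coef_rows), outdir / "model_coefficients.csv"))
    _manifest(outdir, config, {}, outputs)
    return {"index_table": table, "cross_visit": cross, "differences": diffs, "models": models,
            "validation": report, "outdir": outdir}


def run_aim2(
    responses: pd.DataFrame,
    participants: pd.DataFrame,
    taxonomy: ItemTaxonomy | None = None,
    config: AnalysisConfig | None = None,
    outdir: str | Path = "aim2_out",
) -> dict:
    """PET-matched amyloid-group indices and the full contrast suite."""
    taxonomy = taxonomy or default_taxonomy()
    config = config or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pet = participants.dropna(subset=["dvr"]).copy()
    if pet.empty:
        raise ValueError("no participant has a DVR value; Aim 2 requires a PET subset")
    pet["amyloid_status"] = [
        classify_amyloid(d, config.dvr_threshold) for d in pet["dvr"]
    ]
    sizes = pet["amyloid_status"].value_counts().to_dict()
    if len(sizes) < 2:
        only = next(iter(sizes))
        raise ValueError(f"all PET participants classify as {only}; contrast suite impossible")
    for status, n in sizes.items():
        if n < config.min_group_size:
            log.warning("amyloid %s group has only %d participants (< %d)",
                        status, n, config.min_group_size)

    # PET-matched visit per participant
    visit_dates = responses.groupby("participant_id").apply(
        lambda g: sorted(set(zip(g["visit"], g["visit_date"]))), include_groups=False
    )
    matched_rows = []
    for _, row in pet.iterrows():
        pid = row["participant_id"]
        if pid not in visit_dates.index:
            log.warning("PET participant %s has no recall data; skipped", pid)
            continue
        vd = visit_dates.loc[pid]
        if pd.isna(row["pet_date"]):
            visit = max(v for v, _ in vd)  # no scan date: use the latest assessment
        else:
            visit = select_lm_visit(vd, row["pet_date"], tie_break=config.tie_break)
        sub = responses[(responses["participant_id"] == pid) & (responses["visit"] == visit)]
        matched_rows.append(sub)
    matched = pd.concat(matched_rows, ignore_index=True)
    matched = matched.assign(visit=0)  # single pseudo-visit: the PET-matched one

    grouping = pet.set_index("participant_id")["amyloid_status"]
    table = compute_index_table(matched, grouping=grouping, config=config)
    suite = amyloid_contrast_suite(table, taxonomy, config=config)

    outputs = [
        _write_csv(table, outdir / "indices_by_amyloid_group.csv"),
        _write_csv(suite, outdir / "amyloid_contrasts.csv"),
        _write_csv(
            pd.DataFrame(
                [{"amyloid_status": k, "n": v} for k, v in sorted(sizes.items())]
            ),
            outdir / "group_sizes.csv",
        ),
    ]
    for by in ("story", "lexical_category", "serial_position"):
        outputs.append(_write_csv(aggregate_indices(table, by, taxonomy),
                                  outdir / f"aggregate_by_{by}.csv"))
    _manifest(outdir, config, {}, outputs)
    return {"index_table": table, "suite": suite, "group_sizes": sizes, "outdir": outdir}


def run_all(outdir: str | Path, seed: int = 0, n: int = 1141, visits: int = 7,
            config: AnalysisConfig | None = None) -> dict:
    """simulate + aim1 + aim2 composed into one output bundle."""
    outdir = Path(outdir)
    config = config or AnalysisConfig()
    sim_paths = run_simulate(outdir / "simulated", seed=seed, n=n, visits=visits)
    from .datamodel import read_participants, read_responses

    responses = read_responses(sim_paths["responses"])
    participants = read_participants(sim_paths["participants"])
    taxonomy = default_taxonomy()
    aim1 = run_aim1(responses, taxonomy, config, outdir / "aim1")
    aim2 = run_aim2(responses, participants, taxonomy, config, outdir / "aim2")
    return {"simulate": sim_paths, "aim1": aim1, "aim2": aim2, "outdir": outdir}
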