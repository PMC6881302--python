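"""End-to-end orchestration: simulate -> fit -> analyze -> report.

One top-level seed deterministically derives a seed per stage (cohort
generation, model fitting), so a (spec, config, priors, seed) quadruple
reproduces every number in the report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__
from .attitudes import build_attitude_design, fit_liking_model, simple_effects
from .behavior import build_stay_table, exclusion_filter, fit_stay_model
from .cohort import CohortSpec, generate_study
from .fitting import PriorSpec, fit_map
from .io import (
    fits_to_frame,
    sessions_from_trials,
    write_fits,
    write_trials,
)
from .task import TaskConfig, config_to_dict

__all__ = ["run_full_pipeline", "fit_cohort"]

logger = logging.getLogger("twostep_social")


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2)
    return {
        "cohort": int(children[0].generate_state(1)[0] % (2**31)),
        "fitting": int(children[1].generate_state(1)[0] % (2**31)),
    }


def fit_cohort(
    sessions: dict,
    priors: PriorSpec,
    config: TaskConfig,
    seed: int,
    n_restarts: int = 10,
) -> dict:
    """MAP-fit every session, each subject with its own derived seed."""
    fits = {}
    ss = np.random.SeedSequence(seed)
    subject_ids = sorted(sessions)
    for sid, child in zip(subject_ids, ss.spawn(len(subject_ids))):
        rng = np.random.default_rng(child)
        fits[sid] = fit_map(
            sessions[sid], priors, config, n_restarts=n_restarts, rng=rng,
            subject_id=sid,
        )
    return fits


def run_full_pipeline(
    spec: CohortSpec,
    config: TaskConfig,
    priors: Optional[PriorSpec] = None,
    seed: int = 0,
    out_dir: Optional[Union[str, Path]] = None,
    n_restarts: int = 10,
) -> dict:
    """Run the whole analysis and return (and optionally write) the report.

    Stages: synthetic-study generation, miss-rate exclusion, per-subject MAP
    fitting, parameter-recovery scoring against ground truth, the stay/switch
    mixed logistic regression, the liking mixed linear regression, and simple
    effects of model-free value at the 25th and 75th percentiles of fitted w.
    Intermediate CSVs and a JSON report are written when ``out_dir`` is set.
    """
    if priors is None:
        priors = PriorSpec()
    seeds = _stage_seeds(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.time()
    rng = np.random.default_rng(seeds["cohort"])
    trials, liking, agents = generate_study(spec, config, rng)
    timings["generate_study_s"] = round(time.time() - t0, 2)
    logger.info("generated %d subjects (%d trial rows)", spec.n_subjects, len(trials))
    if out is not None:
        write_trials(trials, out / "trials.csv")
        liking.to_csv(out / "liking.csv", index=False, lineterminator="\n")
        agents.to_csv(out / "agents.csv", index=False, lineterminator="\n")

    sessions = sessions_from_trials(trials)
    included, exclusion_report = exclusion_filter(sessions)
    logger.info(
        "exclusion: %d of %d subjects retained", len(included), len(sessions)
    )

    t0 = time.time()
    kept = {sid: sessions[sid] for sid in sorted(included)}
    fits = fit_cohort(kept, priors, config, seeds["fitting"], n_restarts)
    timings["fit_map_s"] = round(time.time() - t0, 2)
    if out is not None:
        write_fits(fits, out / "fits.csv")

    fits_frame = fits_to_frame(fits)
    truth = agents[agents["subject_id"].isin(included)]
    merged = truth.merge(fits_frame, on="subject_id", suffixes=("_true", "_hat"))
    recovery = {}
    for name in ("alpha", "beta", "lam", "w", "pi"):
        t = merged[f"{name}_true"].to_numpy()
        e = merged[f"{name}_hat"].to_numpy()
        recovery[name] = {
            "corr": float(np.corrcoef(t, e)[0, 1]) if np.std(t) > 0 else None,
            "bias": float(np.mean(e - t)),
            "rmse": float(np.sqrt(np.mean((e - t) ** 2))),
        }

    t0 = time.time()
    stay_table = build_stay_table(sessions)
    stay_result = fit_stay_model(stay_table)
    timings["stay_model_s"] = round(time.time() - t0, 2)
    logger.info("stay model: %s (converged=%s)", stay_result.method, stay_result.converged)
    if out is not None:
        stay_table.to_csv(out / "stay_table.csv", index=False, lineterminator="\n")
        (out / "stay_model.json").write_text(
            json.dumps(stay_result.to_dict(), indent=2) + "\n"
        )

    t0 = time.time()
    liking_kept = liking[liking["subject_id"].isin(included)]
    design = build_attitude_design(fits, liking_kept)
    attitude_result = fit_liking_model(design)
    se_low = simple_effects(design, percentile=0.25)
    se_high = simple_effects(design, percentile=0.75)
    timings["attitude_model_s"] = round(time.time() - t0, 2)
    if out is not None:
        (out / "attitude_model.json").write_text(
            json.dumps(attitude_result.to_dict(), indent=2) + "\n"
        )

    report = {
        "software_version": __version__,
        "seed": seed,
        "stage_seeds": seeds,
        "task_config": config_to_dict(config),
        "cohort": {
            "n_subjects": spec.n_subjects,
            "miss_rate": spec.miss_rate,
        },
        "exclusion": {
            "n_included": len(included),
            "n_excluded": int(exclusion_report["excluded"].sum()),
            "excluded_subjects": sorted(
                exclusion_report.index[exclusion_report["excluded"]].tolist()
            ),
            "miss_rates": exclusion_report["miss_rate"].round(4).to_dict(),
        },
        "recovery": recovery,
        "stay_model": stay_result.to_dict(),
        "attitude_model": attitude_result.to_dict(),
        "simple_effects": {
            "mf_at_w_p25": {k: v for k, v in se_low.items() if k != "result"},
            "mf_at_w_p75": {k: v for k, v in se_high.items() if k != "result"},
        },
        "timings": timings,
    }
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
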