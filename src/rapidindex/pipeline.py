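"""End-to-end pipeline: simulate -> filter -> train -> score -> evaluate.

Wires the whole package into one reproducible run: generate a synthetic
training cohort, train the index model on stable sessions, score a
case-control cohort with both the surprise index and the PEW score, and
produce the session-level accuracy comparison.  Every numeric artifact
is a deterministic function of the run configuration and its seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alerting import RapidConfig, compute_rapid_index, generate_alerts, train_rapid
from .evaluation import (
    EvaluationConfig,
    accuracy,
    classify_sessions,
    compare_paired,
    warning_times,
)
from .pews import PewsScoringTable, compute_pews
from .synthetic import generate_cohort, nurse_observations
from .vitals import ValidityConfig, filter_session

log = logging.getLogger("rapidindex")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    The demo defaults (12 training sessions, 6 cases / 6 controls,
    10-20 h sessions) complete in minutes on one CPU; study-scale runs
    only change these numbers.
    """

    seed: int = 0
    n_training_sessions: int = 12
    n_cases: int = 6
    n_controls: int = 6
    training_duration_minutes: int = 720
    eval_duration_minutes: int = 900
    onset_gap_median_minutes: int = 480
    pews_interval_minutes: int = 60
    min_training_duration_minutes: int = 240
    validity: ValidityConfig = field(default_factory=ValidityConfig)
    rapid: RapidConfig = field(default_factory=RapidConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "validity" in kwargs:
            kwargs["validity"] = ValidityConfig(**kwargs["validity"])
        if "rapid" in kwargs:
            kwargs["rapid"] = RapidConfig(**kwargs["rapid"])
        if "evaluation" in kwargs:
            kwargs["evaluation"] = EvaluationConfig(**kwargs["evaluation"])
        return cls(**kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 — re-raise with stage name
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def _estimates_dict(est) -> dict:
    pct = lambda v: round(100 * v, 1)
    return {
        "sensitivity_pct": pct(est.sensitivity),
        "sensitivity_ci_pct": [pct(v) for v in est.sensitivity_ci],
        "specificity_pct": pct(est.specificity),
        "specificity_ci_pct": [pct(v) for v in est.specificity_ci],
        "ppv_pct": pct(est.ppv),
        "ppv_ci_pct": [pct(v) for v in est.ppv_ci],
        "npv_pct": pct(est.npv),
        "npv_ci_pct": [pct(v) for v in est.npv_ci],
        "prevalence": est.prevalence,
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline; write artifacts under ``outdir``; return results.

    Artifacts: ``map.json`` (trained projection), per-session index CSVs
    under ``index/``, ``alerts.csv``, ``events.csv``, ``results.json``
    and ``run.log``.  Rerunning with the same config and seed reproduces
    identical numeric outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


@_stage("simulate-training")
def _simulate_training(config: RunConfig):
    gen, _ = generate_cohort(
        config.n_training_sessions,
        0,
        seed=config.seed,
        duration_minutes=config.training_duration_minutes,
        full=True,
    )
    return gen


@_stage("train")
def _train(config: RunConfig, training_sessions):
    # training exclusions: sessions longer than 4 h, no recorded deterioration
    eligible = [
        g.session
        for g in training_sessions
        if g.session.intended_minutes > config.min_training_duration_minutes
        and not g.session.annotations
    ]
    log.info("training on %d/%d eligible sessions", len(eligible), len(training_sessions))
    if not eligible:
        raise ValueError("no eligible training sessions")
    return train_rapid(eligible, config.rapid, seed=config.seed, validity=config.validity)


@_stage("simulate-eval")
def _simulate_eval(config: RunConfig):
    return generate_cohort(
        config.n_controls,
        config.n_cases,
        seed=config.seed + 1,
        duration_minutes=config.eval_duration_minutes,
        onset_gap_median_minutes=config.onset_gap_median_minutes,
        full=True,
    )


@_stage("score")
def _score(config: RunConfig, model, cohort, outdir: Path):
    (outdir / "index").mkdir(exist_ok=True)
    rapid_alerts: dict[str, list[int]] = {}
    alert_rows = []
    for g in cohort:
        series = compute_rapid_index(g.session, model, validity=config.validity)
        series.frame.to_csv(outdir / "index" / f"{g.session.session_id}.csv")
        events = generate_alerts(series)
        rapid_alerts[g.session.session_id] = [e.start_minute for e in events]
        alert_rows += [
            {
                "session_id": e.session_id,
                "start_minute": e.start_minute,
                "end_minute": e.end_minute,
                "peak_index": e.peak_index,
            }
            for e in events
        ]
    import pandas as pd

    pd.DataFrame(
        alert_rows, columns=["session_id", "start_minute", "end_minute", "peak_index"]
    ).to_csv(outdir / "alerts.csv", index=False)
    return rapid_alerts


@_stage("pews")
def _pews(config: RunConfig, cohort):
    table = PewsScoringTable()
    pew_alerts: dict[str, list[int]] = {}
    for i, g in enumerate(cohort):
        obs = nurse_observations(
            g, every_minutes=config.pews_interval_minutes, seed=config.seed + 100 + i
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pew_alerts[g.session.session_id] = [
                o.timestamp
                for o in obs
                if compute_pews(o, table, g.session.patient_age_months) >= table.alert_threshold
            ]
    return pew_alerts


@_stage("evaluate")
def _evaluate(config: RunConfig, cohort, events, rapid_alerts, pew_alerts):
    case_ids = list(events["session_id"])
    control_ids = [g.session.session_id for g in cohort if g.session.session_id not in case_ids]
    event_minutes = dict(zip(events["session_id"], events["event_minute"]))

    results: dict = {"n_cases": len(case_ids), "n_controls": len(control_ids)}
    for name, alerts in (("pews", pew_alerts), ("rapid", rapid_alerts)):
        per_method: dict = {}
        for hours in (24.0, config.evaluation.detection_window_hours):
            cfg = dataclasses.replace(config.evaluation, detection_window_hours=hours)
            table = classify_sessions(
                {sid: alerts.get(sid, []) for sid in case_ids},
                {sid: alerts.get(sid, []) for sid in control_ids},
                event_minutes,
                cfg,
            )
            est = accuracy(table, cfg)
            per_method[f"window_{int(hours)}h"] = {
                "contingency": {"tp": table.tp, "fn": table.fn, "fp": table.fp, "tn": table.tn},
                **_estimates_dict(est),
                "warning_times_hours": dataclasses.asdict(
                    warning_times({sid: alerts.get(sid, []) for sid in case_ids}, event_minutes, cfg)
                ),
            }
        per_method["total_alerts"] = sum(len(v) for v in alerts.values())
        results[name] = per_method

    cfg = config.evaluation
    window = cfg.detection_window_hours * 60
    case_flags = {
        name: np.array(
            [
                any(
                    event_minutes[sid] - window <= a <= event_minutes[sid]
                    for a in alerts.get(sid, [])
                )
                for sid in case_ids
            ]
        )
        for name, alerts in (("pews", pew_alerts), ("rapid", rapid_alerts))
    }
    control_flags = {
        name: np.array([not alerts.get(sid, []) for sid in control_ids])
        for name, alerts in (("pews", pew_alerts), ("rapid", rapid_alerts))
    }
    sens_cmp = compare_paired(case_flags["pews"], case_flags["rapid"])
    spec_cmp = compare_paired(control_flags["pews"], control_flags["rapid"])
    results["comparison"] = {
        "sensitivity_difference_pct": round(100 * sens_cmp.difference, 1),
        "sensitivity_mcnemar_p": sens_cmp.p_value,
        "specificity_difference_pct": round(100 * spec_cmp.difference, 1),
        "specificity_mcnemar_p": spec_cmp.p_value,
    }
    return results


def _run(config: RunConfig, outdir: Path) -> dict:
    log.info("rapidindex %s, seed %d", __version__, config.seed)
    training = _simulate_training(config)
    model = _train(config, training)
    model.nsmap.to_json(outdir / "map.json")
    log.info(
        "trained: %d models, stress %.4g, threshold %.3f",
        len(model.nsmap.training_projections),
        model.nsmap.stress,
        model.threshold if model.threshold is not None else float("nan"),
    )
    cohort, events = _simulate_eval(config)
    events.to_csv(outdir / "events.csv", index=False)
    rapid_alerts = _score(config, model, cohort, outdir)
    pew_alerts = _pews(config, cohort)
    results = _evaluate(config, cohort, events, rapid_alerts, pew_alerts)
    results["seed"] = config.seed
    results["threshold"] = model.threshold
    results["neuroscale_stress"] = model.nsmap.stress
    (outdir / "results.json").write_text(json.dumps(results, indent=1, sort_keys=True))
    log.info("done")
    return results
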