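"""End-to-end study orchestration.

``run_full_study`` executes the repeated train/validation protocol on
synthetic data: each round draws a fresh leakage-safe well split of
Datasets A and B, runs the calibration stages 1-6 on the training wells,
predicts the validation wells from initial conditions only (step 7), and
scores the four ML baselines on the identical splits with the identical
R^2 implementation.  Summaries cover both sides of the comparison: calibration
and prediction error tables (mean +/- 95% CI over wells) and a model
comparison table of R^2 scores with ANOVA and Bonferroni-corrected
pairwise tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import calibrate, metrics, ml
from .datasets import Dataset, DesignSpec, TruthParams, generate_dataset
from .model import GlobalParams, InhibitionParams, TimeCourse

__all__ = ["StudyConfig", "MechanismPredictor", "run_full_study"]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Everything needed to reproduce one study run bit-for-bit."""

    design_a: DesignSpec = field(default_factory=DesignSpec.dataset_a)
    design_b: DesignSpec = field(default_factory=DesignSpec.dataset_b)
    truth: TruthParams = field(default_factory=TruthParams)
    rounds: int = 50
    train_frac: float = 0.75
    models: Sequence[str] = ml.MODEL_NAMES
    seed: int = 0
    fit_rtol: float = 1e-6
    outdir: Path | None = None

    def config_hash(self) -> str:
        payload = json.dumps({
            "design_a": repr(self.design_a), "design_b": repr(self.design_b),
            "truth": repr(self.truth), "rounds": self.rounds,
            "train_frac": self.train_frac, "models": list(self.models),
            "seed": self.seed, "fit_rtol": self.fit_rtol,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


class MechanismPredictor:
    """Mechanism-based model wrapped for the ML comparison harness.

    ``fit`` runs calibration stages 1-6 on the training wells; ``score``
    predicts each requested well from its initial conditions (step 7) and
    returns the same R^2 structure as the ML models, so the comparison is
    split-for-split and metric-for-metric identical.
    """

    def __init__(self, base: GlobalParams | None = None, rtol: float = 1e-6):
        self.base = base or GlobalParams()
        self.rtol = rtol
        self.globals_: GlobalParams | None = None
        self.relation = None
        self.inhibition: InhibitionParams | None = None
        self.stage_results: dict = {}

    def fit(self, data_a: Dataset, data_b: Dataset) -> "MechanismPredictor":
        step1 = calibrate.fit_dataset_a(data_a, base=self.base, rtol=self.rtol, compute_ci=False)
        g = step1.globals_
        fitted = GlobalParams(k_p=g["k_p"], k_d=g["k_d"], v=g["v"], theta=self.base.theta,
                              G_star=self.base.G_star, G_min=self.base.G_min)
        g0 = np.array([data_a.well(i).G0 for i in step1.local_kbys])
        step2 = calibrate.fit_kbys_relation(g0, np.array(list(step1.local_kbys.values())))
        step4 = calibrate.fit_gin_constrained(data_b, fitted, step2.relation, rtol=self.rtol)
        step5 = calibrate.fit_gin_and_local_kbys(
            data_b, fitted, {d: f.ci for d, f in step4.items()}, rtol=self.rtol, compute_ci=False)
        gin_by_dose = step5.diagnostics["gin"]
        g_acs0 = calibrate.accessible_initial_glucose(data_b, fitted, gin_by_dose)
        g_tot0 = {w.well_id: w.G0 for w in data_b.wells}
        step6 = calibrate.refit_relation_accessible(
            step5.local_kbys, g_tot0, {k: g_acs0[k] for k in step5.local_kbys}, step2.relation)
        self.globals_ = fitted
        self.relation = step6.relation
        self.inhibition = InhibitionParams({0.0: 0.0, **{d: v for d, v in gin_by_dose.items() if d > 0}})
        self.stage_results = {"step1": step1, "step2": step2, "step4": step4,
                              "step5": step5, "step6": step6}
        return self

    def predict_course(self, well, time_grid) -> TimeCourse:
        sim = calibrate.predict(well, self.globals_, self.relation, self.inhibition,
                                time_grid, rtol=1e-8)
        return sim.course

    def score(self, dataset: Dataset, well_ids: Sequence[str]) -> dict:
        obs_live, obs_dead, pred_live, pred_dead = [], [], [], []
        per_well_metrics = []
        for wid in well_ids:
            well = dataset.well(wid)
            tc = dataset.courses[wid]
            course = self.predict_course(well, tc.times)
            obs_live.append(tc.live)
            obs_dead.append(tc.dead)
            pred_live.append(course.live)
            pred_dead.append(course.dead)
            per_well_metrics.append(metrics.error_metrics(course, tc))
        obs_live = np.concatenate(obs_live) / 100.0
        obs_dead = np.concatenate(obs_dead) / 100.0
        pred_live = np.concatenate(pred_live) / 100.0
        pred_dead = np.concatenate(pred_dead) / 100.0
        return {
            "live": metrics.r_squared(pred_live, obs_live),
            "dead": metrics.r_squared(pred_dead, obs_dead),
            "total": metrics.r_squared(np.concatenate([pred_live, pred_dead]),
                                       np.concatenate([obs_live, obs_dead])),
            "error_metrics": per_well_metrics,
        }


def _round_seed(seed0: int, round_idx: int) -> int:
    return int((seed0 + 7919 * round_idx) % (2**31 - 1))


def run_full_study(config: StudyConfig) -> dict:
    """Run the repeated calibration/validation/prediction protocol.

    Returns a report bundle with per-round scores, summary tables, the
    calibration/prediction error tables, model-comparison statistics and
    per-round diagnostics; optionally writes everything to
    ``config.outdir`` as CSV/JSON stamped with the config hash and seed.
    """
    t0 = time.time()
    data_a = generate_dataset(config.design_a, config.truth, seed=_round_seed(config.seed, 991))
    data_b = generate_dataset(config.design_b, config.truth, seed=_round_seed(config.seed, 992))
    combined = Dataset(
        wells=data_a.wells + data_b.wells,
        courses={**data_a.courses, **data_b.courses},
        time_grid=data_a.time_grid,
        seed=config.seed, truth=config.truth,
        true_kbys={**data_a.true_kbys, **data_b.true_kbys},
    )
    table = ml.build_feature_table(combined)

    score_rows = []
    train_err, valid_err = [], []
    failures = []
    timings = []
    for r in range(config.rounds):
        seed_r = _round_seed(config.seed, r)
        t_round = time.time()
        try:
            train_ids, valid_ids = ml.split_by_well(combined, config.train_frac, seed_r)
            train_set = set(train_ids)
            a_train = data_a.subset([i for i in train_set if combined.well(i).dataset_tag == "A"])
            b_train = data_b.subset([i for i in train_set if combined.well(i).dataset_tag == "B"])

            mech = MechanismPredictor(base=config.truth.globals_, rtol=config.fit_rtol)
            mech.fit(a_train, b_train)
            mech_train = mech.score(combined, sorted(train_set))
            mech_valid = mech.score(combined, sorted(valid_ids))
            train_err.extend(mech_train.pop("error_metrics"))
            valid_err.extend(mech_valid.pop("error_metrics"))
            for split, res in (("train", mech_train), ("valid", mech_valid)):
                for target in ("live", "dead", "total"):
                    score_rows.append({"round": r, "model": "mechanism", "split": split,
                                       "target": target, "r2": res[target]})

            for name in config.models:
                res = ml.train_and_score(name, table, train_ids, valid_ids, seed=seed_r)
                for split in ("train", "valid"):
                    for target, score in res[split].items():
                        score_rows.append({"round": r, "model": name, "split": split,
                                           "target": target, "r2": score})
            logger.info("round %d done in %.1f s", r, time.time() - t_round)
        except Exception as exc:  # noqa: BLE001 - a failed round is reported, not fatal
            logger.exception("round %d failed", r)
            failures.append({"round": r, "error": f"{type(exc).__name__}: {exc}"})
        timings.append(time.time() - t_round)

    per_round = pd.DataFrame(score_rows)
    summary = (
        per_round.groupby(["model", "split", "target"])["r2"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    from scipy import stats as _st
    summary["ci_half"] = _st.t.ppf(0.975, np.maximum(summary["n"] - 1, 1)) \
        * summary["sd"] / np.sqrt(summary["n"])

    comparison = None
    valid_total = per_round[(per_round["split"] == "valid") & (per_round["target"] == "total")]
    groups = {m: g["r2"].to_numpy() for m, g in valid_total.groupby("model")}
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        f, p = metrics.anova_oneway(*groups.values())
        comparison = {"anova_F": f, "anova_p": p,
                      "pairwise": metrics.pairwise_comparisons(groups)}

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "per_round": per_round,
        "summary": summary,
        "calibration_errors": metrics.summarize_metrics(train_err) if train_err else None,
        "prediction_errors": metrics.summarize_metrics(valid_err) if valid_err else None,
        "comparison": comparison,
        "failures": failures,
        "timings_s": timings,
        "elapsed_s": time.time() - t0,
    }
    if config.outdir is not None:
        _write_report(config, report)
    return report


def _write_report(config: StudyConfig, report: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": report["config_hash"], "seed": report["seed"],
             "rounds": config.rounds, "failures": report["failures"],
             "elapsed_s": report["elapsed_s"]}
    (outdir / "run.json").write_text(json.dumps(stamp, indent=2))
    report["per_round"].to_csv(outdir / "scores_per_round.csv", index=False)
    report["summary"].to_csv(outdir / "scores_summary.csv", index=False)
    if report["calibration_errors"] is not None:
        report["calibration_errors"].to_csv(outdir / "calibration_errors.csv")
    if report["prediction_errors"] is not None:
        report["prediction_errors"].to_csv(outdir / "prediction_errors.csv")
    if report["comparison"] is not None:
        report["comparison"]["pairwise"].to_csv(outdir / "pairwise_comparisons.csv", index=False)
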