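"""Machine-learning baselines on the five measurable features.

Each (well, time point) row carries exactly five features — initial live
confluence, initial dead confluence, initial glucose (mM), inhibitor dose
(uM), and measurement time (days) — and two targets, the live and dead
confluences at that time, normalized by the carrying capacity to [0, 1].
No further feature engineering is applied.

Splitting is leakage-safe at the well level: every time point of a well
lands on the same side, and the split is drawn separately within each
dataset tag (A and B) so both designs are represented in both sets.  The
default 75/25 split of the 120 + 180-well designs gives 90/30 and 135/45
wells, i.e. 225 training and 75 validation wells.

Four regressors are compared at library defaults (no tuning): multivariate
linear regression, inverse-distance-weighted k-nearest-neighbor, a single
decision tree, and a random forest, each fitted per target.
"""

from __future__ import annotations

import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor

from .datasets import Dataset
from .metrics import r_squared

__all__ = [
    "FEATURES",
    "TARGETS",
    "MODEL_NAMES",
    "build_feature_table",
    "split_by_well",
    "make_model",
    "train_and_score",
    "repeated_evaluation",
    "learning_curve",
]

FEATURES = ["n0_confluence", "d0_confluence", "g0_mM", "dose_uM", "time_days"]
TARGETS = ["live", "dead"]
MODEL_NAMES = ("linear", "knn", "tree", "forest")


def build_feature_table(dataset: Dataset) -> pd.DataFrame:
    """One row per (well, time point) with 5 features and 2 targets."""
    frames = []
    for well in dataset.wells:
        tc = dataset.courses[well.well_id]
        frames.append(pd.DataFrame({
            "well_id": well.well_id,
            "dataset_tag": well.dataset_tag,
            "n0_confluence": well.initial_confluence,
            "d0_confluence": well.initial_dead_confluence,
            "g0_mM": well.G0,
            "dose_uM": well.dose,
            "time_days": tc.times,
            "live": tc.live / 100.0,
            "dead": tc.dead / 100.0,
        }))
    df = pd.concat(frames, ignore_index=True)
    n_bad = int(df[FEATURES + TARGETS].isna().any(axis=1).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} rows with missing values", stacklevel=2)
        df = df.dropna(subset=FEATURES + TARGETS).reset_index(drop=True)
    return df


def split_by_well(dataset: Dataset, train_frac: float = 0.75, seed: int = 0
                  ) -> tuple[list[str], list[str]]:
    """Leakage-safe random split of well ids, stratified by dataset tag."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    valid: list[str] = []
    tags = sorted({w.dataset_tag for w in dataset.wells})
    for tag in tags:
        ids = [w.well_id for w in dataset.wells if w.dataset_tag == tag]
        perm = rng.permutation(len(ids))
        n_train = int(round(train_frac * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[i] for i in perm[:n_train])
        valid.extend(ids[i] for i in perm[n_train:])
    return train, valid


def make_model(name: str, seed: int | None = 0):
    """Instantiate one baseline regressor at documented defaults."""
    if name == "linear":
        return LinearRegression()
    if name == "knn":
        return KNeighborsRegressor(weights="distance")
    if name == "tree":
        return DecisionTreeRegressor(random_state=seed)
    if name == "forest":
        return RandomForestRegressor(random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")


def _score_split(df: pd.DataFrame, preds: Mapping[str, np.ndarray]) -> dict[str, float]:
    scores = {}
    for target in TARGETS:
        obs = df[target].to_numpy()
        if np.std(obs) == 0:
            warnings.warn(f"zero-variance target {target!r}; R^2 undefined", stacklevel=2)
            scores[target] = np.nan
            continue
        scores[target] = r_squared(preds[target], obs)
    both_obs = np.concatenate([df[t].to_numpy() for t in TARGETS])
    both_pred = np.concatenate([np.asarray(preds[t]) for t in TARGETS])
    scores["total"] = r_squared(both_pred, both_obs) if np.std(both_obs) > 0 else np.nan
    return scores


def train_and_score(
    model_name: str,
    table: pd.DataFrame,
    train_ids: Sequence[str],
    valid_ids: Sequence[str],
    seed: int | None = 0,
) -> dict:
    """Fit one model on the training wells and score R^2 on both sides.

    Returns train/valid scores (live, dead, total) plus the validation
    predictions.
    """
    train_ids = set(train_ids)
    valid_ids = set(valid_ids)
    if train_ids & valid_ids:
        raise ValueError("train and validation wells overlap")
    train_df = table[table["well_id"].isin(train_ids)]
    valid_df = table[table["well_id"].isin(valid_ids)]
    if train_df.empty or valid_df.empty:
        raise ValueError("empty train or validation split")
    X_train = train_df[FEATURES].to_numpy()
    X_valid = valid_df[FEATURES].to_numpy()
    preds_train: dict[str, np.ndarray] = {}
    preds_valid: dict[str, np.ndarray] = {}
    for target in TARGETS:  # one model per target, as scores are reported per channel
        est = make_model(model_name, seed)
        est.fit(X_train, train_df[target].to_numpy())
        preds_train[target] = est.predict(X_train)
        preds_valid[target] = est.predict(X_valid)
    predictions = valid_df[["well_id", "time_days"]].copy()
    predictions["live_pred"] = preds_valid["live"]
    predictions["dead_pred"] = preds_valid["dead"]
    return {
        "model": model_name,
        "train": _score_split(train_df, preds_train),
        "valid": _score_split(valid_df, preds_valid),
        "predictions": predictions,
    }


def _round_seed(seed0: int, round_idx: int) -> int:
    # deterministic per-round seed; large prime stride keeps streams apart
    return int((seed0 + 7919 * round_idx) % (2**31 - 1))


def repeated_evaluation(
    dataset: Dataset,
    models: Sequence[str] = MODEL_NAMES,
    rounds: int = 50,
    seed0: int = 0,
    train_frac: float = 0.75,
    extra_predictors: Mapping[str, Callable[[Sequence[str], Sequence[str]], dict]] | None = None,
) -> dict:
    """Repeat the split/train/score protocol and summarize mean +/- 95% CI.

    ``extra_predictors`` lets a mechanism-based predictor join the same
    harness: a callable receiving (train_ids, valid_ids) and returning the
    same score structure as :func:`train_and_score`.
    """
    if rounds < 2:
        raise ValueError("need >= 2 rounds for a confidence interval")
    table = build_feature_table(dataset)
    rows = []
    for r in range(rounds):
        seed_r = _round_seed(seed0, r)
        train_ids, valid_ids = split_by_well(dataset, train_frac, seed_r)
        assert not set(train_ids) & set(valid_ids)
        for name in models:
            res = train_and_score(name, table, train_ids, valid_ids, seed=seed_r)
            for split in ("train", "valid"):
                for target, score in res[split].items():
                    rows.append({"round": r, "model": name, "split": split,
                                 "target": target, "r2": score})
        for name, fn in (extra_predictors or {}).items():
            res = fn(train_ids, valid_ids)
            for split in ("train", "valid"):
                for target, score in res.get(split, {}).items():
                    rows.append({"round": r, "model": name, "split": split,
                                 "target": target, "r2": score})
    per_round = pd.DataFrame(rows)
    summary = (
        per_round.groupby(["model", "split", "target"])["r2"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )
    from scipy import stats as _st
    summary["ci_half"] = _st.t.ppf(0.975, summary["n"] - 1) * summary["sd"] / np.sqrt(summary["n"])
    return {"per_round": per_round, "summary": summary}


def learning_curve(
    model_name: str,
    dataset: Dataset,
    fractions: Sequence[float] | None = None,
    rounds: int = 50,
    seed0: int = 0,
    train_frac: float = 0.75,
) -> pd.DataFrame:
    """Scores vs training-set size, subsampled at the well level.

    For each round the usual well split is drawn, then the training wells
    are subsampled to each fraction (5%..100% by default).  At fraction
    1.0 the scores coincide with :func:`repeated_evaluation` under the
    same seeds.
    """
    if fractions is None:
        fractions = np.arange(1, 21) * 0.05
    fractions = [float(f) for f in fractions]
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    table = build_feature_table(dataset)
    rows = []
    for r in range(rounds):
        seed_r = _round_seed(seed0, r)
        train_ids, valid_ids = split_by_well(dataset, train_frac, seed_r)
        rng = np.random.default_rng(seed_r + 1)
        order = rng.permutation(len(train_ids))
        for frac in fractions:
            n = int(round(frac * len(train_ids)))
            if n == 0:
                warnings.warn(f"fraction {frac} selects 0 wells; skipped", stacklevel=2)
                continue
            sub = [train_ids[i] for i in order[:n]] if frac < 1.0 else list(train_ids)
            res = train_and_score(model_name, table, sub, valid_ids, seed=seed_r)
            rows.append({"round": r, "fraction": frac, "n_train_wells": len(sub),
                         "r2_train": res["train"]["total"], "r2_valid": res["valid"]["total"]})
    return pd.DataFrame(rows)
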