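"""Shared test utilities: independent oracles and scenario runners.

The oracles deliberately re-derive results by brute force (pair
enumeration, day-by-window enumeration, exhaustive grid re-evaluation)
so they stay independent of the library code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import StratifiedKFold

from driftgbm import evaluation, features, sampler, synthetic, transfer

# ---------------------------------------------------------------------------
# brute-force oracles


def auroc_pair_oracle(scores, labels) -> float:
    """AUROC by exhaustive enumeration of positive-negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def kdigo_stage_oracle(
    pairs: list[tuple[int, float]], baseline: float, rrt_days: set[int]
) -> dict[int, int]:
    """Per-day KDIGO stage by direct enumeration of every day and
    every trailing 48-hour window pair."""
    lookup = dict(pairs)
    out: dict[int, int] = {}
    days = sorted({d for d, _ in pairs if d >= 0} | set(rrt_days))
    for d in days:
        stage = 3 if d in rrt_days else 0
        v = lookup.get(d)
        if v is not None:
            ratio = v / baseline
            rise = max(
                (v - lookup[e] for e in range(d - 2, d + 1) if e in lookup),
                default=0.0,
            )
            if ratio >= 3.0:
                stage = max(stage, 3)
            if v >= 4.0 and rise >= 0.3:
                stage = max(stage, 3)
            if ratio >= 2.0:
                stage = max(stage, 2)
            if ratio >= 1.5 or rise >= 0.3:
                stage = max(stage, 1)
        if stage:
            out[d] = stage
    return out


def random_scr_series(rng: np.random.Generator):
    """A random small SCr series plus baseline and RRT days."""
    n_days = int(rng.integers(2, 8))
    days = sorted(rng.choice(np.arange(0, 10), size=n_days, replace=False))
    if 0 not in days:
        days = [0] + days
    values = np.round(rng.uniform(0.4, 5.0, size=len(days)), 3)
    pairs = list(zip([int(d) for d in days], [float(v) for v in values]))
    baseline = float(np.round(rng.uniform(0.5, 2.0), 3))
    rrt = set(
        int(d) for d in rng.choice(np.arange(0, 10), size=int(rng.integers(0, 2)))
    )
    return pairs, baseline, rrt


def cv_selection_oracle(
    X: pd.DataFrame,
    y: np.ndarray,
    candidates,
    seed: int,
    cv: int,
    max_rounds: int,
) -> int:
    """Index of the grid point with the best mean CV AUROC, recomputed
    from scratch with xgboost."""
    means = []
    for hp in candidates:
        folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        scores = []
        for tr, va in folds.split(X, y):
            booster = xgb.train(
                {
                    "max_depth": hp.tree_depth,
                    "eta": hp.learning_rate,
                    "min_child_weight": hp.min_child_weight,
                    "objective": "binary:logistic",
                    "eval_metric": "auc",
                    "seed": seed,
                    "nthread": 1,
                    "tree_method": "hist",
                },
                xgb.DMatrix(
                    X.iloc[tr].to_numpy(float), label=y[tr], missing=np.nan,
                    feature_names=list(X.columns),
                ),
                num_boost_round=max_rounds,
                evals=[
                    (
                        xgb.DMatrix(
                            X.iloc[va].to_numpy(float), label=y[va], missing=np.nan,
                            feature_names=list(X.columns),
                        ),
                        "val",
                    )
                ],
                early_stopping_rounds=hp.early_stopping_rounds,
                verbose_eval=False,
            )
            scores.append(float(booster.best_score))
        means.append(float(np.mean(scores)))
    return int(np.argmax(means))


# ---------------------------------------------------------------------------
# scenario runners for the stochastic drift regimes

FIXED_HP = transfer.GbmHyperparams(tree_depth=3, learning_rate=0.1, min_child_weight=1)


def toy_matrix(X: pd.DataFrame, y) -> sampler.SampleMatrix:
    """Wrap a plain (X, y) pair as a one-window-per-row SampleMatrix."""
    y = np.asarray(y)
    meta = pd.DataFrame(
        {
            "encounter_id": [f"e{i}" for i in range(len(X))],
            "t": 1,
            "cutoff_day": 0,
            "role": np.where(y == 1, sampler.ROLE_POSITIVE, sampler.ROLE_NEGATIVE),
            "exclusion_reason": None,
        }
    )
    audit = pd.DataFrame(columns=["encounter_id", "n_pos", "n_neg", "n_excluded"])
    return sampler.SampleMatrix(
        X=X, y=y, meta=meta, audit=audit, task=sampler.TaskSpec(1, delta_t=1)
    )


def run_strategies(
    seed: int,
    years: tuple[int, ...] = (2010, 2011, 2017),
    n_per_year: int = 1500,
    fraction: float = 1.0,
    drift_kwargs: dict | None = None,
) -> dict:
    """Fit all four strategies on one simulated source->target scenario.

    Source = pooled first two years' development sets; target = the
    last year.  Returns validation labels and per-strategy probability
    vectors.
    """
    cfg = synthetic.drift_scenario(
        n_per_year=n_per_year, years=years, seed=seed, **(drift_kwargs or {})
    )
    task = sampler.TaskSpec.any_aki()
    src_dev = []
    for y in years[:2]:
        dev, _ = evaluation.split_cohort(
            synthetic.generate_cohort(cfg, y), task, 0.8, seed
        )
        src_dev.extend(dev)
    src_records = pd.concat([t.to_records() for t in src_dev], ignore_index=True)
    src_scheme = features.fit_scheme(src_records)
    src_matrix = sampler.assemble_matrix(src_dev, None, task, src_scheme)
    source_model, _, _ = transfer.fit_source(
        src_matrix, grid=[FIXED_HP], seed=seed, cv=3, scheme=src_scheme
    )

    target_year = years[-1]
    dev, val = evaluation.split_cohort(
        synthetic.generate_cohort(cfg, target_year), task, 0.8, seed
    )
    tgt_records = pd.concat([t.to_records() for t in dev], ignore_index=True)
    tgt_scheme = features.fit_scheme(tgt_records)
    split = features.split_features(src_scheme, tgt_scheme)
    dev_matrix = sampler.assemble_matrix(dev, None, task, tgt_scheme)
    val_matrix = sampler.assemble_matrix(val, None, task, tgt_scheme)
    if fraction < 1.0:
        idx = evaluation.subsample_nested(dev_matrix.y, fraction, seed=seed)
        dev_matrix = dev_matrix.subset(idx)
    bundle = transfer.fit_transfer(source_model, dev_matrix, split, tgt_scheme, seed=seed)
    X_val = val_matrix.X
    return {
        "y": val_matrix.y,
        "p": {
            "transported": bundle.predict_transported(X_val),
            "adapted": bundle.predict_adapted(X_val),
            "refitted": bundle.predict_refitted(X_val),
            "transfer": bundle.predict(X_val),
        },
        "bundle": bundle,
        "source_model": source_model,
        "val_matrix": val_matrix,
        "config": cfg,
    }


def run_trend(seed: int, n_per_year: int = 800, concept_drift_rate: float = 0.35):
    """Per-target-year AUROC gain of refitting under linear concept drift."""
    cfg = synthetic.drift_scenario(
        n_per_year=n_per_year, concept_drift_rate=concept_drift_rate, seed=seed
    )
    ec = evaluation.ExperimentConfig(
        cohort=cfg,
        tasks={"any": sampler.TaskSpec.any_aki()},
        fractions=(1.0,),
        n_bootstrap=100,
        grid=[FIXED_HP],
        cv_folds=3,
        strategies=("transported", "refitted"),
        seed=seed,
    )
    report = evaluation.run_experiment(ec)
    return report.delta.sort_values("target_year")
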