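"""Temporal-validation experiment harness.

Reproduces the study design around TransferGBM: a fixed source domain
pooled from the first two years, each later year an independent target
domain; stratified 80/20 development/validation splits; nested
training-fraction sweeps emulating gradual EHR accumulation; AUROC
with bootstrap confidence intervals; and the per-year AUROC gain of
internal validation (refitted) over temporal validation (transported),
which quantifies performance drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from driftgbm import features as _features
from driftgbm import sampler as _sampler
from driftgbm import transfer as _transfer
from driftgbm.synthetic import CohortConfig, EncounterTimeline, generate_cohort

__all__ = [
    "auroc",
    "bootstrap_ci",
    "delong_ci",
    "stratified_split",
    "subsample_nested",
    "split_cohort",
    "ExperimentConfig",
    "EvalReport",
    "run_experiment",
]


def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUROC with ties counted as 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_ci(
    scores, labels, B: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the AUROC.

    Resamples positives and negatives separately with replacement
    (stratified), so every resample contains both classes.  Returns
    ``(lower, upper, bootstrap_mean)``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("cannot stratify: a class is absent")
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    ones = np.ones(len(pos))
    zeros = np.zeros(len(neg))
    lab = np.concatenate([ones, zeros])
    for b in range(B):
        sp = pos[rng.integers(0, len(pos), len(pos))]
        sn = neg[rng.integers(0, len(neg), len(neg))]
        stats[b] = roc_auc_score(lab, np.concatenate([sp, sn]))
    lower, upper = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lower), float(upper), float(stats.mean())


def delong_ci(scores, labels, alpha: float = 0.05) -> tuple[float, float, float]:
    """Analytic (DeLong) AUROC confidence interval.

    Returns ``(lower, upper, point)`` using the structural-component
    variance estimator; offered as a deterministic alternative to the
    bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("AUROC undefined: labels contain a single class")
    # structural components via midranks
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    theta = v10.mean()
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = norm.ppf(1 - alpha / 2) * np.sqrt(var)
    return float(max(0.0, theta - half)), float(min(1.0, theta + half)), float(theta)


def stratified_split(
    labels: Sequence[int], frac: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified index split: (``frac`` development, rest validation).

    Label prevalence is preserved within rounding in both parts.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("frac must lie in (0, 1]")
    labels = np.asarray(labels)
    if len(labels) == 0:
        raise ValueError("cannot split empty samples")
    rng = np.random.default_rng(seed)
    dev_parts, val_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        k = int(round(frac * len(idx)))
        dev_parts.append(idx[:k])
        val_parts.append(idx[k:])
    return np.sort(np.concatenate(dev_parts)), np.sort(np.concatenate(val_parts))


def subsample_nested(
    labels: Sequence[int], fraction: float, seed: int = 0
) -> np.ndarray:
    """Stratified subsample without replacement, nested across fractions.

    For one seed the selected sets are prefixes of a fixed per-class
    shuffle, so the 25% subset is contained in the 50% subset and so
    on — emulating gradual data accumulation.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        k = max(1, int(round(fraction * len(idx))))
        parts.append(idx[:k])
    return np.sort(np.concatenate(parts))


def encounter_labels(cohort: Sequence[EncounterTimeline], task) -> np.ndarray:
    """Binary encounter-level task labels (reaches the stage threshold)."""
    trajectories = _sampler.label_cohort(cohort, task)
    return np.array(
        [int(task.stage_threshold in trajectories[t.encounter_id]) for t in cohort]
    )


def split_cohort(
    cohort: Sequence[EncounterTimeline], task, frac: float = 0.8, seed: int = 0
) -> tuple[list[EncounterTimeline], list[EncounterTimeline]]:
    """Encounter-level stratified development/validation split.

    Splitting whole encounters (not windows) keeps all windows of one
    stay on the same side, so no encounter leaks across the split.
    """
    y = encounter_labels(cohort, task)
    dev_idx, val_idx = stratified_split(y, frac, seed)
    return [cohort[i] for i in dev_idx], [cohort[i] for i in val_idx]


@dataclass
class ExperimentConfig:
    """Full grid of a temporal-validation experiment."""

    cohort: CohortConfig
    tasks: Mapping[str, _sampler.TaskSpec] = field(
        default_factory=lambda: {"any": _sampler.TaskSpec.any_aki()}
    )
    n_source_years: int = 2
    fractions: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
    dev_frac: float = 0.8
    n_bootstrap: int = 1000
    n_candidates: int = 8
    cv_folds: int = 5
    stacking_mode: str = "oof"
    stacking_folds: int = 5
    strategies: tuple[str, ...] = ("transported", "refitted", "transfer")
    grid: Sequence[_transfer.GbmHyperparams] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("training fractions must lie in (0, 1]")
        if len(self.cohort.years) <= self.n_source_years:
            raise ValueError("need at least one target year after the source years")
        known = {"transported", "refitted", "transfer", "adapted"}
        unknown = set(self.strategies) - known
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")

    @property
    def source_years(self) -> tuple[int, ...]:
        return self.cohort.years[: self.n_source_years]

    @property
    def target_years(self) -> tuple[int, ...]:
        return self.cohort.years[self.n_source_years:]


@dataclass
class EvalReport:
    """Results of one experiment run.

    ``results`` has one row per (task, target_year, fraction,
    strategy) with the AUROC point estimate, bootstrap CI and bootstrap
    mean; ``delta`` the per-year AUROC gain of refitted internal
    validation over transported temporal validation at full training
    fraction.
    """

    results: pd.DataFrame
    delta: pd.DataFrame

    def save(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.results.to_csv(outdir / "results.csv", index=False)
        self.delta.to_csv(outdir / "delta_auroc.csv", index=False)
        return outdir


def _evaluate(name, scores, y, B, seed, extra) -> dict:
    point = auroc(scores, y)
    lo, hi, boot_mean = bootstrap_ci(scores, y, B=B, seed=seed)
    return {
        "strategy": name,
        "auroc": point,
        "ci_lo": lo,
        "ci_hi": hi,
        "auroc_boot_mean": boot_mean,
        "n_val": len(y),
        "prevalence": float(np.mean(y)),
        **extra,
    }


def run_experiment(
    config: ExperimentConfig,
    cohorts: Mapping[int, Sequence[EncounterTimeline]] | None = None,
) -> EvalReport:
    """Execute the full temporal-validation grid.

    Fits one source model per task on the pooled source years, then for
    every (target year, training fraction) adapts, refits and stacks,
    and evaluates the transported, refitted and TransferGBM strategies
    on the target year's held-out validation windows.
    """
    cc = config.cohort
    if cohorts is None:
        cohorts = {y: generate_cohort(cc, y) for y in cc.years}
    else:
        missing = set(cc.years) - set(cohorts)
        if missing:
            raise ValueError(f"cohorts missing for years {sorted(missing)}")
    rows: list[dict] = []
    delta_rows: list[dict] = []
    for task_name, task in config.tasks.items():
        # --- source domain ------------------------------------------------
        src_dev: list[EncounterTimeline] = []
        for y in config.source_years:
            dev, _ = split_cohort(cohorts[y], task, config.dev_frac, config.seed)
            src_dev.extend(dev)
        src_records = pd.concat([t.to_records() for t in src_dev], ignore_index=True)
        src_scheme = _features.fit_scheme(src_records)
        src_matrix = _sampler.assemble_matrix(src_dev, None, task, src_scheme)
        source_model, hyperparams, _ = _transfer.fit_source(
            src_matrix,
            grid=config.grid,
            seed=config.seed,
            cv=config.cv_folds,
            n_candidates=config.n_candidates,
            scheme=src_scheme,
        )
        # --- target domains ----------------------------------------------
        for year in config.target_years:
            dev, val = split_cohort(cohorts[year], task, config.dev_frac, config.seed)
            tgt_records = pd.concat([t.to_records() for t in dev], ignore_index=True)
            tgt_scheme = _features.fit_scheme(tgt_records)
            split = _features.split_features(src_scheme, tgt_scheme)
            dev_matrix = _sampler.assemble_matrix(dev, None, task, tgt_scheme)
            val_matrix = _sampler.assemble_matrix(val, None, task, tgt_scheme)
            y_val = val_matrix.y
            p_trans = source_model.predict(
                _features.project_frame_to_common(val_matrix.X, split)
            )
            need_transfer = "transfer" in config.strategies
            need_adapted = "adapted" in config.strategies or need_transfer
            need_refitted = "refitted" in config.strategies or need_transfer
            for frac in config.fractions:
                idx = subsample_nested(dev_matrix.y, frac, seed=config.seed)
                sub = dev_matrix.subset(idx)
                preds: dict[str, np.ndarray] = {}
                if "transported" in config.strategies:
                    preds["transported"] = p_trans
                if need_transfer:
                    bundle = _transfer.fit_transfer(
                        source_model,
                        sub,
                        split,
                        target_scheme=tgt_scheme,
                        seed=config.seed,
                        stacking_mode=config.stacking_mode,
                        k_folds=config.stacking_folds,
                    )
                    preds["refitted"] = bundle.predict_refitted(val_matrix.X)
                    preds["adapted"] = bundle.predict_adapted(val_matrix.X)
                    preds["transfer"] = bundle.predict(val_matrix.X)
                else:
                    if need_adapted:
                        adapted = _transfer.adapt_source(
                            source_model, sub, split, seed=config.seed
                        )
                        preds["adapted"] = adapted.predict(
                            _features.project_frame_to_common(val_matrix.X, split)
                        )
                    if need_refitted:
                        refitted = _transfer.refit_target(
                            sub, source_model.hyperparams, split=split, seed=config.seed
                        )
                        preds["refitted"] = refitted.predict(val_matrix.X)
                extra = {"task": task_name, "target_year": year, "fraction": frac}
                for name in config.strategies:
                    rows.append(
                        _evaluate(
                            name, preds[name], y_val, config.n_bootstrap, config.seed, extra
                        )
                    )
                if frac == 1.0 and {"transported", "refitted"} <= set(preds):
                    delta_rows.append(
                        {
                            "task": task_name,
                            "target_year": year,
                            "delta_auroc": auroc(preds["refitted"], y_val)
                            - auroc(preds["transported"], y_val),
                        }
                    )
    results = pd.DataFrame(rows)[
        [
            "task", "target_year", "fraction", "strategy", "auroc",
            "ci_lo", "ci_hi", "auroc_boot_mean", "n_val", "prevalence",
        ]
    ]
    return EvalReport(results=results, delta=pd.DataFrame(delta_rows))


def plot_drift_curves(report: EvalReport, outdir: str | Path) -> list[Path]:
    """Write AUROC-vs-year curves per (task, fraction) as PNG artifacts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (task, frac), grp in report.results.groupby(["task", "fraction"]):
        fig, ax = plt.subplots(figsize=(6, 4))
        for strategy, sg in grp.groupby("strategy"):
            sg = sg.sort_values("target_year")
            ax.plot(sg["target_year"], sg["auroc"], marker="o", label=strategy)
            ax.fill_between(sg["target_year"], sg["ci_lo"], sg["ci_hi"], alpha=0.15)
        ax.set_xlabel("target year")
        ax.set_ylabel("AUROC")
        ax.set_title(f"task={task}, training fraction={frac:.0%}")
        ax.legend()
        path = outdir / f"auroc_{task}_frac{int(frac * 100)}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths
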