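"""TransferGBM: a stacking transfer-learning gradient boosting machine.

The framework corrects temporal performance drift by balancing old and
new knowledge in five steps: (1) fit a source GBM on pooled old-era
data with cross-validated hyperparameter selection; (2) adapt the
source model to the new era by continuing boosting on the target
development data projected into the source input space (common
features, with explicit missing values for source-only features);
(3) refit a fresh GBM on the target development set over its native
feature space, reusing the source feature-engineering scheme and
hyperparameters; (4) build the stacking matrix H of (adapted
probability, refitted probability, label) rows; (5) fit a logistic
regression meta-learner on H.  The final prediction is
``meta(p_adapted(x), p_refitted(x))``.

Three deployable strategies fall out of the bundle: *transported*
(source model applied unchanged to projected new data — temporal
validation), *refitted* (new-era model alone — internal validation),
and *transfer* (the stacking ensemble).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split

from driftgbm.features import FeatureScheme, FeatureSplit, project_frame_to_common
from driftgbm.sampler import SampleMatrix

__all__ = [
    "GbmHyperparams",
    "GbmModel",
    "MetaModel",
    "StackingMatrix",
    "TransferModelBundle",
    "default_grid",
    "fit_source",
    "adapt_source",
    "refit_target",
    "build_stacking_matrix",
    "fit_meta",
    "fit_transfer",
]

MAX_ROUNDS = 300

#: fraction of the development set held out for early stopping when a
#: model is fitted outside cross-validation; sized so the holdout keeps
#: enough positive windows for a stable stopping decision
ES_HOLDOUT_FRAC = 0.2


@dataclass(frozen=True)
class GbmHyperparams:
    """GBM hyperparameters within the searched ranges.

    Tree depth in [2, 10], learning rate in [0.01, 0.1], minimum child
    weight in [1, 10]; the number of trees is determined by early
    stopping, not searched.
    """

    tree_depth: int
    learning_rate: float
    min_child_weight: float
    n_trees: int | None = None
    early_stopping_rounds: int = 20

    def __post_init__(self) -> None:
        if not 2 <= self.tree_depth <= 10:
            raise ValueError("tree_depth must lie in [2, 10]")
        if not 0.01 <= self.learning_rate <= 0.1:
            raise ValueError("learning_rate must lie in [0.01, 0.1]")
        if not 1 <= self.min_child_weight <= 10:
            raise ValueError("min_child_weight must lie in [1, 10]")
        if self.n_trees is not None and self.n_trees < 1:
            raise ValueError("n_trees must be >= 1 once fitted")

    def xgb_params(self, seed: int) -> dict:
        return {
            "max_depth": int(self.tree_depth),
            "eta": float(self.learning_rate),
            "min_child_weight": float(self.min_child_weight),
            "objective": "binary:logistic",
            "eval_metric": "auc",
            "seed": int(seed),
            "nthread": 1,
            "tree_method": "hist",
        }


def default_grid() -> dict[str, tuple[float, float]]:
    """The searched hyperparameter ranges."""
    return {"tree_depth": (2, 10), "learning_rate": (0.01, 0.1), "min_child_weight": (1, 10)}


def _dmatrix(X: pd.DataFrame, y: np.ndarray | None = None) -> xgb.DMatrix:
    return xgb.DMatrix(
        X.to_numpy(dtype=float),
        label=y,
        missing=np.nan,
        feature_names=[str(c) for c in X.columns],
    )


def _fingerprint(X: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X.to_numpy(dtype=float)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, dtype=np.int64)).tobytes())
    return h.hexdigest()[:16]


def _check_two_classes(y: np.ndarray, what: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{what} must contain both classes")


@dataclass
class GbmModel:
    """A fitted GBM over a fixed feature roster."""

    booster: xgb.Booster
    feature_names: tuple[str, ...]
    hyperparams: GbmHyperparams
    role: str  # "source" | "adapted" | "refitted"
    seed: int
    fingerprint: str = ""
    scheme: FeatureScheme | None = None
    split: FeatureSplit | None = None
    cv_results: pd.DataFrame | None = None
    n_source_trees: int = 0  # for adapted models: trees inherited from the source

    @property
    def n_trees(self) -> int:
        return self.booster.num_boosted_rounds()

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if tuple(X.columns) != self.feature_names:
            raise ValueError("input columns do not match the model's feature roster")
        return self.booster.predict(_dmatrix(X))

    def feature_importance(self) -> dict[str, float]:
        return self.booster.get_score(importance_type="gain")


def _train(
    X: pd.DataFrame,
    y: np.ndarray,
    hp: GbmHyperparams,
    seed: int,
    num_rounds: int,
    eval_set: tuple[pd.DataFrame, np.ndarray] | None = None,
    base: xgb.Booster | None = None,
) -> tuple[xgb.Booster, int, float]:
    """Train (optionally continuing ``base``) and return the booster
    cut back to its best iteration, the resulting tree count, and the
    best validation score (nan without an eval set)."""
    dtrain = _dmatrix(X, y)
    n_base = base.num_boosted_rounds() if base is not None else 0
    kwargs: dict = {}
    if eval_set is not None:
        kwargs["evals"] = [(_dmatrix(*eval_set), "val")]
        kwargs["early_stopping_rounds"] = hp.early_stopping_rounds
        kwargs["verbose_eval"] = False
    booster = xgb.train(
        hp.xgb_params(seed),
        dtrain,
        num_boost_round=num_rounds,
        xgb_model=base.copy() if base is not None else None,
        **kwargs,
    )
    score = float("nan")
    if eval_set is not None:
        score = float(booster.best_score)
        # keep at least the inherited trees: adaptation may add nothing
        best_n = max(booster.best_iteration + 1, n_base)
        booster = booster[:best_n] if best_n < booster.num_boosted_rounds() else booster
    return booster, booster.num_boosted_rounds(), score


def _sample_candidates(
    grid: dict[str, tuple[float, float]], n: int, seed: int
) -> list[GbmHyperparams]:
    rng = np.random.default_rng([seed, 11])
    lo_d, hi_d = grid["tree_depth"]
    lo_l, hi_l = grid["learning_rate"]
    lo_w, hi_w = grid["min_child_weight"]
    return [
        GbmHyperparams(
            tree_depth=int(rng.integers(lo_d, hi_d + 1)),
            learning_rate=float(rng.uniform(lo_l, hi_l)),
            min_child_weight=int(rng.integers(lo_w, hi_w + 1)),
        )
        for _ in range(n)
    ]


def cv_score(
    X: pd.DataFrame,
    y: np.ndarray,
    hp: GbmHyperparams,
    seed: int,
    cv: int = 10,
    max_rounds: int = MAX_ROUNDS,
) -> tuple[float, list[int]]:
    """Mean early-stopped validation AUROC over stratified CV folds."""
    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    scores, iters = [], []
    for tr, va in folds.split(X, y):
        _, n_trees, score = _train(
            X.iloc[tr], y[tr], hp, seed, max_rounds, eval_set=(X.iloc[va], y[va])
        )
        scores.append(score)
        iters.append(n_trees)
    return float(np.mean(scores)), iters


def fit_source(
    source_dev: SampleMatrix,
    grid: dict[str, tuple[float, float]] | Sequence[GbmHyperparams] | None = None,
    seed: int = 0,
    cv: int = 10,
    n_candidates: int = 25,
    scheme: FeatureScheme | None = None,
    max_rounds: int = MAX_ROUNDS,
) -> tuple[GbmModel, GbmHyperparams, FeatureScheme | None]:
    """Fit the source GBM with cross-validated hyperparameter search.

    ``grid`` may be an explicit candidate list (searched exhaustively)
    or range bounds sampled ``n_candidates`` times.  The winning
    candidate maximizes mean stratified ``cv``-fold validation AUROC;
    the final model is refitted on all development data with the tree
    count set to the rounded mean of the per-fold early-stopped counts.
    """
    X, y = source_dev.X, source_dev.y
    if len(X) == 0:
        raise ValueError("source development set is empty")
    _check_two_classes(y, "source development data")
    if grid is None:
        grid = default_grid()
    if isinstance(grid, dict):
        if not grid:
            raise ValueError("empty hyperparameter grid")
        candidates = _sample_candidates(grid, n_candidates, seed)
    else:
        candidates = list(grid)
        if not candidates:
            raise ValueError("empty hyperparameter grid")

    rows = []
    for k, hp in enumerate(candidates):
        mean_auc, iters = cv_score(X, y, hp, seed, cv=cv, max_rounds=max_rounds)
        rows.append(
            {
                "candidate": k,
                "tree_depth": hp.tree_depth,
                "learning_rate": hp.learning_rate,
                "min_child_weight": hp.min_child_weight,
                "mean_cv_auroc": mean_auc,
                "mean_n_trees": float(np.mean(iters)),
            }
        )
    cv_results = pd.DataFrame(rows)
    best_k = int(cv_results["mean_cv_auroc"].idxmax())
    best = candidates[best_k]
    n_trees = max(1, int(round(cv_results.loc[best_k, "mean_n_trees"])))
    best = replace(best, n_trees=n_trees)
    booster, _, _ = _train(X, y, best, seed, n_trees)
    model = GbmModel(
        booster=booster,
        feature_names=tuple(X.columns),
        hyperparams=best,
        role="source",
        seed=seed,
        fingerprint=_fingerprint(X, y),
        scheme=scheme,
        cv_results=cv_results,
    )
    return model, best, scheme


def adapt_source(
    source_model: GbmModel,
    target_dev: SampleMatrix,
    split: FeatureSplit,
    n_new_rounds: int | None = None,
    seed: int = 0,
) -> GbmModel:
    """Adapt the source model by continued boosting on projected target data.

    The target development matrix is projected into the source input
    space (source-only features become missing) and boosting continues
    from the source trees for up to ``n_new_rounds`` (default: the
    source tree count) with early stopping on a stratified holdout.
    The source model is not mutated; with ``n_new_rounds=0`` the
    adapted model is prediction-identical to the source.
    """
    Xp = project_frame_to_common(target_dev.X, split)
    if tuple(Xp.columns) != source_model.feature_names:
        raise ValueError("projected target data incompatible with source input space")
    if n_new_rounds is None:
        n_new_rounds = source_model.n_trees
    n_src = source_model.n_trees
    if n_new_rounds == 0:
        booster = source_model.booster.copy()
    else:
        y = target_dev.y
        _check_two_classes(y, "target development data")
        Xtr, Xva, ytr, yva = train_test_split(
            Xp, y, test_size=ES_HOLDOUT_FRAC, stratify=y, random_state=seed
        )
        booster, _, _ = _train(
            Xtr,
            ytr,
            source_model.hyperparams,
            seed,
            n_new_rounds,
            eval_set=(Xva, yva),
            base=source_model.booster,
        )
    return GbmModel(
        booster=booster,
        feature_names=source_model.feature_names,
        hyperparams=source_model.hyperparams,
        role="adapted",
        seed=seed,
        fingerprint=_fingerprint(target_dev.X, target_dev.y),
        scheme=source_model.scheme,
        split=split,
        n_source_trees=n_src,
    )


def refit_target(
    target_dev: SampleMatrix,
    source_hyperparams: GbmHyperparams,
    split: FeatureSplit | None = None,
    seed: int = 0,
    max_rounds: int = MAX_ROUNDS,
) -> GbmModel:
    """Train a fresh GBM on the target development set.

    Uses the source model's hyperparameters but the target's native
    feature space (common plus target-only features; source-only
    features never appear), with the tree count re-determined by early
    stopping on a stratified holdout.
    """
    X, y = target_dev.X, target_dev.y
    if len(X) == 0:
        raise ValueError("target development set is empty")
    _check_two_classes(y, "target development data")
    if split is not None:
        forbidden = set(split.unique_source) & set(X.columns)
        if forbidden:
            raise ValueError(f"target matrix contains source-only features {sorted(forbidden)}")
    Xtr, Xva, ytr, yva = train_test_split(X, y, test_size=ES_HOLDOUT_FRAC, stratify=y, random_state=seed)
    booster, n_trees, _ = _train(
        Xtr, ytr, source_hyperparams, seed, max_rounds, eval_set=(Xva, yva)
    )
    return GbmModel(
        booster=booster,
        feature_names=tuple(X.columns),
        hyperparams=replace(source_hyperparams, n_trees=n_trees),
        role="refitted",
        seed=seed,
        fingerprint=_fingerprint(X, y),
        split=split,
    )


@dataclass
class StackingMatrix:
    """The matrix H of base-model probabilities and true labels."""

    p_adapted: np.ndarray
    p_refitted: np.ndarray
    y: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        n = len(self.y)
        if len(self.p_adapted) != n or len(self.p_refitted) != n:
            raise ValueError("H columns must have equal length")
        for p in (self.p_adapted, self.p_refitted):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("stacking probabilities must lie in [0, 1]")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p_adapted": self.p_adapted, "p_refitted": self.p_refitted, "label": self.y}
        )


def build_stacking_matrix(
    adapted: GbmModel,
    refitted: GbmModel,
    target_dev: SampleMatrix,
    mode: str = "oof",
    k_folds: int = 5,
    seed: int = 0,
    source_model: GbmModel | None = None,
) -> StackingMatrix:
    """Construct H over the target development samples.

    ``faithful`` mode uses plain in-sample predictions of the fitted
    base models (the framework as originally written); ``oof`` (the
    default) re-derives both base models per stratified fold and uses
    out-of-fold predictions, so the meta-learner never sees a
    probability produced by a model trained on that same row.
    """
    X, y = target_dev.X, target_dev.y
    split = adapted.split
    if mode == "faithful":
        p_a = adapted.predict(project_frame_to_common(X, split))
        p_r = refitted.predict(X)
        return StackingMatrix(p_a, p_r, y.copy(), mode)
    if mode != "oof":
        raise ValueError(f"unknown stacking mode {mode!r}")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2 in oof mode")
    if source_model is None:
        raise ValueError("oof mode needs the source model to re-adapt per fold")
    p_a = np.empty(len(y))
    p_r = np.empty(len(y))
    folds = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for tr, va in folds.split(X, y):
        fold_dev = target_dev.subset(tr)
        a_k = adapt_source(source_model, fold_dev, split, seed=seed)
        r_k = refit_target(fold_dev, refitted.hyperparams, split=split, seed=seed)
        p_a[va] = a_k.predict(project_frame_to_common(X.iloc[va], split))
        p_r[va] = r_k.predict(X.iloc[va])
    return StackingMatrix(p_a, p_r, y.copy(), mode)


@dataclass
class MetaModel:
    """Logistic-regression combiner of the two base probabilities."""

    coef: np.ndarray  # shape (2,): weights on (p_adapted, p_refitted)
    intercept: float
    C: float

    def predict(self, p_adapted: np.ndarray, p_refitted: np.ndarray) -> np.ndarray:
        z = self.intercept + self.coef[0] * np.asarray(p_adapted) + self.coef[1] * np.asarray(
            p_refitted
        )
        return expit(z)


def fit_meta(H: StackingMatrix, seed: int = 0, C: float = 10.0) -> MetaModel:
    """Fit the logistic meta-learner on H.

    Light L2 regularization (inverse strength ``C``) keeps the
    coefficients finite even when H is perfectly separable.
    """
    _check_two_classes(H.y, "stacking matrix labels")
    Z = np.column_stack([H.p_adapted, H.p_refitted])
    if np.allclose(Z.std(axis=0), 0.0):
        raise ValueError("degenerate stacking matrix: constant probability columns")
    lr = LogisticRegression(C=C, solver="lbfgs", max_iter=1000)
    lr.fit(Z, H.y)
    coef = lr.coef_[0].astype(float)
    if not np.all(np.isfinite(coef)):
        raise RuntimeError("meta-learner coefficients are not finite")
    return MetaModel(coef=coef, intercept=float(lr.intercept_[0]), C=C)


@dataclass
class TransferModelBundle:
    """The complete fitted TransferGBM: sub-models plus provenance."""

    source: GbmModel
    adapted: GbmModel
    refitted: GbmModel
    meta: MetaModel
    split: FeatureSplit
    source_scheme: FeatureScheme | None
    target_scheme: FeatureScheme | None
    hyperparams: GbmHyperparams
    provenance: dict = field(default_factory=dict)

    def _check(self) -> None:
        for part in ("source", "adapted", "refitted", "meta"):
            if getattr(self, part) is None:
                raise ValueError(f"bundle is unfitted: missing {part}")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """TransferGBM probability: meta(p_adapted, p_refitted)."""
        self._check()
        return self.meta.predict(self.predict_adapted(X), self.predict_refitted(X))

    def predict_adapted(self, X: pd.DataFrame) -> np.ndarray:
        self._check()
        return self.adapted.predict(project_frame_to_common(X, self.split))

    def predict_transported(self, X: pd.DataFrame) -> np.ndarray:
        """SourceGBM applied unchanged to projected target data."""
        self._check()
        return self.source.predict(project_frame_to_common(X, self.split))

    def predict_refitted(self, X: pd.DataFrame) -> np.ndarray:
        self._check()
        return self.refitted.predict(X)

    # -- persistence --------------------------------------------------

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in ("source", "adapted", "refitted"):
            getattr(self, name).booster.save_model(str(path / f"{name}.json"))
        manifest = {
            "meta": {"coef": self.meta.coef.tolist(), "intercept": self.meta.intercept,
                     "C": self.meta.C},
            "split": {
                "common": list(self.split.common),
                "unique_source": list(self.split.unique_source),
                "unique_target": list(self.split.unique_target),
                "source_roster": list(self.split.source_roster),
                "target_roster": list(self.split.target_roster),
            },
            "hyperparams": {
                "tree_depth": self.hyperparams.tree_depth,
                "learning_rate": self.hyperparams.learning_rate,
                "min_child_weight": self.hyperparams.min_child_weight,
                "n_trees": self.hyperparams.n_trees,
                "early_stopping_rounds": self.hyperparams.early_stopping_rounds,
            },
            "models": {
                name: {
                    "feature_names": list(getattr(self, name).feature_names),
                    "role": getattr(self, name).role,
                    "seed": getattr(self, name).seed,
                    "fingerprint": getattr(self, name).fingerprint,
                    "n_source_trees": getattr(self, name).n_source_trees,
                }
                for name in ("source", "adapted", "refitted")
            },
            "source_scheme": self.source_scheme.to_json() if self.source_scheme else None,
            "target_scheme": self.target_scheme.to_json() if self.target_scheme else None,
            "provenance": self.provenance,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TransferModelBundle":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        hp = GbmHyperparams(**manifest["hyperparams"])
        split = FeatureSplit(
            common=tuple(manifest["split"]["common"]),
            unique_source=tuple(manifest["split"]["unique_source"]),
            unique_target=tuple(manifest["split"]["unique_target"]),
            source_roster=tuple(manifest["split"]["source_roster"]),
            target_roster=tuple(manifest["split"]["target_roster"]),
        )
        models = {}
        for name in ("source", "adapted", "refitted"):
            booster = xgb.Booster()
            booster.load_model(str(path / f"{name}.json"))
            info = manifest["models"][name]
            models[name] = GbmModel(
                booster=booster,
                feature_names=tuple(info["feature_names"]),
                hyperparams=hp,
                role=info["role"],
                seed=info["seed"],
                fingerprint=info["fingerprint"],
                split=split if name != "source" else None,
                n_source_trees=info["n_source_trees"],
            )
        meta = MetaModel(
            coef=np.asarray(manifest["meta"]["coef"], dtype=float),
            intercept=float(manifest["meta"]["intercept"]),
            C=float(manifest["meta"]["C"]),
        )
        return cls(
            source=models["source"],
            adapted=models["adapted"],
            refitted=models["refitted"],
            meta=meta,
            split=split,
            source_scheme=FeatureScheme.from_json(manifest["source_scheme"])
            if manifest["source_scheme"]
            else None,
            target_scheme=FeatureScheme.from_json(manifest["target_scheme"])
            if manifest["target_scheme"]
            else None,
            hyperparams=hp,
            provenance=manifest["provenance"],
        )


def fit_transfer(
    source_model: GbmModel,
    target_dev: SampleMatrix,
    split: FeatureSplit,
    target_scheme: FeatureScheme | None = None,
    seed: int = 0,
    stacking_mode: str = "oof",
    k_folds: int = 5,
    n_new_rounds: int | None = None,
) -> TransferModelBundle:
    """Run steps 2-5 against a fitted source model: adapt, refit, stack,
    and fit the meta-learner; returns the complete bundle."""
    adapted = adapt_source(source_model, target_dev, split, n_new_rounds=n_new_rounds, seed=seed)
    refitted = refit_target(target_dev, source_model.hyperparams, split=split, seed=seed)
    H = build_stacking_matrix(
        adapted, refitted, target_dev, mode=stacking_mode, k_folds=k_folds, seed=seed,
        source_model=source_model,
    )
    meta = fit_meta(H, seed=seed)
    provenance = {
        "seed": seed,
        "stacking_mode": stacking_mode,
        "source_fingerprint": source_model.fingerprint,
        "target_fingerprint": _fingerprint(target_dev.X, target_dev.y),
        # the transported path is the source booster verbatim: its
        # training fingerprint proves no target-data exposure
        "transported_training_fingerprint": source_model.fingerprint,
    }
    return TransferModelBundle(
        source=source_model,
        adapted=adapted,
        refitted=refitted,
        meta=meta,
        split=split,
        source_scheme=source_model.scheme,
        target_scheme=target_scheme,
        hyperparams=source_model.hyperparams,
        provenance=provenance,
    )
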