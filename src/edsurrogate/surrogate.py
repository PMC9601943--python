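"""Surrogate regression models for the simulated ED outputs.

A :class:`SurrogateModel` is built from a scenario-day data frame and a
target column (``pnt`` or ``wt``); :meth:`SurrogateModel.fit` returns a
:class:`SurrogateResults` holding three fitted regressors — random forest
(RF), gradient boosting (GB) and AdaBoost.R2 (AB) — together with their
train/test and 10-fold cross-validated metrics and a ``summary()`` table.

The evaluation protocol is a single 85%/15% random split plus shuffled
10-fold cross-validation.  Hyperparameters default to the study settings:
RF with 5 candidate features per split and 500 trees; GB with 3 trees,
learning rate 0.1, depth 3, min-split 2, full subsampling; AB with 50 tree
estimators, learning rate 1.0 and the linear loss of AdaBoost.R2.

Cost levels enter as a sixth feature: the scenario's escalated cost at one
delta level is appended to the staffing counts, and one model set is fitted
per level.  Because every level rescales all coefficients by a common
multiplier, tree-based fits are identical across levels up to estimator
randomness — the per-level view mainly exercises the reporting layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.model_selection import KFold, train_test_split
from sklearn.tree import DecisionTreeRegressor

from .cost import CostTable, scenario_cost
from .metrics import MetricSet, compute_metrics, round_half_up
from .simulate import RESOURCE_FIELDS

__all__ = [
    "HyperParams",
    "SplitSpec",
    "SurrogateModel",
    "SurrogateResults",
    "attach_cost_feature",
    "fit_regressors",
    "evaluate_protocol",
    "MODEL_NAMES",
]

MODEL_NAMES = ("RF", "GB", "AB")


@dataclass(frozen=True)
class HyperParams:
    """Published hyperparameter settings for the three regressors."""

    rf_trees: int = 500           # configurable within the studied 10-2000 range
    rf_max_features: int = 5
    gb_trees: int = 3
    gb_learning_rate: float = 0.1
    gb_depth: int = 3
    gb_min_split: int = 2
    gb_subsample: float = 1.0
    ab_estimators: int = 50
    ab_learning_rate: float = 1.0
    ab_loss: str = "linear"
    ab_base_depth: int = 3

    def __post_init__(self) -> None:
        if min(self.rf_trees, self.rf_max_features, self.gb_trees,
               self.gb_depth, self.gb_min_split, self.ab_estimators,
               self.ab_base_depth) < 1:
            raise ValueError("tree counts, depths and feature counts must be >= 1")
        if min(self.gb_learning_rate, self.gb_subsample, self.ab_learning_rate) <= 0:
            raise ValueError("learning rates and subsample fraction must be positive")


@dataclass(frozen=True)
class SplitSpec:
    """85/15 random train/test split plus shuffled 10-fold cross-validation."""

    train_fraction: float = 0.85
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


def _make_models(hp: HyperParams, n_features: int, seed: int):
    return {
        "RF": RandomForestRegressor(
            n_estimators=hp.rf_trees,
            max_features=min(hp.rf_max_features, n_features),
            random_state=seed,
        ),
        "GB": GradientBoostingRegressor(
            n_estimators=hp.gb_trees,
            learning_rate=hp.gb_learning_rate,
            max_depth=hp.gb_depth,
            min_samples_split=hp.gb_min_split,
            subsample=hp.gb_subsample,
            random_state=seed,
        ),
        "AB": AdaBoostRegressor(
            estimator=DecisionTreeRegressor(max_depth=hp.ab_base_depth,
                                            random_state=seed),
            n_estimators=hp.ab_estimators,
            learning_rate=hp.ab_learning_rate,
            loss=hp.ab_loss,
            random_state=seed,
        ),
    }


def attach_cost_feature(daily: pd.DataFrame, table: CostTable, level: str) -> pd.DataFrame:
    """Append the scenario cost at one delta level as a ``cost`` column."""
    out = daily.copy()
    out["cost"] = [
        scenario_cost({f: int(row[f]) for f in RESOURCE_FIELDS}, table, level)
        for _, row in out.iterrows()
    ]
    return out


class SurrogateModel:
    """Regression surrogate of one simulated output.

    Parameters
    ----------
    data : DataFrame with the staffing-count columns, optionally a ``cost``
        column, and the target column.
    target : {"pnt", "wt"} (or any numeric column name).
    features : feature column names; defaults to the staffing counts plus
        ``cost`` when present.
    """

    def __init__(self, data: pd.DataFrame, target: str,
                 features: tuple[str, ...] | None = None,
                 hyperparams: HyperParams | None = None,
                 split: SplitSpec | None = None):
        if features is None:
            features = RESOURCE_FIELDS + (("cost",) if "cost" in data.columns else ())
        missing = [c for c in (*features, target) if c not in data.columns]
        if missing:
            raise KeyError(f"missing columns: {missing}")
        data = data.dropna(subset=[*features, target])
        if len(data) < 20:
            raise ValueError("need at least 20 training rows")
        # canonical row order: the split depends on the seed, not on how
        # the caller happened to order the campaign rows
        data = data.sort_values([*features, target], kind="mergesort")
        self.data = data.reset_index(drop=True)
        self.target = target
        self.features = tuple(features)
        self.hyperparams = hyperparams or HyperParams()
        self.split = split or SplitSpec()

    @classmethod
    def from_campaign(cls, daily: pd.DataFrame, target: str,
                      table: CostTable | None = None, level: str | None = None,
                      **kw) -> "SurrogateModel":
        """Build from a simulation campaign, optionally cost-augmented."""
        if (table is None) != (level is None):
            raise ValueError("give both table and level, or neither")
        data = attach_cost_feature(daily, table, level) if table is not None else daily
        return cls(data, target, **kw)

    @property
    def X(self) -> np.ndarray:
        return self.data[list(self.features)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.data[self.target].to_numpy(dtype=float)

    def fit(self, seed: int | None = None) -> "SurrogateResults":
        """Fit RF/GB/AB, evaluate on the split and by cross-validation."""
        seed = self.split.seed if seed is None else seed
        X, y = self.X, self.y
        idx = np.arange(len(y))
        train_idx, test_idx = train_test_split(
            idx, train_size=self.split.train_fraction, random_state=seed,
            shuffle=True,
        )
        models = _make_models(self.hyperparams, X.shape[1], seed)
        train_metrics, test_metrics, cv_metrics = {}, {}, {}
        constant = bool(np.all(y == y[0]))
        for name, est in models.items():
            est.fit(X[train_idx], y[train_idx])
            train_metrics[name] = compute_metrics(
                y[train_idx], self._predict_est(est, X[train_idx]))
            test_metrics[name] = compute_metrics(
                y[test_idx], self._predict_est(est, X[test_idx]))
            cv_metrics[name] = self._cross_validate(name, X, y, seed)
        return SurrogateResults(
            model=self, seed=seed, estimators=models,
            train_idx=train_idx, test_idx=test_idx,
            train_metrics=train_metrics, test_metrics=test_metrics,
            cv_metrics=cv_metrics, constant_target=constant,
        )

    def _predict_est(self, est, X) -> np.ndarray:
        pred = est.predict(X)
        if self.target == "pnt":  # treated-patient counts are integers
            pred = np.rint(pred)
        return pred

    def _cross_validate(self, name: str, X, y, seed: int) -> MetricSet:
        kf = KFold(n_splits=self.split.cv_folds, shuffle=True, random_state=seed)
        actual_all, pred_all = [], []
        for tr, te in kf.split(X):
            if len(te) < 1:
                raise ValueError("cross-validation fold with no test rows")
            est = _make_models(self.hyperparams, X.shape[1], seed)[name]
            est.fit(X[tr], y[tr])
            actual_all.append(y[te])
            pred_all.append(self._predict_est(est, X[te]))
        return compute_metrics(np.concatenate(actual_all), np.concatenate(pred_all))


@dataclass
class SurrogateResults:
    """Fitted surrogates with their evaluation metrics."""

    model: SurrogateModel
    seed: int
    estimators: dict
    train_idx: np.ndarray
    test_idx: np.ndarray
    train_metrics: dict[str, MetricSet]
    test_metrics: dict[str, MetricSet]
    cv_metrics: dict[str, MetricSet]
    constant_target: bool = False

    def predict(self, X, model: str = "AB") -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.model.features)].to_numpy(dtype=float)
        return self.model._predict_est(self.estimators[model], np.asarray(X, dtype=float))

    def best_model(self, phase: str = "train") -> str:
        """Name of the highest-R^2 model in the given phase."""
        metrics = self.train_metrics if phase == "train" else self.test_metrics
        defined = {k: m.r2 for k, m in metrics.items() if m.r2 is not None}
        if not defined:
            raise ValueError("R^2 undefined for every model (constant target)")
        return max(defined, key=defined.get)

    def metrics_frame(self) -> pd.DataFrame:
        """Tidy metrics table: one row per model and evaluation phase."""
        rows = []
        for phase, metrics in (("train", self.train_metrics),
                               ("test", self.test_metrics),
                               ("cv", self.cv_metrics)):
            for name in MODEL_NAMES:
                m = metrics[name]
                rows.append({"target": self.model.target, "model": name,
                             "phase": phase, **m.as_dict()})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Surrogate fit: target={self.model.target}  "
            f"n={len(self.model.data)}  features={', '.join(self.model.features)}",
            f"split: {self.model.split.train_fraction:.0%} train / "
            f"{1 - self.model.split.train_fraction:.0%} test, "
            f"{self.model.split.cv_folds}-fold CV, seed={self.seed}",
        ]
        if self.constant_target:
            lines.append("note: constant target; R^2 not computable")
        header = f"{'model':<6}{'phase':<7}{'MSE':>12}{'RMSE':>10}{'MAE':>10}{'R2':>10}"
        lines += ["", header, "-" * len(header)]
        for _, r in self.metrics_frame().iterrows():
            r2 = "   n/a" if r["R2"] is None or pd.isna(r["R2"]) else f"{r['R2']:.4f}"
            lines.append(
                f"{r['model']:<6}{r['phase']:<7}"
                f"{round_half_up(r['MSE'], 4):>12}{round_half_up(r['RMSE'], 4):>10}"
                f"{round_half_up(r['MAE'], 4):>10}{r2:>10}"
            )
        return "\n".join(lines)


def fit_regressors(data: pd.DataFrame, target: str,
                   hyperparams: HyperParams | None = None,
                   split: SplitSpec | None = None,
                   seed: int | None = None) -> SurrogateResults:
    """Convenience wrapper: build a SurrogateModel and fit it."""
    return SurrogateModel(data, target, hyperparams=hyperparams,
                          split=split).fit(seed=seed)


def evaluate_protocol(
    daily: pd.DataFrame,
    table: CostTable | None = None,
    targets: tuple[str, ...] = ("pnt", "wt"),
    split: SplitSpec | None = None,
    hyperparams: HyperParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the split + CV protocol, per delta level when a table is given.

    Returns the concatenated tidy metrics table with a ``level`` column
    ("none" when no cost table is supplied).
    """
    frames = []
    levels = list(table.levels) if table is not None else [None]
    for level in levels:
        for target in targets:
            m = SurrogateModel.from_campaign(
                daily, target, table=table, level=level,
                split=split, hyperparams=hyperparams,
            )
            res = m.fit(seed=seed)
            f = res.metrics_frame()
            f.insert(0, "level", level if level is not None else "none")
            frames.append(f)
    return pd.concat(frames, ignore_index=True)
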