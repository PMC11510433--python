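"""Regressor registry, TPE hyperparameter tuning, and final-model evaluation.

Each registry entry pairs a scikit-learn estimator factory with a declared
hyperparameter search space.  Tuning minimizes the composite loss of
:mod:`dessol.scoring` with the seeded TPE sampler from :mod:`dessol._tpe`;
final models are judged on a held-out test subset by RMSD, MAPE and the
outlier percentage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso, LinearRegression, Ridge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR, NuSVR

from ._tpe import CatParam, FloatParam, IntParam, minimize
from .scoring import ScoreBreakdown, custom_loss, mape, outlier_fraction, rmsd

__all__ = [
    "RegressorFamily",
    "registry",
    "make_estimator",
    "TuningConfig",
    "ModelReport",
    "tune",
    "evaluate",
    "NuSVRPreset",
    "nusvr_preset",
    "overfitting_screen",
]


@dataclass(frozen=True)
class RegressorFamily:
    name: str
    factory: Callable[..., Any]
    space: Mapping[str, FloatParam | IntParam | CatParam]
    seedable: bool = True

    def build(self, params: Mapping[str, Any], seed: int | None = None):
        kwargs = dict(params)
        if self.seedable and seed is not None:
            kwargs["random_state"] = seed
        return self.factory(**kwargs)


def _mlp_factory(hidden: int = 32, **kwargs):
    return MLPRegressor(hidden_layer_sizes=(hidden,), max_iter=800, **kwargs)


_REGISTRY: dict[str, RegressorFamily] = {
    f.name: f
    for f in [
        RegressorFamily(
            "nusvr",
            NuSVR,
            {
                "C": FloatParam(1e-2, 1e2, log=True),
                "nu": FloatParam(0.05, 0.95),
                "gamma": FloatParam(1e-3, 10.0, log=True),
            },
            seedable=False,
        ),
        RegressorFamily(
            "svr",
            SVR,
            {
                "C": FloatParam(1e-2, 1e2, log=True),
                "epsilon": FloatParam(1e-3, 1.0, log=True),
                "gamma": FloatParam(1e-3, 10.0, log=True),
            },
            seedable=False,
        ),
        RegressorFamily(
            "random_forest",
            RandomForestRegressor,
            {
                "n_estimators": IntParam(20, 200, log=True),
                "max_depth": IntParam(2, 16),
                "min_samples_leaf": IntParam(1, 8),
            },
        ),
        RegressorFamily(
            "gradient_boosting",
            GradientBoostingRegressor,
            {
                "n_estimators": IntParam(20, 200, log=True),
                "learning_rate": FloatParam(0.01, 0.5, log=True),
                "max_depth": IntParam(1, 6),
            },
        ),
        RegressorFamily(
            "knn",
            KNeighborsRegressor,
            {
                "n_neighbors": IntParam(1, 25),
                "weights": CatParam(["uniform", "distance"]),
            },
            seedable=False,
        ),
        RegressorFamily("ridge", Ridge, {"alpha": FloatParam(1e-8, 1e3, log=True)}, seedable=False),
        RegressorFamily(
            "lasso",
            Lasso,
            {"alpha": FloatParam(1e-8, 10.0, log=True)},
            seedable=False,
        ),
        RegressorFamily(
            "mlp",
            _mlp_factory,
            {
                "hidden": IntParam(8, 128, log=True),
                "alpha": FloatParam(1e-6, 1e-1, log=True),
                "learning_rate_init": FloatParam(1e-4, 1e-1, log=True),
            },
        ),
        RegressorFamily("linear", LinearRegression, {"fit_intercept": CatParam([True])}, seedable=False),
    ]
}


def registry() -> dict[str, RegressorFamily]:
    """Available regressor families with their declared search spaces."""
    return dict(_REGISTRY)


def make_estimator(name: str, params: Mapping[str, Any] | None = None, seed: int | None = None):
    """Instantiate a registry estimator; unknown names raise KeyError."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown regressor {name!r}; known: {sorted(_REGISTRY)}")
    return _REGISTRY[name].build(params or {}, seed=seed)


@dataclass(frozen=True)
class TuningConfig:
    """Settings for a tuning run (desk-scale default: 50 trials)."""

    regressor_names: tuple[str, ...] = ("nusvr",)
    n_trials: int = 50
    seed: int = 0
    loss_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    descriptor_set: str = "B2"
    base_metric: str = "mae"
    with_lca: bool = True
    sampler: str = "tpe"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        unknown = [n for n in self.regressor_names if n not in _REGISTRY]
        if unknown:
            raise ValueError(f"unknown regressor name(s): {unknown}")


@dataclass
class ModelReport:
    """Tuning and evaluation summary for one regressor family."""

    regressor_name: str
    best_params: dict[str, Any]
    best_loss: float
    seed: int
    n_trials: int
    sampler: str
    descriptor_set: str
    train_rmsd: float | None = None
    train_mape: float | None = None
    train_outlier_pct: float | None = None
    lca_gap: float | None = None
    test_rmsd: float | None = None
    test_mape: float | None = None
    test_outlier_pct: float | None = None
    failed: bool = False
    trace: list = field(default_factory=list, repr=False)
    model: Any = field(default=None, repr=False, compare=False)

    def to_json(self) -> str:
        """Stable serialization (excludes the fitted model and raw trace)."""
        payload = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("model", "trace")
        }
        return json.dumps(payload, sort_keys=True)


def _fit_and_report(family: RegressorFamily, params, cfg: TuningConfig, X, y) -> ScoreBreakdown:
    model = family.build(params, seed=cfg.seed)
    return custom_loss(
        model,
        X,
        y,
        weights=cfg.loss_weights,
        cv_seed=cfg.seed,
        base_metric=cfg.base_metric,
        with_lca=cfg.with_lca,
    )


def tune(cfg: TuningConfig, train_features, train_targets) -> dict[str, ModelReport]:
    """TPE-minimize the composite loss for each configured regressor family.

    Deterministic for a fixed seed and trial count.  A family whose every
    trial fails is reported with ``failed=True``; the run continues.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("training features contain non-finite values")
    reports: dict[str, ModelReport] = {}
    for name in cfg.regressor_names:
        family = _REGISTRY[name]

        def objective(params, family=family):
            return _fit_and_report(family, params, cfg, X, y).total

        best_params, best_loss, trace = minimize(
            objective, dict(family.space), cfg.n_trials, seed=cfg.seed
        )
        report = ModelReport(
            regressor_name=name,
            best_params=best_params,
            best_loss=best_loss,
            seed=cfg.seed,
            n_trials=cfg.n_trials,
            sampler=cfg.sampler,
            descriptor_set=cfg.descriptor_set,
            trace=trace,
        )
        if not np.isfinite(best_loss):
            report.failed = True
            reports[name] = report
            continue
        model = family.build(best_params, seed=cfg.seed)
        breakdown = custom_loss(
            model,
            X,
            y,
            weights=cfg.loss_weights,
            cv_seed=cfg.seed,
            base_metric=cfg.base_metric,
            with_lca=cfg.with_lca,
        )
        pred = model.predict(X)
        report.train_rmsd = rmsd(pred, y)
        report.train_mape = mape(pred, y)
        report.train_outlier_pct = outlier_fraction(pred, y)[0]
        report.lca_gap = breakdown.lca_gap
        report.model = model
        reports[name] = report
    return reports


def evaluate(model, test_features, test_targets) -> dict[str, float]:
    """Test-set RMSD, MAPE and outlier percentage for a fitted model."""
    X = np.asarray(test_features, dtype=float)
    y = np.asarray(test_targets, dtype=float)
    if hasattr(model, "n_features_in_") and X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature length {X.shape[1]} does not match the fitted model's "
            f"{model.n_features_in_}"
        )
    pred = model.predict(X)
    return {
        "rmsd": rmsd(pred, y),
        "mape": mape(pred, y),
        "outlier_pct": outlier_fraction(pred, y)[0],
    }


def attach_test_metrics(report: ModelReport, test_features, test_targets) -> ModelReport:
    """Fill a report's test metrics from held-out data (model must be fitted)."""
    if report.model is None:
        raise ValueError(f"report for {report.regressor_name!r} has no fitted model")
    metrics = evaluate(report.model, test_features, test_targets)
    report.test_rmsd = metrics["rmsd"]
    report.test_mape = metrics["mape"]
    report.test_outlier_pct = metrics["outlier_pct"]
    return report


@dataclass(frozen=True)
class NuSVRPreset:
    """Published final-model hyperparameters for the nu-SVR regressor."""

    C: float = 6.8251
    degree: int = 8
    gamma: float = 0.8358
    max_iter: int = 61378442
    nu: float = 0.4754

    def __post_init__(self) -> None:
        if not 0.0 < self.nu < 1.0:
            raise ValueError("nu must lie strictly between 0 and 1")

    def build(self, **overrides) -> NuSVR:
        kwargs = {
            "C": self.C,
            "degree": self.degree,
            "gamma": self.gamma,
            "max_iter": self.max_iter,
            "nu": self.nu,
        }
        kwargs.update(overrides)
        return NuSVR(**kwargs)


def nusvr_preset() -> NuSVRPreset:
    """The published nu-SVR hyperparameters, usable to instantiate the final model."""
    return NuSVRPreset()


def overfitting_screen(
    reports: Sequence[ModelReport], threshold: float = 2.0
) -> list[ModelReport]:
    """Drop reports whose test/train error ratio exceeds ``threshold``.

    Survivors are ranked by ascending test MAPE.  Reports lacking either
    metric are dropped as unevaluable.
    """
    kept = []
    for rep in reports:
        if rep.failed or rep.train_mape is None or rep.test_mape is None:
            continue
        if rep.train_mape == 0:
            if rep.test_mape == 0:
                kept.append(rep)
            continue
        if rep.test_mape / rep.train_mape <= threshold:
            kept.append(rep)
    return sorted(kept, key=lambda r: r.test_mape)
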