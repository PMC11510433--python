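"""Evaluation metrics and the composite anti-overfitting loss.

Accuracy metrics are RMSD, MAPE and the outlier percentage (errors beyond
three standard deviations).  The composite loss adds, to the training-set
base error, penalties for physically inadmissible positive log-solubility
predictions, for outliers, and for the train/validation gap of a five-point
learning curve computed by five-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import KFold

__all__ = [
    "LCA_FRACTIONS",
    "ScoreBreakdown",
    "LearningCurve",
    "rmsd",
    "mape",
    "outlier_fraction",
    "learning_curve",
    "custom_loss",
]

LCA_FRACTIONS = (0.5, 0.625, 0.75, 0.875, 1.0)


def _check_pair(pred, obs) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError(f"pred and obs must be equal-length vectors, got {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty prediction vector")
    return pred, obs


def rmsd(pred, obs) -> float:
    """Root-mean-square deviation between predictions and observations."""
    pred, obs = _check_pair(pred, obs)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mape(pred, obs) -> float:
    """Mean absolute percentage error, 100/n * sum(|(obs - pred)/obs|)."""
    pred, obs = _check_pair(pred, obs)
    if np.any(obs == 0):
        raise ValueError("MAPE undefined for zero observations")
    return float(100.0 * np.mean(np.abs((obs - pred) / obs)))


def outlier_fraction(pred, obs, k: float = 3.0) -> tuple[float, np.ndarray]:
    """Percentage (and mask) of errors exceeding k standard deviations.

    The SD is the population SD (ddof=0) of the error vector itself; a
    degenerate SD of zero yields no outliers.
    """
    pred, obs = _check_pair(pred, obs)
    if pred.size < 2:
        raise ValueError("need at least 2 points to estimate the error SD")
    err = obs - pred
    sd = float(np.std(err))
    mask = np.abs(err) > k * sd if sd > 0 else np.zeros_like(err, dtype=bool)
    return float(100.0 * mask.sum() / mask.size), mask


@dataclass(frozen=True)
class LearningCurve:
    """Cross-validated train/validation MAE at five training-set fractions."""

    fractions: tuple[float, ...]
    train_mae: tuple[float, ...]
    test_mae: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) != 5:
            raise ValueError("learning curve must have exactly 5 points")
        if list(self.fractions) != sorted(self.fractions) or not (
            self.fractions[0] == 0.5 and self.fractions[-1] == 1.0
        ):
            raise ValueError("fractions must increase from 0.5 to 1.0")

    @property
    def gap(self) -> float:
        """Mean validation-minus-train MAE over the curve points."""
        return float(
            np.mean(np.asarray(self.test_mae) - np.asarray(self.train_mae))
        )


def learning_curve(model, features, targets, seed: int = 0, n_folds: int = 5) -> LearningCurve:
    """Five-point learning curve via seeded subsampling and k-fold CV.

    For each fraction, a random subset of that size is drawn and the mean
    train and validation MAE over the folds is recorded.  Deterministic for
    a fixed seed.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if len(X) < n_folds * 5:
        raise ValueError(f"need at least {n_folds * 5} samples for the learning curve, got {len(X)}")
    rng = np.random.default_rng(seed)
    train_maes, test_maes = [], []
    for frac in LCA_FRACTIONS:
        n_sub = max(int(round(frac * len(X))), n_folds * 2)
        idx = rng.permutation(len(X))[:n_sub]
        Xs, ys = X[idx], y[idx]
        kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_train, fold_test = [], []
        for tr, va in kf.split(Xs):
            m = clone(model)
            m.fit(Xs[tr], ys[tr])
            fold_train.append(float(np.mean(np.abs(ys[tr] - m.predict(Xs[tr])))))
            fold_test.append(float(np.mean(np.abs(ys[va] - m.predict(Xs[va])))))
        train_maes.append(float(np.mean(fold_train)))
        test_maes.append(float(np.mean(fold_test)))
    return LearningCurve(LCA_FRACTIONS, tuple(train_maes), tuple(test_maes))


@dataclass(frozen=True)
class ScoreBreakdown:
    """Components of the composite loss; ``total`` is their weighted sum."""

    base_error: float
    positive_fraction: float
    outlier_frac: float
    lca_gap: float
    weights: tuple[float, float, float, float]
    total: float

    def as_dict(self) -> dict[str, float]:
        return {
            "base_error": self.base_error,
            "positive_fraction": self.positive_fraction,
            "outlier_fraction": self.outlier_frac,
            "lca_gap": self.lca_gap,
            "total": self.total,
        }


def custom_loss(
    model,
    train_features,
    train_targets,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0),
    cv_seed: int = 0,
    base_metric: str = "mae",
    with_lca: bool = True,
) -> ScoreBreakdown:
    """Composite training loss with overfitting penalties.

    total = w0*base_error + w1*positive_fraction + w2*outlier_fraction/100
          + w3*max(learning-curve gap, 0)

    where base_error is the training-set MAE (or MSE if ``base_metric='mse'``),
    positive_fraction is the share of predictions with log10_x >= 0, and the
    gap comes from :func:`learning_curve`.  The model is fitted in place on
    the full training set.
    """
    if base_metric not in ("mae", "mse"):
        raise ValueError(f"base_metric must be 'mae' or 'mse', got {base_metric!r}")
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_targets, dtype=float)
    model.fit(X, y)
    pred = model.predict(X)
    err = y - pred
    base = float(np.mean(np.abs(err))) if base_metric == "mae" else float(np.mean(err**2))
    pos_frac = float(np.mean(pred >= 0.0))
    out_pct, _ = outlier_fraction(pred, y)
    if with_lca:
        gap = learning_curve(model, X, y, seed=cv_seed).gap
    else:
        gap = 0.0
    w0, w1, w2, w3 = weights
    total = w0 * base + w1 * pos_frac + w2 * out_pct / 100.0 + w3 * max(gap, 0.0)
    return ScoreBreakdown(
        base_error=base,
        positive_fraction=pos_frac,
        outlier_frac=out_pct,
        lca_gap=gap,
        weights=tuple(weights),
        total=float(total),
    )
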