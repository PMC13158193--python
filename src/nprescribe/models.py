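"""Candidate yield-response families and calibration-split selection.

Three families are fit on the concatenated [covariates, N] design under
squared-error loss and compared by RMSE on the held-out grouped calibration
split:

* ``ridge`` — linear ridge regression (interpretable reference);
* ``additive`` — a generalized additive structure: each continuous feature
  expanded in a cubic B-spline basis with 5 interior knots at training
  empirical quantiles {1/6,...,5/6}, one-hot indicators entering linearly,
  no pairwise interactions, fit by ridge with penalty eta = 1.0;
* ``tree_ensemble`` — a bagged random-forest regressor (300 trees, fixed
  seed) to capture nonlinear interactions among soil, weather, vegetation
  and management signals.

Ties in calibration RMSE break toward the simpler family
(ridge < additive < tree_ensemble).
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.preprocessing import SplineTransformer

from .preprocess import FeatureMatrix

FAMILIES = ("ridge", "additive", "tree_ensemble")


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    family: str = "tree_ensemble"
    ridge_alpha: float = 1.0
    spline_degree: int = 3
    spline_knots: int = 5
    additive_penalty: float = 1.0  # eta
    n_trees: int = 300
    seed: int = 0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ModelError(f"unknown family {self.family!r}")
        if self.additive_penalty < 0 or self.ridge_alpha < 0:
            raise ModelError("ridge penalties must be >= 0")
        if self.spline_knots < 1 or self.n_trees < 1:
            raise ModelError("spline_knots and n_trees must be >= 1")


def _quantile_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Interior knots at quantiles k/(n_knots+1); de-degenerated if needed."""
    qs = np.linspace(0, 1, n_knots + 2)[1:-1]
    knots = np.quantile(x, qs)
    if not np.all(np.diff(knots) > 0):
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            lo, hi = lo - 0.5, lo + 0.5
        knots = np.linspace(lo, hi, n_knots)
    return knots


class _AdditiveRegressor:
    """Per-feature spline expansion on continuous columns + linear one-hots,
    followed by a single ridge fit."""

    def __init__(self, cfg: ModelConfig, is_onehot: np.ndarray):
        self.cfg = cfg
        self.is_onehot = is_onehot
        self._splines: list[SplineTransformer] = []
        self._ridge = Ridge(alpha=cfg.additive_penalty)

    def _expand(self, X: np.ndarray, fit: bool) -> np.ndarray:
        cont = np.where(~self.is_onehot)[0]
        blocks = []
        for k, j in enumerate(cont):
            col = X[:, [j]]
            if fit:
                knots = _quantile_knots(X[:, j], self.cfg.spline_knots)
                tr = SplineTransformer(
                    degree=self.cfg.spline_degree,
                    knots=knots.reshape(-1, 1),
                    extrapolation="linear",
                    include_bias=False,
                )
                tr.fit(col)
                self._splines.append(tr)
            else:
                tr = self._splines[k]
            blocks.append(tr.transform(col))
        if self.is_onehot.any():
            blocks.append(X[:, self.is_onehot])
        return np.column_stack(blocks)

    def fit(self, X, y):
        self._splines = []
        self._ridge.fit(self._expand(X, fit=True), y)
        return self

    def predict(self, X):
        return self._ridge.predict(self._expand(X, fit=False))


@dataclass
class FittedYieldModel:
    estimator: object
    family: str
    columns: list[str]
    config: ModelConfig

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        if fm.columns != self.columns:
            raise ModelError("feature registry differs from training layout")
        return np.asarray(self.estimator.predict(fm.X), dtype=float)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "FittedYieldModel":
        return joblib.load(path)


def fit_yield_model(cfg: ModelConfig, fm: FeatureMatrix, y=None) -> FittedYieldModel:
    """Fit one candidate family on a feature matrix (targets default to
    ``fm.y``); deterministic given the config seed."""
    cfg.validate()
    if fm.X.shape[1] == 0:
        raise ModelError("degenerate design: no feature columns")
    target = fm.y if y is None else np.asarray(y, dtype=float)
    if cfg.family == "ridge":
        est = Ridge(alpha=cfg.ridge_alpha)
    elif cfg.family == "additive":
        est = _AdditiveRegressor(cfg, fm.is_onehot)
    else:
        est = RandomForestRegressor(
            n_estimators=cfg.n_trees, random_state=cfg.seed, n_jobs=1
        )
    est.fit(fm.X, target)
    return FittedYieldModel(
        estimator=est, family=cfg.family, columns=list(fm.columns), config=cfg
    )


def score(y_true, y_pred) -> tuple[float, float]:
    """(RMSE, MAE); errors on empty input."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ModelError("score requires equal-length non-empty vectors")
    err = y_true - y_pred
    return float(np.sqrt(np.mean(err**2))), float(np.mean(np.abs(err)))


def select_model(
    candidates: list[ModelConfig],
    train_fm: FeatureMatrix,
    cal_fm: FeatureMatrix,
) -> tuple[FittedYieldModel, list[dict]]:
    """Fit each candidate on train, score on calibration, keep lowest RMSE.

    Exact RMSE ties break toward the simpler family in FAMILIES order.
    Returns the winning fitted model and a per-family report.
    """
    if not candidates:
        raise ModelError("need at least one candidate")
    report = []
    fitted = []
    for cfg in candidates:
        model = fit_yield_model(cfg, train_fm)
        rmse, mae = score(cal_fm.y, model.predict(cal_fm))
        fitted.append(model)
        report.append(
            {"family": cfg.family, "calibration_rmse": rmse, "calibration_mae": mae}
        )
    best = min(
        range(len(candidates)),
        key=lambda i: (
            report[i]["calibration_rmse"],
            FAMILIES.index(candidates[i].family),
        ),
    )
    report[best]["selected"] = True
    for i, row in enumerate(report):
        row.setdefault("selected", False)
    return fitted[best], report
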