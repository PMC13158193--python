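"""Split conformal yield intervals and comparator interval methods.

Split conformal prediction turns the fitted yield model into prediction
intervals with a finite-sample marginal coverage guarantee. Absolute
residual scores s_i = |y_i - yhat_i| are computed on the disjoint
calibration partition; for miscoverage alpha the conformal quantile is the
r-th smallest score with the finite-sample rank correction

    r = ceil((n + 1) * (1 - alpha)),

taken as an exact order statistic (no interpolation — interpolating would
forfeit the guarantee). If r exceeds n (tiny calibration sets) the maximum
score is used, a documented conservative fallback. The interval at a query
is the symmetric expansion [yhat - q, yhat + q]; its width 2q is constant
across queries, which is the defining property of the split construction.

Three uncertainty comparators are provided: per-quantile gradient-boosted
pinball regression, a bootstrap ensemble of the main model family, and
Monte-Carlo dropout over a small multilayer perceptron. None carries the
finite-sample guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor

from .models import FittedYieldModel, ModelConfig, fit_yield_model
from .preprocess import FeatureMatrix


class CalibrationError(ValueError):
    pass


def conformal_quantile(scores, alpha: float) -> float:
    """Rank-corrected empirical quantile of the nonconformity scores."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise CalibrationError("cannot calibrate on an empty score set")
    if not (0.0 < alpha < 1.0):
        raise CalibrationError("alpha must lie in (0, 1)")
    r = math.ceil((n + 1) * (1.0 - alpha))
    ordered = np.sort(scores)
    if r > n:
        return float(ordered[-1])
    return float(ordered[r - 1])


@dataclass
class ConformalCalibration:
    scores: np.ndarray
    alpha: float
    q: float

    @property
    def level(self) -> float:
        return 1.0 - self.alpha


def calibrate(
    model: FittedYieldModel, cal_fm: FeatureMatrix, alpha: float
) -> ConformalCalibration:
    """Score the calibration partition and fix the conformal quantile."""
    scores = np.abs(cal_fm.y - model.predict(cal_fm))
    return ConformalCalibration(
        scores=scores, alpha=alpha, q=conformal_quantile(scores, alpha)
    )


def conformal_interval(y_hat, q: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric interval(s) [yhat - q, yhat + q]."""
    if q < 0:
        raise CalibrationError("conformal quantile must be >= 0")
    y_hat = np.asarray(y_hat, dtype=float)
    return y_hat - q, y_hat + q


def empirical_coverage(lower, upper, y_true, groups=None) -> dict:
    """Fraction of targets inside their intervals, plus width; optionally
    per-group coverage with mean-group and worst-group summaries."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    y_true = np.asarray(y_true, dtype=float)
    inside = (lower <= y_true) & (y_true <= upper)
    report = {
        "coverage": float(np.mean(inside)),
        "mean_width": float(np.mean(upper - lower)),
        "n": int(y_true.size),
    }
    if groups is not None:
        groups = np.asarray(groups)
        per_group = {}
        for g in np.unique(groups):
            per_group[g] = float(np.mean(inside[groups == g]))
        vals = np.array(list(per_group.values()))
        report["per_group"] = per_group
        report["mean_group_coverage"] = float(vals.mean())
        report["worst_group_coverage"] = float(vals.min())
    return report


@dataclass(frozen=True)
class IntervalMethodConfig:
    method: str = "conformal"  # conformal | quantile_regression | ensemble | dropout
    ensemble_members: int = 10  # M
    dropout_rate: float = 0.20  # p
    dropout_passes: int = 50  # T
    hidden_units: tuple[int, int] = (64, 64)
    epochs: int = 150
    seed: int = 0

    def validate(self) -> None:
        if self.method not in {"conformal", "quantile_regression", "ensemble", "dropout"}:
            raise CalibrationError(f"unknown interval method {self.method!r}")
        if self.ensemble_members < 2 or self.dropout_passes < 2:
            raise CalibrationError("M and T must be >= 2")
        if not (0.0 < self.dropout_rate < 1.0):
            raise CalibrationError("dropout rate must lie in (0, 1)")


class MCDropoutMLP:
    """Minimal fully connected regressor with inverted dropout.

    Two ReLU hidden layers; dropout stays active at prediction time so that
    repeated stochastic forward passes sample an approximate predictive
    distribution. Trained with Adam on mean squared error.
    """

    def __init__(self, hidden=(64, 64), p_drop=0.2, epochs=150, batch=128,
                 lr=1e-3, seed=0):
        self.hidden = hidden
        self.p_drop = p_drop
        self.epochs = epochs
        self.batch = batch
        self.lr = lr
        self.seed = seed
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self._y_mu = 0.0
        self._y_sd = 1.0

    def _init(self, d_in: int, rng):
        dims = [d_in, *self.hidden, 1]
        self.weights = [
            rng.normal(0, np.sqrt(2.0 / dims[i]), (dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]

    def _forward(self, X, rng=None):
        """Forward pass; dropout applied after each hidden layer whenever an
        rng is supplied (training and stochastic prediction alike)."""
        acts = [X]
        h = X
        masks = []
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            if i < len(self.weights) - 1:
                h = np.maximum(z, 0.0)
                if rng is not None:
                    keep = rng.random(h.shape) >= self.p_drop
                    h = h * keep / (1.0 - self.p_drop)
                    masks.append(keep)
                acts.append(h)
            else:
                h = z[:, 0]
        return h, acts, masks

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self._y_mu, self._y_sd = float(y.mean()), float(y.std() + 1e-8)
        t = (y - self._y_mu) / self._y_sd
        rng = np.random.default_rng(self.seed)
        self._init(X.shape[1], rng)
        m = [np.zeros_like(w) for w in self.weights + self.biases]
        v = [np.zeros_like(w) for w in self.weights + self.biases]
        step = 0
        for _ in range(self.epochs):
            order = rng.permutation(len(X))
            for start in range(0, len(X), self.batch):
                idx = order[start : start + self.batch]
                xb, tb = X[idx], t[idx]
                pred, acts, masks = self._forward(xb, rng)
                grad_out = 2.0 * (pred - tb) / len(idx)
                grads_w, grads_b = [], []
                delta = grad_out[:, None]
                for i in range(len(self.weights) - 1, -1, -1):
                    h_in = acts[i]
                    grads_w.insert(0, h_in.T @ delta)
                    grads_b.insert(0, delta.sum(axis=0))
                    if i > 0:
                        delta = delta @ self.weights[i].T
                        delta = delta * masks[i - 1] / (1.0 - self.p_drop)
                        delta = delta * (acts[i] > 0)
                step += 1
                params = self.weights + self.biases
                grads = grads_w + [g.reshape(b.shape) for g, b in
                                   zip(grads_b, self.biases)]
                for k, (p, g) in enumerate(zip(params, grads)):
                    m[k] = 0.9 * m[k] + 0.1 * g
                    v[k] = 0.999 * v[k] + 0.001 * g**2
                    mhat = m[k] / (1 - 0.9**step)
                    vhat = v[k] / (1 - 0.999**step)
                    p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)
        return self

    def predict_stochastic(self, X, n_passes: int, seed: int = 0) -> np.ndarray:
        """(n_passes, n_samples) array of dropout-perturbed predictions."""
        X = np.asarray(X, dtype=float)
        rng = np.random.default_rng(seed)
        out = np.empty((n_passes, len(X)))
        for t in range(n_passes):
            pred, _, _ = self._forward(X, rng)
            out[t] = pred
        return out * self._y_sd + self._y_mu


def baseline_intervals(
    cfg: IntervalMethodConfig,
    train_fm: FeatureMatrix,
    query_fm: FeatureMatrix,
    alpha: float,
    model_cfg: ModelConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Comparator intervals for the query points at nominal level 1 - alpha.

    quantile_regression: gradient-boosted pinball regressors at quantiles
    (alpha/2, 1 - alpha/2); crossed endpoints repaired by sorting.
    ensemble: M bootstrap-resampled fits of ``model_cfg`` (the selected main
    family); central (1 - alpha) percentile interval over member outputs.
    dropout: T stochastic forward passes of the dropout MLP; same percentile
    interval.
    """
    cfg.validate()
    lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0
    if cfg.method == "quantile_regression":
        lo_est = GradientBoostingRegressor(
            loss="quantile", alpha=lo_q, random_state=cfg.seed
        )
        hi_est = GradientBoostingRegressor(
            loss="quantile", alpha=hi_q, random_state=cfg.seed
        )
        lo_est.fit(train_fm.X, train_fm.y)
        hi_est.fit(train_fm.X, train_fm.y)
        a = lo_est.predict(query_fm.X)
        b = hi_est.predict(query_fm.X)
        return np.minimum(a, b), np.maximum(a, b)

    if cfg.method == "ensemble":
        model_cfg = model_cfg or ModelConfig()
        rng = np.random.default_rng(cfg.seed)
        preds = np.empty((cfg.ensemble_members, len(query_fm.X)))
        n = len(train_fm.X)
        for m in range(cfg.ensemble_members):
            idx = rng.integers(0, n, size=n)
            boot = FeatureMatrix(
                X=train_fm.X[idx],
                columns=train_fm.columns,
                is_onehot=train_fm.is_onehot,
                y=train_fm.y[idx],
                n_rate=train_fm.n_rate[idx],
                index=train_fm.index[idx],
            )
            member = fit_yield_model(
                ModelConfig(**{**model_cfg.__dict__, "seed": cfg.seed + 1 + m}),
                boot,
            )
            preds[m] = member.estimator.predict(query_fm.X)
        return (
            np.percentile(preds, 100 * lo_q, axis=0),
            np.percentile(preds, 100 * hi_q, axis=0),
        )

    if cfg.method == "dropout":
        net = MCDropoutMLP(
            hidden=cfg.hidden_units,
            p_drop=cfg.dropout_rate,
            epochs=cfg.epochs,
            seed=cfg.seed,
        )
        net.fit(train_fm.X, train_fm.y)
        draws = net.predict_stochastic(
            query_fm.X, cfg.dropout_passes, seed=cfg.seed + 1
        )
        return (
            np.percentile(draws, 100 * lo_q, axis=0),
            np.percentile(draws, 100 * hi_q, axis=0),
        )

    raise CalibrationError(
        "baseline_intervals handles the comparator methods; use calibrate() "
        "for split conformal"
    )
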