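"""Train-only-fitted cleaning and encoding.

All statistics — imputation medians, winsor bounds, category vocabularies and
standardization moments — are computed on the training partition alone and
then applied unchanged to calibration and test data, so nothing learned
downstream can leak across the grouped split.

Per numeric feature z the transform is: impute the training median, clip to
the training winsor bounds, then standardize

    z' = (z - mu_tr) / (sigma_tr + eps),      eps = 1e-8,

with the population convention (divide by n) for sigma. Winsor bounds are
empirical quantiles with linear interpolation of order statistics. The yield
target and the nitrogen rate are winsorized like any other numeric column
but kept in native units (yield enters the profit model unscaled; the rate
is additionally standardized as a model feature). Categorical features map
missing and unseen levels to a reserved "unknown" token before one-hot
encoding. Planting/harvest dates are converted to season-timing features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import schema

EPS = 1e-8


class FitError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def normalize_category(value) -> str:
    """Trim, lowercase; missing becomes the reserved 'unknown' token."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "unknown"
    if pd.isna(value):
        return "unknown"
    s = str(value).strip().lower()
    return s if s else "unknown"


def derive_time_features(planting, harvest) -> tuple[float, float]:
    """Season-timing features from one (planting, harvest) date pair.

    Returns (season_length_days, planting_day_of_year). A harvest before
    planting is flagged by returning NaNs (imputed downstream like any other
    missing numeric value).
    """
    p = pd.to_datetime(planting, errors="coerce")
    h = pd.to_datetime(harvest, errors="coerce")
    if pd.isna(p) or pd.isna(h) or h < p:
        return (np.nan, np.nan)
    return (float((h - p).days), float(p.dayofyear))


def _time_feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    if "PlantingDate" not in table.columns or "HarvestDate" not in table.columns:
        nan = np.full(len(table), np.nan)
        return pd.DataFrame(
            {"SeasonLengthDays": nan, "PlantingDayOfYear": nan}, index=table.index
        )
    p = pd.to_datetime(table["PlantingDate"], errors="coerce")
    h = pd.to_datetime(table["HarvestDate"], errors="coerce")
    length = (h - p).dt.days.astype(float)
    doy = p.dt.dayofyear.astype(float)
    bad = length < 0
    length[bad] = np.nan
    doy[bad] = np.nan
    return pd.DataFrame(
        {"SeasonLengthDays": length.to_numpy(), "PlantingDayOfYear": doy.to_numpy()},
        index=table.index,
    )


@dataclass
class NumericStats:
    median: float
    lo: float
    hi: float
    mu: float
    sd: float


@dataclass
class PreprocessorState:
    numeric_stats: dict[str, NumericStats] = field(default_factory=dict)
    vocabularies: dict[str, list[str]] = field(default_factory=dict)
    winsor_q: tuple[float, float] = (0.01, 0.99)
    eps: float = EPS
    missingness: dict[str, float] = field(default_factory=dict)
    fitted: bool = False


@dataclass
class FeatureMatrix:
    """Model-ready design matrix with its column registry.

    ``y`` and ``n_rate`` are kept in native units alongside the standardized
    matrix; ``is_onehot`` marks indicator columns (splines are only expanded
    on continuous columns).
    """

    X: np.ndarray
    columns: list[str]
    is_onehot: np.ndarray
    y: np.ndarray
    n_rate: np.ndarray
    index: pd.Index

    def select(self, base_columns: list[str]) -> "FeatureMatrix":
        """Restrict to columns derived from the given base (pre-encoding)
        names; the nitrogen-rate column is always retained."""
        keep_base = set(base_columns) | {schema.RATE}
        keep = [
            i
            for i, name in enumerate(self.columns)
            if name.split("=", 1)[0] in keep_base
        ]
        return FeatureMatrix(
            X=self.X[:, keep],
            columns=[self.columns[i] for i in keep],
            is_onehot=self.is_onehot[keep],
            y=self.y,
            n_rate=self.n_rate,
            index=self.index,
        )


def _numeric_frame(table: pd.DataFrame) -> pd.DataFrame:
    """All numeric model inputs incl. derived time features, N and Yield."""
    cols = {}
    for col in schema.NUMERIC_COVARIATES + [schema.RATE, schema.TARGET]:
        if col not in table.columns:
            raise SchemaError(f"missing column {col!r}")
        cols[col] = pd.to_numeric(table[col], errors="coerce")
    frame = pd.DataFrame(cols, index=table.index)
    return pd.concat([frame, _time_feature_frame(table)], axis=1)


def fit_preprocessor(
    train: pd.DataFrame, winsor_q: tuple[float, float] = (0.01, 0.99)
) -> PreprocessorState:
    """Fit imputation, winsorization, encoding and standardization on train."""
    if len(train) == 0:
        raise FitError("cannot fit preprocessor on an empty table")
    lo_q, hi_q = winsor_q
    if not (0.0 <= lo_q <= hi_q <= 1.0):
        raise FitError("winsor quantiles must satisfy 0 <= lo <= hi <= 1")

    state = PreprocessorState(winsor_q=(lo_q, hi_q))
    numeric = _numeric_frame(train)

    for col in numeric.columns:
        vals = numeric[col].to_numpy(float)
        state.missingness[col] = float(np.mean(np.isnan(vals)))
        finite = vals[~np.isnan(vals)]
        if finite.size == 0:
            # fully missing column: neutral statistics, transforms to zeros
            state.numeric_stats[col] = NumericStats(0.0, 0.0, 0.0, 0.0, 0.0)
            continue
        med = float(np.median(finite))
        lo, hi = (float(q) for q in np.quantile(finite, [lo_q, hi_q]))
        imputed = np.where(np.isnan(vals), med, vals)
        clipped = np.clip(imputed, lo, hi)
        state.numeric_stats[col] = NumericStats(
            median=med,
            lo=lo,
            hi=hi,
            mu=float(np.mean(clipped)),
            sd=float(np.std(clipped)),  # population convention
        )

    for col in schema.CATEGORICAL_COVARIATES:
        if col not in train.columns:
            raise SchemaError(f"missing column {col!r}")
        raw = train[col].map(normalize_category)
        state.missingness[col] = float(np.mean(raw == "unknown"))
        vocab = sorted(set(raw) | {"unknown"})
        state.vocabularies[col] = vocab

    state.fitted = True
    return state


def transform(
    table: pd.DataFrame, state: PreprocessorState, n_override=None
) -> FeatureMatrix:
    """Apply a fitted preprocessor; deterministic and idempotent.

    ``n_override`` substitutes a candidate nitrogen rate (scalar or per-row
    array) for the observed one before standardization — the grid sweep of
    the decision layer. Override values are decision inputs, not noisy
    measurements, so they are standardized but not winsorized.
    """
    if not state.fitted:
        raise FitError("preprocessor state is not fitted")
    numeric = _numeric_frame(table)
    unknown = set(numeric.columns) - set(state.numeric_stats)
    if unknown:
        raise SchemaError(f"columns not seen at fit time: {sorted(unknown)}")

    blocks: list[np.ndarray] = []
    names: list[str] = []
    onehot: list[bool] = []

    n_native = None
    y_native = None
    for col in numeric.columns:
        st = state.numeric_stats[col]
        vals = numeric[col].to_numpy(float)
        vals = np.where(np.isnan(vals), st.median, vals)
        vals = np.clip(vals, st.lo, st.hi)
        if col == schema.TARGET:
            y_native = vals
            continue  # target never enters the design matrix
        if col == schema.RATE:
            if n_override is not None:
                vals = np.broadcast_to(
                    np.asarray(n_override, dtype=float), (len(table),)
                ).copy()
            n_native = vals
        blocks.append((vals - st.mu) / (st.sd + state.eps))
        names.append(col)
        onehot.append(False)

    for col, vocab in state.vocabularies.items():
        raw = table[col].map(normalize_category)
        known = raw.where(raw.isin(vocab), "unknown")
        for cat in vocab:
            blocks.append((known == cat).to_numpy(float))
            names.append(f"{col}={cat}")
            onehot.append(True)

    X = np.column_stack(blocks)
    return FeatureMatrix(
        X=X,
        columns=names,
        is_onehot=np.asarray(onehot),
        y=y_native,
        n_rate=n_native,
        index=table.index,
    )


def deduplicate(table: pd.DataFrame) -> pd.DataFrame:
    """Drop exact duplicate rows after type normalization, keeping the first.

    Categorical and date fields are normalized (trim/lowercase, ISO dates)
    before comparison so rows differing only in formatting count as equal.
    """
    probe = table.copy()
    for col in schema.CATEGORICAL_COVARIATES:
        if col in probe.columns:
            probe[col] = probe[col].map(normalize_category)
    for col in schema.DATE_COLUMNS:
        if col in probe.columns:
            probe[col] = pd.to_datetime(probe[col], errors="coerce").dt.strftime(
                "%Y-%m-%d"
            )
    keep = ~probe.duplicated(keep="first")
    return table.loc[keep].copy()


def missingness_summary(state: PreprocessorState) -> pd.Series:
    """Per-feature missing fraction observed on the training split."""
    return pd.Series(state.missingness, name="missing_fraction").sort_index()
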