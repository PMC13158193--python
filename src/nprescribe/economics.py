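"""Profit model, environmental surplus penalty, and interval propagation.

Profit for context x at candidate rate N is the affine map

    pi(x, N) = p_g * y(x, N) - c_N * N - c_app - lambda * phi(x, N),

with phi(x, N) = max(0, N - N_ref(x)) the surplus proxy: nitrogen applied
above the context's reference level, standing in for loss/leaching risk.
The reference rate is the training-split mean N of the record's
(region, crop) subgroup, falling back to a global reference (default
105.19 kg/ha) when the subgroup is absent from training.

Because the map is affine in yield, a yield interval propagates to a profit
interval exactly: apply the formula to each endpoint. The profit-interval
width is p_g times the yield-interval width.

Default parameter values (p_g=1.0, c_N=0.02, c_app=0.25, lambda=0.5) are
artifact defaults on the package's abstract currency/yield scale; every
value is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import normalize_category

GLOBAL_REFERENCE_RATE = 105.19  # kg/ha


@dataclass(frozen=True)
class EconomicParams:
    p_g: float = 1.0  # currency per yield unit
    c_N: float = 0.02  # currency per kg/ha nitrogen
    c_app: float = 0.25  # fixed application cost
    lam: float = 0.5  # environmental penalty weight, >= 0

    def validate(self) -> None:
        if self.p_g <= 0:
            raise ValueError("grain price p_g must be > 0")
        if self.lam < 0:
            raise ValueError("penalty weight lambda must be >= 0")


@dataclass
class ReferenceRateTable:
    rates: dict[tuple[str, str], float] = field(default_factory=dict)
    fallback: float = GLOBAL_REFERENCE_RATE

    def lookup(self, region, crop) -> float:
        key = (normalize_category(region), normalize_category(crop))
        return self.rates.get(key, self.fallback)

    def lookup_table(self, table: pd.DataFrame) -> np.ndarray:
        return np.array(
            [self.lookup(r, c) for r, c in zip(table["Region"], table["CropType"])]
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": r, "crop": c, "reference_rate": v}
            for (r, c), v in sorted(self.rates.items())
        ]
        return pd.DataFrame(rows)


def build_reference_rates(
    train: pd.DataFrame, fallback: float = GLOBAL_REFERENCE_RATE
) -> ReferenceRateTable:
    """Per-(region, crop) mean training nitrogen rate, with global fallback."""
    region = train["Region"].map(normalize_category)
    crop = train["CropType"].map(normalize_category)
    n = pd.to_numeric(train["N"], errors="coerce")
    means = n.groupby([region, crop]).mean()
    rates = {key: float(v) for key, v in means.items() if np.isfinite(v)}
    return ReferenceRateTable(rates=rates, fallback=fallback)


def surplus(n_rate, n_ref):
    """phi = max(0, N - N_ref)."""
    return np.maximum(0.0, np.asarray(n_rate, dtype=float) - np.asarray(n_ref, dtype=float))


def profit(y, n_rate, n_ref, params: EconomicParams):
    """pi = p_g*y - c_N*N - c_app - lambda*phi."""
    y = np.asarray(y, dtype=float)
    n_rate = np.asarray(n_rate, dtype=float)
    return (
        params.p_g * y
        - params.c_N * n_rate
        - params.c_app
        - params.lam * surplus(n_rate, n_ref)
    )


@dataclass(frozen=True)
class ProfitInterval:
    lower: float
    upper: float
    n_rate: float


def propagate(lower_y, upper_y, n_rate, n_ref, params: EconomicParams):
    """Map yield-interval endpoints through the profit formula.

    Exact to machine precision; works element-wise on arrays. Returns
    (L_pi, U_pi).
    """
    return (
        profit(lower_y, n_rate, n_ref, params),
        profit(upper_y, n_rate, n_ref, params),
    )
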