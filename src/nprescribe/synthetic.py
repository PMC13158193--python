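"""Synthetic field-data generator.

Emulates the statistical structure the prescription framework assumes:
region x crop x season x year grouping, a heterogeneous concave yield-nitrogen
response, optionally heteroscedastic noise, configurable missingness and
duplicated records. The true response surface is returned alongside the table
so decision rules can be scored against a known oracle.

The response family is quadratic in nitrogen with group-specific coefficients,

    y = a(r, c) + da(x) + (b(r, c) + db(x)) * N - c(r, c) * N**2 + eps,

where ``(r, c)`` indexes (region, crop), ``da``/``db`` are small linear
loadings on standardized covariates (so contextual features carry signal),
and ``eps`` is Gaussian with sd ``noise_sd_base * (1 + |z_rain| / 2)`` when
heteroscedastic noise is enabled. A quadratic keeps the profit-maximizing
rate available in closed form: with grain price ``p_g`` and nitrogen cost
``c_N`` the unconstrained optimum is ``(p_g*b - c_N) / (2*p_g*c)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema

_CROPS = ["wheat", "maize", "rice", "soybean", "barley", "cotton"]
_SEASONS = ["kharif", "rabi", "zaid"]
_SOIL_TYPES = ["loam", "clay", "sandy", "silt"]
_GROWTH_STAGES = ["vegetative", "flowering", "grain_fill", "maturity"]
_FERTILIZERS = ["urea", "dap", "npk"]
_PESTICIDE = ["low", "medium", "high"]
# nominal planting month per season (kharif: monsoon, rabi: winter, zaid: spring)
_SEASON_PLANTING_MONTH = {"kharif": 6, "rabi": 11, "zaid": 3}

# linear loadings of standardized covariates on the response intercept (da)
# and nitrogen slope (db); kept small relative to the group coefficients
_A_LOADINGS = {"NDVI": 0.30, "OrganicCarbon": 0.20, "Rainfall": 0.15, "Slope": -0.10}
_B_LOADINGS = {"WaterHoldingCapacity": 0.002, "NDVI": 0.0015}


class GeneratorConfigError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic field-data generator."""

    n_samples: int = 10_000
    n_regions: int = 4
    n_crops: int = 3
    n_years: int = 3
    n_seasons: int = 2
    intercept_range: tuple[float, float] = (2.0, 4.0)  # a, yield units
    slope_range: tuple[float, float] = (0.025, 0.05)  # b, yield per kg/ha
    curvature_range: tuple[float, float] = (8e-5, 2e-4)  # c, yield per (kg/ha)^2
    noise_sd_base: float = 0.6  # yield units
    heteroscedastic: bool = True
    missing_rate_per_feature: float = 0.02
    duplicate_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise GeneratorConfigError("n_samples must be >= 1")
        for name in ("n_regions", "n_crops", "n_years", "n_seasons"):
            if getattr(self, name) < 1:
                raise GeneratorConfigError(f"{name} must be >= 1")
        if self.n_crops > len(_CROPS) or self.n_seasons > len(_SEASONS):
            raise GeneratorConfigError("too many crops or seasons requested")
        if self.curvature_range[0] <= 0:
            raise GeneratorConfigError("curvature range must be strictly positive")
        for name in ("missing_rate_per_feature", "duplicate_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate < 1.0):
                raise GeneratorConfigError(f"{name} must lie in [0, 1)")
        if self.noise_sd_base < 0:
            raise GeneratorConfigError("noise_sd_base must be >= 0")


@dataclass
class TrueResponse:
    """Ground-truth yield response used for oracle evaluation.

    ``coefficients`` maps (region, crop) to (a, b, c) of the quadratic
    response; ``covariate_scales`` stores the (mean, sd) used to standardize
    the covariates entering the loadings, so the noise-free response can be
    recomputed for any table produced by the same generator.
    """

    coefficients: dict[tuple[str, str], tuple[float, float, float]]
    covariate_scales: dict[str, tuple[float, float]]
    a_loadings: dict[str, float] = field(default_factory=lambda: dict(_A_LOADINGS))
    b_loadings: dict[str, float] = field(default_factory=lambda: dict(_B_LOADINGS))
    noise_sd_base: float = 0.6
    heteroscedastic: bool = True

    def group_yield(self, region: str, crop: str, n_rate) -> np.ndarray:
        """Noise-free group-level response a + b*N - c*N**2 (loadings at 0)."""
        a, b, c = self.coefficients[(region, crop)]
        n_rate = np.asarray(n_rate, dtype=float)
        return a + b * n_rate - c * n_rate**2

    def _zscore(self, table: pd.DataFrame, col: str) -> np.ndarray:
        mu, sd = self.covariate_scales[col]
        z = (pd.to_numeric(table[col], errors="coerce").to_numpy(float) - mu) / sd
        return np.nan_to_num(z)  # missing covariate contributes no shift

    def expected_yield(self, table: pd.DataFrame, n_rate) -> np.ndarray:
        """Noise-free per-row response including covariate loadings.

        Rows whose region/crop labels were masked by missingness injection
        fall back to the mean coefficients across groups (the marginal
        response).
        """
        n_rate = np.broadcast_to(np.asarray(n_rate, dtype=float), (len(table),))
        mean_abc = tuple(np.mean(list(self.coefficients.values()), axis=0))
        abc = np.array(
            [
                self.coefficients.get((r, c), mean_abc)
                for r, c in zip(table["Region"], table["CropType"])
            ]
        )
        da = sum(w * self._zscore(table, col) for col, w in self.a_loadings.items())
        db = sum(w * self._zscore(table, col) for col, w in self.b_loadings.items())
        return abc[:, 0] + da + (abc[:, 1] + db) * n_rate - abc[:, 2] * n_rate**2

    def noise_sd(self, rainfall_z) -> np.ndarray:
        z = np.asarray(rainfall_z, dtype=float)
        if self.heteroscedastic:
            return self.noise_sd_base * (1.0 + np.abs(z) / 2.0)
        return np.full_like(z, self.noise_sd_base)


def true_optimal_rate(
    resp: TrueResponse,
    group: tuple[str, str],
    econ,
    grid_min: float = 10.0,
    grid_max: float = 200.0,
) -> float:
    """Closed-form profit-maximizing rate for a (region, crop) group.

    The vertex of ``p_g*(a + b*N - c*N**2) - c_N*N`` is
    ``(p_g*b - c_N) / (2*p_g*c)``; the result is clipped to the candidate
    grid range. The fixed application cost and the surplus penalty do not
    move the unconstrained vertex (the penalty only lowers it, which is why
    the expected-profit rule with a penalty prescribes at most this rate).
    """
    if econ.p_g == 0:
        raise ValueError("optimal rate undefined at zero grain price")
    a, b, c = resp.coefficients[group]
    vertex = (econ.p_g * b - econ.c_N) / (2.0 * econ.p_g * c)
    return float(np.clip(vertex, grid_min, grid_max))


def _dates_for(season: np.ndarray, year: np.ndarray, rng: np.random.Generator):
    months = np.array([_SEASON_PLANTING_MONTH[s] for s in season])
    parts = pd.DataFrame(
        {"year": year, "month": months, "day": np.ones(len(season), dtype=int)}
    )
    plant = pd.to_datetime(parts) + pd.to_timedelta(
        rng.integers(0, 21, size=len(season)), unit="D"
    )
    length = np.maximum(
        np.round(rng.normal(120, 10, size=len(season))), 30
    ).astype(int)
    harvest = plant + pd.to_timedelta(length, unit="D")
    return plant.dt.strftime("%Y-%m-%d"), harvest.dt.strftime("%Y-%m-%d")


def generate_field_table(cfg: GeneratorConfig) -> tuple[pd.DataFrame, TrueResponse]:
    """Generate a field table plus its ground-truth response.

    Deterministic given ``cfg`` (including the seed); returns exactly
    ``cfg.n_samples`` rows with the full column set of :mod:`nprescribe.schema`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples

    regions = [f"region_{i + 1}" for i in range(cfg.n_regions)]
    crops = _CROPS[: cfg.n_crops]
    seasons = _SEASONS[: cfg.n_seasons]
    years = [2018 + i for i in range(cfg.n_years)]

    coefficients = {
        (r, c): (
            float(rng.uniform(*cfg.intercept_range)),
            float(rng.uniform(*cfg.slope_range)),
            float(rng.uniform(*cfg.curvature_range)),
        )
        for r in regions
        for c in crops
    }

    df = pd.DataFrame(index=range(n))
    df["Region"] = rng.choice(regions, size=n)
    df["CropType"] = rng.choice(crops, size=n)
    df["Season"] = rng.choice(seasons, size=n)
    df["Year"] = rng.choice(years, size=n).astype(int)

    # weather / climate
    df["Temperature"] = rng.normal(25, 5, n)
    df["Humidity"] = np.clip(rng.normal(65, 12, n), 5, 100)
    df["Rainfall"] = rng.gamma(4.0, 35.0, n)
    df["SolarRadiation"] = np.clip(rng.normal(18, 4, n), 1, None)
    df["WindSpeed"] = np.abs(rng.normal(3, 1.5, n))
    df["GrowingDegreeDays"] = np.clip(rng.normal(1500, 250, n), 200, None)

    # soil / terrain
    df["SoilType"] = rng.choice(_SOIL_TYPES, size=n)
    df["pH"] = np.clip(rng.normal(6.5, 0.7, n), 3.5, 9.5)
    df["ElectricalConductivity"] = np.abs(rng.normal(0.8, 0.3, n))
    df["OrganicCarbon"] = np.abs(rng.normal(1.2, 0.4, n))
    df["CationExchangeCapacity"] = np.clip(rng.normal(18, 5, n), 1, None)
    texture = rng.dirichlet([4.0, 3.0, 3.0], size=n) * 100.0
    df["Sand"], df["Silt"], df["Clay"] = texture[:, 0], texture[:, 1], texture[:, 2]
    df["BulkDensity"] = np.clip(rng.normal(1.4, 0.1, n), 0.8, 2.0)
    df["WaterHoldingCapacity"] = np.clip(rng.normal(22, 5, n), 2, None)
    df["Slope"] = np.abs(rng.normal(3, 2, n))
    df["Aspect"] = rng.uniform(0, 360, n)
    df["Elevation"] = np.clip(rng.normal(300, 120, n), 0, None)

    # crop condition
    df["NDVI"] = np.clip(rng.normal(0.5, 0.2, n), -1, 1)
    df["EVI"] = np.clip(0.8 * df["NDVI"] + rng.normal(0, 0.05, n), -1, 1)
    df["LAI"] = np.abs(rng.normal(3, 1, n))
    df["Chlorophyll"] = np.clip(rng.normal(40, 8, n), 1, None)

    # management
    df["GrowthStage"] = rng.choice(_GROWTH_STAGES, size=n)
    df["IrrigationFrequency"] = rng.poisson(3, n)
    df["FertilizerType"] = rng.choice(_FERTILIZERS, size=n)
    df["PesticideUsage"] = rng.choice(_PESTICIDE, size=n)
    df["PlantingDate"], df["HarvestDate"] = _dates_for(
        df["Season"].to_numpy(), df["Year"].to_numpy(), rng
    )

    df["N"] = np.clip(rng.normal(105, 35, n), 0, 250)

    # scales used by the loadings; fixed population values so the oracle does
    # not depend on the realized sample
    covariate_scales = {
        "NDVI": (0.5, 0.2),
        "OrganicCarbon": (1.2, 0.4),
        "Rainfall": (140.0, 70.0),
        "Slope": (3.0, 2.0),
        "WaterHoldingCapacity": (22.0, 5.0),
    }
    truth = TrueResponse(
        coefficients=coefficients,
        covariate_scales=covariate_scales,
        noise_sd_base=cfg.noise_sd_base,
        heteroscedastic=cfg.heteroscedastic,
    )

    rain_z = (df["Rainfall"].to_numpy() - 140.0) / 70.0
    sd = truth.noise_sd(rain_z)
    df["Yield"] = truth.expected_yield(df, df["N"].to_numpy()) + rng.normal(0, 1, n) * sd

    df = df[schema.ALL_COLUMNS]

    if cfg.duplicate_rate > 0 and n > 1:
        k = int(round(cfg.duplicate_rate * n))
        targets = rng.choice(n, size=min(k, n // 2), replace=False)
        sources = rng.choice(np.setdiff1d(np.arange(n), targets), size=len(targets))
        df.iloc[targets] = df.iloc[sources].to_numpy()

    if cfg.missing_rate_per_feature > 0:
        df = inject_missingness(
            df, cfg.missing_rate_per_feature, seed=int(rng.integers(2**31))
        )

    return df, truth


def inject_missingness(table: pd.DataFrame, rate: float, seed: int) -> pd.DataFrame:
    """Mask covariate cells independently with probability ``rate``.

    Yield and N are never masked; deterministic given ``seed``.
    """
    if not (0.0 <= rate < 1.0):
        raise GeneratorConfigError("missing rate must lie in [0, 1)")
    out = table.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    cols = [c for c in schema.COVARIATES if c in out.columns]
    mask = rng.random((len(out), len(cols))) < rate
    for j, col in enumerate(cols):
        out.loc[mask[:, j], col] = np.nan
    return out


def with_seed(cfg: GeneratorConfig, seed: int) -> GeneratorConfig:
    """Convenience: a copy of ``cfg`` with a different seed."""
    return replace(cfg, seed=seed)
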