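"""Pipeline orchestration, decision metrics, ablations and sensitivity.

``run_pipeline`` wires the stages end to end: data (generated or loaded) ->
deduplication -> grouped split -> train-only preprocessing -> model selection
-> conformal calibration at each coverage level -> per-sample nitrogen-grid
sweep -> prescriptions under every strategy. Everything downstream of the
seeds is deterministic; re-running a config reproduces the artifacts
byte-for-byte.

Evaluation of counterfactual prescriptions needs an assumption about the
yield a sample would have realized at a rate it did not receive. Two explicit
modes are provided and stamped on every report: ``oracle`` uses the synthetic
generator's true response (available only for generated data), and
``model_estimate`` uses the fitted model's own prediction at the prescribed
rate. Dispersion statistics use the population (divide-by-n) convention.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import schema
from .decide import (
    AbstentionPolicy,
    NitrogenGrid,
    Prescription,
    prescribe_eonr,
    prescribe_expected,
    prescribe_lcb,
    prescribe_uniform,
)
from .economics import (
    EconomicParams,
    ReferenceRateTable,
    build_reference_rates,
    profit,
    propagate,
)
from .grouping import SplitAssignment, grouped_split, partition_table, table_group_ids
from .models import FittedYieldModel, ModelConfig, fit_yield_model, score, select_model
from .preprocess import (
    PreprocessorState,
    deduplicate,
    fit_preprocessor,
    transform,
)
from .synthetic import GeneratorConfig, TrueResponse, generate_field_table
from .uncertainty import ConformalCalibration, calibrate, empirical_coverage

logger = logging.getLogger("nprescribe")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s [%(name)s:%(stage)s] %(message)s"))
    logger.addHandler(_h)


def _log(stage: str, msg: str) -> None:
    logger.info(msg, extra={"stage": stage})


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class ScenarioSpec:
    id: str
    p_g: float
    c_N: float
    c_app: float
    lam: float

    def params(self) -> EconomicParams:
        p = EconomicParams(p_g=self.p_g, c_N=self.c_N, c_app=self.c_app, lam=self.lam)
        p.validate()
        return p


def default_scenarios(base: EconomicParams) -> list[ScenarioSpec]:
    """One-at-a-time perturbations: +/-25% p_g and c_N, +/-50% c_app,
    lambda in {0, 2x baseline}."""
    mk = lambda sid, **kw: ScenarioSpec(
        id=sid,
        p_g=kw.get("p_g", base.p_g),
        c_N=kw.get("c_N", base.c_N),
        c_app=kw.get("c_app", base.c_app),
        lam=kw.get("lam", base.lam),
    )
    return [
        mk("p_g+25", p_g=1.25 * base.p_g),
        mk("p_g-25", p_g=0.75 * base.p_g),
        mk("c_N+25", c_N=1.25 * base.c_N),
        mk("c_N-25", c_N=0.75 * base.c_N),
        mk("c_app+50", c_app=1.5 * base.c_app),
        mk("c_app-50", c_app=0.5 * base.c_app),
        mk("lambda_0", lam=0.0),
        mk("lambda_x2", lam=2.0 * base.lam),
    ]


@dataclass
class RunConfig:
    generator: GeneratorConfig | None = field(default_factory=GeneratorConfig)
    data_path: str | None = None
    split_seed: int = 42
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    winsor_q: tuple[float, float] = (0.01, 0.99)
    model_candidates: tuple[ModelConfig, ...] = (
        ModelConfig(family="ridge"),
        ModelConfig(family="additive"),
        ModelConfig(family="tree_ensemble"),
    )
    coverage_levels: tuple[float, ...] = (0.90, 0.95)
    econ: EconomicParams = field(default_factory=EconomicParams)
    reference_fallback: float = 105.19
    grid: NitrogenGrid = field(default_factory=NitrogenGrid)
    policy: AbstentionPolicy = field(default_factory=AbstentionPolicy)
    strategies: tuple[str, ...] = ("lcb", "expected", "uniform", "eonr_point")
    evaluation_mode: str = "oracle"  # oracle | model_estimate

    def validate(self) -> None:
        if self.generator is None and self.data_path is None:
            raise PipelineError("config", "either a generator or a data path is required")
        for level in self.coverage_levels:
            if not (0.0 < level < 1.0):
                raise PipelineError("config", "coverage levels must lie in (0, 1)")
        self.econ.validate()


@dataclass
class PipelineResult:
    cfg: RunConfig
    tables: dict[str, pd.DataFrame]
    truth: TrueResponse | None
    assignment: SplitAssignment
    pre_state: PreprocessorState
    model: FittedYieldModel
    selection_report: list[dict]
    calibrations: dict[float, ConformalCalibration]
    ref_rates: ReferenceRateTable
    yhat_grid: np.ndarray  # (n_test, n_grid) model predictions over candidates
    n_ref: np.ndarray  # per test sample reference rate
    train_mean_n: float
    prescriptions: dict[tuple[str, float], list[Prescription]]

    @property
    def test(self) -> pd.DataFrame:
        return self.tables["test"]

    def point_profit_grid(self, econ: EconomicParams | None = None) -> np.ndarray:
        """pi_hat over the grid for every test sample (penalty included)."""
        econ = econ or self.cfg.econ
        rates = self.cfg.grid.rates
        return profit(
            self.yhat_grid, rates[None, :], self.n_ref[:, None], econ
        )

    def profit_interval_grid(
        self, level: float, econ: EconomicParams | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        econ = econ or self.cfg.econ
        q = self.calibrations[level].q
        rates = self.cfg.grid.rates
        return propagate(
            self.yhat_grid - q,
            self.yhat_grid + q,
            rates[None, :],
            self.n_ref[:, None],
            econ,
        )


def _load_table(cfg: RunConfig) -> tuple[pd.DataFrame, TrueResponse | None]:
    if cfg.data_path is not None:
        return pd.read_csv(cfg.data_path), None
    table, truth = generate_field_table(cfg.generator)
    return table, truth


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full prescription pipeline; deterministic given seeds."""
    cfg.validate()
    try:
        table, truth = _load_table(cfg)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged diagnostics
        raise PipelineError("data", str(exc)) from exc
    _log("data", f"{len(table)} rows")

    table = deduplicate(table)
    assignment = grouped_split(table, seed=cfg.split_seed, proportions=cfg.proportions)
    tables = partition_table(table, assignment)
    _log("split", {p: len(t) for p, t in tables.items()}.__repr__())

    pre_state = fit_preprocessor(tables["train"], winsor_q=cfg.winsor_q)
    fms = {p: transform(t, pre_state) for p, t in tables.items()}

    model, selection_report = select_model(
        list(cfg.model_candidates), fms["train"], fms["calibration"]
    )
    _log("model", f"selected {model.family}")

    calibrations = {
        level: calibrate(model, fms["calibration"], alpha=1.0 - level)
        for level in cfg.coverage_levels
    }

    ref_rates = build_reference_rates(tables["train"], fallback=cfg.reference_fallback)
    n_ref = ref_rates.lookup_table(tables["test"])
    train_mean_n = float(
        pd.to_numeric(tables["train"]["N"], errors="coerce").mean()
    )

    rates = cfg.grid.rates
    yhat_grid = np.empty((len(tables["test"]), len(rates)))
    for j, n_candidate in enumerate(rates):
        fm_j = transform(tables["test"], pre_state, n_override=n_candidate)
        yhat_grid[:, j] = model.predict(fm_j)
    _log("sweep", f"{yhat_grid.shape[0]} samples x {yhat_grid.shape[1]} candidates")

    result = PipelineResult(
        cfg=cfg,
        tables=tables,
        truth=truth,
        assignment=assignment,
        pre_state=pre_state,
        model=model,
        selection_report=selection_report,
        calibrations=calibrations,
        ref_rates=ref_rates,
        yhat_grid=yhat_grid,
        n_ref=n_ref,
        train_mean_n=train_mean_n,
        prescriptions={},
    )

    pi_hat = result.point_profit_grid()
    pi_hat_no_penalty = result.point_profit_grid(replace(cfg.econ, lam=0.0))
    for level in cfg.coverage_levels:
        lower, upper = result.profit_interval_grid(level)
        for strategy in cfg.strategies:
            key = (strategy, level)
            if strategy == "lcb":
                result.prescriptions[key] = [
                    prescribe_lcb(lower[i], upper[i], cfg.grid, cfg.policy)
                    for i in range(len(pi_hat))
                ]
            elif strategy == "expected":
                result.prescriptions[key] = [
                    prescribe_expected(pi_hat[i], cfg.grid) for i in range(len(pi_hat))
                ]
            elif strategy == "uniform":
                result.prescriptions[key] = [
                    prescribe_uniform(train_mean_n) for _ in range(len(pi_hat))
                ]
            elif strategy == "eonr_point":
                result.prescriptions[key] = [
                    prescribe_eonr(pi_hat_no_penalty[i], cfg.grid)
                    for i in range(len(pi_hat))
                ]
            else:
                raise PipelineError("prescribe", f"unknown strategy {strategy!r}")
    _log("prescribe", f"{len(result.prescriptions)} strategy/level combinations")
    return result


def prescriptions_frame(result: PipelineResult) -> pd.DataFrame:
    """Flat per-sample prescription table across strategies and levels."""
    rows = []
    for (strategy, level), prescs in sorted(result.prescriptions.items()):
        for idx, p in zip(result.test.index, prescs):
            rows.append(
                {
                    "sample_id": idx,
                    "strategy": strategy,
                    "level": level,
                    "status": p.status,
                    "rate": p.rate,
                    "lcb": p.lcb,
                    "width": p.width,
                    "ambiguity_span": p.ambiguity_span,
                    "triggers": ";".join(p.triggers),
                }
            )
    return pd.DataFrame(rows)


def _realized_yield(
    result: PipelineResult, rates: np.ndarray, mode: str
) -> np.ndarray:
    if mode == "oracle":
        if result.truth is None:
            raise PipelineError("evaluate", "oracle mode requires the true response")
        return result.truth.expected_yield(result.test, rates)
    if mode == "model_estimate":
        fm = transform(result.test, result.pre_state, n_override=rates)
        return result.model.predict(fm)
    raise PipelineError("evaluate", f"unknown evaluation mode {mode!r}")


def _population_sd(x: np.ndarray) -> float:
    return float(np.std(x)) if x.size else float("nan")


def _summary(values: np.ndarray, prefix: str) -> dict:
    if values.size == 0:
        return {
            f"{prefix}_mean": float("nan"),
            f"{prefix}_sd": float("nan"),
            f"{prefix}_iqr": float("nan"),
            f"{prefix}_p95": float("nan"),
        }
    q1, q3 = np.percentile(values, [25, 75])
    return {
        f"{prefix}_mean": float(np.mean(values)),
        f"{prefix}_sd": _population_sd(values),
        f"{prefix}_iqr": float(q3 - q1),
        f"{prefix}_p95": float(np.percentile(values, 95)),
    }


def strategy_outcomes(
    result: PipelineResult, strategy: str, level: float, mode: str | None = None
) -> pd.DataFrame:
    """Per-sample rate, realized profit and status for one strategy/level."""
    mode = mode or result.cfg.evaluation_mode
    prescs = result.prescriptions[(strategy, level)]
    rates = np.array([p.rate if p.prescribed else np.nan for p in prescs])
    prescribed = ~np.isnan(rates)
    profit_vals = np.full(len(rates), np.nan)
    if prescribed.any():
        fill = np.where(prescribed, rates, result.n_ref)  # placeholder rows dropped
        y = _realized_yield(result, fill, mode)
        pi = profit(y, fill, result.n_ref, result.cfg.econ)
        profit_vals[prescribed] = pi[prescribed]
    return pd.DataFrame(
        {
            "sample_id": result.test.index,
            "rate": rates,
            "profit": profit_vals,
            "prescribed": prescribed,
        }
    )


def evaluate_strategies(
    result: PipelineResult, level: float, mode: str | None = None
) -> pd.DataFrame:
    """Decision report: one row per strategy at the given coverage level."""
    mode = mode or result.cfg.evaluation_mode
    rows = []
    for strategy in result.cfg.strategies:
        out = strategy_outcomes(result, strategy, level, mode)
        sub = out[out.prescribed]
        row = {
            "strategy": strategy,
            "level": level,
            "evaluation_mode": mode,
            "n": len(out),
            "prescribed_fraction": float(out.prescribed.mean()),
            "abstention_rate": float(1.0 - out.prescribed.mean()),
        }
        row.update(_summary(sub["rate"].to_numpy(), "n_rate"))
        row.update(_summary(sub["profit"].to_numpy(), "profit"))
        rows.append(row)
    return pd.DataFrame(rows)


def run_scenarios(
    result: PipelineResult,
    scenarios: list[ScenarioSpec],
    level: float = 0.90,
    practical_threshold: float = 5.0,
) -> pd.DataFrame:
    """Economic sensitivity of the LCB rule.

    Re-derives profit intervals from the cached yield predictions and
    conformal quantile — the yield model, quantiles and grid are never
    refit — and re-runs only the LCB rule. Reports the mean absolute change
    in prescribed rate and the fraction of samples shifting by more than the
    practical threshold (5 kg/ha), over samples prescribed under both the
    baseline and the scenario.
    """
    grid = result.cfg.grid
    policy = result.cfg.policy
    base_prescs = result.prescriptions[("lcb", level)]
    base_rates = np.array([p.rate if p.prescribed else np.nan for p in base_prescs])

    rows = []
    for spec in scenarios:
        econ = spec.params()
        lower, upper = result.profit_interval_grid(level, econ)
        prescs = [
            prescribe_lcb(lower[i], upper[i], grid, policy)
            for i in range(len(base_prescs))
        ]
        rates = np.array([p.rate if p.prescribed else np.nan for p in prescs])
        both = ~np.isnan(base_rates) & ~np.isnan(rates)
        delta = np.abs(rates[both] - base_rates[both])
        rows.append(
            {
                "scenario": spec.id,
                "p_g": spec.p_g,
                "c_N": spec.c_N,
                "c_app": spec.c_app,
                "lam": spec.lam,
                "n_compared": int(both.sum()),
                "mean_abs_delta_n": float(delta.mean()) if delta.size else 0.0,
                "changed_fraction": float(np.mean(delta > practical_threshold))
                if delta.size
                else 0.0,
                "mean_scenario_rate": float(np.nanmean(rates))
                if np.isfinite(rates).any()
                else float("nan"),
                "mean_scenario_rate_paired": float(np.mean(rates[both]))
                if both.any()
                else float("nan"),
                "mean_base_rate_paired": float(np.mean(base_rates[both]))
                if both.any()
                else float("nan"),
                "abstention_rate": float(np.mean(np.isnan(rates))),
            }
        )
    return pd.DataFrame(rows)


def groupwise_decision_diffs(
    prop: pd.DataFrame, ref: pd.DataFrame, groups
) -> pd.DataFrame:
    """Per-group paired differences between two strategy outcome tables.

    Both inputs come from :func:`strategy_outcomes` on the same result (same
    sample order). Reports mean profit difference, mean rate difference and
    the fraction of samples where the proposed strategy strictly improves
    profit, over samples prescribed under both strategies.
    """
    if len(prop) != len(ref):
        raise PipelineError("evaluate", "paired inputs must align")
    groups = np.asarray(groups)
    both = prop["prescribed"].to_numpy() & ref["prescribed"].to_numpy()
    d_pi = prop["profit"].to_numpy() - ref["profit"].to_numpy()
    d_n = prop["rate"].to_numpy() - ref["rate"].to_numpy()
    rows = []
    for g in pd.unique(groups):
        m = (groups == g) & both
        rows.append(
            {
                "group": g,
                "n": int(m.sum()),
                "mean_delta_profit": float(np.mean(d_pi[m])) if m.any() else float("nan"),
                "mean_delta_n": float(np.mean(d_n[m])) if m.any() else float("nan"),
                "fraction_improved": float(np.mean(d_pi[m] > 0)) if m.any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def quantile_bins(values: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Bin index per value using empirical-quantile breakpoints."""
    values = np.asarray(values, dtype=float)
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, len(edges) - 2)


def reliability_coverage_tradeoff(
    result: PipelineResult,
    levels: tuple[float, ...] | None = None,
    heatmap_covariates: tuple[str, str] = ("NDVI", "Rainfall"),
    n_bins: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Coverage / width / abstention per level, plus a binned abstention map.

    The first frame has one row per coverage level: empirical test coverage
    of the yield intervals at the observed rates, mean interval width,
    abstention rate and prescribed fraction of the LCB rule. The second
    frame is the abstention rate over quantile bins of two covariates at the
    highest level.
    """
    levels = levels or result.cfg.coverage_levels
    fm_test = transform(result.test, result.pre_state)
    yhat = result.model.predict(fm_test)
    rows = []
    for level in levels:
        q = result.calibrations[level].q
        cov = empirical_coverage(yhat - q, yhat + q, fm_test.y)
        prescs = result.prescriptions[("lcb", level)]
        abstained = np.array([not p.prescribed for p in prescs])
        rows.append(
            {
                "level": level,
                "coverage": cov["coverage"],
                "mean_width": cov["mean_width"],
                "abstention_rate": float(abstained.mean()),
                "prescribed_fraction": float(1 - abstained.mean()),
            }
        )
    tradeoff = pd.DataFrame(rows)

    top = max(levels)
    prescs = result.prescriptions[("lcb", top)]
    abstained = np.array([not p.prescribed for p in prescs], dtype=float)
    c1, c2 = heatmap_covariates
    v1 = pd.to_numeric(result.test[c1], errors="coerce").to_numpy()
    v2 = pd.to_numeric(result.test[c2], errors="coerce").to_numpy()
    ok = np.isfinite(v1) & np.isfinite(v2)
    b1 = np.full(len(abstained), -1)
    b2 = np.full(len(abstained), -1)
    b1[ok] = quantile_bins(v1[ok], n_bins)
    b2[ok] = quantile_bins(v2[ok], n_bins)
    cells = []
    for i in np.unique(b1[ok]):
        for j in np.unique(b2[ok]):
            m = (b1 == i) & (b2 == j)
            if m.any():
                cells.append(
                    {
                        f"{c1}_bin": int(i),
                        f"{c2}_bin": int(j),
                        "n": int(m.sum()),
                        "abstention_rate": float(abstained[m].mean()),
                    }
                )
    return tradeoff, pd.DataFrame(cells)


def feature_group_ablation(result: PipelineResult) -> pd.DataFrame:
    """Calibration RMSE when training on single covariate groups vs all.

    Uses the tree-ensemble family throughout (the selected backbone); the
    nitrogen rate is always included.
    """
    fms = {
        p: transform(t, result.pre_state) for p, t in result.tables.items()
    }
    variants = {"full": None, **schema.FEATURE_GROUPS}
    tree_cfg = next(
        (c for c in result.cfg.model_candidates if c.family == "tree_ensemble"),
        ModelConfig(family="tree_ensemble"),
    )
    rows = []
    for name, base_cols in variants.items():
        tr = fms["train"] if base_cols is None else fms["train"].select(base_cols)
        ca = fms["calibration"] if base_cols is None else fms["calibration"].select(base_cols)
        model = fit_yield_model(tree_cfg, tr)
        rmse, mae = score(ca.y, model.predict(ca))
        rows.append({"variant": name, "calibration_rmse": rmse, "calibration_mae": mae})
    return pd.DataFrame(rows)


def coverage_simulation(
    seed: int = 7,
    n_train: int = 4000,
    n_cal: int = 1000,
    n_test: int = 1000,
    alphas: tuple[float, ...] = (0.10, 0.05),
    generator: GeneratorConfig | None = None,
    model_cfg: ModelConfig | None = None,
) -> dict[float, dict]:
    """Conformal coverage under exchangeability at fixed sample sizes.

    Generates one synthetic table and splits it into contiguous
    train/calibration/test blocks — rows are independent draws, so the
    calibration and test blocks are exchangeable, which is the premise of
    the conformal guarantee being measured. The tree-ensemble model is fit
    on the training block; coverage is the fraction of test yields inside
    the split conformal intervals at each alpha.
    """
    n_total = n_train + n_cal + n_test
    gen = generator or GeneratorConfig()
    gen = replace(gen, n_samples=n_total, seed=seed)
    table, _ = generate_field_table(gen)

    parts = {
        "train": table.iloc[:n_train],
        "calibration": table.iloc[n_train : n_train + n_cal],
        "test": table.iloc[n_train + n_cal :],
    }
    pre_state = fit_preprocessor(parts["train"])
    fms = {p: transform(t, pre_state) for p, t in parts.items()}
    cfg = model_cfg or ModelConfig(family="tree_ensemble", seed=seed)
    model = fit_yield_model(cfg, fms["train"])
    yhat_test = model.predict(fms["test"])

    out = {}
    for alpha in alphas:
        cal = calibrate(model, fms["calibration"], alpha)
        lower, upper = yhat_test - cal.q, yhat_test + cal.q
        report = empirical_coverage(lower, upper, fms["test"].y)
        report["alpha"] = alpha
        report["q"] = cal.q
        out[alpha] = report
    return out
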