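"""Candidate nitrogen grid, prescription rules, and the abstention policy.

Four rules prescribe a rate from the candidate grid (default 10 to 200 kg/ha
in 5 kg/ha steps, 39 candidates):

* ``lcb`` — maximize the lower endpoint of the profit interval (conservative,
  downside-protected); may abstain;
* ``expected`` — maximize point-estimated profit (penalty included);
* ``uniform`` — the training-split mean rate applied everywhere;
* ``eonr_point`` — the grid rate maximizing p_g*yhat - c_N*N - c_app with the
  environmental penalty excluded (classical economically optimal rate from a
  point predictor).

Ties always break toward the smallest rate. The abstention policy withholds
the LCB prescription when the ambiguity set — candidates whose profit upper
bound reaches the winner's lower bound — spans more than a threshold, when
the profit interval at the winner is too wide, or when the winner's lower
bound falls below a floor; each trigger is independently switchable and
recorded on the prescription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DecisionError(ValueError):
    pass


@dataclass(frozen=True)
class NitrogenGrid:
    n_min: float = 10.0  # kg/ha
    n_max: float = 200.0
    step: float = 5.0

    @property
    def rates(self) -> np.ndarray:
        if self.step <= 0 or self.n_min > self.n_max:
            raise DecisionError("invalid grid specification")
        k = int(np.floor((self.n_max - self.n_min) / self.step + 1e-9))
        return self.n_min + self.step * np.arange(k + 1)

    def __len__(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class AbstentionPolicy:
    """Selective-recommendation thresholds; each trigger is independently
    switchable. The default ambiguity threshold is half the default grid
    span: abstain when the set of economically indistinguishable rates
    covers more than half of the candidate range."""

    enabled: bool = True
    ambiguity_span: float | None = 95.0  # kg/ha; None disables this trigger
    max_width: float | None = None  # currency
    min_lcb: float | None = None  # currency


@dataclass
class Prescription:
    status: str  # "prescribed" | "abstain"
    rate: float | None
    lcb: float
    ambiguity_span: float
    width: float
    triggers: list[str] = field(default_factory=list)

    @property
    def prescribed(self) -> bool:
        return self.status == "prescribed"


def candidate_grid(
    n_min: float = 10.0, n_max: float = 200.0, step: float = 5.0
) -> NitrogenGrid:
    grid = NitrogenGrid(n_min=n_min, n_max=n_max, step=step)
    grid.rates  # validates
    return grid


def prescribe_lcb(
    lower: np.ndarray,
    upper: np.ndarray,
    grid: NitrogenGrid,
    policy: AbstentionPolicy = AbstentionPolicy(),
) -> Prescription:
    """LCB rule for one sample given profit intervals over the grid."""
    rates = grid.rates
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if lower.size == 0 or lower.shape != rates.shape or upper.shape != rates.shape:
        raise DecisionError("need one profit interval per grid candidate")
    best = int(np.argmax(lower))  # first max -> smallest-N tie-break
    ambiguous = upper >= lower[best]
    amb_rates = rates[ambiguous]
    span = float(amb_rates.max() - amb_rates.min())
    width = float(upper[best] - lower[best])

    triggers: list[str] = []
    if policy.enabled:
        if policy.ambiguity_span is not None and span > policy.ambiguity_span:
            triggers.append("ambiguity_span")
        if policy.max_width is not None and width > policy.max_width:
            triggers.append("interval_width")
        if policy.min_lcb is not None and lower[best] < policy.min_lcb:
            triggers.append("lcb_floor")
    if triggers:
        return Prescription(
            status="abstain",
            rate=None,
            lcb=float(lower[best]),
            ambiguity_span=span,
            width=width,
            triggers=triggers,
        )
    return Prescription(
        status="prescribed",
        rate=float(rates[best]),
        lcb=float(lower[best]),
        ambiguity_span=span,
        width=width,
        triggers=[],
    )


def prescribe_expected(point_profits: np.ndarray, grid: NitrogenGrid) -> Prescription:
    """Expected-profit rule; never abstains."""
    rates = grid.rates
    point_profits = np.asarray(point_profits, dtype=float)
    if point_profits.size == 0 or point_profits.shape != rates.shape:
        raise DecisionError("need one point profit per grid candidate")
    best = int(np.argmax(point_profits))
    return Prescription(
        status="prescribed",
        rate=float(rates[best]),
        lcb=float(point_profits[best]),
        ambiguity_span=0.0,
        width=0.0,
    )


def prescribe_uniform(train_mean_n: float) -> Prescription:
    """Constant training-mean rate (not snapped to the grid)."""
    return Prescription(
        status="prescribed",
        rate=float(train_mean_n),
        lcb=float("nan"),
        ambiguity_span=0.0,
        width=0.0,
    )


def prescribe_eonr(point_profits_no_penalty: np.ndarray, grid: NitrogenGrid) -> Prescription:
    """Point EONR: argmax of penalty-free point profit over the grid."""
    return prescribe_expected(point_profits_no_penalty, grid)


def prescribe_baseline(kind: str, **kwargs) -> Prescription:
    if kind == "uniform":
        return prescribe_uniform(kwargs["train_mean_n"])
    if kind == "eonr_point":
        return prescribe_eonr(kwargs["point_profits_no_penalty"], kwargs["grid"])
    raise DecisionError(f"unknown baseline {kind!r}")
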