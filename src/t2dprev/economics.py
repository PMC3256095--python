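"""Incremental cost-effectiveness statistics and deterministic sensitivity runs.

The comparison is always intervention minus control on a common scenario.
A negative ICER is reported as the signed ratio — matching how such
tables are conventionally printed — but always together with a quadrant
flag, because a negative ratio alone cannot distinguish a dominant
strategy (cheaper and better) from a dominated one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import SimulationResult, simulate_cohort
from .mortality import MortalityModel
from .parameters import ParameterBundle, ScenarioConfig

__all__ = [
    "QUADRANTS",
    "IncrementalResult",
    "incremental",
    "icer",
    "CEACCurve",
    "ceac",
    "default_wtp_grid",
    "summary_table",
    "one_way_sensitivity",
]

QUADRANTS = (
    "cost-saving-more-effective",
    "trade-off",
    "dominated",
    "less-costly-less-effective",
)


@dataclass
class IncrementalResult:
    """Incremental cost, incremental QALYs, and their ratio with context."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    quadrant: str

    @property
    def icer_defined(self) -> bool:
        return self.icer is not None


def incremental(delta_cost: float, delta_qalys: float) -> IncrementalResult:
    """Classify an (incremental cost, incremental QALY) pair.

    ΔQ > 0, ΔC < 0: the intervention dominates (cost saving, more
    effective); ΔQ > 0, ΔC >= 0: a genuine trade-off; ΔQ < 0, ΔC > 0:
    dominated; ΔQ < 0, ΔC <= 0: less costly but less effective.  With
    ΔQ = 0 the ratio is undefined and left as None.
    """
    if delta_qalys > 0:
        quadrant = "cost-saving-more-effective" if delta_cost < 0 else "trade-off"
    elif delta_qalys < 0:
        quadrant = "dominated" if delta_cost > 0 else "less-costly-less-effective"
    else:
        if delta_cost > 0:
            quadrant = "dominated"
        elif delta_cost < 0:
            quadrant = "cost-saving-more-effective"
        else:
            quadrant = "trade-off"
        return IncrementalResult(delta_cost, delta_qalys, None, quadrant)
    return IncrementalResult(delta_cost, delta_qalys, delta_cost / delta_qalys, quadrant)


def icer(control: SimulationResult, intervention: SimulationResult) -> IncrementalResult:
    """Incremental result of two simulations of the same scenario."""
    if (
        control.scenario.sex != intervention.scenario.sex
        or control.scenario.start_age != intervention.scenario.start_age
    ):
        raise ValueError("control and intervention results come from different scenarios")
    return incremental(
        intervention.discounted_cost - control.discounted_cost,
        intervention.discounted_qalys - control.discounted_qalys,
    )


@dataclass
class CEACCurve:
    """Probability the intervention is cost-effective along a willingness-to-pay grid."""

    wtp_grid: np.ndarray
    probability: np.ndarray
    n_draws: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp_grid, "probability": self.probability})


def default_wtp_grid() -> np.ndarray:
    """EUR 0 to 50,000 per QALY in steps of 1,000."""
    return np.arange(0.0, 50_001.0, 1_000.0)


def ceac(
    delta_costs: Sequence[float],
    delta_qalys: Sequence[float],
    wtp_grid: Sequence[float] | None = None,
) -> CEACCurve:
    """Cost-effectiveness acceptability curve from incremental draws.

    At each willingness-to-pay λ the probability is the fraction of draws
    with strictly positive incremental net monetary benefit
    λ·ΔQALY − ΔCost; a draw exactly on the breakeven line counts as not
    cost-effective.
    """
    dc = np.asarray(delta_costs, dtype=float)
    dq = np.asarray(delta_qalys, dtype=float)
    if dc.size == 0 or dc.shape != dq.shape:
        raise ValueError("need at least one (delta_cost, delta_qalys) draw, equally many of each")
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("willingness-to-pay grid is empty")
    if (np.diff(grid) <= 0).any():
        raise ValueError("willingness-to-pay grid must be strictly increasing")
    nmb = grid[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp_grid=grid, probability=prob, n_draws=dc.size)


def _run_pair(
    scenario: ScenarioConfig, bundle: ParameterBundle, mortality: MortalityModel
) -> tuple[SimulationResult, SimulationResult, IncrementalResult]:
    ctrl = simulate_cohort(scenario, "control", bundle, mortality)
    intv = simulate_cohort(scenario, "intervention", bundle, mortality)
    return ctrl, intv, icer(ctrl, intv)


def summary_table(
    bundle: ParameterBundle,
    mortality: MortalityModel,
    scenarios: Iterable[ScenarioConfig] | None = None,
) -> pd.DataFrame:
    """Deterministic per-scenario summary: lifetime discounted cost and
    QALYs per arm, incremental values, ICER and quadrant.

    QALY columns are lifetime discounted totals per person from cohort
    entry, and cost columns lifetime discounted EUR per person.
    """
    if scenarios is None:
        scenarios = bundle.scenarios()
    rows = []
    for sc in scenarios:
        ctrl, intv, inc = _run_pair(sc, bundle, mortality)
        rows.append(
            {
                "sex": sc.sex,
                "start_age": sc.start_age,
                "cost_control": ctrl.discounted_cost,
                "cost_intervention": intv.discounted_cost,
                "qalys_control": ctrl.discounted_qalys,
                "qalys_intervention": intv.discounted_qalys,
                "delta_cost": inc.delta_cost,
                "delta_qalys": inc.delta_qalys,
                "icer": np.nan if inc.icer is None else inc.icer,
                "quadrant": inc.quadrant,
            }
        )
    return pd.DataFrame(rows)


def one_way_sensitivity(
    bundle: ParameterBundle,
    mortality: MortalityModel,
    axis: str,
    values: Sequence[float | int],
    scenarios: Iterable[ScenarioConfig] | None = None,
) -> pd.DataFrame:
    """Deterministic one-way sensitivity analysis.

    ``axis`` is ``"discount_rate"`` (both cost and QALY rates move
    together) or ``"effect_horizon"`` (years until the intervention effect
    has fully waned).  Everything else stays at the supplied bundle's
    values.  Returns one row per (axis value, scenario) with the ICER.
    """
    if axis not in ("discount_rate", "effect_horizon"):
        raise ValueError(f"unknown sensitivity axis {axis!r}")
    if scenarios is None:
        scenarios = list(bundle.scenarios())
    else:
        scenarios = list(scenarios)
    rows = []
    for value in values:
        b = bundle.copy()
        if axis == "discount_rate":
            if not 0.0 <= float(value) <= 0.2:
                raise ValueError(f"discount rate {value} outside [0, 0.2]")
            b.discount.rate_costs = float(value)
            b.discount.rate_qalys = float(value)
        else:
            b.effect.effect_horizon = int(value)
            if b.effect.decay == "linear" and b.effect.effect_horizon < 2:
                raise ValueError("effect horizon must be >= 2 under linear decay")
        for sc in scenarios:
            _, _, inc = _run_pair(sc, b, mortality)
            rows.append(
                {
                    "axis": axis,
                    "value": value,
                    "sex": sc.sex,
                    "start_age": sc.start_age,
                    "delta_cost": inc.delta_cost,
                    "delta_qalys": inc.delta_qalys,
                    "icer": np.nan if inc.icer is None else inc.icer,
                    "quadrant": inc.quadrant,
                }
            )
    return pd.DataFrame(rows)
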