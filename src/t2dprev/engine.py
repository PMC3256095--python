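"""Annual-cycle cohort recursion over the four-state model.

Conventions, fixed and documented because published tables depend on them:

* Cycles are one year; the cohort ages one year per cycle.  Cycle ``t``
  (0-based) covers ages ``start_age + t`` up to and including ``max_age``;
  the residual alive mass at ``max_age`` contributes its final-cycle
  rewards and is not propagated further.
* Rewards (state costs, programme costs, utilities) accrue at cycle
  start on the occupancy entering the cycle, discounted by
  ``(1 + r)^(-t)`` with ``t = 0`` for the first cycle.  No half-cycle
  correction is applied.
* The intervention effect is at full strength in model year 1 and, under
  linear decay with horizon ``H`` (default 7), wanes with weight
  ``w = (H - y) / (H - 1)`` so that from year ``H`` onward both arms use
  the control transition matrix.
* The programme cost is paid only by the alive fraction of the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mortality import MortalityModel
from .parameters import (
    ALIVE_STATES,
    STATES,
    ArmParameters,
    EffectProfile,
    InterventionCostSchedule,
    ParameterBundle,
    ScenarioConfig,
    TransitionMatrix,
)

__all__ = [
    "ARMS",
    "blend_weight",
    "blend_transition",
    "embed_mortality",
    "intervention_cost_stream",
    "SimulationResult",
    "simulate_cohort",
    "MicrosimResult",
    "microsimulate_cohort",
]

ARMS = ("control", "intervention")


def blend_weight(cycle_year: int, effect: EffectProfile) -> float:
    """Intervention-effect weight for a 1-based model year.

    ``linear``: 1 in year 1, declining by 1/(H-1) per year, 0 from year H.
    ``none``: full effect through year H-1, then 0 (a step, no taper).
    """
    if cycle_year < 1:
        raise ValueError(f"cycle_year is 1-based, got {cycle_year}")
    h = effect.effect_horizon
    if effect.decay == "linear":
        if h < 2:
            raise ValueError("linear decay requires an effect horizon of at least 2 years")
        return max(0.0, (h - cycle_year) / (h - 1.0))
    return 1.0 if cycle_year < h else 0.0


def blend_transition(
    cycle_year: int, arm_params: ArmParameters, effect: EffectProfile, arm: str
) -> TransitionMatrix:
    """Effective alive-state transition matrix for one arm in one model year.

    The intervention arm interpolates each free probability between the
    control and intervention values with the decay weight; staying
    probabilities are residuals, so rows sum to one exactly.
    """
    if arm == "control":
        return arm_params.control
    if arm != "intervention":
        raise ValueError(f"unknown arm {arm!r}")
    w = blend_weight(cycle_year, effect)
    if w == 0.0:
        return arm_params.control
    if w == 1.0:
        return arm_params.intervention
    c, i = arm_params.control, arm_params.intervention
    return TransitionMatrix(
        p_ngt_igt=c.p_ngt_igt + w * (i.p_ngt_igt - c.p_ngt_igt),
        p_igt_ngt=c.p_igt_ngt + w * (i.p_igt_ngt - c.p_igt_ngt),
        p_igt_t2d=c.p_igt_t2d + w * (i.p_igt_t2d - c.p_igt_t2d),
        p_t2d_igt=c.p_t2d_igt + w * (i.p_t2d_igt - c.p_t2d_igt),
    )


def embed_mortality(
    alive_matrix: TransitionMatrix, mortality: MortalityModel, age: int | float, sex: str
) -> np.ndarray:
    """Compose glycaemic transitions with death into a 4x4 row-stochastic matrix.

    Death competes first: a person in state s dies with probability
    ``d_s`` (background mr for NGT/IGT, mr + t2d2d for T2D); survivors
    follow the alive-state matrix, so each alive row is the glycaemic row
    scaled by ``1 - d_s`` with ``d_s`` in the Dead column.  Dead is
    absorbing.
    """
    d_alive, d_t2d = mortality.death_probabilities(age, sex)
    deaths = np.array([d_alive, d_alive, d_t2d])
    if (deaths < 0).any() or (deaths > 1).any():
        raise ValueError(f"death probabilities outside [0, 1]: {deaths}")
    full = np.zeros((4, 4))
    full[:3, :3] = alive_matrix.as_array() * (1.0 - deaths)[:, None]
    full[:3, 3] = deaths
    full[3, 3] = 1.0
    return full


def intervention_cost_stream(
    cycle_year: int, schedule: InterventionCostSchedule, effect: EffectProfile
) -> float:
    """Programme cost per (alive) participant in a 1-based model year.

    Year 1 carries screening + course + partial-year mentoring; years 2
    through ``participation_years`` carry a full follow-up year; nothing
    afterwards.
    """
    if cycle_year < 1:
        raise ValueError(f"cycle_year is 1-based, got {cycle_year}")
    if cycle_year == 1 and effect.participation_years >= 1:
        return schedule.year1_total
    if cycle_year <= effect.participation_years:
        return schedule.followup_total
    return 0.0


@dataclass
class SimulationResult:
    """Lifetime trajectory and accumulated (discounted) rewards for one arm."""

    scenario: ScenarioConfig
    arm: str
    trace: pd.DataFrame
    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float

    def occupancy(self, cycle: int) -> np.ndarray:
        row = self.trace.iloc[cycle]
        return row[["share_ngt", "share_igt", "share_t2d", "share_dead"]].to_numpy(dtype=float)


def simulate_cohort(
    scenario: ScenarioConfig,
    arm: str,
    bundle: ParameterBundle,
    mortality: MortalityModel,
) -> SimulationResult:
    """Run the deterministic cohort recursion for one scenario and arm.

    Returns the per-cycle occupancy trace together with discounted and
    undiscounted lifetime cost (EUR/person) and QALYs.
    """
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}")
    problems = scenario.validate()
    if problems:
        raise ValueError("; ".join(problems))
    utilities = bundle.utilities[scenario.sex]
    u = np.array([utilities.u_ngt, utilities.u_igt, utilities.u_t2d, utilities.u_dead])
    c = np.array([bundle.costs.c_ngt, bundle.costs.c_igt, bundle.costs.c_t2d, 0.0])
    r_cost = bundle.discount.rate_costs
    r_qaly = bundle.discount.rate_qalys

    occ = np.asarray(scenario.initial_distribution, dtype=float)
    n_cycles = scenario.n_cycles
    rows = []
    disc_cost = disc_qalys = undisc_cost = undisc_qalys = 0.0
    for t in range(n_cycles):
        age = scenario.start_age + t
        year = t + 1
        alive_share = occ[:3].sum()
        cycle_cost = float(occ @ c)
        if arm == "intervention":
            cycle_cost += intervention_cost_stream(year, bundle.intervention_cost, bundle.effect) * alive_share
        cycle_qalys = float(occ @ u)
        df_cost = (1.0 + r_cost) ** (-t)
        df_qaly = (1.0 + r_qaly) ** (-t)
        disc_cost += df_cost * cycle_cost
        disc_qalys += df_qaly * cycle_qalys
        undisc_cost += cycle_cost
        undisc_qalys += cycle_qalys
        rows.append(
            {
                "cycle": t,
                "age": age,
                "share_ngt": occ[0],
                "share_igt": occ[1],
                "share_t2d": occ[2],
                "share_dead": occ[3],
                "cycle_cost": cycle_cost,
                "cycle_qalys": cycle_qalys,
                "discount_factor": df_cost,
            }
        )
        if t < n_cycles - 1:
            tm = blend_transition(year, bundle.arms, bundle.effect, arm)
            full = embed_mortality(tm, mortality, age, scenario.sex)
            occ = occ @ full
    trace = pd.DataFrame(rows)
    return SimulationResult(
        scenario=scenario,
        arm=arm,
        trace=trace,
        discounted_cost=disc_cost,
        discounted_qalys=disc_qalys,
        undiscounted_cost=undisc_cost,
        undiscounted_qalys=undisc_qalys,
    )


@dataclass
class MicrosimResult:
    """Monte-Carlo estimate of per-person lifetime rewards with standard errors."""

    n_individuals: int
    discounted_cost: float
    discounted_qalys: float
    se_cost: float
    se_qalys: float


def microsimulate_cohort(
    scenario: ScenarioConfig,
    arm: str,
    bundle: ParameterBundle,
    mortality: MortalityModel,
    n_individuals: int = 50_000,
    rng: np.random.Generator | None = None,
) -> MicrosimResult:
    """Individual-level Monte-Carlo twin of :func:`simulate_cohort`.

    Simulates ``n_individuals`` independent state paths with the same
    transition matrices, reward timing and discounting conventions as the
    cohort recursion, and returns sample means with Monte-Carlo standard
    errors.  Serves as an independent stochastic oracle for the cohort
    engine: the cohort result is the exact expectation of what is sampled
    here.
    """
    if rng is None:
        rng = np.random.default_rng()
    utilities = bundle.utilities[scenario.sex]
    u = np.array([utilities.u_ngt, utilities.u_igt, utilities.u_t2d, utilities.u_dead])
    c = np.array([bundle.costs.c_ngt, bundle.costs.c_igt, bundle.costs.c_t2d, 0.0])
    r_cost = bundle.discount.rate_costs
    r_qaly = bundle.discount.rate_qalys

    init = np.asarray(scenario.initial_distribution, dtype=float)
    states = rng.choice(4, size=n_individuals, p=init)
    cost_acc = np.zeros(n_individuals)
    qaly_acc = np.zeros(n_individuals)
    n_cycles = scenario.n_cycles
    for t in range(n_cycles):
        age = scenario.start_age + t
        year = t + 1
        df_cost = (1.0 + r_cost) ** (-t)
        df_qaly = (1.0 + r_qaly) ** (-t)
        cycle_cost = c[states].copy()
        if arm == "intervention":
            stream = intervention_cost_stream(year, bundle.intervention_cost, bundle.effect)
            if stream:
                cycle_cost[states < 3] += stream
        cost_acc += df_cost * cycle_cost
        qaly_acc += df_qaly * u[states]
        if t < n_cycles - 1:
            tm = blend_transition(year, bundle.arms, bundle.effect, arm)
            full = embed_mortality(tm, mortality, age, scenario.sex)
            cum = np.cumsum(full, axis=1)
            draws = rng.random(n_individuals)
            # row-wise inverse-CDF sampling of the next state
            new_states = np.empty_like(states)
            for s in range(4):
                mask = states == s
                if mask.any():
                    new_states[mask] = np.searchsorted(cum[s], draws[mask], side="right")
            states = np.minimum(new_states, 3)
    sqrt_n = np.sqrt(n_individuals)
    return MicrosimResult(
        n_individuals=n_individuals,
        discounted_cost=float(cost_acc.mean()),
        discounted_qalys=float(qaly_acc.mean()),
        se_cost=float(cost_acc.std(ddof=1) / sqrt_n),
        se_qalys=float(qaly_acc.std(ddof=1) / sqrt_n),
    )
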