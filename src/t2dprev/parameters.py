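"""Model parameters: transition probabilities, costs, utilities, distributions.

The model distinguishes three alive glycaemic states — normal glucose
tolerance (NGT), impaired glucose tolerance (IGT) and diagnosed type 2
diabetes (T2D) — plus an absorbing Dead state.  This module defines the
parameter containers, validates them, fits the sampling distributions used
by the probabilistic sensitivity analysis (Beta for probabilities and
utilities, Gamma for costs, both by the method of moments), and ships the
published base case as the default configuration.

All monetary values are 2007 euros per person per year unless stated
otherwise.  Internal arithmetic is kept at full floating precision;
rounding happens only where a printed table value is reproduced (cents for
euros, three decimals for utilities).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "SEXES",
    "ALIVE_STATES",
    "STATES",
    "ConfigError",
    "TransitionMatrix",
    "ArmParameters",
    "EffectProfile",
    "CostSet",
    "CostItem",
    "InterventionCostBreakdown",
    "InterventionCostSchedule",
    "UtilitySet",
    "DistributionSpec",
    "DiscountSettings",
    "ScenarioConfig",
    "ParameterBundle",
    "beta_from_moments",
    "gamma_from_moments",
    "gamma_unit_shape",
    "derive_uigt",
    "round_cents",
    "default_bundle",
    "default_intervention_breakdown",
    "default_distributions",
    "load_config",
    "save_config",
]

SEXES = ("male", "female")
ALIVE_STATES = ("ngt", "igt", "t2d")
STATES = ALIVE_STATES + ("dead",)


class ConfigError(ValueError):
    """Raised when a parameter bundle violates one or more invariants.

    The message enumerates every violated invariant, not only the first,
    so a bad configuration file can be fixed in one pass.
    """

    def __init__(self, problems: Iterable[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.problems))


def round_cents(x: float) -> float:
    """Round a euro amount to cents, half away from zero.

    Plain ``round`` uses banker's rounding on binary floats and turns
    e.g. 137.9475 into 137.94; cost tables are conventionally rounded
    half-up, which this helper reproduces.
    """
    return math.copysign(math.floor(abs(x) * 100.0 + 0.5) / 100.0, x)


# ---------------------------------------------------------------------------
# moment fitting
# ---------------------------------------------------------------------------

def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Fit a Beta distribution to a (mean, standard error) pair.

    Uses the method of moments: with nu = mean*(1-mean)/se**2 - 1,
    alpha = mean*nu and beta = (1-mean)*nu, so the fitted Beta has exactly
    the requested mean and standard deviation.

    Raises ``ValueError`` when the mean is outside (0, 1) or the variance
    is infeasible for a Beta on [0, 1] (nu <= 0).
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"Beta mean must lie strictly in (0, 1), got {mean}")
    if se <= 0.0:
        raise ValueError(f"standard error must be positive, got {se}")
    nu = mean * (1.0 - mean) / se**2 - 1.0
    if nu <= 0.0:
        raise ValueError(
            f"variance {se**2:g} is infeasible for a Beta with mean {mean:g} "
            f"(requires se^2 < mean*(1-mean))"
        )
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Fit a Gamma distribution (shape, scale) to a (mean, standard error) pair."""
    if mean <= 0.0:
        raise ValueError(f"Gamma mean must be positive, got {mean}")
    if se <= 0.0:
        raise ValueError(f"standard error must be positive, got {se}")
    shape = (mean / se) ** 2
    scale = se**2 / mean
    return shape, scale


def gamma_unit_shape(mean: float) -> tuple[float, float]:
    """Gamma parameters when the standard error is set equal to the mean.

    This is the convention used for all cost parameters: an exponential-
    shaped Gamma with shape 1.00 and scale equal to the mean, expressing a
    coefficient of variation of 100%.
    """
    return gamma_from_moments(mean, mean)


def derive_uigt(u_ngt: float) -> float:
    """Utility for IGT, defined as a 1% decrement from the NGT utility.

    Rounded to three decimals, matching the precision utilities are
    reported at (0.772 -> 0.764 for men, 0.747 -> 0.740 for women).
    """
    if not 0.0 < u_ngt <= 1.0:
        raise ValueError(f"uNGT must lie in (0, 1], got {u_ngt}")
    return round(0.99 * u_ngt, 3)


# ---------------------------------------------------------------------------
# core parameter containers
# ---------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """One-year transition probabilities among the alive glycaemic states.

    Only the four free off-diagonal probabilities are stored; staying
    probabilities are the row residuals, so each row sums to one by
    construction.  NGT->T2D and T2D->NGT are structural zeros: diabetes is
    modelled as developing through IGT, and remission from diagnosed T2D
    goes back to IGT only.
    """

    p_ngt_igt: float
    p_igt_ngt: float
    p_igt_t2d: float
    p_t2d_igt: float

    @property
    def p_ngt_ngt(self) -> float:
        return 1.0 - self.p_ngt_igt

    @property
    def p_igt_igt(self) -> float:
        return 1.0 - self.p_igt_ngt - self.p_igt_t2d

    @property
    def p_t2d_t2d(self) -> float:
        return 1.0 - self.p_t2d_igt

    def as_array(self) -> np.ndarray:
        """Row-stochastic 3x3 array over (NGT, IGT, T2D)."""
        return np.array(
            [
                [self.p_ngt_ngt, self.p_ngt_igt, 0.0],
                [self.p_igt_ngt, self.p_igt_igt, self.p_igt_t2d],
                [0.0, self.p_t2d_igt, self.p_t2d_t2d],
            ]
        )

    def validate(self, label: str = "transitions") -> list[str]:
        problems = []
        for name in ("p_ngt_igt", "p_igt_ngt", "p_igt_t2d", "p_t2d_igt"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{label}.{name} = {v} outside [0, 1]")
        for name in ("p_ngt_ngt", "p_igt_igt", "p_t2d_t2d"):
            v = getattr(self, name)
            if v < -1e-9:
                problems.append(f"{label}: residual {name} = {v} is negative")
        rows = self.as_array().sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            problems.append(f"{label}: rows sum to {rows}, expected 1")
        return problems


@dataclass
class ArmParameters:
    """Transition matrices for the two strategies under comparison."""

    control: TransitionMatrix
    intervention: TransitionMatrix

    def matrix(self, arm: str) -> TransitionMatrix:
        if arm not in ("control", "intervention"):
            raise ValueError(f"unknown arm {arm!r}")
        return getattr(self, arm)

    def validate(self) -> list[str]:
        return self.control.validate("transitions.control") + self.intervention.validate(
            "transitions.intervention"
        )


@dataclass
class EffectProfile:
    """How long, and in what shape, the intervention effect persists.

    ``effect_horizon`` is the first model year in which intervention and
    control transition probabilities coincide again (default 7: full effect
    in year 1, linearly waning through year 6, none from year 7).
    ``participation_years`` is how long the programme — and its cost — runs
    (default 5 years).
    """

    effect_horizon: int = 7
    participation_years: int = 5
    decay: str = "linear"

    def validate(self) -> list[str]:
        problems = []
        if self.effect_horizon < 1:
            problems.append(f"effect.effect_horizon = {self.effect_horizon}, must be >= 1")
        if self.decay == "linear" and self.effect_horizon < 2:
            problems.append("effect.decay = 'linear' requires effect_horizon >= 2")
        if self.participation_years < 0:
            problems.append(
                f"effect.participation_years = {self.participation_years}, must be >= 0"
            )
        if self.decay not in ("linear", "none"):
            problems.append(f"effect.decay = {self.decay!r}, must be 'linear' or 'none'")
        return problems


@dataclass
class CostSet:
    """Annual direct health-care cost by glycaemic state (EUR/person/year)."""

    c_ngt: float = 1744.21
    c_igt: float = 2696.48
    c_t2d: float = 5861.92

    def cost(self, state: str) -> float:
        return {"ngt": self.c_ngt, "igt": self.c_igt, "t2d": self.c_t2d, "dead": 0.0}[state]

    def validate(self) -> list[str]:
        return [
            f"costs.{name} = {v} is negative"
            for name, v in (("cNGT", self.c_ngt), ("cIGT", self.c_igt), ("cT2D", self.c_t2d))
            if v < 0
        ]

    @staticmethod
    def igt_from_t2d(c_t2d: float, share: float = 0.46) -> float:
        """IGT cost as a fixed share (46%) of the diabetes cost, in cents."""
        return round_cents(share * c_t2d)


@dataclass(frozen=True)
class CostItem:
    """One line of the intervention cost build-up: unit cost x multiplicity."""

    label: str
    unit_cost: float
    multiplicity: float

    @property
    def total(self) -> float:
        return round_cents(self.unit_cost * self.multiplicity)


@dataclass
class InterventionCostBreakdown:
    """Itemised build-up of the programme cost per participant.

    Mirrors the published cost table: screening (mailed information
    folders, apportioned over the recruitment yield), an eight-week group
    course, and ongoing follow-up mentoring, plus participant transport to
    educational events.  In year 1 the course runs first and mentoring
    covers the remaining three quarters of the year; from year 2 onward a
    full mentoring year plus event transport applies.
    """

    screening_items: list[CostItem]
    course_items: list[CostItem]
    course_transport: list[CostItem]
    followup_items: list[CostItem]
    followup_transport: list[CostItem]
    year1_followup_fraction: float = 0.75

    def screening_total(self) -> float:
        return round_cents(sum(i.total for i in self.screening_items))

    def course_total(self) -> float:
        """Course cost per person, excluding transport."""
        return round_cents(sum(i.total for i in self.course_items))

    def course_total_with_transport(self) -> float:
        return round_cents(self.course_total() + sum(i.total for i in self.course_transport))

    def followup_total(self) -> float:
        """Follow-up mentoring per person per year, excluding transport."""
        return round_cents(sum(i.total for i in self.followup_items))

    def followup_year_total(self) -> float:
        """Complete cost of a follow-up year (mentoring plus event transport)."""
        return round_cents(
            self.followup_total() + sum(i.total for i in self.followup_transport)
        )

    def year1_followup_total(self) -> float:
        return round_cents(
            round_cents(self.followup_total() * self.year1_followup_fraction)
            + sum(i.total for i in self.followup_transport)
        )

    def year1_total(self) -> float:
        return round_cents(
            self.screening_total()
            + self.course_total_with_transport()
            + self.year1_followup_total()
        )

    def annualised(self, participation_years: int = 5) -> float:
        """Average programme cost per participation year (the PSA cost anchor)."""
        return round_cents(
            (self.year1_total() + (participation_years - 1) * self.followup_year_total())
            / participation_years
        )

    def to_schedule(self) -> "InterventionCostSchedule":
        return InterventionCostSchedule(
            year1_total=self.year1_total(),
            followup_total=self.followup_year_total(),
            breakdown=self,
        )


def default_intervention_breakdown() -> InterventionCostBreakdown:
    # Folder mailing is apportioned over the observed recruitment yield:
    # 244 folders mailed per 52 recruited participants at EUR24.15 each.
    # Prevention-manager time is charged at EUR32/h shared by a 10-person
    # group; follow-up time is 41 1/3 h per group-year (8 h of events and
    # preparation plus per-participant counselling and measurements).
    rate_per_person_hour = 32.0 / 10.0
    return InterventionCostBreakdown(
        screening_items=[CostItem("Mailing informational folders", 24.15, 244.0 / 52.0)],
        course_items=[
            CostItem("Phone hotline", 3.80, 1),
            CostItem("Email mentoring", 3.80, 1),
            CostItem("Newsletter", 1.75, 8),
            CostItem("Journal", 1.68, 2),
            CostItem("Collection of medical data", 0.15, 2),
            CostItem("Postage", 0.35, 2),
            CostItem("Prevention manager (contact + preparation)", rate_per_person_hour, 26),
        ],
        course_transport=[CostItem("Driving to course, round-trips", 3.00, 8)],
        followup_items=[
            CostItem("Phone hotline", 3.80, 2),
            CostItem("Email mentoring", 3.80, 2),
            CostItem("Newsletter", 0.90, 12),
            CostItem("Journal", 1.49, 4),
            CostItem("Collection of medical data", 0.15, 2),
            CostItem("Postage", 0.35, 4),
            CostItem("Events, 10-person group", 45.0 / 10.0, 4),
            CostItem(
                "Prevention manager (contact + preparation)",
                rate_per_person_hour,
                124.0 / 3.0,
            ),
        ],
        followup_transport=[CostItem("Driving to events, round-trips", 3.00, 2)],
    )


@dataclass
class InterventionCostSchedule:
    """Programme cost stream: a first (course) year, then follow-up years."""

    year1_total: float = 390.43
    followup_total: float = 189.93
    breakdown: InterventionCostBreakdown | None = None

    def validate(self) -> list[str]:
        problems = []
        if self.year1_total < 0:
            problems.append(f"intervention_cost.year1_total = {self.year1_total} is negative")
        if self.followup_total < 0:
            problems.append(
                f"intervention_cost.followup_total = {self.followup_total} is negative"
            )
        return problems

    def scaled(self, factor: float) -> "InterventionCostSchedule":
        return InterventionCostSchedule(
            year1_total=self.year1_total * factor,
            followup_total=self.followup_total * factor,
            breakdown=None,
        )


@dataclass
class UtilitySet:
    """Health-state utility weights (0 = dead, 1 = full health) for one sex."""

    u_ngt: float
    u_igt: float
    u_t2d: float
    u_dead: float = 0.0

    def utility(self, state: str) -> float:
        return {"ngt": self.u_ngt, "igt": self.u_igt, "t2d": self.u_t2d, "dead": self.u_dead}[
            state
        ]

    def validate(self, label: str = "utilities") -> list[str]:
        problems = []
        if not 0.0 <= self.u_t2d <= self.u_igt <= self.u_ngt <= 1.0:
            problems.append(
                f"{label}: require 0 <= uT2D <= uIGT <= uNGT <= 1, got "
                f"({self.u_t2d}, {self.u_igt}, {self.u_ngt})"
            )
        if self.u_dead != 0.0:
            problems.append(f"{label}: u_dead must be 0, got {self.u_dead}")
        return problems


@dataclass
class DistributionSpec:
    """Sampling distribution for one uncertain parameter.

    Built from a (mean, se) pair by the method of moments unless explicit
    shape parameters are supplied.  ``se == 0`` denotes a degenerate
    (point-mass) distribution, used to collapse the probabilistic model
    onto the deterministic one.
    """

    family: str
    mean: float
    se: float
    alpha: float | None = None
    beta_param: float | None = None

    def __post_init__(self):
        if self.family not in ("beta", "gamma"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ValueError(f"standard error must be >= 0, got {self.se}")
        if self.se > 0 and (self.alpha is None or self.beta_param is None):
            if self.family == "beta":
                self.alpha, self.beta_param = beta_from_moments(self.mean, self.se)
            else:
                self.alpha, self.beta_param = gamma_from_moments(self.mean, self.se)

    @property
    def degenerate(self) -> bool:
        return self.se == 0.0

    def analytic_mean(self) -> float:
        if self.degenerate:
            return self.mean
        if self.family == "beta":
            return self.alpha / (self.alpha + self.beta_param)
        return self.alpha * self.beta_param

    def analytic_sd(self) -> float:
        if self.degenerate:
            return 0.0
        if self.family == "beta":
            a, b = self.alpha, self.beta_param
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
        return math.sqrt(self.alpha) * self.beta_param

    def sample(self, rng: np.random.Generator) -> float:
        if self.degenerate:
            return self.mean
        if self.family == "beta":
            return float(rng.beta(self.alpha, self.beta_param))
        return float(rng.gamma(self.alpha, self.beta_param))

    def validate(self, label: str) -> list[str]:
        problems = []
        if self.degenerate:
            return problems
        if self.alpha is None or self.beta_param is None or self.alpha <= 0 or self.beta_param <= 0:
            problems.append(f"distributions.{label}: shape parameters must be positive")
            return problems
        if self.family == "beta":
            if abs(self.analytic_mean() - self.mean) > 0.01:
                problems.append(
                    f"distributions.{label}: Beta({self.alpha:g}, {self.beta_param:g}) mean "
                    f"{self.analytic_mean():.4f} is further than 0.01 from stated mean {self.mean}"
                )
        return problems


@dataclass
class DiscountSettings:
    """Annual discount rates converting future euros/QALYs to present value."""

    rate_costs: float = 0.03
    rate_qalys: float = 0.03

    def validate(self) -> list[str]:
        return [
            f"discount.{name} = {v} outside [0, 0.2]"
            for name, v in (("costs", self.rate_costs), ("qalys", self.rate_qalys))
            if not 0.0 <= v <= 0.2
        ]


@dataclass
class ScenarioConfig:
    """One cohort to simulate: sex, entry age, and the starting mix of states.

    The default starting distribution reflects population screening of
    adults without known diabetes: 84% NGT, 16% IGT, nobody with T2D.
    """

    sex: str
    start_age: int
    initial_distribution: tuple[float, float, float, float] = (0.84, 0.16, 0.0, 0.0)
    max_age: int = 100

    @property
    def n_cycles(self) -> int:
        return self.max_age - self.start_age + 1

    def label(self) -> str:
        return f"{self.sex}_{self.start_age}"

    def validate(self) -> list[str]:
        problems = []
        if self.sex not in SEXES:
            problems.append(f"scenario.sex = {self.sex!r}, must be one of {SEXES}")
        init = np.asarray(self.initial_distribution, dtype=float)
        if init.shape != (4,):
            problems.append("scenario.initial_distribution must have 4 entries")
        else:
            if (init < 0).any():
                problems.append(f"scenario.initial_distribution has negative entries: {init}")
            if abs(init.sum() - 1.0) > 1e-12:
                problems.append(
                    f"scenario.initial_distribution sums to {init.sum()!r}, expected 1"
                )
        if not self.start_age < self.max_age:
            problems.append(
                f"scenario.start_age = {self.start_age} must be below max_age = {self.max_age}"
            )
        return problems


# ---------------------------------------------------------------------------
# the full bundle
# ---------------------------------------------------------------------------

@dataclass
class ParameterBundle:
    """Everything the deterministic and probabilistic pipelines need,
    except mortality (which comes from a life table)."""

    arms: ArmParameters
    effect: EffectProfile
    costs: CostSet
    intervention_cost: InterventionCostSchedule
    utilities: dict[str, UtilitySet]
    discount: DiscountSettings
    distributions: dict[str, DistributionSpec]
    initial_distribution: tuple[float, float, float, float] = (0.84, 0.16, 0.0, 0.0)
    max_age: int = 100
    start_ages: tuple[int, ...] = (30, 50, 70)

    def scenario(self, sex: str, start_age: int) -> ScenarioConfig:
        return ScenarioConfig(
            sex=sex,
            start_age=start_age,
            initial_distribution=tuple(self.initial_distribution),
            max_age=self.max_age,
        )

    def scenarios(self) -> list[ScenarioConfig]:
        """The default age-by-sex grid (men and women entering at 30/50/70)."""
        return [self.scenario(sex, age) for sex in SEXES for age in self.start_ages]

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)

    def validate(self) -> "ParameterBundle":
        problems = self.arms.validate()
        problems += self.effect.validate()
        problems += self.costs.validate()
        problems += self.intervention_cost.validate()
        for sex in SEXES:
            if sex not in self.utilities:
                problems.append(f"utilities missing for sex {sex!r}")
            else:
                problems += self.utilities[sex].validate(f"utilities.{sex}")
        problems += self.discount.validate()
        for key, spec in self.distributions.items():
            problems += spec.validate(key)
        for sex in SEXES:
            for age in self.start_ages:
                problems += self.scenario(sex, age).validate()
        if problems:
            raise ConfigError(problems)
        return self


def default_distributions() -> dict[str, DistributionSpec]:
    """Sampling distributions for the probabilistic analysis.

    Control-arm transition probabilities and utilities get Betas fitted by
    moments to their published (mean, SE); every cost gets a unit-shape
    Gamma (SE set equal to the mean).  The intervention-cost entry is the
    annualised programme cost over five participation years.
    """
    specs: dict[str, DistributionSpec] = {
        "ngt2igt": DistributionSpec("beta", 0.163, 0.037),
        "igt2ngt": DistributionSpec("beta", 0.162, 0.037),
        "igt2t2d": DistributionSpec("beta", 0.062, 0.024),
        "t2d2igt": DistributionSpec("beta", 0.005, 0.007),
        "cNGT": DistributionSpec("gamma", 1744.21, 1744.21),
        "cIGT": DistributionSpec("gamma", 2696.48, 2696.48),
        "cT2D": DistributionSpec("gamma", 5861.92, 5861.92),
        "c_intervention": DistributionSpec("gamma", 230.03, 230.03),
        "uNGT_male": DistributionSpec("beta", 0.772, 0.004),
        "uNGT_female": DistributionSpec("beta", 0.747, 0.004),
        "uIGT_male": DistributionSpec("beta", 0.764, 0.006),
        "uIGT_female": DistributionSpec("beta", 0.740, 0.006),
        "uT2D_male": DistributionSpec("beta", 0.724, 0.010),
        "uT2D_female": DistributionSpec("beta", 0.701, 0.010),
    }
    return specs


def default_bundle() -> ParameterBundle:
    """The published base case: transition matrices, costs, utilities,
    intervention cost schedule, 3% discounting, ages 30/50/70."""
    control = TransitionMatrix(
        p_ngt_igt=0.163, p_igt_ngt=0.162, p_igt_t2d=0.06, p_t2d_igt=0.005
    )
    intervention = TransitionMatrix(
        p_ngt_igt=0.152, p_igt_ngt=0.177, p_igt_t2d=0.03, p_t2d_igt=0.005
    )
    breakdown = default_intervention_breakdown()
    bundle = ParameterBundle(
        arms=ArmParameters(control=control, intervention=intervention),
        effect=EffectProfile(),
        costs=CostSet(),
        intervention_cost=breakdown.to_schedule(),
        utilities={
            "male": UtilitySet(u_ngt=0.772, u_igt=0.764, u_t2d=0.724),
            "female": UtilitySet(u_ngt=0.747, u_igt=0.740, u_t2d=0.701),
        },
        discount=DiscountSettings(),
        distributions=default_distributions(),
    )
    return bundle.validate()


# ---------------------------------------------------------------------------
# configuration file I/O
# ---------------------------------------------------------------------------
#
# Schema (YAML or JSON; every key optional, absent keys take the defaults):
#
#   transitions:
#     control:       {ngt2igt, igt2ngt, igt2t2d, t2d2igt}
#     intervention:  {ngt2igt, igt2ngt, igt2t2d, t2d2igt}
#   effect:          {effect_horizon, participation_years, decay}
#   costs:           {cNGT, cIGT, cT2D}
#   intervention_cost: {year1_total, followup_total}
#   utilities:
#     male:          {uNGT, uIGT, uT2D}
#     female:        {uNGT, uIGT, uT2D}
#   discount:        {costs, qalys}
#   distributions:   {<name>: {family, mean, se[, alpha, beta]}}
#   scenario:        {initial_distribution, max_age, start_ages}

_TM_KEYS = {"ngt2igt": "p_ngt_igt", "igt2ngt": "p_igt_ngt",
            "igt2t2d": "p_igt_t2d", "t2d2igt": "p_t2d_igt"}


def _matrix_to_dict(tm: TransitionMatrix) -> dict:
    return {k: getattr(tm, attr) for k, attr in _TM_KEYS.items()}


def _matrix_from_dict(d: dict, base: TransitionMatrix) -> TransitionMatrix:
    kwargs = {attr: float(d.get(k, getattr(base, attr))) for k, attr in _TM_KEYS.items()}
    return TransitionMatrix(**kwargs)


def bundle_to_dict(bundle: ParameterBundle) -> dict:
    return {
        "transitions": {
            "control": _matrix_to_dict(bundle.arms.control),
            "intervention": _matrix_to_dict(bundle.arms.intervention),
        },
        "effect": {
            "effect_horizon": bundle.effect.effect_horizon,
            "participation_years": bundle.effect.participation_years,
            "decay": bundle.effect.decay,
        },
        "costs": {"cNGT": bundle.costs.c_ngt, "cIGT": bundle.costs.c_igt,
                  "cT2D": bundle.costs.c_t2d},
        "intervention_cost": {
            "year1_total": bundle.intervention_cost.year1_total,
            "followup_total": bundle.intervention_cost.followup_total,
        },
        "utilities": {
            sex: {"uNGT": u.u_ngt, "uIGT": u.u_igt, "uT2D": u.u_t2d}
            for sex, u in bundle.utilities.items()
        },
        "discount": {"costs": bundle.discount.rate_costs, "qalys": bundle.discount.rate_qalys},
        "distributions": {
            name: {
                "family": s.family, "mean": s.mean, "se": s.se,
                "alpha": s.alpha, "beta": s.beta_param,
            }
            for name, s in bundle.distributions.items()
        },
        "scenario": {
            "initial_distribution": list(bundle.initial_distribution),
            "max_age": bundle.max_age,
            "start_ages": list(bundle.start_ages),
        },
    }


def bundle_from_dict(data: dict) -> ParameterBundle:
    base = default_bundle()
    data = data or {}

    tr = data.get("transitions", {})
    arms = ArmParameters(
        control=_matrix_from_dict(tr.get("control", {}), base.arms.control),
        intervention=_matrix_from_dict(tr.get("intervention", {}), base.arms.intervention),
    )
    eff = data.get("effect", {})
    effect = EffectProfile(
        effect_horizon=int(eff.get("effect_horizon", base.effect.effect_horizon)),
        participation_years=int(eff.get("participation_years", base.effect.participation_years)),
        decay=str(eff.get("decay", base.effect.decay)),
    )
    co = data.get("costs", {})
    costs = CostSet(
        c_ngt=float(co.get("cNGT", base.costs.c_ngt)),
        c_igt=float(co.get("cIGT", base.costs.c_igt)),
        c_t2d=float(co.get("cT2D", base.costs.c_t2d)),
    )
    ic = data.get("intervention_cost", {})
    schedule = InterventionCostSchedule(
        year1_total=float(ic.get("year1_total", base.intervention_cost.year1_total)),
        followup_total=float(ic.get("followup_total", base.intervention_cost.followup_total)),
        breakdown=base.intervention_cost.breakdown if not ic else None,
    )
    ut = data.get("utilities", {})
    utilities = {}
    for sex in SEXES:
        u = ut.get(sex, {})
        bu = base.utilities[sex]
        utilities[sex] = UtilitySet(
            u_ngt=float(u.get("uNGT", bu.u_ngt)),
            u_igt=float(u.get("uIGT", bu.u_igt)),
            u_t2d=float(u.get("uT2D", bu.u_t2d)),
        )
    di = data.get("discount", {})
    discount = DiscountSettings(
        rate_costs=float(di.get("costs", base.discount.rate_costs)),
        rate_qalys=float(di.get("qalys", base.discount.rate_qalys)),
    )
    distributions = dict(base.distributions)
    for name, spec in data.get("distributions", {}).items():
        distributions[name] = DistributionSpec(
            family=str(spec["family"]),
            mean=float(spec["mean"]),
            se=float(spec["se"]),
            alpha=None if spec.get("alpha") is None else float(spec["alpha"]),
            beta_param=None if spec.get("beta") is None else float(spec["beta"]),
        )
    sc = data.get("scenario", {})
    bundle = ParameterBundle(
        arms=arms,
        effect=effect,
        costs=costs,
        intervention_cost=schedule,
        utilities=utilities,
        discount=discount,
        distributions=distributions,
        initial_distribution=tuple(
            float(x) for x in sc.get("initial_distribution", base.initial_distribution)
        ),
        max_age=int(sc.get("max_age", base.max_age)),
        start_ages=tuple(int(a) for a in sc.get("start_ages", base.start_ages)),
    )
    return bundle.validate()


def load_config(path: str | Path) -> ParameterBundle:
    """Read a YAML/JSON configuration, fill defaults, validate, return the bundle."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is not None and not isinstance(data, dict):
        raise ConfigError([f"configuration root must be a mapping, got {type(data).__name__}"])
    return bundle_from_dict(data or {})


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write the complete bundle as YAML; ``load_config`` restores it losslessly."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=False)
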