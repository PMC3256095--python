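"""Probabilistic sensitivity analysis: parameter sampling and paired-arm runs.

Each Monte-Carlo draw produces one complete parameter bundle: control-arm
transition probabilities from their Betas, state and programme costs from
unit-shape Gammas, and sex-specific utilities from their Betas.  Both
arms are then simulated with that same bundle (common random parameters),
which is what makes the per-draw incremental pairs — and the acceptability
curve built from them — meaningful.

Intervention-arm transition probabilities carry no published
distributions.  By default each one is tied to its control draw through
the deterministic relative effect (for example the IGT→T2D probability is
halved, 0.03 vs 0.06), so baseline uncertainty propagates while the
relative treatment effect stays fixed; ``independent_intervention=True``
instead samples the intervention arm from Betas centred on its own
deterministic values.  Mortality is not sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import CEACCurve, ceac
from .engine import simulate_cohort
from .mortality import MortalityModel
from .parameters import (
    SEXES,
    DistributionSpec,
    ParameterBundle,
    ScenarioConfig,
    TransitionMatrix,
    beta_from_moments,
)

__all__ = ["PSADrawSet", "sample_parameters", "run_psa"]

_TRANSITION_KEYS = ("ngt2igt", "igt2ngt", "igt2t2d", "t2d2igt")
_TM_ATTR = {
    "ngt2igt": "p_ngt_igt",
    "igt2ngt": "p_igt_ngt",
    "igt2t2d": "p_igt_t2d",
    "t2d2igt": "p_t2d_igt",
}


@dataclass
class PSADrawSet:
    """Reproducible record of a probabilistic analysis.

    ``params`` holds one row per draw with every sampled parameter;
    ``deltas`` the per-draw incremental cost and QALYs (intervention
    minus control) for the analysed scenario.
    """

    seed: int
    n_draws: int
    scenario: ScenarioConfig
    params: pd.DataFrame
    deltas: pd.DataFrame

    def ceac(self, wtp_grid=None) -> CEACCurve:
        return ceac(self.deltas["delta_cost"], self.deltas["delta_qalys"], wtp_grid)

    def mean_incrementals(self) -> tuple[float, float]:
        return (
            float(self.deltas["delta_cost"].mean()),
            float(self.deltas["delta_qalys"].mean()),
        )


def _intervention_spec(bundle: ParameterBundle, key: str) -> DistributionSpec:
    """Beta for an intervention-arm transition, centred on its deterministic
    value with the control draw's relative SE (used only when sampling the
    arms independently)."""
    ctrl_spec = bundle.distributions[key]
    mean = getattr(bundle.arms.intervention, _TM_ATTR[key])
    if ctrl_spec.degenerate or mean <= 0.0 or mean >= 1.0:
        return DistributionSpec(ctrl_spec.family, mean, 0.0)
    se = ctrl_spec.se * mean / ctrl_spec.mean
    try:
        return DistributionSpec("beta", mean, se)
    except ValueError:
        return DistributionSpec("beta", mean, 0.0)


def sample_parameters(
    bundle: ParameterBundle,
    rng: np.random.Generator,
    independent_intervention: bool = False,
    max_resamples: int = 1000,
) -> tuple[ParameterBundle, dict[str, float]]:
    """Draw one parameter bundle; returns (sampled bundle, sampled record).

    Transition rows whose sampled exit probabilities exceed one (a
    negative staying residual) are resampled as a block, up to
    ``max_resamples`` times.
    """
    sampled = bundle.copy()
    record: dict[str, float] = {}

    ratios = {
        key: (
            getattr(bundle.arms.intervention, attr) / getattr(bundle.arms.control, attr)
            if getattr(bundle.arms.control, attr) > 0
            else 1.0
        )
        for key, attr in _TM_ATTR.items()
    }

    for attempt in range(max_resamples):
        ctrl_draw = {k: bundle.distributions[k].sample(rng) for k in _TRANSITION_KEYS}
        if independent_intervention:
            int_draw = {
                k: _intervention_spec(bundle, k).sample(rng) for k in _TRANSITION_KEYS
            }
        else:
            int_draw = {k: min(1.0, ctrl_draw[k] * ratios[k]) for k in _TRANSITION_KEYS}
        ctrl_tm = TransitionMatrix(**{_TM_ATTR[k]: ctrl_draw[k] for k in _TRANSITION_KEYS})
        int_tm = TransitionMatrix(**{_TM_ATTR[k]: int_draw[k] for k in _TRANSITION_KEYS})
        if not ctrl_tm.validate() and not int_tm.validate():
            break
    else:
        raise RuntimeError(
            f"could not draw a feasible transition matrix in {max_resamples} attempts"
        )
    sampled.arms.control = ctrl_tm
    sampled.arms.intervention = int_tm
    for k in _TRANSITION_KEYS:
        record[k] = ctrl_draw[k]
        record[f"{k}_intervention"] = int_draw[k]

    record["cNGT"] = sampled.costs.c_ngt = bundle.distributions["cNGT"].sample(rng)
    record["cIGT"] = sampled.costs.c_igt = bundle.distributions["cIGT"].sample(rng)
    record["cT2D"] = sampled.costs.c_t2d = bundle.distributions["cT2D"].sample(rng)

    # the annualised programme cost scales the whole payment schedule
    spec = bundle.distributions["c_intervention"]
    drawn = spec.sample(rng)
    record["c_intervention"] = drawn
    factor = drawn / spec.mean if spec.mean > 0 else 1.0
    sampled.intervention_cost = bundle.intervention_cost.scaled(factor)

    for sex in SEXES:
        for state, attr in (("uNGT", "u_ngt"), ("uIGT", "u_igt"), ("uT2D", "u_t2d")):
            value = bundle.distributions[f"{state}_{sex}"].sample(rng)
            setattr(sampled.utilities[sex], attr, value)
            record[f"{state}_{sex}"] = value
    return sampled, record


def run_psa(
    scenario: ScenarioConfig,
    bundle: ParameterBundle,
    mortality: MortalityModel,
    n_draws: int = 10_000,
    seed: int = 0,
    independent_intervention: bool = False,
) -> PSADrawSet:
    """Monte-Carlo propagation of parameter uncertainty for one scenario.

    For every draw both arms are simulated with the same sampled bundle
    and the incremental (cost, QALY) pair is stored.  Identical seed and
    configuration reproduce the draw set bitwise.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    param_rows = []
    delta_rows = []
    for _ in range(n_draws):
        sampled, record = sample_parameters(
            bundle, rng, independent_intervention=independent_intervention
        )
        ctrl = simulate_cohort(scenario, "control", sampled, mortality)
        intv = simulate_cohort(scenario, "intervention", sampled, mortality)
        param_rows.append(record)
        delta_rows.append(
            {
                "delta_cost": intv.discounted_cost - ctrl.discounted_cost,
                "delta_qalys": intv.discounted_qalys - ctrl.discounted_qalys,
            }
        )
    return PSADrawSet(
        seed=seed,
        n_draws=n_draws,
        scenario=scenario,
        params=pd.DataFrame(param_rows),
        deltas=pd.DataFrame(delta_rows),
    )
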