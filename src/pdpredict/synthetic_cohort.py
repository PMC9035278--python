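"""Synthetic two-group cohorts: demographics, scenario-controlled agent
parameters, and full simulated sessions.

The generator emulates the study design — an autism group (n=43, 35 male) and
a control group (n=42, 35 male), group IQ ~ Normal(105, 13.4) vs
Normal(113, 11.6) truncated below 70 (the study's exclusion criterion), age ~
Normal(28, 9) vs Normal(26, 5.8) truncated below 18 — and injects group-level
behavioral differences only through agent parameters.  Named scenarios encode
the two candidate mechanisms for reduced correct predictions:

* ``reluctance`` — the autism group has a higher registration threshold
  (theta 0.6 vs 0.2), everything else equal;
* ``impairment_noise`` — higher prediction emission noise (epsilon 0.25 vs
  0.05);
* ``impairment_memory`` — leakier belief memory (eta 0.6 vs 1.0);
* ``null`` — identical parameters in both groups.

Effect sizes are calibration choices sized to yield roughly a seven-round
gap in declared inability at the study's sample size; they are configuration,
not claims about autistic participants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .agents import AgentParams, BetaBernoulliAgent
from .pd_engine import SessionConfig, SessionRecord, play_session

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "Participant",
    "SCENARIOS",
    "scenario_params",
    "generate_cohort",
    "scenario_experiment",
]

SCENARIOS = ("reluctance", "impairment_noise", "impairment_memory", "null", "custom")

_BASE = AgentParams()  # theta=0.2, epsilon=0.05, eta=1.0, omega=2.0, tau=1.0


def scenario_params(scenario: str) -> tuple[AgentParams, AgentParams]:
    """(autism, control) agent parameters for a named scenario.

    Each non-null scenario differs from the shared baseline in exactly one
    knob, so the scenarios are clean single-mechanism hypotheses.
    """
    if scenario == "reluctance":
        return replace(_BASE, theta=0.6), _BASE
    if scenario == "impairment_noise":
        return replace(_BASE, epsilon=0.25), _BASE
    if scenario == "impairment_memory":
        return replace(_BASE, eta=0.6), _BASE
    if scenario == "null":
        return _BASE, _BASE
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass(frozen=True)
class GroupSpec:
    """Demographic distribution of one group."""

    n: int
    n_male: int
    iq_mean: float
    iq_sd: float
    age_mean: float
    age_sd: float

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= self.n_male <= self.n:
            raise ValueError("male count must be between 0 and group size")
        if self.iq_sd <= 0 or self.age_sd <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout, scenario, and the master seed all randomness flows from."""

    autism: GroupSpec = GroupSpec(
        n=43, n_male=35, iq_mean=105.0, iq_sd=13.4, age_mean=28.0, age_sd=9.0
    )
    control: GroupSpec = GroupSpec(
        n=42, n_male=35, iq_mean=113.0, iq_sd=11.6, age_mean=26.0, age_sd=5.8
    )
    scenario: str = "reluctance"
    params_autism: Optional[AgentParams] = None  # required for scenario="custom"
    params_control: Optional[AgentParams] = None
    session: SessionConfig = field(default_factory=SessionConfig)
    master_seed: int = 0

    def resolve_params(self) -> tuple[AgentParams, AgentParams]:
        if self.scenario == "custom":
            if self.params_autism is None or self.params_control is None:
                raise ValueError("custom scenario requires both parameter sets")
            return self.params_autism, self.params_control
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return scenario_params(self.scenario)


@dataclass(frozen=True)
class Participant:
    """One synthetic participant: identity, covariates and agent parameters."""

    id: str
    group: str  # "autism" | "control"
    age: float
    sex: str  # "M" | "F"
    iq: int
    params: Optional[AgentParams] = None


_IQ_FLOOR = 70  # study exclusion criterion: IQ < 70
_AGE_FLOOR = 18.0  # adult sample


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, floor: float
) -> float:
    # resample rather than clip, preserving the conditional shape above floor
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if x >= floor:
            return x
    raise RuntimeError("truncated normal sampling failed")  # pragma: no cover


def _group_participants(
    group: str,
    prefix: str,
    spec: GroupSpec,
    params: AgentParams,
    master_seed: int,
    group_key: int,
) -> list[Participant]:
    sexes = ["M"] * spec.n_male + ["F"] * (spec.n - spec.n_male)
    order_rng = np.random.default_rng(
        np.random.SeedSequence([master_seed, group_key, 10_000])
    )
    order_rng.shuffle(sexes)
    out = []
    for i in range(spec.n):
        rng = np.random.default_rng(
            np.random.SeedSequence([master_seed, group_key, i])
        )
        iq = int(round(_truncated_normal(rng, spec.iq_mean, spec.iq_sd, _IQ_FLOOR)))
        age = _truncated_normal(rng, spec.age_mean, spec.age_sd, _AGE_FLOOR)
        out.append(
            Participant(
                id=f"{prefix}{i + 1:03d}",
                group=group,
                age=round(age, 1),
                sex=sexes[i],
                iq=iq,
                params=params,
            )
        )
    return out


def generate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[list[Participant], list[SessionRecord]]:
    """Draw a cohort and simulate one full session per participant.

    Every participant's covariates and session are driven by a seed derived
    deterministically from (master_seed, group, index), so cohorts are
    reproducible and extending one group does not perturb the other.
    """
    p_autism, p_control = config.resolve_params()
    participants = _group_participants(
        "autism", "A", config.autism, p_autism, config.master_seed, group_key=1
    ) + _group_participants(
        "control", "C", config.control, p_control, config.master_seed, group_key=2
    )
    sessions = []
    for part in participants:
        group_key = 1 if part.group == "autism" else 2
        idx = int(part.id[1:]) - 1
        session_seed = int(
            np.random.SeedSequence(
                [config.master_seed, group_key, idx, 20_000]
            ).generate_state(1)[0]
            % (2**31 - 1)
        )
        agent = BetaBernoulliAgent(part.params, config.session.payoffs)
        sessions.append(
            play_session(
                agent, config.session, rng_seed=session_seed, participant_id=part.id
            )
        )
    return participants, sessions


def scenario_experiment(
    n_per_group: int = 200,
    master_seed: int = 0,
    scenarios: Sequence[str] = ("reluctance", "impairment_noise", "impairment_memory", "null"),
    coding: str = "autism1",
):
    """The identifiability experiment: which metrics separate which mechanism.

    For each scenario, simulates a cohort of ``n_per_group`` per group and
    fits the diagnosis + IQ regression for declared inability, failed ratio
    and correct predictions.  Reluctance should move declared inability but
    not the failed/attempted ratio; emission-noise impairment should move the
    failed ratio.  Returns a tidy DataFrame of diagnosis betas and p-values.
    """
    import pandas as pd

    from .metrics import summaries_frame
    from .stats import diagnosis_regression

    rows = []
    base = CohortConfig()
    for k, scenario in enumerate(scenarios):
        config = CohortConfig(
            autism=replace(
                base.autism,
                n=n_per_group,
                n_male=round(n_per_group * base.autism.n_male / base.autism.n),
            ),
            control=replace(
                base.control,
                n=n_per_group,
                n_male=round(n_per_group * base.control.n_male / base.control.n),
            ),
            scenario=scenario,
            master_seed=master_seed + k,
        )
        participants, sessions = generate_cohort(config)
        frame = summaries_frame(participants, sessions)
        for metric in ("declared_inability", "failed_ratio", "correct_predictions"):
            res = diagnosis_regression(frame, metric, coding=coding)
            rows.append(
                {
                    "scenario": scenario,
                    "metric": metric,
                    "diagnosis_beta": res.coef("diagnosis"),
                    "diagnosis_se": res.se("diagnosis"),
                    "diagnosis_p": res.p("diagnosis"),
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)
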