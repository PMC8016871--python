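"""End-to-end evaluation: 90-day tree -> Markov projection -> CE metrics.

`evaluate` runs both strategy arms through the short-term decision tree
and the long-term cohort model on one parameter set and one mortality
schedule and returns the incremental comparison (genetic testing = arm A,
no testing = comparator B).  This is the single entry point reused by the
base case, the one-way sensitivity analysis and the probabilistic
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .markov import MarkovTrace, MortalitySchedule, run_markov
from .metrics import CEResult
from .params import ParameterSet
from .synth import default_schedule
from .tree import NinetyDayOutcome, build_arm, ninety_day_cost_qaly

__all__ = ["ArmResult", "PipelineResult", "evaluate_arm", "evaluate"]

ARMS = ("genetic_testing", "no_testing")


@dataclass(frozen=True)
class ArmResult:
    """One strategy arm's lifetime totals and intermediate outputs."""

    name: str
    ninety_day: NinetyDayOutcome
    trace: MarkovTrace

    @property
    def total_cost(self) -> float:
        return self.ninety_day.cost_90d + self.trace.total_cost

    @property
    def total_qaly(self) -> float:
        return self.ninety_day.qaly_90d + self.trace.total_qaly


@dataclass(frozen=True)
class PipelineResult:
    genetic: ArmResult
    no_testing: ArmResult

    @property
    def ce(self) -> CEResult:
        return CEResult(cost_A=self.genetic.total_cost,
                        cost_B=self.no_testing.total_cost,
                        qaly_A=self.genetic.total_qaly,
                        qaly_B=self.no_testing.total_qaly)


def evaluate_arm(name: str, params: ParameterSet,
                 schedule: MortalitySchedule) -> ArmResult:
    """Run one arm through the 90-day tree and the Markov model."""
    arm = build_arm(name, params)
    ninety = ninety_day_cost_qaly(arm, params)
    trace = run_markov(ninety.distribution, params, schedule)
    return ArmResult(name, ninety, trace)


def evaluate(params: ParameterSet,
             schedule: MortalitySchedule | None = None) -> PipelineResult:
    """Evaluate both arms; the shipped calibrated schedule is the default."""
    if schedule is None:
        schedule = default_schedule(params)
    return PipelineResult(
        genetic=evaluate_arm("genetic_testing", params, schedule),
        no_testing=evaluate_arm("no_testing", params, schedule),
    )
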