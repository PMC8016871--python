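"""The 90-day decision tree.

Both strategy arms start from a cohort of minor-stroke / high-risk-TIA
patients in the minor-or-no-disability state (mRS 0–2).  The
genetic-testing arm genotypes every patient and switches CYP2C19
loss-of-function carriers with a low recurrence-risk score (ESRS < 3) from
clopidogrel–aspirin to dipyridamole–aspirin; everyone else — and the whole
no-testing arm — receives clopidogrel–aspirin.  Within 90 days patients may
suffer a recurrent stroke (ischemic or intracerebral hemorrhage), a major
extracranial hemorrhage (ECH) or a myocardial infarction (MI), modelled as
mutually exclusive chance branches; only recurrence can change disability.

The tree emits, per arm, the 90-day distribution over the four mRS-based
health states together with the costs (testing, antiplatelet drugs, event
hospitalizations) and quality-adjusted life time accrued in the first 90
days.  That distribution seeds the long-term Markov model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import ParameterSet

__all__ = [
    "StateDistribution",
    "Subgroup",
    "StrategyArm",
    "NinetyDayOutcome",
    "proportion_within_90d",
    "apply_hazard_ratio",
    "adjusted_disability_rate",
    "mix_subgroups",
    "build_arm",
    "ninety_day_distribution",
    "ninety_day_cost_qaly",
]

DAYS_90_YEARS = 90.0 / 365.25
ECH_EPISODE_YEARS = 14.0 / 365.25
MI_EPISODE_YEARS = 30.0 / 365.25

_TOL = 1e-9


@dataclass(frozen=True)
class StateDistribution:
    """Probability mass over the four mRS-based health states."""

    p_minor: float      # mRS 0-2
    p_moderate: float   # mRS 3-4
    p_severe: float     # mRS 5
    p_dead: float       # mRS 6

    def __post_init__(self):
        comps = self.as_tuple()
        if any(c < -_TOL for c in comps):
            raise ValueError(f"negative state mass: {comps}")
        if abs(sum(comps) - 1.0) > 1e-6:
            raise ValueError(f"state masses sum to {sum(comps)}, not 1")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.p_minor, self.p_moderate, self.p_severe, self.p_dead)

    @property
    def p_alive(self) -> float:
        return self.p_minor + self.p_moderate + self.p_severe


@dataclass(frozen=True)
class Subgroup:
    """One genotype/risk-score stratum of an arm with its 90-day risks."""

    label: str          # noncarrier | carrier_high_esrs | carrier_low_esrs | pooled
    proportion: float
    therapy: str        # clopidogrel_aspirin | dipyridamole_aspirin | aspirin_mono
    recurrence_90d: float
    ich_prop: float
    ech_90d: float
    mi_90d: float


@dataclass(frozen=True)
class StrategyArm:
    name: str                     # genetic_testing | no_testing
    subgroups: tuple[Subgroup, ...]

    def __post_init__(self):
        total = sum(g.proportion for g in self.subgroups)
        if abs(total - 1.0) > _TOL:
            raise ValueError(
                f"{self.name}: subgroup proportions sum to {total}, not 1")


@dataclass(frozen=True)
class NinetyDayOutcome:
    """Per-arm 90-day summary: seed distribution, cost and QALYs."""

    distribution: StateDistribution
    cost_90d: float
    qaly_90d: float
    recurrence_90d: float = 0.0   # pooled event risk, kept for reporting


# ---------------------------------------------------------------------------
# derivation primitives
# ---------------------------------------------------------------------------

def proportion_within_90d(rate_90d: float, rate_1y: float) -> float:
    """Fraction of first-year recurrences that occur within 90 days.

    E.g. 90-day and one-year recurrence risks of 8.3 % and 10.3 % under
    clopidogrel–aspirin imply 80.6 % of first-year recurrences are early.
    """
    if not (0 < rate_90d <= rate_1y <= 1):
        raise ValueError(
            f"need 0 < rate_90d <= rate_1y <= 1, got ({rate_90d}, {rate_1y})")
    return rate_90d / rate_1y


def apply_hazard_ratio(p: float, hr: float) -> float:
    """Scale a 90-day event probability by a treatment hazard ratio.

    Applied multiplicatively on the probability scale (the convention the
    source arithmetic follows: 0.0932 x 0.78 = 0.0727).
    """
    if not 0 <= p <= 1:
        raise ValueError(f"probability outside [0,1]: {p}")
    if hr <= 0:
        raise ValueError(f"hazard ratio must be > 0: {hr}")
    out = p * hr
    if out > 1:
        raise ValueError(f"p*hr = {out} exceeds 1")
    return out


def adjusted_disability_rate(a: float, b: float, c: float,
                             policy: str = "left_to_right") -> float:
    """Moderate-disability rate after switching non-benefiting patients.

    ``a`` is the moderate-disability rate due to recurrence without
    genotyping, ``b`` the relative risk of disability under dual therapy
    versus aspirin alone, and ``c`` the proportion of patients who do not
    benefit from clopidogrel–aspirin (carriers with ESRS < 3).

    The published formula "A*(B - C)/B*(1 - C)" is typographically
    ambiguous; the default ``left_to_right`` policy evaluates
    ``(a*(b - c)/b) * (1 - c)``, the alternative ``ratio`` policy
    ``a * ((b - c)/b) / (1 - c)``.
    """
    if policy == "left_to_right":
        out = a * (b - c) / b * (1.0 - c)
    elif policy == "ratio":
        if c >= 1:
            raise ValueError("c must be < 1 under the ratio policy")
        out = a * ((b - c) / b) / (1.0 - c)
    else:
        raise ValueError(f"unknown policy '{policy}'")
    if not 0 <= out <= 1:
        raise ValueError(f"adjusted disability rate {out} outside [0,1]")
    return out


# ---------------------------------------------------------------------------
# arm construction and pooling
# ---------------------------------------------------------------------------

def build_arm(name: str, params: ParameterSet) -> StrategyArm:
    """Assemble a strategy arm's subgroups from a parameter set."""
    ich = params["ich_prop_90d"]
    ech = params["ech_rate_90d"]
    mi = params["mi_rate_90d"]
    if name == "no_testing":
        groups = (Subgroup("pooled", 1.0, "clopidogrel_aspirin",
                           params["rec90_pooled_no_testing"], ich, ech, mi),)
    elif name == "genetic_testing":
        groups = (
            Subgroup("noncarrier", params["prop_noncarrier"],
                     "clopidogrel_aspirin", params["rec90_noncarrier"],
                     ich, ech, mi),
            Subgroup("carrier_high_esrs", params["prop_carrier_high_esrs"],
                     "clopidogrel_aspirin", params["rec90_carrier_high_esrs"],
                     ich, ech, mi),
            Subgroup("carrier_low_esrs", params["prop_carrier_low_esrs"],
                     "dipyridamole_aspirin", params["rec90_carrier_low_esrs"],
                     ich, ech, mi),
        )
    else:
        raise ValueError(f"unknown arm '{name}'")
    return StrategyArm(name, groups)


def mix_subgroups(arm: StrategyArm) -> dict[str, float]:
    """Proportion-weighted pooled 90-day event risks of an arm.

    ECH and MI risks are identical across subgroups by construction, so the
    weighting only matters for stroke recurrence.
    """
    w = [g.proportion for g in arm.subgroups]
    pooled = {
        "recurrence_90d": sum(wi * g.recurrence_90d
                              for wi, g in zip(w, arm.subgroups)),
        "ich_prop": sum(wi * g.ich_prop for wi, g in zip(w, arm.subgroups)),
        "ech_90d": sum(wi * g.ech_90d for wi, g in zip(w, arm.subgroups)),
        "mi_90d": sum(wi * g.mi_90d for wi, g in zip(w, arm.subgroups)),
    }
    return pooled


# ---------------------------------------------------------------------------
# the 90-day outcome
# ---------------------------------------------------------------------------

def _table_distribution(arm_name: str, params: ParameterSet
                        ) -> StateDistribution:
    suffix = "genetic" if arm_name == "genetic_testing" else "no_testing"
    p_minor = params[f"p90_minor_{suffix}"]
    moderate = params[f"p90_moderate_{suffix}"]
    severe = params[f"p90_severe_{suffix}"]
    dead = params[f"p90_dead_{suffix}"]
    # When the minor proportion is varied in sensitivity analyses the
    # distribution must be renormalized.  Default policy: the moderate
    # state absorbs the change (dual therapy's disability benefit is a
    # minor <-> moderate trade-off); "proportional" rescales all residual
    # states instead.  At the shipped base values both are a no-op.
    if params.structural.p90_renormalization == "moderate":
        moderate = 1.0 - p_minor - severe - dead
    else:
        total_res = moderate + severe + dead
        scale = (1.0 - p_minor) / total_res if total_res > 0 else 0.0
        moderate, severe, dead = (moderate * scale, severe * scale,
                                  dead * scale)
    return StateDistribution(p_minor, moderate, severe, dead)


def _derived_distribution(arm: StrategyArm, params: ParameterSet
                          ) -> StateDistribution:
    """Reconstruct the 90-day distribution from subgroup event rates.

    Secondary pathway: moderate disability comes from the disability-rate
    adjustment, severe disability and death scale with pooled recurrence
    relative to the no-testing arm.  The published pooled table values are
    the primary inputs of the default pipeline.
    """
    pooled = mix_subgroups(arm)
    r = pooled["recurrence_90d"]
    r_ref = params["rec90_pooled_no_testing"]
    a = params["p90_moderate_no_testing"]
    sev_ref = params["p90_severe_no_testing"]
    dead_ref = params["p90_dead_no_testing"]
    if arm.name == "no_testing":
        moderate, severe, dead = a, sev_ref, dead_ref
    else:
        moderate = adjusted_disability_rate(
            a, params["rr_disability_dapt"], params["prop_carrier_low_esrs"],
            policy=params.structural.disability_formula_policy)
        severe = sev_ref * r / r_ref
        dead = dead_ref * r / r_ref
    return StateDistribution(1.0 - moderate - severe - dead,
                             moderate, severe, dead)


def ninety_day_distribution(arm: StrategyArm, params: ParameterSet
                            ) -> StateDistribution:
    """Distribution over mRS states 90 days after the index event."""
    if params.structural.ninety_day_mode == "derived":
        return _derived_distribution(arm, params)
    return _table_distribution(arm.name, params)


def _drug_cost(arm: StrategyArm, params: ParameterSet) -> float:
    prices = {
        "clopidogrel_aspirin": params["cost_drug_clopidogrel_aspirin_90d"],
        "dipyridamole_aspirin": params["cost_drug_dipyridamole_aspirin_90d"],
    }
    return sum(g.proportion * prices[g.therapy] for g in arm.subgroups)


def recurrence_band_split(dist: StateDistribution, recurrence: float
                          ) -> tuple[float, float]:
    """Split recurrence mass by resulting mRS band (0-2 vs 3-6).

    All non-minor 90-day mass is attributable to recurrence (only
    recurrence moves disability), so recurrences landing back in mRS 0-2
    are the remainder after the moderate/severe/dead mass is accounted for.
    """
    non_minor = dist.p_moderate + dist.p_severe + dist.p_dead
    band36 = min(non_minor, recurrence)
    band02 = max(recurrence - band36, 0.0)
    return band02, band36


def ninety_day_cost_qaly(arm: StrategyArm, params: ParameterSet
                         ) -> NinetyDayOutcome:
    """Expected 90-day cost and QALYs of an arm (booked undiscounted).

    Cost = genetic-testing fee (testing arm only) + proportion-weighted
    90-day antiplatelet price + expected event hospitalizations (recurrent
    stroke split ischemic/ICH and by resulting mRS band; ECH; MI).
    QALYs = end-state utility x 90 days, minus multiplicative temporary
    disutilities for the ECH (2-week) and MI (30-day) episodes.
    """
    pooled = mix_subgroups(arm)
    dist = ninety_day_distribution(arm, params)
    r, ich = pooled["recurrence_90d"], pooled["ich_prop"]
    ech, mi = pooled["ech_90d"], pooled["mi_90d"]

    cost = _drug_cost(arm, params)
    if arm.name == "genetic_testing":
        cost += params["cost_genetic_testing"]
    band02, band36 = recurrence_band_split(dist, r)
    price02 = ((1 - ich) * params["cost_hosp_ischemic_mrs02"]
               + ich * params["cost_hosp_ich_mrs02"])
    price36 = ((1 - ich) * params["cost_hosp_ischemic_mrs36"]
               + ich * params["cost_hosp_ich_mrs36"])
    cost += band02 * price02 + band36 * price36
    cost += ech * params["cost_hosp_ech"] + mi * params["cost_hosp_mi"]

    utils = (params["utility_mrs02"], params["utility_mrs34"],
             params["utility_mrs5"], params["utility_death"])
    qaly = DAYS_90_YEARS * sum(p * u for p, u in zip(dist.as_tuple(), utils))
    # ECH/MI patients keep minor disability; their episode multiplies the
    # state utility by the episode utility for its duration.
    u_minor = params["utility_mrs02"]
    if params.structural.temporary_disutility_mode == "multiplicative":
        qaly -= ech * ECH_EPISODE_YEARS * u_minor * (1 - params["utility_ech"])
        qaly -= mi * MI_EPISODE_YEARS * u_minor * (1 - params["utility_mi"])
    else:  # absolute replacement of the state utility during the episode
        qaly -= ech * ECH_EPISODE_YEARS * (u_minor - params["utility_ech"])
        qaly -= mi * MI_EPISODE_YEARS * (u_minor - params["utility_mi"])
    return NinetyDayOutcome(dist, cost, qaly, recurrence_90d=r)
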