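"""Model parameters: definitions, defaults, validation, config I/O.

Every quantity the model consumes — event probabilities, costs (2019 CNY),
health-state utilities, discount rates and the 90-day outcome distributions
of both strategy arms — is a named :class:`ParamSpec` carrying a base value,
an uncertainty range ``[low, high]`` and a sampling-distribution tag used by
the probabilistic sensitivity analysis.  Structural settings (time horizon,
starting age, willingness-to-pay thresholds, iteration counts) live in
:class:`StructuralSettings`.

The shipped defaults (:func:`default_parameters`) are the published
base-case inputs for genotype-guided antiplatelet therapy after minor
stroke / high-risk TIA in China.  Parameters whose uncertainty was reported
as "± 20 %" carry ``low = 0.8·base`` and ``high = 1.2·base``.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ParamSpec",
    "StructuralSettings",
    "ParameterSet",
    "default_parameters",
    "load_config",
    "loads_config",
    "serialize",
    "validate",
    "params_table",
]

DISTRIBUTIONS = ("triangular", "normal", "beta", "fixed")

#: units labels used below
CNY = "CNY"
PROB = "probability"
UTIL = "utility"
RATE = "rate per person-year"
RATIO = "ratio"


@dataclass
class ParamSpec:
    """One named model input with base value, range and distribution tag."""

    name: str
    base: float
    low: float
    high: float
    dist: str = "triangular"
    units: str = ""

    def is_fixed(self) -> bool:
        return self.dist == "fixed" or self.low == self.high

    def violations(self) -> list[str]:
        v = []
        if not (self.low <= self.base <= self.high):
            v.append(f"{self.name}: low <= base <= high violated "
                     f"({self.low}, {self.base}, {self.high})")
        if self.dist not in DISTRIBUTIONS:
            v.append(f"{self.name}: unknown distribution tag '{self.dist}'")
        if self.units in (PROB, UTIL):
            if self.low < 0 or self.high > 1:
                kind = "probability" if self.units == PROB else "utility"
                v.append(f"{self.name}: {kind} outside [0, 1]")
        if self.units == CNY and self.low < 0:
            v.append(f"{self.name}: cost < 0")
        return v


@dataclass
class StructuralSettings:
    """Non-sampled settings of the decision model."""

    horizon_years: int = 30
    cycle_length_years: float = 1.0
    start_age: float = 62.0
    wtp_primary: float = 72_100.0     # 2019 per-capita GDP, CNY/QALY
    wtp_upper: float = 216_000.0      # ~3x GDP threshold, CNY/QALY
    psa_iterations: int = 10_000
    half_cycle_correction: bool = False
    rng_seed: int = 20190117
    #: parenthesization policy for the disability-rate adjustment formula
    disability_formula_policy: str = "left_to_right"
    #: temporary-event disutility mode: "multiplicative" or "replacement"
    temporary_disutility_mode: str = "multiplicative"
    #: how the 90-day state distribution is obtained: "table" or "derived"
    ninety_day_mode: str = "table"
    #: how the residual 90-day states rebalance when an arm's minor
    #: proportion is varied: "moderate" (the moderate state absorbs the
    #: change) or "proportional"
    p90_renormalization: str = "moderate"
    #: which occupancy accrues the per-cycle state rewards:
    #: "start" (state occupied during the cycle, the TreeAge-style
    #: convention), "end", or "mid" (half-cycle correction)
    state_accrual: str = "start"

    def violations(self) -> list[str]:
        v = []
        if self.horizon_years < 1:
            v.append("structural: horizon_years < 1")
        if not (self.wtp_primary > 0 and self.wtp_upper > 0):
            v.append("structural: wtp values must be > 0")
        if self.disability_formula_policy not in ("left_to_right", "ratio"):
            v.append("structural: unknown disability_formula_policy")
        if self.temporary_disutility_mode not in ("multiplicative",
                                                  "replacement"):
            v.append("structural: unknown temporary_disutility_mode")
        if self.ninety_day_mode not in ("table", "derived"):
            v.append("structural: unknown ninety_day_mode")
        if self.state_accrual not in ("start", "mid", "end"):
            v.append("structural: unknown state_accrual")
        if self.p90_renormalization not in ("moderate", "proportional"):
            v.append("structural: unknown p90_renormalization")
        return v


@dataclass
class ParameterSet:
    """The complete, validated input set for one model run."""

    specs: dict[str, ParamSpec]
    structural: StructuralSettings = field(default_factory=StructuralSettings)

    def __getitem__(self, name: str) -> float:
        return self.specs[name].base

    def copy(self) -> "ParameterSet":
        # manual rebuild: much cheaper than deepcopy in PSA inner loops
        return ParameterSet(
            specs={k: dataclasses.replace(v) for k, v in self.specs.items()},
            structural=dataclasses.replace(self.structural),
        )

    def with_base(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the named base values replaced."""
        ps = self.copy()
        for name, value in overrides.items():
            if name not in ps.specs:
                raise KeyError(f"unknown parameter '{name}'")
            ps.specs[name].base = float(value)
        return ps

    @property
    def discount_cost(self) -> float:
        return self["discount_cost"]

    @property
    def discount_outcome(self) -> float:
        return self["discount_outcome"]


def _spec(name, base, low, high, dist, units) -> ParamSpec:
    return ParamSpec(name, float(base), float(low), float(high), dist, units)


def _pm20(name, base, dist, units) -> ParamSpec:
    return _spec(name, base, 0.8 * base, 1.2 * base, dist, units)


def default_parameters() -> ParameterSet:
    """The shipped base-case parameter set (all costs in 2019 CNY).

    Probabilities, costs and utilities carry the published ranges; sampled
    parameters default to triangular distributions over (low, base, high),
    the only distribution family fully determined by those triples.
    Quantities without published uncertainty (the 90-day subgroup event
    risks, subgroup weights, discount rates) are tagged ``fixed`` and are
    excluded from probabilistic sampling; discount rates still carry ranges
    for deterministic one-way analysis.
    """
    s: list[ParamSpec] = [
        # --- one-time hospitalization costs -------------------------------
        _spec("cost_hosp_ischemic_mrs02", 12_499.91, 7_021.54, 15_861.18,
              "triangular", CNY),
        _spec("cost_hosp_ischemic_mrs36", 18_700.45, 9_711.31, 24_627.33,
              "triangular", CNY),
        _spec("cost_hosp_ich_mrs02", 14_086.15, 7_515.65, 17_613.39,
              "triangular", CNY),
        _spec("cost_hosp_ich_mrs36", 18_700.45, 9_711.31, 24_627.33,
              "triangular", CNY),
        _spec("cost_hosp_ech", 9_125.97, 5_563.25, 18_330.50,
              "triangular", CNY),
        _spec("cost_hosp_mi", 21_276.20, 8_292.31, 37_291.96,
              "triangular", CNY),
        # --- annual post-hospitalization (maintenance) costs ---------------
        _spec("annual_posthosp_cost_mrs02", 8_767.42, 2_189.32, 10_945.34,
              "triangular", CNY),
        _spec("annual_posthosp_cost_mrs35", 13_850.50, 4_104.98, 18_060.64,
              "triangular", CNY),
        # --- 90-day drug and testing costs ---------------------------------
        _pm20("cost_drug_clopidogrel_aspirin_90d", 490.45, "triangular", CNY),
        _pm20("cost_drug_dipyridamole_aspirin_90d", 504.00, "triangular", CNY),
        _pm20("cost_genetic_testing", 1_076.50, "triangular", CNY),
        # --- health-state utilities ----------------------------------------
        _spec("utility_mrs02", 0.75, 0.70, 0.90, "triangular", UTIL),
        _spec("utility_mrs34", 0.39, 0.10, 0.50, "triangular", UTIL),
        _spec("utility_mrs5", 0.20, 0.00, 0.32, "triangular", UTIL),
        _spec("utility_death", 0.0, 0.0, 0.0, "fixed", UTIL),
        _spec("utility_ech", 0.80, 0.79, 0.84, "triangular", UTIL),
        _spec("utility_mi", 0.84, 0.67, 0.96, "triangular", UTIL),
        # --- long-term event probabilities ---------------------------------
        _spec("annual_recurrence_rate", 0.1219, 0.1163, 0.1276,
              "triangular", RATE),
        _spec("ich_prop_longterm", 0.075, 0.075, 0.146, "triangular", PROB),
        _spec("death_on_recurrence", 0.1933, 0.1737, 0.2128,
              "triangular", PROB),
        _spec("rr_recurrence_per_year", 1.017, 1.013, 1.022,
              "triangular", RATIO),
        _spec("ech_rate_annual", 0.0038, 0.0030, 0.0048, "triangular", PROB),
        _pm20("ech_fatality", 0.06, "triangular", PROB),
        _spec("mi_rate_annual", 0.0085, 0.0060, 0.0114, "triangular", PROB),
        _spec("mi_fatality", 0.15, 0.103, 0.246, "triangular", PROB),
        # mortality endpoints of the age-specific non-stroke death schedule
        _spec("nonstroke_mortality_start", 0.0089, 0.0089, 0.0089,
              "fixed", PROB),
        _spec("nonstroke_mortality_end", 0.1654, 0.1654, 0.1654,
              "fixed", PROB),
        # --- discount rates (one-way analysis only; not sampled) -----------
        _spec("discount_cost", 0.03, 0.03, 0.08, "fixed", RATE),
        _spec("discount_outcome", 0.03, 0.024, 0.036, "fixed", RATE),
        # --- 90-day outcome distributions by arm ---------------------------
        # Only the minor/no-disability proportions carry published ranges;
        # when they move, the residual states are renormalized
        # proportionally.  The no-testing range mirrors the genetic arm's
        # absolute offsets around its own base.
        _spec("p90_minor_genetic", 0.9506, 0.9390, 0.9610, "triangular", PROB),
        _spec("p90_moderate_genetic", 0.0404, 0.0404, 0.0404, "fixed", PROB),
        _spec("p90_severe_genetic", 0.0054, 0.0054, 0.0054, "fixed", PROB),
        _spec("p90_dead_genetic", 0.0036, 0.0036, 0.0036, "fixed", PROB),
        _spec("p90_minor_no_testing", 0.9376, 0.9260, 0.9480,
              "triangular", PROB),
        _spec("p90_moderate_no_testing", 0.0527, 0.0527, 0.0527,
              "fixed", PROB),
        _spec("p90_severe_no_testing", 0.0058, 0.0058, 0.0058, "fixed", PROB),
        _spec("p90_dead_no_testing", 0.0039, 0.0039, 0.0039, "fixed", PROB),
        # --- 90-day event risks (trial-reported; no published ranges) ------
        _spec("rec90_noncarrier", 0.0717, 0.0717, 0.0717, "fixed", PROB),
        _spec("rec90_carrier_high_esrs", 0.0871, 0.0871, 0.0871,
              "fixed", PROB),
        _spec("rec90_carrier_low_esrs", 0.0727, 0.0727, 0.0727,
              "fixed", PROB),
        _spec("rec90_pooled_no_testing", 0.082, 0.082, 0.082, "fixed", PROB),
        _spec("ich_prop_90d", 0.0377, 0.0377, 0.0377, "fixed", PROB),
        _spec("ech_rate_90d", 0.0108, 0.0108, 0.0108, "fixed", PROB),
        _spec("mi_rate_90d", 0.0012, 0.0012, 0.0012, "fixed", PROB),
        # --- genotype/risk-score subgroup weights (genetic-testing arm) ----
        _spec("prop_carrier_low_esrs", 0.37, 0.37, 0.37, "fixed", PROB),
        _spec("prop_noncarrier", 0.41, 0.41, 0.41, "fixed", PROB),
        _spec("prop_carrier_high_esrs", 0.22, 0.22, 0.22, "fixed", PROB),
        # --- derivation inputs (used only in derived 90-day mode) ----------
        _spec("hr_dipyridamole_vs_aspirin", 0.78, 0.68, 0.90, "fixed", RATIO),
        _spec("rr_disability_dapt", 0.78, 0.62, 0.99, "fixed", RATIO),
        # diagnostic accuracy of genotyping (no misclassification branch by
        # default; exposed for exploration)
        _spec("test_accuracy", 1.0, 1.0, 1.0, "fixed", PROB),
    ]
    return ParameterSet(specs={p.name: p for p in s})


def validate(ps: ParameterSet) -> list[str]:
    """Return all invariant violations (empty list means valid)."""
    v: list[str] = []
    for spec in ps.specs.values():
        v.extend(spec.violations())
    v.extend(ps.structural.violations())
    if "discount_cost" in ps.specs:
        d = ps.specs["discount_cost"]
        if not (0 <= d.base <= 0.08):
            v.append("discount_cost: outside [0, 0.08]")
    if "discount_outcome" in ps.specs:
        d = ps.specs["discount_outcome"]
        if not (0 <= d.base <= 0.08):
            v.append("discount_outcome: outside [0, 0.08]")
    return v


# ---------------------------------------------------------------------------
# config I/O — flat YAML: parameter name -> scalar (base override) or a
# mapping with base/low/high/dist sub-keys; structural settings under the
# reserved key "structural".
# ---------------------------------------------------------------------------

_STRUCTURAL_FIELDS = {f.name for f in dataclasses.fields(StructuralSettings)}
_SPEC_KEYS = {"base", "low", "high", "dist", "units"}


def _apply_overrides(ps: ParameterSet, doc: Mapping) -> ParameterSet:
    for key, value in doc.items():
        if key == "structural":
            if not isinstance(value, Mapping):
                raise ValueError("structural: expected a mapping")
            for sk, sv in value.items():
                if sk not in _STRUCTURAL_FIELDS:
                    raise ValueError(f"unknown structural key '{sk}'")
                setattr(ps.structural, sk, sv)
            continue
        if key not in ps.specs:
            raise ValueError(f"unknown parameter '{key}'")
        spec = ps.specs[key]
        if isinstance(value, Mapping):
            unknown = set(value) - _SPEC_KEYS
            if unknown:
                raise ValueError(
                    f"{key}: unknown sub-key(s) {sorted(unknown)}")
            for sk, sv in value.items():
                setattr(spec, sk, float(sv) if sk not in ("dist", "units")
                        else str(sv))
        else:
            spec.base = float(value)
    return ps


def loads_config(text: str) -> ParameterSet:
    """Parse a config document (YAML dialect) into a ParameterSet.

    Unspecified parameters fall back to the shipped defaults; unknown keys
    are an error; the result is validated before being returned.
    """
    doc = yaml.safe_load(text)
    ps = default_parameters()
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ValueError("config root must be a mapping")
    ps = _apply_overrides(ps, doc)
    violations = validate(ps)
    if violations:
        raise ValueError("invalid configuration:\n  " +
                         "\n  ".join(violations))
    return ps


def load_config(path: str | Path) -> ParameterSet:
    """Load and validate a parameter configuration file."""
    return loads_config(Path(path).read_text())


def serialize(ps: ParameterSet) -> str:
    """Write a ParameterSet as a config document (lossless round-trip)."""
    doc: dict = {
        name: {"base": sp.base, "low": sp.low, "high": sp.high,
               "dist": sp.dist, "units": sp.units}
        for name, sp in ps.specs.items()
    }
    doc["structural"] = dataclasses.asdict(ps.structural)
    return yaml.safe_dump(doc, sort_keys=True)


def params_table(ps: ParameterSet) -> "pandas.DataFrame":  # noqa: F821
    """Full parameter table (name, base, low, high, dist, units)."""
    import pandas as pd

    rows = [dataclasses.asdict(sp) for sp in ps.specs.values()]
    return pd.DataFrame(rows, columns=["name", "base", "low", "high",
                                       "dist", "units"])


def params_to_csv(ps: ParameterSet, path_or_buf) -> None:
    params_table(ps).to_csv(path_or_buf, index=False)
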