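"""Deterministic and probabilistic sensitivity analyses.

One-way (tornado) analysis re-runs the full pipeline with each parameter
at the endpoints of its published range, everything else at base.  The
probabilistic analysis draws every sampled parameter independently from
its tagged distribution (triangular over ``(low, base, high)`` by
default), evaluates both arms per draw, and summarizes the resulting
cloud of incremental (cost, effect) pairs as a cost-effectiveness plane
and an acceptability curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import MortalitySchedule
from .metrics import icer, nmb
from .params import ParameterSet, ParamSpec
from .pipeline import evaluate

__all__ = [
    "OwsaRow",
    "PSAResult",
    "run_owsa",
    "sample_parameter_set",
    "run_psa",
    "ceac",
    "default_wtp_grid",
]


@dataclass(frozen=True)
class OwsaRow:
    parameter: str
    low_input: float
    high_input: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


@dataclass(frozen=True)
class PSAResult:
    """Paired arm outcomes of a probabilistic sensitivity analysis."""

    cost_genetic: np.ndarray
    cost_no_testing: np.ndarray
    qaly_genetic: np.ndarray
    qaly_no_testing: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return self.cost_genetic.size

    @property
    def d_cost(self) -> np.ndarray:
        return self.cost_genetic - self.cost_no_testing

    @property
    def d_qaly(self) -> np.ndarray:
        return self.qaly_genetic - self.qaly_no_testing

    def fraction_beneficial(self) -> float:
        """Share of draws in which genetic testing gains QALYs."""
        return float((self.d_qaly > 0).mean())

    def fraction_cost_effective(self, wtp: float) -> float:
        """Share of draws with positive net monetary benefit at ``wtp``."""
        return float((wtp * self.d_qaly - self.d_cost > 0).mean())

    def fraction_dominant(self) -> float:
        """Share of draws that gain QALYs and save cost."""
        return float(((self.d_qaly > 0) & (self.d_cost < 0)).mean())

    def to_frame(self) -> "pandas.DataFrame":  # noqa: F821
        import pandas as pd

        return pd.DataFrame({
            "cost_genetic": self.cost_genetic,
            "cost_no_testing": self.cost_no_testing,
            "qaly_genetic": self.qaly_genetic,
            "qaly_no_testing": self.qaly_no_testing,
            "d_cost": self.d_cost,
            "d_qaly": self.d_qaly,
        })


# ---------------------------------------------------------------------------
# one-way analysis
# ---------------------------------------------------------------------------

def run_owsa(params: ParameterSet,
             schedule: MortalitySchedule | None = None) -> list[OwsaRow]:
    """Tornado analysis over every parameter with a non-degenerate range.

    Each parameter is evaluated at its low and high bound with everything
    else at base; rows come back sorted by ICER spread, largest first.
    """
    rows = []
    for name, spec in params.specs.items():
        # fixed-tagged parameters with a degenerate range have no
        # uncertainty to explore; ranged parameters are varied even when
        # excluded from probabilistic sampling (e.g. discount rates)
        if spec.low == spec.high and spec.dist == "fixed":
            continue
        icers = {}
        for bound in ("low", "high"):
            value = getattr(spec, bound)
            try:
                res = evaluate(params.with_base(**{name: value}), schedule)
            except Exception as exc:
                raise RuntimeError(
                    f"one-way analysis failed for '{name}' at "
                    f"{bound}={value}") from exc
            ce = res.ce
            icers[bound] = icer(ce.d_cost, ce.d_qaly)
        rows.append(OwsaRow(name, spec.low, spec.high,
                            icers["low"], icers["high"]))
    rows.sort(key=lambda r: r.spread, reverse=True)
    return rows


def owsa_frame(rows: list[OwsaRow]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame([{
        "parameter": r.parameter,
        "low": r.low_input,
        "high": r.high_input,
        "icer_low": r.icer_at_low,
        "icer_high": r.icer_at_high,
        "spread": r.spread,
    } for r in rows])


# ---------------------------------------------------------------------------
# probabilistic analysis
# ---------------------------------------------------------------------------

def _draw(spec: ParamSpec, rng: np.random.Generator) -> float:
    if spec.is_fixed():
        return spec.base
    if spec.dist == "triangular":
        x = rng.triangular(spec.low, spec.base, spec.high)
    elif spec.dist == "normal":
        # published range read as a central 95% interval
        sd = (spec.high - spec.low) / (2 * 1.959963984540054)
        x = rng.normal(spec.base, sd)
    elif spec.dist == "beta":
        # method-of-moments beta over [low, high] with mean at base
        span = spec.high - spec.low
        m = (spec.base - spec.low) / span
        k = 10.0  # concentration
        x = spec.low + span * rng.beta(m * k, (1 - m) * k)
    else:  # pragma: no cover
        raise ValueError(f"unsupported distribution '{spec.dist}'")
    if spec.units in ("probability", "utility"):
        x = min(max(x, 0.0), 1.0)
    return float(x)


def sample_parameter_set(params: ParameterSet,
                         rng: np.random.Generator) -> ParameterSet:
    """Draw one full parameter set; fixed-tagged specs keep their base."""
    ps = params.copy()
    for spec in ps.specs.values():
        spec.base = _draw(spec, rng)
    return ps


def run_psa(params: ParameterSet, n: int | None = None,
            seed: int | None = None,
            schedule: MortalitySchedule | None = None) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    ``n`` independent parameter sets are drawn and the full two-arm
    pipeline is evaluated on each; the mortality schedule is held at the
    calibrated fixture (its uncertainty is not published).  Reproducible
    under a fixed seed.
    """
    if n is None:
        n = params.structural.psa_iterations
    if seed is None:
        seed = params.structural.rng_seed
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cg = np.empty(n)
    cn = np.empty(n)
    qg = np.empty(n)
    qn = np.empty(n)
    if schedule is None:
        from .synth import default_schedule
        schedule = default_schedule(params)
    for i in range(n):
        sampled = sample_parameter_set(params, rng)
        res = evaluate(sampled, schedule)
        cg[i] = res.genetic.total_cost
        cn[i] = res.no_testing.total_cost
        qg[i] = res.genetic.total_qaly
        qn[i] = res.no_testing.total_qaly
    return PSAResult(cg, cn, qg, qn, seed)


def default_wtp_grid() -> np.ndarray:
    """0 to 250,000 CNY/QALY in steps of 2,500 (covers both thresholds)."""
    return np.arange(0, 250_001, 2_500, dtype=float)


def ceac(psa: PSAResult, wtp_grid=None) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    For each willingness-to-pay value, the fraction of PSA draws in which
    genetic testing has positive net monetary benefit.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    dq, dc = psa.d_qaly, psa.d_cost
    return [(float(w), float((w * dq - dc > 0).mean())) for w in wtp_grid]
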