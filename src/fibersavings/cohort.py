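"""Deterministic cohort model: averted constipation cases and annual savings.

The model is a chain of products per stratum:

    eligible   = population x (1 - fraction meeting fiber recommendations)
    prevalent  = eligible x constipation prevalence
    responders = prevalent x responder fraction
    averted    = responders x expected prevalence reduction
    savings    = averted x per-case annual treatment cost

where the expected prevalence reduction averages ``min(1, g x r)`` over the
intake-shift distribution (r = per-gram reduction). A k% reduction in
prevalence is taken to avert k% of constipation-related treatment cost;
severity migration (prescription -> OTC) is not modelled. Individuals
already meeting recommendations are outside the intervention and
contribute no savings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .params import DoseResponse, IntakeShiftDistribution, ModelConfig, Stratum

__all__ = [
    "StratumSavings",
    "SavingsResult",
    "per_case_annual_cost",
    "prevalence_reduction_fraction",
    "expected_reduction",
    "stratum_savings",
    "run_model",
]


@dataclass(frozen=True)
class StratumSavings:
    """Model outputs for a single stratum (persons and 2012 USD)."""

    eligible_population: float
    prevalent_cases: float
    responder_cases: float
    averted_cases: float
    per_case_annual_cost: float
    annual_savings: float


@dataclass(frozen=True)
class SavingsResult:
    """Per-stratum and aggregate model outputs."""

    per_stratum: dict[str, StratumSavings]
    total_averted_cases: float = field(default=0.0)
    total_annual_savings: float = field(default=0.0)

    def to_frame(self) -> pd.DataFrame:
        """Flat table, one row per stratum plus a TOTAL row."""
        rows = {
            label: vars(entry).copy() for label, entry in self.per_stratum.items()
        }
        df = pd.DataFrame.from_dict(rows, orient="index")
        total = df.sum()
        total["per_case_annual_cost"] = float("nan")
        df.loc["TOTAL"] = total
        df.index.name = "stratum"
        return df


def per_case_annual_cost(rx_frac: float, rx_cost: float, otc_cost: float) -> float:
    """Mean annual treatment cost per prevalent case under the rx/OTC mix."""
    return rx_frac * rx_cost + (1.0 - rx_frac) * otc_cost


def prevalence_reduction_fraction(increment: float, dr: DoseResponse) -> float:
    """Proportional prevalence reduction for one fiber increment (g/day).

    Linear in the increment, capped at 1 so extreme sweeps cannot avert
    more than every case.
    """
    if increment < 0:
        raise ValueError(f"fiber increment must be >= 0, got {increment}")
    return min(1.0, increment * dr.per_gram_reduction)


def expected_reduction(shift: IntakeShiftDistribution, dr: DoseResponse) -> float:
    """Population-average prevalence reduction under an intake-shift mix."""
    return sum(
        frac * prevalence_reduction_fraction(g, dr) for g, frac in shift.items()
    )


def stratum_savings(
    s: Stratum, shift: IntakeShiftDistribution, dr: DoseResponse
) -> StratumSavings:
    """Evaluate the model chain for one stratum.

    A per-stratum ``shift`` on ``s`` takes precedence over the
    config-level ``shift`` argument.
    """
    effective_shift = s.shift if s.shift is not None else shift
    eligible = s.population_count * (1.0 - s.pct_meeting_recs)
    prevalent = eligible * s.constipation_prev
    responders = prevalent * s.responder_frac
    averted = responders * expected_reduction(effective_shift, dr)
    cost = per_case_annual_cost(s.rx_frac, s.rx_annual_cost, s.otc_annual_cost)
    return StratumSavings(
        eligible_population=eligible,
        prevalent_cases=prevalent,
        responder_cases=responders,
        averted_cases=averted,
        per_case_annual_cost=cost,
        annual_savings=averted * cost,
    )


def run_model(cfg: ModelConfig) -> SavingsResult:
    """Run the cohort model over every stratum in scope and aggregate."""
    in_scope = cfg.strata_in_scope()
    if not in_scope:
        raise ValueError(
            f"population_scope {cfg.population_scope!r} selects no strata"
        )
    per_stratum = {
        s.label: stratum_savings(s, cfg.shift, cfg.dose_response) for s in in_scope
    }
    return SavingsResult(
        per_stratum=per_stratum,
        total_averted_cases=sum(e.averted_cases for e in per_stratum.values()),
        total_annual_savings=sum(e.annual_savings for e in per_stratum.values()),
    )
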