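"""Five-year budget-impact projection and GDP-contribution arithmetic.

Deterministic 2024-2028 projection of the Bulgarian 50-74 population (annual
decline 1.147%), incident CRC cases (0.431 per 1,000 person-years, pooled over
sex), advanced-stage cases with and without screening (stage III-IV shares 33%
vs 54% at diagnosis), avoided advanced-stage cases, and the treatment
expenditure those avoided cases would have incurred (EUR 6,417.85 each).

Rounding convention: the population and case chains are carried unrounded
internally; the published table's integers are display values, rounded
half-up per cell from the unrounded running product, with stage-share cells
computed from the unrounded case count and column totals from the unrounded
yearly sums. Savings are computed from the unrounded avoided-case chain.

The GDP block converts the QALYs gained by working-age patients into a
theoretical incremental GDP contribution under the stated one-QALY-equals-
one-work-year assumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conversions import BGN_PER_EUR

__all__ = [
    "ProjectionConfig",
    "GDPInputs",
    "project_population",
    "project_cases",
    "total_savings",
    "gdp_per_working_capita",
    "gdp_contribution",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ProjectionConfig:
    """Inputs of the deterministic 2024-2028 projection."""

    base_year: int = 2024
    base_population: int = 2_233_977       # ages 50-74
    annual_decline: float = 0.01147
    incidence: float = 0.000431            # per person-year, pooled male+female
    late_share_without: float = 0.54
    late_share_with: float = 0.33
    late_cost: float = 6417.85             # EUR per advanced-stage course
    n_years: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.annual_decline < 1.0:
            raise ValueError("annual_decline must lie in [0, 1)")
        for name in ("late_share_without", "late_share_with"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.late_share_with > self.late_share_without:
            raise ValueError("screening must not increase the advanced-stage share")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


def project_population(config: ProjectionConfig) -> np.ndarray:
    """Unrounded yearly population series, base year first.

    Follows the closed form ``base * (1 - decline)**k``; display rounding is
    applied only in :func:`project_cases`.
    """
    k = np.arange(config.n_years)
    return config.base_population * (1.0 - config.annual_decline) ** k


def project_cases(config: ProjectionConfig) -> pd.DataFrame:
    """Year-by-year projection table.

    Integer columns mirror the published display convention (rounded half-up
    per cell from the unrounded chain); the ``savings_eur`` column is computed
    from the unrounded avoided-case count so yearly amounts and the total are
    consistent.
    """
    pop = project_population(config)
    cases = pop * config.incidence
    late_wo = cases * config.late_share_without
    late_w = cases * config.late_share_with
    avoided = late_wo - late_w
    savings = avoided * config.late_cost
    rows = []
    for i in range(config.n_years):
        rows.append(
            {
                "year": config.base_year + i,
                "population": _round_half_up(pop[i]),
                "new_cases": _round_half_up(cases[i]),
                "late_without": _round_half_up(late_wo[i]),
                "late_with": _round_half_up(late_w[i]),
                "avoided": _round_half_up(late_wo[i]) - _round_half_up(late_w[i]),
                "avoided_unrounded": avoided[i],
                "savings_eur": savings[i],
                "savings_bgn": savings[i] * BGN_PER_EUR,
            }
        )
    frame = pd.DataFrame(rows)
    totals = {
        "year": "total",
        "population": None,
        "new_cases": _round_half_up(float(cases.sum())),
        "late_without": _round_half_up(float(late_wo.sum())),
        "late_with": _round_half_up(float(late_w.sum())),
        "avoided": int(frame["avoided"].sum()),
        "avoided_unrounded": float(avoided.sum()),
        "savings_eur": float(savings.sum()),
        "savings_bgn": float(savings.sum()) * BGN_PER_EUR,
    }
    return pd.concat([frame, pd.DataFrame([totals])], ignore_index=True)


def total_savings(rows: pd.DataFrame) -> float:
    """Sum of the yearly savings (EUR), from the unrounded avoided chain."""
    yearly = rows[rows["year"] != "total"]
    return float(yearly["savings_eur"].sum())


@dataclass(frozen=True)
class GDPInputs:
    """Inputs of the theoretical GDP-contribution projection."""

    gdp_total: float = 93_946_530_472.80       # EUR, 2023
    working_age_population: int = 3_900_300
    working_share_of_patients: float = 0.56
    total_qalys_gained: float = 1179.59

    def __post_init__(self) -> None:
        if self.working_age_population <= 0:
            raise ValueError("working_age_population must be > 0")
        if self.gdp_total <= 0 or self.total_qalys_gained < 0:
            raise ValueError("GDP and QALY inputs must be positive")
        if not 0.0 <= self.working_share_of_patients <= 1.0:
            raise ValueError("working_share_of_patients must lie in [0, 1]")


def gdp_per_working_capita(inputs: GDPInputs) -> float:
    """GDP per working-age person, EUR, rounded to cents."""
    return round(inputs.gdp_total / inputs.working_age_population, 2)


def gdp_contribution(inputs: GDPInputs) -> float:
    """Theoretical incremental GDP contribution of the QALYs gained, EUR.

    working-age QALYs x GDP per working-age capita, under the stated
    assumption that one QALY gained corresponds to one full year of
    productive work capacity — a theoretical upper-bound projection, not an
    observed productivity effect.
    """
    working_qalys = inputs.total_qalys_gained * inputs.working_share_of_patients
    return working_qalys * gdp_per_working_capita(inputs)
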