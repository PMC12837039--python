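"""Discrete-time Markov cohort engine for the CRC screening cost-utility model.

Four health states: undiagnosed CRC, diagnosed stage I-II, diagnosed stage
III-IV, and dead (absorbing). The whole cohort enters undiagnosed; the arm's
stage split at diagnosis routes it to the two diagnosed states. Stage I-II
patients face an annual probability of progressing to stage III-IV (recurrence)
and a stage-specific annual mortality; stage III-IV patients face a higher
annual mortality. Costs (one-time screening, colonoscopy at diagnosis,
optional stage III-IV treatment, palliative care on the transition to death)
and utilities (per year of state membership) are accrued per cycle and
discounted.

The published description of the original TreeAge build leaves several
structural choices open (when diagnosis occurs, reward timing, how one-time
transition costs are discounted, which patients are charged for colonoscopy,
how the advanced-stage treatment cost enters). Each open choice is a field of
:class:`StructuralVariant`; the calibration harness in :mod:`crcua.cua`
searches the variant grid against the published base-case totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Literal

import numpy as np

__all__ = [
    "HealthState",
    "StageSplit",
    "ArmParameters",
    "CostSet",
    "UtilitySet",
    "StructuralVariant",
    "ModelConfig",
    "CohortTrace",
    "build_transition_matrix",
    "discount_factor",
    "discount_factors",
    "run_cohort",
    "accrued_totals",
]

WITH_SCREENING = "with_screening"
WITHOUT_SCREENING = "without_screening"


class HealthState(IntEnum):
    """The four mutually exclusive health states of the cohort model."""

    UNDIAGNOSED = 0
    STAGE_I_II = 1
    STAGE_III_IV = 2
    DEAD = 3


N_STATES = len(HealthState)


@dataclass(frozen=True)
class StageSplit:
    """Stage distribution at diagnosis (early = I-II, late = III-IV)."""

    p_early: float
    p_late: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_early <= 1.0 and 0.0 <= self.p_late <= 1.0):
            raise ValueError("stage-split probabilities must lie in [0, 1]")
        if abs(self.p_early + self.p_late - 1.0) > 1e-9:
            raise ValueError(
                f"stage split must sum to 1, got {self.p_early + self.p_late!r}"
            )

    @classmethod
    def from_early(cls, p_early: float) -> "StageSplit":
        return cls(p_early, 1.0 - p_early)


@dataclass(frozen=True)
class ArmParameters:
    """Per-arm stage split plus the shared annual transition probabilities."""

    arm_label: str
    stage_split: StageSplit
    p_progress: float       # stage I-II -> III-IV, annual
    p_die_early: float      # stage I-II -> dead, annual
    p_die_late: float       # stage III-IV -> dead, annual

    def __post_init__(self) -> None:
        for name in ("p_progress", "p_die_early", "p_die_late"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v!r}")
        if self.p_progress + self.p_die_early > 1.0 + 1e-12:
            raise ValueError("stage I-II outgoing probabilities exceed 1")
        if self.p_die_late < self.p_die_early:
            raise ValueError("advanced-stage mortality must be >= early-stage mortality")


@dataclass(frozen=True)
class CostSet:
    """One-time cost items, in EUR."""

    screening_cost: float = 7.84
    colonoscopy_cost: float = 498.08
    late_treatment_cost: float = 6417.85
    palliative_cost: float = 1076.78

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")


@dataclass(frozen=True)
class UtilitySet:
    """Per-year health-state utilities. The dead state accrues nothing."""

    u_early: float = 0.74
    u_late: float = 0.46
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.u_dead != 0.0:
            raise ValueError("the dead state accrues no utility")


@dataclass(frozen=True)
class StructuralVariant:
    """Degrees of freedom the published model description leaves open.

    diagnosis_timing
        ``at_entry``: the cohort starts already split over the diagnosed
        states. ``after_one_cycle``: one full cycle undiagnosed, then
        deterministic transit per the arm's stage split.
    undiagnosed_utility_mode
        Utility of the undiagnosed year: full health (1.0) or the
        stage-split-weighted mean of the diagnosed utilities.
    half_cycle_correction
        Average start- and end-of-cycle occupancy for state rewards instead
        of start-of-cycle membership.
    late_cost_recurrence
        How the stage III-IV treatment cost enters: once on every entry into
        the state (diagnosis or progression), every cycle spent in the state,
        or excluded from the per-patient accrual entirely.
    colonoscopy_charge
        Charge the diagnostic colonoscopy to all newly diagnosed patients or
        only to those diagnosed at stage I-II.
    transition_cost_timing
        Discount one-time transition costs at the cycle the transition
        initiates (``departure``, TreeAge-style accrual in the source cycle)
        or at the arrival cycle.
    discount_convention
        ``delayed``: factor 1/(1+r)^t with t = 0 for the first cycle (no
        discounting in year one). ``from_first_cycle``: 1/(1+r)^(t+1).
    """

    diagnosis_timing: Literal["at_entry", "after_one_cycle"] = "after_one_cycle"
    undiagnosed_utility_mode: Literal["full_health", "stage_weighted"] = "full_health"
    half_cycle_correction: bool = False
    late_cost_recurrence: Literal["once_on_entry", "every_cycle", "excluded"] = "excluded"
    colonoscopy_charge: Literal["all_diagnosed", "early_only"] = "all_diagnosed"
    transition_cost_timing: Literal["departure", "arrival"] = "departure"
    discount_convention: Literal["delayed", "from_first_cycle"] = "delayed"

    def __post_init__(self) -> None:
        allowed = {
            "diagnosis_timing": ("at_entry", "after_one_cycle"),
            "undiagnosed_utility_mode": ("full_health", "stage_weighted"),
            "late_cost_recurrence": ("once_on_entry", "every_cycle", "excluded"),
            "colonoscopy_charge": ("all_diagnosed", "early_only"),
            "transition_cost_timing": ("departure", "arrival"),
            "discount_convention": ("delayed", "from_first_cycle"),
        }
        for name, values in allowed.items():
            if getattr(self, name) not in values:
                raise ValueError(f"{name} must be one of {values}, got {getattr(self, name)!r}")


#: The structural variant selected by the calibration grid search against the
#: published base-case totals (see docs/methods.md). It is the package default.
CALIBRATED_VARIANT = StructuralVariant()


@dataclass(frozen=True)
class ModelConfig:
    """Complete configuration of the two-arm cohort model."""

    arms: dict = field(default_factory=dict)   # arm_label -> ArmParameters
    costs: CostSet = field(default_factory=CostSet)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    variant: StructuralVariant = CALIBRATED_VARIANT
    horizon_cycles: int = 50
    cycle_length_years: float = 1.0
    discount_rate: float = 0.035

    def __post_init__(self) -> None:
        if self.horizon_cycles < 0:
            raise ValueError("horizon_cycles must be >= 0")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must lie in [0, 1)")
        for label, params in self.arms.items():
            if params.arm_label != label:
                raise ValueError(f"arm key {label!r} does not match label {params.arm_label!r}")

    def arm(self, arm_label: str) -> ArmParameters:
        try:
            return self.arms[arm_label]
        except KeyError:
            raise KeyError(
                f"unknown arm {arm_label!r}; available: {sorted(self.arms)}"
            ) from None

    def with_variant(self, variant: StructuralVariant) -> "ModelConfig":
        return replace(self, variant=variant)


@dataclass
class CohortTrace:
    """Per-cycle output of :func:`run_cohort`.

    ``occupancy`` has ``horizon + 1`` rows (state distribution at the start of
    each cycle plus the final distribution); the cost and QALY series have one
    entry per cycle, already discounted.
    """

    arm_label: str
    occupancy: np.ndarray       # (horizon+1, 4)
    cycle_costs: np.ndarray     # (horizon,)
    cycle_qalys: np.ndarray     # (horizon,)
    total_cost: float
    total_qaly: float

    def to_frame(self):
        """Cycle-by-cycle trace as a :class:`pandas.DataFrame`."""
        import pandas as pd

        h = len(self.cycle_costs)
        return pd.DataFrame(
            {
                "cycle": np.arange(h),
                "undiagnosed": self.occupancy[:h, HealthState.UNDIAGNOSED],
                "stage_i_ii": self.occupancy[:h, HealthState.STAGE_I_II],
                "stage_iii_iv": self.occupancy[:h, HealthState.STAGE_III_IV],
                "dead": self.occupancy[:h, HealthState.DEAD],
                "discounted_cost": self.cycle_costs,
                "discounted_qaly": self.cycle_qalys,
            }
        )


def discount_factor(cycle_index: int, rate: float, convention: str = "delayed") -> float:
    """Discount multiplier for one cycle.

    Under the ``delayed`` convention the first cycle (index 0) is undiscounted
    and cycle t is discounted by 1/(1+rate)^t — discounting starts after the
    first year. ``from_first_cycle`` uses 1/(1+rate)^(t+1).
    """
    if cycle_index < 0:
        raise ValueError("cycle_index must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    exponent = cycle_index if convention == "delayed" else cycle_index + 1
    return float((1.0 + rate) ** -exponent)


def discount_factors(n: int, rate: float, convention: str = "delayed") -> np.ndarray:
    """Vector of discount multipliers for cycles ``0 .. n-1``."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.arange(n, dtype=float)
    if convention != "delayed":
        t = t + 1.0
    return (1.0 + rate) ** -t


def build_transition_matrix(
    params: ArmParameters, variant: StructuralVariant = CALIBRATED_VARIANT
) -> np.ndarray:
    """Row-stochastic annual transition matrix over the four health states.

    The undiagnosed row routes to the diagnosed states per the arm's stage
    split (used at the cycle dictated by ``variant.diagnosis_timing``); the
    stage I-II row carries progression and early-stage mortality; the stage
    III-IV row carries advanced-stage mortality; dead is absorbing.
    """
    sp = params.stage_split
    stay_early = 1.0 - params.p_progress - params.p_die_early
    stay_late = 1.0 - params.p_die_late
    if stay_early < -1e-12 or stay_late < -1e-12:
        raise ValueError("outgoing probabilities exceed 1; negative stay probability")
    m = np.array(
        [
            [0.0, sp.p_early, sp.p_late, 0.0],
            [0.0, max(stay_early, 0.0), params.p_progress, params.p_die_early],
            [0.0, 0.0, max(stay_late, 0.0), params.p_die_late],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return m


def run_cohort(config: ModelConfig, arm_label: str) -> CohortTrace:
    """Run the cohort through the model and accrue discounted rewards.

    The cohort starts with full mass undiagnosed (or, under the ``at_entry``
    variant, already distributed over the diagnosed states). Per cycle, state
    membership earns utility and — for the ``every_cycle`` treatment accrual —
    cost; transitions into stage III-IV and into death trigger the one-time
    treatment and palliative costs; diagnosis triggers the colonoscopy cost.
    The screening cost is charged exactly once, at entry, in the screening arm
    only.
    """
    params = config.arm(arm_label)
    v = config.variant
    h = config.horizon_cycles
    m = build_transition_matrix(params, v)
    sp = params.stage_split

    d = discount_factors(h + 1, config.discount_rate, v.discount_convention)

    occupancy = np.zeros((h + 1, N_STATES))
    cycle_costs = np.zeros(h)
    cycle_qalys = np.zeros(h)

    if v.diagnosis_timing == "at_entry":
        occupancy[0, HealthState.STAGE_I_II] = sp.p_early
        occupancy[0, HealthState.STAGE_III_IV] = sp.p_late
    else:
        occupancy[0, HealthState.UNDIAGNOSED] = 1.0

    if v.undiagnosed_utility_mode == "full_health":
        u_undiag = 1.0
    else:
        u_undiag = sp.p_early * config.utilities.u_early + sp.p_late * config.utilities.u_late
    u_vec = np.array([u_undiag, config.utilities.u_early, config.utilities.u_late, 0.0])

    costs = config.costs
    if h > 0:
        if arm_label == WITH_SCREENING:
            cycle_costs[0] += costs.screening_cost * d[0]
        if v.diagnosis_timing == "at_entry":
            # the whole cohort is diagnosed in cycle 0
            colo_mass = 1.0 if v.colonoscopy_charge == "all_diagnosed" else sp.p_early
            cycle_costs[0] += costs.colonoscopy_cost * colo_mass * d[0]
            if v.late_cost_recurrence == "once_on_entry":
                cycle_costs[0] += costs.late_treatment_cost * sp.p_late * d[0]

    for t in range(h):
        occ = occupancy[t]
        occupancy[t + 1] = occ @ m

        # one-time transition costs for transitions occurring during cycle t
        d_event = d[t] if v.transition_cost_timing == "departure" else d[t + 1]
        from_undiag = occ[HealthState.UNDIAGNOSED]
        if from_undiag > 0.0:
            colo_mass = from_undiag if v.colonoscopy_charge == "all_diagnosed" else from_undiag * sp.p_early
            cycle_costs[t] += costs.colonoscopy_cost * colo_mass * d_event
        into_late = from_undiag * sp.p_late + occ[HealthState.STAGE_I_II] * params.p_progress
        into_dead = (
            occ[HealthState.STAGE_I_II] * params.p_die_early
            + occ[HealthState.STAGE_III_IV] * params.p_die_late
        )
        if v.late_cost_recurrence == "once_on_entry":
            cycle_costs[t] += costs.late_treatment_cost * into_late * d_event
        cycle_costs[t] += costs.palliative_cost * into_dead * d_event

        # state-membership rewards
        member = occ if not v.half_cycle_correction else 0.5 * (occ + occupancy[t + 1])
        if v.late_cost_recurrence == "every_cycle":
            cycle_costs[t] += costs.late_treatment_cost * member[HealthState.STAGE_III_IV] * d[t]
        cycle_qalys[t] = float(member @ u_vec) * d[t] * config.cycle_length_years

    return CohortTrace(
        arm_label=arm_label,
        occupancy=occupancy,
        cycle_costs=cycle_costs,
        cycle_qalys=cycle_qalys,
        total_cost=float(cycle_costs.sum()),
        total_qaly=float(cycle_qalys.sum()),
    )


def accrued_totals(trace: CohortTrace) -> tuple[float, float]:
    """Re-sum the per-cycle series; idempotent check of the stored totals."""
    return float(trace.cycle_costs.sum()), float(trace.cycle_qalys.sum())
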