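"""Synthetic inputs: campaign records and a microsimulation oracle.

Two generators with the statistical structure the analysis assumes:

* :func:`generate_participants` draws individual-level screening records
  (sex, age band, FIT result, communication channel) whose margins converge
  to the published campaign table, for exercising the campaign analytics on
  record-level data.
* :func:`microsim_cohort` simulates independent individual disease
  trajectories with per-cycle multinomial transitions from the same
  transition matrix and reward rules as the cohort engine. By the law of
  large numbers its mean discounted cost and QALY converge to the cohort
  expectation, making it a brute-force oracle for
  :func:`crcua.markov.run_cohort` under every structural variant.

Both are reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import (
    WITH_SCREENING,
    ArmParameters,
    CostSet,
    HealthState,
    ModelConfig,
    StageSplit,
    UtilitySet,
    build_transition_matrix,
    discount_factors,
)

__all__ = [
    "MarginSpec",
    "MicrosimResult",
    "default_margin_spec",
    "generate_participants",
    "microsim_cohort",
    "perturbed_fixture",
]


@dataclass(frozen=True)
class MarginSpec:
    """Margins and rates driving the participant-record generator."""

    n_total: int
    sex_dist: dict = field(default_factory=dict)        # sex -> fraction
    age_dist: dict = field(default_factory=dict)        # band -> fraction
    positivity_by_age: dict = field(default_factory=dict)
    sex_positivity_ratio: dict = field(default_factory=dict)  # sex -> rate multiplier
    channel_dist: dict = field(default_factory=dict)
    suspicious_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sex_dist", "age_dist", "channel_dist"):
            dist = getattr(self, name)
            if dist and abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for band, p in self.positivity_by_age.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"positivity for {band!r} must be a probability")
        if not 0.0 <= self.suspicious_rate <= 1.0:
            raise ValueError("suspicious_rate must be a probability")

    def cell_positivity(self, sex: str, band: str) -> float:
        """Positivity of a (sex, age) cell by proportional scaling.

        The published table gives only margins; the cell model scales the
        age-band rate by the sex rate ratio (sex positivity over overall
        positivity), clamped to [0, 1]. Both margins are then matched up to a
        small residual because the scaling is multiplicative rather than
        additive.
        """
        ratio = self.sex_positivity_ratio.get(sex, 1.0)
        return min(1.0, max(0.0, self.positivity_by_age[band] * ratio))


def default_margin_spec(params: dict | None = None) -> MarginSpec:
    """Margin spec matching the published campaign table.

    The generator targets the per-stratum positives (their age-band sum,
    13,263) rather than the table's header count of 13,281; the 18-record
    discrepancy is internal to the published table.
    """
    if params is None:
        from .parameters import load_parameters

        params = load_parameters()
    camp = params["campaign"]
    sex_tab = camp["sex"]
    age_tab = camp["age"]
    n_sex = sum(v["tested"] for v in sex_tab.values())
    n_age = sum(v["tested"] for v in age_tab.values())
    pos_age = sum(v["positive"] for v in age_tab.values())
    overall = pos_age / n_age
    chan = camp["channels"]
    n_chan = sum(chan.values())
    return MarginSpec(
        n_total=camp["total_tests"],
        sex_dist={k: v["tested"] / n_sex for k, v in sex_tab.items()},
        age_dist={k: v["tested"] / n_age for k, v in age_tab.items()},
        positivity_by_age={k: v["positive"] / v["tested"] for k, v in age_tab.items()},
        sex_positivity_ratio={
            k: (v["positive"] / v["tested"]) / overall for k, v in sex_tab.items()
        },
        channel_dist={k: v / n_chan for k, v in chan.items()},
        suspicious_rate=camp["n_suspicious"] / camp["total_tests"],
    )


def _categorical(rng: np.random.Generator, keys: list, probs: np.ndarray, n: int) -> np.ndarray:
    idx = rng.choice(len(keys), size=n, p=probs)
    return np.asarray(keys, dtype=object)[idx]


def generate_participants(spec: MarginSpec, seed: int | None = 0) -> pd.DataFrame:
    """Draw ``spec.n_total`` independent participant records.

    Sex, age band and channel are drawn from their marginals; the FIT result
    is suspicious at the independent suspicious rate, otherwise positive with
    the (sex, age) cell's positivity. Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_total
    if n == 0:
        return pd.DataFrame(columns=["id", "sex", "age_band", "fit_result", "channel"])
    sexes = list(spec.sex_dist)
    sex = _categorical(rng, sexes, np.array([spec.sex_dist[s] for s in sexes]), n)
    bands = list(spec.age_dist)
    age = _categorical(rng, bands, np.array([spec.age_dist[b] for b in bands]), n)
    channels = list(spec.channel_dist)
    channel = _categorical(rng, channels, np.array([spec.channel_dist[c] for c in channels]), n)

    p_cell = np.empty(n)
    for s in sexes:
        for b in bands:
            mask = (sex == s) & (age == b)
            if mask.any():
                p_cell[mask] = spec.cell_positivity(s, b)
    u = rng.random(n)
    suspicious = rng.random(n) < spec.suspicious_rate
    positive = (u < p_cell) & ~suspicious
    result = np.where(suspicious, "suspicious", np.where(positive, "positive", "negative"))
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "sex": sex,
            "age_band": age,
            "fit_result": result,
            "channel": channel,
        }
    )


@dataclass(frozen=True)
class MicrosimResult:
    """Mean discounted accruals of the simulated individuals, with SEs."""

    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float
    n_individuals: int


def microsim_cohort(
    config: ModelConfig, arm_label: str, n_individuals: int, seed: int | None = 0
) -> MicrosimResult:
    """Individual-level Monte Carlo counterpart of :func:`run_cohort`.

    Simulates ``n_individuals`` independent trajectories with the same
    transition matrix, reward rules and discounting as the cohort engine and
    returns the sample means with their standard errors. The cohort model's
    totals are the exact expectations of these means.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be > 0")
    params = config.arm(arm_label)
    v = config.variant
    h = config.horizon_cycles
    m = build_transition_matrix(params, v)
    sp = params.stage_split
    costs = config.costs
    d = discount_factors(h + 1, config.discount_rate, v.discount_convention)

    rng = np.random.default_rng(seed)
    n = n_individuals
    U, E, L, D = (
        int(HealthState.UNDIAGNOSED),
        int(HealthState.STAGE_I_II),
        int(HealthState.STAGE_III_IV),
        int(HealthState.DEAD),
    )
    if v.undiagnosed_utility_mode == "full_health":
        u_undiag = 1.0
    else:
        u_undiag = sp.p_early * config.utilities.u_early + sp.p_late * config.utilities.u_late
    u_state = np.array([u_undiag, config.utilities.u_early, config.utilities.u_late, 0.0])

    cost = np.zeros(n)
    qaly = np.zeros(n)
    if v.diagnosis_timing == "at_entry":
        state = np.where(rng.random(n) < sp.p_early, E, L).astype(np.int8)
        if h > 0:
            if v.colonoscopy_charge == "all_diagnosed":
                cost += costs.colonoscopy_cost * d[0]
            else:
                cost += np.where(state == E, costs.colonoscopy_cost * d[0], 0.0)
            if v.late_cost_recurrence == "once_on_entry":
                cost += np.where(state == L, costs.late_treatment_cost * d[0], 0.0)
    else:
        state = np.full(n, U, dtype=np.int8)
    if arm_label == WITH_SCREENING and h > 0:
        cost += costs.screening_cost * d[0]

    for t in range(h):
        u = rng.random(n)
        new = state.copy()

        undiag = state == U
        if undiag.any():
            new[undiag] = np.where(u[undiag] < sp.p_early, E, L).astype(np.int8)
        early = state == E
        if early.any():
            ue = u[early]
            nxt = np.full(ue.shape, E, dtype=np.int8)
            nxt[ue < params.p_progress + params.p_die_early] = D
            nxt[ue < params.p_progress] = L
            new[early] = nxt
        late = state == L
        if late.any():
            nl = np.where(u[late] < params.p_die_late, D, L).astype(np.int8)
            new[late] = nl

        d_event = d[t] if v.transition_cost_timing == "departure" else d[t + 1]
        diagnosed_now = undiag & (new != U)
        if diagnosed_now.any():
            if v.colonoscopy_charge == "all_diagnosed":
                cost[diagnosed_now] += costs.colonoscopy_cost * d_event
            else:
                cost[diagnosed_now & (new == E)] += costs.colonoscopy_cost * d_event
        entered_late = (new == L) & (state != L)
        if v.late_cost_recurrence == "once_on_entry" and entered_late.any():
            cost[entered_late] += costs.late_treatment_cost * d_event
        entered_dead = (new == D) & (state != D)
        if entered_dead.any():
            cost[entered_dead] += costs.palliative_cost * d_event
        if v.late_cost_recurrence == "every_cycle":
            cost[state == L] += costs.late_treatment_cost * d[t]

        if v.half_cycle_correction:
            qaly += 0.5 * (u_state[state] + u_state[new]) * d[t] * config.cycle_length_years
        else:
            qaly += u_state[state] * d[t] * config.cycle_length_years
        state = new

    return MicrosimResult(
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n_individuals=n,
    )


def perturbed_fixture(
    base: ModelConfig,
    relative_shift: float,
    fields: tuple[str, ...] | None = None,
    seed: int | None = None,
) -> ModelConfig:
    """Config with selected parameters multiplied by ``1 + relative_shift``.

    ``fields`` may name any of ``p_progress``, ``p_die_early``,
    ``p_die_late``, ``p_early`` (stage split), ``u_early``, ``u_late`` and the
    cost items; ``None`` perturbs all of them. With a ``seed``, each selected
    parameter gets its own shift drawn uniformly from [0, relative_shift]
    (or [relative_shift, 0] for negative shifts), which is useful for
    randomized property checks. Probabilities are clamped to [0, 1]; a shift
    that collapses a probability to zero is rejected.
    """
    all_fields = (
        "p_progress",
        "p_die_early",
        "p_die_late",
        "p_early",
        "u_early",
        "u_late",
        "screening_cost",
        "colonoscopy_cost",
        "late_treatment_cost",
        "palliative_cost",
    )
    if fields is None:
        fields = all_fields
    unknown = set(fields) - set(all_fields)
    if unknown:
        raise ValueError(f"unknown fields {sorted(unknown)}")
    rng = np.random.default_rng(seed) if seed is not None else None

    def shift_for(_name: str) -> float:
        if rng is None:
            return relative_shift
        lo, hi = sorted((0.0, relative_shift))
        return float(rng.uniform(lo, hi))

    def bump_prob(x: float, name: str) -> float:
        y = min(1.0, max(0.0, x * (1.0 + shift_for(name))))
        if x > 0.0 and y == 0.0:
            raise ValueError(f"shift collapses {name} to zero")
        return y

    arms = {}
    for label, arm in base.arms.items():
        kwargs = dict(
            p_progress=arm.p_progress,
            p_die_early=arm.p_die_early,
            p_die_late=arm.p_die_late,
        )
        for name in ("p_progress", "p_die_early", "p_die_late"):
            if name in fields:
                kwargs[name] = bump_prob(kwargs[name], name)
        split = arm.stage_split
        if "p_early" in fields:
            new_p_early = bump_prob(split.p_early, "p_early")
            if new_p_early != split.p_early:
                split = StageSplit.from_early(new_p_early)
        arms[label] = ArmParameters(arm_label=label, stage_split=split, **kwargs)

    u = base.utilities
    utilities = UtilitySet(
        u_early=bump_prob(u.u_early, "u_early") if "u_early" in fields else u.u_early,
        u_late=bump_prob(u.u_late, "u_late") if "u_late" in fields else u.u_late,
        u_dead=0.0,
    )
    c = base.costs
    cost_kwargs = {}
    for name in ("screening_cost", "colonoscopy_cost", "late_treatment_cost", "palliative_cost"):
        value = getattr(c, name)
        if name in fields:
            value = max(0.0, value * (1.0 + shift_for(name)))
        cost_kwargs[name] = value
    return replace(base, arms=arms, utilities=utilities, costs=CostSet(**cost_kwargs))
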