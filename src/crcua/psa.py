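"""Probabilistic sensitivity analysis of the two-arm cohort model.

Parameter uncertainty is propagated by Monte Carlo: each iteration draws a
full parameter set — costs from normal distributions (SD 20% of the mean),
utilities from gamma distributions (SD 20%), transition probabilities and
stage splits from beta distributions (SD 10%), all parameterized by method of
moments and sampled independently — re-runs both arms, and records the
incremental pair. Decision uncertainty is summarized as the fraction of
iterations with non-negative incremental net monetary benefit
(WTP x dQALY - dCost) at the willingness-to-pay threshold, and as a
cost-effectiveness acceptability curve over a WTP grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .markov import (
    WITH_SCREENING,
    WITHOUT_SCREENING,
    ArmParameters,
    CostSet,
    ModelConfig,
    StageSplit,
    UtilitySet,
    run_cohort,
)

__all__ = [
    "DistributionSpec",
    "PSAConfig",
    "PSAResult",
    "moments_to_params",
    "default_specs",
    "sample_config",
    "run_psa",
    "acceptability_curve",
]

#: Published willingness-to-pay threshold: 3x Bulgarian GDP per capita, EUR.
DEFAULT_WTP_EUR = 44081.03


@dataclass(frozen=True)
class DistributionSpec:
    """One uncertain parameter: its family, base-case mean and absolute SD."""

    parameter_id: str
    family: str  # normal | gamma | beta
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.family not in ("normal", "gamma", "beta"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.family == "gamma" and self.mean <= 0 and self.sd > 0:
            raise ValueError("gamma requires a positive mean")
        if self.family == "beta" and not 0.0 < self.mean < 1.0:
            raise ValueError("beta requires a mean in (0, 1)")


def moments_to_params(spec: DistributionSpec) -> dict:
    """Method-of-moments distribution parameters for a spec.

    normal -> {loc, scale}; gamma -> {shape, scale} with shape = (m/sd)^2 and
    scale = sd^2/m; beta -> {a, b} with a = m(m(1-m)/v - 1), b = (1-m)(...)
    where v = sd^2. A beta variance of at least m(1-m) is infeasible.
    """
    m, sd = spec.mean, spec.sd
    if spec.family == "normal":
        return {"loc": m, "scale": sd}
    if spec.family == "gamma":
        return {"shape": (m / sd) ** 2, "scale": sd**2 / m}
    v = sd**2
    if v >= m * (1.0 - m):
        raise ValueError(
            f"beta variance {v!r} is infeasible for mean {m!r} (must be < m(1-m))"
        )
    nu = m * (1.0 - m) / v - 1.0
    return {"a": m * nu, "b": (1.0 - m) * nu}


@dataclass(frozen=True)
class PSAConfig:
    """Monte Carlo settings: iteration count, seed, WTP threshold, SD rules."""

    n_iterations: int = 1000
    seed: int = 0
    wtp: float = DEFAULT_WTP_EUR
    cost_sd_fraction: float = 0.20
    utility_sd_fraction: float = 0.20
    probability_sd_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.wtp <= 0:
            raise ValueError("wtp must be > 0")


def default_specs(base: ModelConfig, psa_config: PSAConfig) -> list[DistributionSpec]:
    """Distribution specs covering every cost, utility and probability.

    Stage splits are represented by their early fraction only; the late
    fraction is set to the complement at sampling time, preserving the
    stage-split invariant.
    """
    c, u = base.costs, base.utilities
    arm_w = base.arm(WITH_SCREENING)
    arm_wo = base.arm(WITHOUT_SCREENING)
    fc, fu, fp = (
        psa_config.cost_sd_fraction,
        psa_config.utility_sd_fraction,
        psa_config.probability_sd_fraction,
    )
    specs = [
        DistributionSpec("cost.screening", "normal", c.screening_cost, fc * c.screening_cost),
        DistributionSpec("cost.colonoscopy", "normal", c.colonoscopy_cost, fc * c.colonoscopy_cost),
        DistributionSpec(
            "cost.late_treatment", "normal", c.late_treatment_cost, fc * c.late_treatment_cost
        ),
        DistributionSpec("cost.palliative", "normal", c.palliative_cost, fc * c.palliative_cost),
        DistributionSpec("utility.early", "gamma", u.u_early, fu * u.u_early),
        DistributionSpec("utility.late", "gamma", u.u_late, fu * u.u_late),
        DistributionSpec("prob.progress", "beta", arm_w.p_progress, fp * arm_w.p_progress),
        DistributionSpec("prob.die_early", "beta", arm_w.p_die_early, fp * arm_w.p_die_early),
        DistributionSpec("prob.die_late", "beta", arm_w.p_die_late, fp * arm_w.p_die_late),
        DistributionSpec(
            "split.with_screening.early",
            "beta",
            arm_w.stage_split.p_early,
            fp * arm_w.stage_split.p_early,
        ),
        DistributionSpec(
            "split.without_screening.early",
            "beta",
            arm_wo.stage_split.p_early,
            fp * arm_wo.stage_split.p_early,
        ),
    ]
    return specs


def _draw(spec: DistributionSpec, rng: np.random.Generator) -> tuple[float, bool]:
    """One draw from a spec (value, was_clamped); sd = 0 returns the mean."""
    if spec.sd == 0.0:
        return spec.mean, False
    p = moments_to_params(spec)
    if spec.family == "normal":
        raw = float(rng.normal(p["loc"], p["scale"]))
        return max(0.0, raw), raw < 0.0
    if spec.family == "gamma":
        raw = float(rng.gamma(p["shape"], p["scale"]))
    else:
        raw = float(rng.beta(p["a"], p["b"]))
    return min(1.0, max(0.0, raw)), not 0.0 <= raw <= 1.0


def sample_config(
    base: ModelConfig,
    specs: list[DistributionSpec],
    rng: np.random.Generator,
) -> tuple[ModelConfig, int]:
    """Replace the uncertain parameters of ``base`` by one joint draw.

    Draws are independent. Normal cost draws are truncated at zero, gamma
    utility draws and beta probability draws are clamped to [0, 1], and each
    arm's late stage fraction is the complement of its sampled early fraction.
    Returns the sampled config together with the number of clamped draws.
    """
    values: dict[str, float] = {}
    n_clamped = 0
    for spec in specs:
        v, clamped = _draw(spec, rng)
        values[spec.parameter_id] = v
        n_clamped += clamped

    c = base.costs
    costs = CostSet(
        screening_cost=values.get("cost.screening", c.screening_cost),
        colonoscopy_cost=values.get("cost.colonoscopy", c.colonoscopy_cost),
        late_treatment_cost=values.get("cost.late_treatment", c.late_treatment_cost),
        palliative_cost=values.get("cost.palliative", c.palliative_cost),
    )
    u = base.utilities
    utilities = UtilitySet(
        u_early=values.get("utility.early", u.u_early),
        u_late=values.get("utility.late", u.u_late),
        u_dead=0.0,
    )
    arms = {}
    for label, split_key in (
        (WITH_SCREENING, "split.with_screening.early"),
        (WITHOUT_SCREENING, "split.without_screening.early"),
    ):
        old = base.arm(label)
        p_early = values.get(split_key, old.stage_split.p_early)
        # keep the base split bitwise when the draw is degenerate
        split = old.stage_split if p_early == old.stage_split.p_early else StageSplit.from_early(p_early)
        arms[label] = ArmParameters(
            arm_label=label,
            stage_split=split,
            p_progress=values.get("prob.progress", old.p_progress),
            p_die_early=values.get("prob.die_early", old.p_die_early),
            p_die_late=values.get("prob.die_late", old.p_die_late),
        )
    return replace(base, costs=costs, utilities=utilities, arms=arms), n_clamped


@dataclass
class PSAResult:
    """Iteration-level PSA output with summary statistics.

    The per-iteration arrays hold both arms' discounted totals and their
    increments; ``acceptability`` is the fraction of iterations with
    non-negative incremental net monetary benefit at ``wtp``;
    ``quadrant_shares`` are the fractions of the incremental plane quadrants
    (keys ``"SE"``, ``"NE"``, ``"SW"``, ``"NW"``; positive dQALY is east,
    positive dCost is north; boundary iterations count toward the
    more-favourable quadrant).
    """

    wtp: float
    cost_with: np.ndarray
    qaly_with: np.ndarray
    cost_without: np.ndarray
    qaly_without: np.ndarray
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    acceptability: float
    quadrant_shares: dict = field(default_factory=dict)
    n_redraws: int = 0
    n_clamped: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.delta_cost)

    @property
    def means(self) -> dict:
        return {
            "cost_with": float(self.cost_with.mean()),
            "qaly_with": float(self.qaly_with.mean()),
            "cost_without": float(self.cost_without.mean()),
            "qaly_without": float(self.qaly_without.mean()),
            "delta_cost": float(self.delta_cost.mean()),
            "delta_qaly": float(self.delta_qaly.mean()),
        }

    def to_frame(self):
        """Scatter data (iteration, both arms, increments) as a DataFrame."""
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(self.n_iterations),
                "cost_with": self.cost_with,
                "qaly_with": self.qaly_with,
                "cost_without": self.cost_without,
                "qaly_without": self.qaly_without,
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
            }
        )


def _nmb(wtp: float, dq: np.ndarray, dc: np.ndarray) -> np.ndarray:
    return wtp * dq - dc


def run_psa(
    base: ModelConfig,
    psa_config: PSAConfig,
    specs: list[DistributionSpec] | None = None,
) -> PSAResult:
    """Monte Carlo re-evaluation of both arms under parameter uncertainty.

    Fully reproducible from ``psa_config.seed``. Iterations whose draw fails
    model validation (e.g. a sampled advanced-stage mortality below the
    early-stage one) are re-drawn and counted in ``n_redraws``.
    """
    if specs is None:
        specs = default_specs(base, psa_config)
    rng = np.random.default_rng(psa_config.seed)
    n = psa_config.n_iterations
    cw = np.empty(n)
    qw = np.empty(n)
    co = np.empty(n)
    qo = np.empty(n)
    n_redraws = 0
    n_clamped = 0
    for i in range(n):
        while True:
            try:
                cfg, clamped = sample_config(base, specs, rng)
                break
            except ValueError:
                n_redraws += 1
                if n_redraws > 100 * n:
                    raise RuntimeError("PSA sampling keeps failing validation")
        n_clamped += clamped
        tw = run_cohort(cfg, WITH_SCREENING)
        to = run_cohort(cfg, WITHOUT_SCREENING)
        cw[i], qw[i] = tw.total_cost, tw.total_qaly
        co[i], qo[i] = to.total_cost, to.total_qaly

    dc = cw - co
    dq = qw - qo
    acceptability = float(np.mean(_nmb(psa_config.wtp, dq, dc) >= 0.0))
    quadrants = {
        "SE": float(np.mean((dq >= 0) & (dc <= 0))),   # more QALYs, cheaper
        "NE": float(np.mean((dq >= 0) & (dc > 0))),
        "SW": float(np.mean((dq < 0) & (dc <= 0))),
        "NW": float(np.mean((dq < 0) & (dc > 0))),
    }
    return PSAResult(
        wtp=psa_config.wtp,
        cost_with=cw,
        qaly_with=qw,
        cost_without=co,
        qaly_without=qo,
        delta_cost=dc,
        delta_qaly=dq,
        acceptability=acceptability,
        quadrant_shares=quadrants,
        n_redraws=n_redraws,
        n_clamped=n_clamped,
    )


def acceptability_curve(result: PSAResult, wtp_grid) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve over a WTP grid.

    Each point is the fraction of iterations with non-negative incremental
    net monetary benefit at that willingness-to-pay value.
    """
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("the WTP grid is empty")
    return [
        (float(w), float(np.mean(_nmb(w, result.delta_qaly, result.delta_cost) >= 0.0)))
        for w in grid
    ]
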