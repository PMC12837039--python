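"""Descriptive statistics of the screening campaign.

Works from the published aggregate counts (sex- and age-stratified tests and
positives, channel attributions, budget) or from individual-level participant
records such as those produced by :mod:`crcua.synthetic`. The number of tests
is treated as the number of participants (repeat-testing data were not
collected).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "StratifiedCounts",
    "ChannelCounts",
    "BudgetSummary",
    "EmptyStratumError",
    "positivity",
    "channel_shares",
    "cost_per_participant",
    "target_exceedance",
]

SEXES = ("female", "male", "unspecified")
AGE_BANDS = ("18-49", "50-60", "61-74", "75+")
CHANNELS = ("television", "personal_network", "laboratory", "physician", "other")
RESULTS = ("negative", "positive", "suspicious")


class EmptyStratumError(ValueError):
    """Raised when a positivity rate is requested for an empty stratum.

    Distinct from a zero rate: an empty stratum has no defined rate at all.
    """


@dataclass(frozen=True)
class StratifiedCounts:
    """Tested/positive counts by sex and by age band, plus overall totals.

    The sex margins sum to the overall total; the age margins may fall short
    of it by a remainder of participants with unrecorded age (they do in the
    published table: 93,218 of 93,381 have a recorded age band).
    """

    n_tested: int
    n_positive: int
    n_suspicious: int
    sex: dict = field(default_factory=dict)   # sex -> (tested, positive)
    age: dict = field(default_factory=dict)   # band -> (tested, positive)

    def __post_init__(self) -> None:
        if self.n_positive + self.n_suspicious > self.n_tested:
            raise ValueError("positives plus suspicious results exceed tests")
        for margin in (self.sex, self.age):
            for key, (tested, positive) in margin.items():
                if positive > tested:
                    raise ValueError(f"stratum {key!r} has more positives than tests")
        if sum(t for t, _ in self.sex.values()) > self.n_tested:
            raise ValueError("sex-margin tests exceed the overall total")
        if sum(t for t, _ in self.age.values()) > self.n_tested:
            raise ValueError("age-margin tests exceed the overall total")

    @property
    def n_negative(self) -> int:
        return self.n_tested - self.n_positive - self.n_suspicious

    @property
    def age_unspecified(self) -> int:
        """Participants without a recorded age band."""
        return self.n_tested - sum(t for t, _ in self.age.values())

    @classmethod
    def from_records(cls, records: pd.DataFrame) -> "StratifiedCounts":
        """Build the aggregate counts from individual-level records.

        Expects columns ``sex``, ``age_band`` and ``fit_result``.
        """
        pos = records["fit_result"] == "positive"
        sex = {
            s: (int((records["sex"] == s).sum()), int((pos & (records["sex"] == s)).sum()))
            for s in records["sex"].unique()
        }
        age = {
            a: (
                int((records["age_band"] == a).sum()),
                int((pos & (records["age_band"] == a)).sum()),
            )
            for a in records["age_band"].unique()
        }
        return cls(
            n_tested=len(records),
            n_positive=int(pos.sum()),
            n_suspicious=int((records["fit_result"] == "suspicious").sum()),
            sex=sex,
            age=age,
        )

    def to_frame(self) -> pd.DataFrame:
        """Stratified table (margin, stratum, tested, positive, positivity %)."""
        rows = [("overall", "all", self.n_tested, self.n_positive)]
        rows += [("sex", k, t, p) for k, (t, p) in self.sex.items()]
        rows += [("age", k, t, p) for k, (t, p) in self.age.items()]
        frame = pd.DataFrame(rows, columns=["margin", "stratum", "tested", "positive"])
        frame["positivity_pct"] = 100.0 * frame["positive"] / frame["tested"]
        return frame


def positivity(counts: StratifiedCounts, selector="overall") -> float:
    """Positivity percentage of a stratum or union of strata.

    ``selector`` is ``"overall"``, ``("sex", key)``, ``("age", key)`` or
    ``("age", [key, ...])`` for a union of age bands. Returns
    ``100 * positives / tested`` at full precision.
    """
    if selector == "overall":
        tested, positive = counts.n_tested, counts.n_positive
    else:
        margin_name, keys = selector
        margin = counts.sex if margin_name == "sex" else counts.age
        if isinstance(keys, str):
            keys = [keys]
        try:
            cells = [margin[k] for k in keys]
        except KeyError as exc:
            raise KeyError(f"unknown stratum {exc.args[0]!r} in margin {margin_name!r}") from None
        tested = sum(t for t, _ in cells)
        positive = sum(p for _, p in cells)
    if tested == 0:
        raise EmptyStratumError(f"stratum {selector!r} has no tests; positivity undefined")
    return 100.0 * positive / tested


@dataclass(frozen=True)
class ChannelCounts:
    """Participants by the communication channel they credited.

    The published channel counts sum to fewer than the participant total, so
    two denominator policies exist: ``respondents`` (shares sum to 100%) and
    ``all_participants``.
    """

    counts: dict = field(default_factory=dict)
    n_participants: int | None = None

    def __post_init__(self) -> None:
        for k, v in self.counts.items():
            if v < 0:
                raise ValueError(f"channel {k!r} has a negative count")


def channel_shares(channels: ChannelCounts, denominator: str = "respondents") -> dict:
    """Percentage share per channel under the chosen denominator policy."""
    total = sum(channels.counts.values())
    if denominator == "respondents":
        denom = total
    elif denominator == "all_participants":
        if channels.n_participants is None:
            raise ValueError("all_participants policy requires n_participants")
        denom = channels.n_participants
    else:
        raise ValueError(f"unknown denominator policy {denominator!r}")
    if denom == 0:
        raise ValueError("channel-share denominator is zero")
    return {k: 100.0 * v / denom for k, v in channels.counts.items()}


@dataclass(frozen=True)
class BudgetSummary:
    """Campaign budget and its published allocation shares."""

    total_budget: float = 731_340.27
    share_logistics: float = 0.46
    share_communication: float = 0.34
    share_professional: float = 0.05
    share_admin: float = 0.15
    n_participants: int = 93_381

    def __post_init__(self) -> None:
        shares = (
            self.share_logistics
            + self.share_communication
            + self.share_professional
            + self.share_admin
        )
        if abs(shares - 1.0) > 0.005:
            raise ValueError(f"budget shares must sum to 1, got {shares!r}")
        if self.total_budget < 0:
            raise ValueError("total_budget must be non-negative")


def cost_per_participant(budget: BudgetSummary) -> float:
    """Total budget divided by participants, EUR, rounded to cents."""
    if budget.n_participants <= 0:
        raise ValueError("n_participants must be > 0")
    return round(budget.total_budget / budget.n_participants, 2)


def target_exceedance(screened: int, target: int) -> float:
    """Percentage by which the screened count exceeds the original target."""
    if target <= 0:
        raise ValueError("target must be > 0")
    return 100.0 * (screened - target) / target
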