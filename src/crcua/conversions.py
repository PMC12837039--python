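"""Probability and currency conversions for the screening cost-utility model.

The Markov engine runs on annual transition probabilities, while the
literature inputs are 5-year quantities: SEER 5-year survival by stage group
and Danish 5-year cumulative incidence functions (CIF) of recurrence. The two
conversions here assume a constant hazard within the 5-year window:

    annual mortality  = 1 - s5 ** (1/5)          (s5 = 5-year survival)
    annual incidence  = 1 - (1 - c5) ** (1/5)    (c5 = 5-year CIF)

Monetary amounts are carried dually in EUR and BGN under Bulgaria's fixed
currency-board peg of 1.95583 BGN per EUR.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "BGN_PER_EUR",
    "Money",
    "RecurrenceInputs",
    "annual_from_five_year_survival",
    "annual_from_five_year_cif",
    "pooled_cif",
    "convert_currency",
]

#: Fixed exchange rate of the Bulgarian currency board (BGN per EUR).
BGN_PER_EUR = 1.95583

_CURRENCIES = ("EUR", "BGN")


def annual_from_five_year_survival(s5: float) -> float:
    """Annual mortality probability from a 5-year survival probability.

    Parameters
    ----------
    s5 : float
        5-year survival probability, in (0, 1].

    Returns
    -------
    float
        Annual mortality probability ``1 - s5**(1/5)``, in [0, 1).
    """
    if not 0.0 < s5 <= 1.0:
        raise ValueError(f"5-year survival must be in (0, 1], got {s5!r}")
    return 1.0 - s5 ** 0.2


def annual_from_five_year_cif(c5: float) -> float:
    """Annual event probability from a 5-year cumulative incidence.

    Parameters
    ----------
    c5 : float
        5-year cumulative incidence, in [0, 1). A certain event (``c5 == 1``)
        has no finite annual probability under the constant-hazard formula.

    Returns
    -------
    float
        Annual probability ``1 - (1 - c5)**(1/5)``.
    """
    if not 0.0 <= c5 < 1.0:
        raise ValueError(f"5-year cumulative incidence must be in [0, 1), got {c5!r}")
    return 1.0 - (1.0 - c5) ** 0.2


@dataclass(frozen=True)
class RecurrenceInputs:
    """5-year recurrence CIFs by primary site and stage (Danish registry)."""

    cif_colon_stage1: float = 0.068
    cif_rectal_stage1: float = 0.095
    cif_colon_stage2: float = 0.116
    cif_rectal_stage2: float = 0.184

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v!r}")


def pooled_cif(inputs: RecurrenceInputs) -> float:
    """Unweighted mean of the four site-by-stage recurrence CIFs.

    No colon/rectal case-mix weighting is applied; the plain mean of the four
    published values (equivalently, the mean of the two stage means 8.15% and
    15.00%) gives the pooled 5-year CIF of 11.575% used for the early-to-late
    progression probability.
    """
    return (
        inputs.cif_colon_stage1
        + inputs.cif_rectal_stage1
        + inputs.cif_colon_stage2
        + inputs.cif_rectal_stage2
    ) / 4.0


@dataclass(frozen=True)
class Money:
    """A non-negative monetary amount with an explicit currency."""

    value: float
    currency: str = "EUR"

    def __post_init__(self) -> None:
        if self.currency not in _CURRENCIES:
            raise ValueError(f"unknown currency {self.currency!r}; expected one of {_CURRENCIES}")
        if self.value < 0:
            raise ValueError(f"monetary amount must be non-negative, got {self.value!r}")

    def to(self, target: str) -> "Money":
        return convert_currency(self, target)

    @property
    def eur(self) -> float:
        return self.to("EUR").value

    @property
    def bgn(self) -> float:
        return self.to("BGN").value


def convert_currency(amount: Money, target: str) -> Money:
    """Convert a :class:`Money` amount between EUR and BGN at the fixed peg."""
    if target not in _CURRENCIES:
        raise ValueError(f"unknown currency {target!r}; expected one of {_CURRENCIES}")
    if target == amount.currency:
        return amount
    if amount.currency == "EUR":
        return Money(amount.value * BGN_PER_EUR, "BGN")
    return Money(amount.value / BGN_PER_EUR, "EUR")
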