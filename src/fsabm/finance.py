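"""Loan arithmetic for Skyloo construction microloans.

Loans carry 1% monthly interest over a nominal two-year term.  The level
payment is computed as an annuity-due (payments at the start of each
month), which for a MK200,000 principal gives MK9320/month after rounding
to the nearest MK10.  Repayment in the simulation follows the balance
recursion B <- B*(1+r) - payment until the balance clears, with the final
payment truncated to the exact payoff.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LoanState", "required_payment", "loan_schedule"]


@dataclass
class LoanState:
    """One household's construction loan held by the business."""

    principal: float
    payment: float
    balance: float
    payments_made: int = 0
    #: first tick at which a repayment falls due (next month boundary
    #: after installation)
    first_due_tick: int = 0

    @property
    def closed(self) -> bool:
        return self.balance <= 0.0


def required_payment(
    principal: float,
    rate: float,
    term: int,
    granularity: float | None = 10.0,
) -> float:
    """Level monthly payment amortizing ``principal`` over ``term`` months.

    Annuity-due convention (payments at the start of each month):
    ``P*r / [(1+r) * (1 - (1+r)**-n)]``, optionally rounded to the nearest
    ``granularity`` MK.  With zero interest this is simply ``P / n``.
    """
    if term < 1:
        raise ValueError("term must be at least one month")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if principal <= 0:
        raise ValueError("principal must be positive")
    if rate == 0:
        pay = principal / term
    else:
        pay = principal * rate / ((1 + rate) * (1 - (1 + rate) ** -term))
    if granularity:
        pay = round(pay / granularity) * granularity
    return pay


def loan_schedule(principal: float, rate: float, payment: float) -> tuple[int, float]:
    """Number of payments and truncated final payment for a given level payment.

    Runs the balance recursion ``B <- B*(1+r) - payment`` until the balance
    reaches zero; the last payment is cut to the exact remaining payoff.
    Raises if the payment cannot amortize the loan (payment <= interest).
    """
    if principal <= 0:
        raise ValueError("principal must be positive")
    if payment <= principal * rate:
        raise ValueError("payment does not cover interest; loan never amortizes")
    balance = float(principal)
    term = 0
    while True:
        accrued = balance * (1 + rate)
        term += 1
        if accrued <= payment + 1e-9:
            return term, accrued
        balance = accrued - payment
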