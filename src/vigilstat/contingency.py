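"""Disproportionality statistics on 2x2 contingency tables.

For one drug (or drug combination) and one adverse-event preferred term the
counting collapses to the classic pharmacovigilance table

                        event of interest   all other events
    drug of interest            a                  b
    all other drugs             c                  d

where the counting unit is a distinct (report, PT) pair.  Three measures are
implemented:

* PRR — proportional reporting ratio, (a/(a+b)) / (c/(c+d)), with a
  log-scale Wald 95% confidence interval.
* ROR — reporting odds ratio, (a·d)/(b·c), with a log-scale Wald 95% CI.
* BCPNN information component — IC = log2 of the ratio of the joint
  reporting probability to the product of its margins, under independent
  Beta priors on the joint and marginal probabilities.  The closed-form
  posterior mean E[IC] and variance V[IC] give the conservative lower bound
  IC−2SD = E[IC] − 2·sqrt(V[IC]).

A term is conventionally called a signal when a >= 3, the lower 95% CI bound
of PRR and ROR exceeds 1, and IC−2SD > 0.  Zero cells make PRR/ROR undefined
(no continuity correction is applied); the BCPNN priors keep IC finite for
any non-negative table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "TwoByTwo",
    "BcpnnParams",
    "RatioResult",
    "prr_stat",
    "ror_stat",
    "bcpnn_stat",
    "Z_95",
]

#: Two-sided 95% normal quantile used in the Wald intervals.
Z_95 = 1.959963984540054


@dataclass(frozen=True)
class TwoByTwo:
    """Observed 2x2 table of (report, PT)-pair counts."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
        if self.a + self.b + self.c + self.d <= 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class BcpnnParams:
    """Prior constants of the BCPNN information component.

    The defaults encode vague priors: Beta(1, 1) on each margin
    (alpha1/beta1 with totals alpha/beta) and a joint prior whose scale
    gamma is tied to the margins so that E[IC] = 0 under exact independence
    of the priors.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha: float = 2.0
    beta: float = 2.0
    gamma11: float = 1.0

    def gamma(self, t: TwoByTwo) -> float:
        """Derived joint-prior scale for an observed table."""
        C = t.total
        Cx = t.a + t.b
        Cy = t.a + t.c
        return (
            self.gamma11
            * (C + self.alpha)
            * (C + self.beta)
            / ((Cx + self.alpha1) * (Cy + self.beta1))
        )


DEFAULT_BCPNN = BcpnnParams()


class RatioResult(NamedTuple):
    """A ratio statistic with its 95% Wald CI; NaN triple when undefined."""

    estimate: float
    ci_low: float
    ci_high: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)


_UNDEFINED = RatioResult(math.nan, math.nan, math.nan)


def prr_stat(t: TwoByTwo) -> RatioResult:
    """Proportional reporting ratio with log-scale Wald 95% CI.

    PRR = (a/(a+b)) / (c/(c+d));
    CI = exp(ln PRR ± z·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d))).

    Requires both row margins positive; with a = 0 or c = 0 the statistic
    (or its CI) is undefined and a NaN result is returned.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("degenerate margin: a+b and c+d must both be positive")
    if t.a == 0 or t.c == 0:
        return _UNDEFINED
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d))
    return RatioResult(
        prr, prr * math.exp(-Z_95 * se), prr * math.exp(Z_95 * se)
    )


def ror_stat(t: TwoByTwo) -> RatioResult:
    """Reporting odds ratio with log-scale Wald 95% CI.

    ROR = (a·d)/(b·c); CI = exp(ln ROR ± z·sqrt(1/a + 1/b + 1/c + 1/d)).
    Any zero cell makes the statistic undefined (NaN result, no exception).
    """
    if t.a == 0 or t.b == 0 or t.c == 0 or t.d == 0:
        return _UNDEFINED
    ror = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return RatioResult(
        ror, ror * math.exp(-Z_95 * se), ror * math.exp(Z_95 * se)
    )


class IcResult(NamedTuple):
    """BCPNN information-component posterior moments, in bits."""

    eic: float
    vic: float
    ic_minus_2sd: float


def bcpnn_stat(t: TwoByTwo, p: BcpnnParams = DEFAULT_BCPNN) -> IcResult:
    """Posterior mean/variance of the information component and IC−2SD.

    With C = a+b+c+d, Cx = a+b, Cy = a+c, Cxy = a and the derived joint
    prior scale γ:

        E[IC] = log2[ (Cxy+γ11)(C+α)(C+β) / ((C+γ)(Cx+α1)(Cy+β1)) ]
        V[IC] = (1/ln²2) [ (C−Cxy+γ−γ11)/((Cxy+γ11)(1+C+γ))
                         + (C−Cx+α−α1)/((Cx+α1)(1+C+α))
                         + (C−Cy+β−β1)/((Cy+β1)(1+C+β)) ]

    Both are finite for any non-negative table thanks to the priors.
    """
    C = t.total
    Cx = t.a + t.b
    Cy = t.a + t.c
    Cxy = t.a
    g = p.gamma(t)
    eic = math.log2(
        (Cxy + p.gamma11)
        * (C + p.alpha)
        * (C + p.beta)
        / ((C + g) * (Cx + p.alpha1) * (Cy + p.beta1))
    )
    vic = (
        (C - Cxy + g - p.gamma11) / ((Cxy + p.gamma11) * (1 + C + g))
        + (C - Cx + p.alpha - p.alpha1) / ((Cx + p.alpha1) * (1 + C + p.alpha))
        + (C - Cy + p.beta - p.beta1) / ((Cy + p.beta1) * (1 + C + p.beta))
    ) / math.log(2) ** 2
    return IcResult(eic, vic, eic - 2 * math.sqrt(vic))
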