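"""Disproportionality statistics (ROR, PRR, χ², BCPNN IC) and signal criteria.

All statistics operate on a report-level 2×2 table::

                event   other
    drug          a       b
    background    c       d

The information component uses the closed-form posterior moments of the
BCPNN with the standard shrinkage priors, so it stays finite for every
table including a = 0.  ROR and PRR are flagged incalculable (NaN) on zero
cells instead of applying continuity corrections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .contingency import ContingencyTable
from .mapping import VocabMap

__all__ = [
    "SignalCriteria",
    "DisproResult",
    "ror_with_ci",
    "prr_chi2",
    "bcpnn_ic",
    "analyze_table",
    "analyze_tables",
    "evaluate_signal",
    "results_to_frame",
]

_Z95 = 1.96
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the composite signal rule.

    A pair is a signal when all four hold: a ≥ min_a; ROR ≥ min_ror with the
    lower 95% bound > ror_ci_low_gt; PRR > min_prr with χ² > min_chi2 (both
    strict); IC−2SD > ic_minus_2sd_gt.  A signal is strong when additionally
    IC−2SD ≥ strong_ic_minus_2sd.
    """

    min_a: int = 6
    min_ror: float = 2.0
    ror_ci_low_gt: float = 1.0
    min_prr: float = 2.0
    min_chi2: float = 4.0
    ic_minus_2sd_gt: float = 0.0
    strong_ic_minus_2sd: float = 1.0

    def evaluate(
        self,
        a: int,
        ror: float,
        ror_ci_low: float,
        prr: float,
        chi2: float,
        ic_minus_2sd: float,
    ) -> tuple[bool, bool]:
        """Return (is_signal, is_strong); NaN statistics fail their condition."""

        def ok(value: float) -> bool:
            return isinstance(value, (int, float)) and math.isfinite(value)

        is_signal = (
            a >= self.min_a
            and ok(ror)
            and ror >= self.min_ror
            and ok(ror_ci_low)
            and ror_ci_low > self.ror_ci_low_gt
            and ok(prr)
            and prr > self.min_prr
            and ok(chi2)
            and chi2 > self.min_chi2
            and ok(ic_minus_2sd)
            and ic_minus_2sd > self.ic_minus_2sd_gt
        )
        is_strong = is_signal and ic_minus_2sd >= self.strong_ic_minus_2sd
        return is_signal, is_strong


@dataclass(frozen=True)
class DisproResult:
    table: ContingencyTable
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    e_ic: float
    v_ic: float
    ic_minus_2sd: float
    is_signal: bool = False
    is_strong: bool = False

    @property
    def drug(self) -> str:
        return self.table.drug

    @property
    def event(self) -> str:
        return self.table.event


def ror_with_ci(table: ContingencyTable) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% Woolf (log-normal) interval.

    Any zero cell makes the estimate incalculable: (nan, nan, nan).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        return (math.nan, math.nan, math.nan)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_ror = math.log(ror)
    return (ror, math.exp(log_ror - _Z95 * se), math.exp(log_ror + _Z95 * se))


def prr_chi2(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and the Pearson χ² of the 2×2 table.

    PRR is incalculable (nan) when the background never reports the event
    (c = 0) or a margin is empty; χ² is nan when any margin is zero.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if a + b == 0 or c + d == 0 or c == 0:
        prr = math.nan
    else:
        prr = (a / (a + b)) / (c / (c + d))
    row1, row2, col1, col2 = a + b, c + d, a + c, b + d
    if 0 in (row1, row2, col1, col2):
        return (prr, math.nan)
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    chi2 = n * diff * diff / (row1 * row2 * col1 * col2)
    return (prr, chi2)


def bcpnn_ic(table: ContingencyTable) -> tuple[float, float, float]:
    """Posterior mean and variance of the information component, in bits.

    Closed-form BCPNN moments with priors α1 = β1 = 1, α = β = 2, γ11 = 1 and
    γ chosen so the prior IC is centred at independence.  Returns
    (E(IC), V(IC), IC − 2·sqrt(V(IC))).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    alpha1 = beta1 = 1.0
    alpha = beta = 2.0
    gamma11 = 1.0
    row = a + b + alpha1  # drug margin + prior
    col = a + c + beta1  # event margin + prior
    gamma = gamma11 * (n + alpha) * (n + beta) / (row * col)
    e_ic = math.log2((a + gamma11) * (n + alpha) * (n + beta) / ((n + gamma) * row * col))
    v_ic = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - (a + b) + alpha - alpha1) / (row * (1 + n + alpha))
        + (n - (a + c) + beta - beta1) / (col * (1 + n + beta))
    ) / (_LN2 * _LN2)
    return (e_ic, v_ic, e_ic - 2.0 * math.sqrt(v_ic))


def analyze_table(
    table: ContingencyTable,
    criteria: SignalCriteria | None = None,
    yates: bool = False,
) -> DisproResult:
    """Compute all statistics for one table and apply the signal criteria."""
    criteria = criteria or SignalCriteria()
    ror, lo, hi = ror_with_ci(table)
    prr, chi2 = prr_chi2(table, yates=yates)
    e_ic, v_ic, ic2sd = bcpnn_ic(table)
    result = DisproResult(
        table=table,
        ror=ror,
        ror_ci_low=lo,
        ror_ci_high=hi,
        prr=prr,
        chi2=chi2,
        e_ic=e_ic,
        v_ic=v_ic,
        ic_minus_2sd=ic2sd,
    )
    return evaluate_signal(result, criteria)


def analyze_tables(
    tables: Iterable[ContingencyTable],
    criteria: SignalCriteria | None = None,
    yates: bool = False,
) -> list[DisproResult]:
    criteria = criteria or SignalCriteria()
    return [analyze_table(t, criteria, yates=yates) for t in tables]


def evaluate_signal(result: DisproResult, criteria: SignalCriteria) -> DisproResult:
    """Fill in the is_signal / is_strong verdicts from the computed statistics."""
    is_signal, is_strong = criteria.evaluate(
        a=result.table.a,
        ror=result.ror,
        ror_ci_low=result.ror_ci_low,
        prr=result.prr,
        chi2=result.chi2,
        ic_minus_2sd=result.ic_minus_2sd,
    )
    return replace(result, is_signal=is_signal, is_strong=is_strong)


def results_to_frame(results: Iterable[DisproResult], vocab: VocabMap | None = None) -> pd.DataFrame:
    """Results as a frame mirroring the published column order."""
    rows = []
    for r in results:
        soc = r.table.event if r.table.level == "SOC" else (
            vocab.soc_of(r.table.event) if vocab is not None else ""
        )
        rows.append(
            {
                "drug": r.drug,
                "event": r.event,
                "level": r.table.level,
                "soc": soc,
                "N": r.table.a,
                "PRR": r.prr,
                "chi2": r.chi2,
                "ROR": r.ror,
                "ROR_CI025": r.ror_ci_low,
                "IC": r.e_ic,
                "IC_2SD": r.ic_minus_2sd,
                "is_signal": r.is_signal,
                "is_strong": r.is_strong,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "drug", "event", "level", "soc", "N", "PRR", "chi2",
            "ROR", "ROR_CI025", "IC", "IC_2SD", "is_signal", "is_strong",
        ],
    )
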