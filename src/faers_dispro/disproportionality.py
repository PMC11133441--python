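"""Disproportionality signal detection: ROR and PRR on per-PT 2x2 tables.

For each Preferred Term the event list is collapsed into the four-cell table

    ==============  ==========  ===========
    .               target PT   other PTs
    ==============  ==========  ===========
    target drug     a           b
    other drugs     c           d
    ==============  ==========  ===========

where the counting unit is one distinct (report, PT) event.  Two classical
frequentist measures are computed:

* reporting odds ratio  ROR = ad / bc, with the Woolf 95% confidence
  interval  exp(ln ROR +- z * sqrt(1/a + 1/b + 1/c + 1/d)),
* proportional reporting ratio  PRR = [a/(a+b)] / [c/(c+d)], accompanied by
  the uncorrected Pearson chi-square
  (ad - bc)^2 (a+b+c+d) / [(a+b)(c+d)(a+c)(b+d)].

A PT is flagged as a signal when a >= 3 and the ROR CI lower bound exceeds 1
(ROR rule), or when a >= 3, PRR > 2 and chi-square > 4 (PRR rule); all
inequalities except the a-gate are strict.  With a zero cell the estimates
are undefined by default; the optional Haldane-Anscombe correction adds 0.5
to every cell instead.  No multiple-testing adjustment is applied — these
thresholds are screening rules, and flagged pairs are hypotheses for review,
not established causal associations.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from faers_dispro.dedup_cohort import CohortEvent

Z_95 = 1.96


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """The a/b/c/d four-cell table of one drug-event contrast."""

    a: int  # target drug, target PT
    b: int  # target drug, other PTs
    c: int  # other drugs, target PT
    d: int  # other drugs, other PTs

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"cell {name} must be nonnegative, got {value}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self, delta: float = 0.5) -> Tuple[float, float, float, float]:
        return (self.a + delta, self.b + delta, self.c + delta, self.d + delta)


@dataclass(frozen=True, slots=True)
class SignalResult:
    """Per-PT disproportionality estimates and threshold flags.

    Undefined estimates (zero cells without correction) are ``nan`` and never
    satisfy a threshold.
    """

    pt: str
    table: ContingencyTable
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ror_signal: bool
    prr_signal: bool


def build_contingency(events: Sequence[CohortEvent], pt: str) -> ContingencyTable:
    """Collapse an event list into the 2x2 table for one (normalised) PT."""
    a = b = c = d = 0
    for ev in events:
        if ev.is_target_drug:
            if ev.pt == pt:
                a += 1
            else:
                b += 1
        else:
            if ev.pt == pt:
                c += 1
            else:
                d += 1
    return ContingencyTable(a, b, c, d)


def ror(
    table: ContingencyTable, z: float = Z_95, correction: bool = False
) -> Tuple[float, float, float]:
    """Reporting odds ratio with its Woolf log-scale confidence interval.

    Returns ``(estimate, ci_low, ci_high)``.  With any zero cell the result
    is ``(nan, nan, nan)`` unless ``correction`` applies Haldane-Anscombe
    +0.5 to every cell.
    """
    cells = table.corrected() if correction else (table.a, table.b, table.c, table.d)
    a, b, c, d = (float(x) for x in cells)
    if min(a, b, c, d) <= 0:
        return (math.nan, math.nan, math.nan)
    estimate = (a * d) / (b * c)
    half_width = z * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(estimate)
    return (estimate, math.exp(log_est - half_width), math.exp(log_est + half_width))


def prr(table: ContingencyTable, correction: bool = False) -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)].

    ``nan`` when the target margin is empty or the background rate is zero
    (c = 0) without correction.
    """
    cells = table.corrected() if correction else (table.a, table.b, table.c, table.d)
    a, b, c, d = (float(x) for x in cells)
    if a + b <= 0 or c + d <= 0 or c <= 0:
        return math.nan
    return (a / (a + b)) / (c / (c + d))


def chi_square(table: ContingencyTable) -> float:
    """Uncorrected Pearson chi-square of the 2x2 table.

    Computed as (ad - bc)^2 (a+b+c+d) / [(a+b)(c+d)(a+c)(b+d)]; ``nan``
    when any margin is zero.
    """
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return math.nan
    return (a * d - b * c) ** 2 * (a + b + c + d) / denom


def flag_signals(
    table: ContingencyTable,
    ror_ci_low: float,
    prr_value: float,
    chi2_value: float,
    min_a: int = 3,
) -> Tuple[bool, bool]:
    """Apply the two screening rules; undefined (nan) estimates never flag."""
    gate = table.a >= min_a
    ror_signal = gate and not math.isnan(ror_ci_low) and ror_ci_low > 1.0
    prr_signal = (
        gate
        and not math.isnan(prr_value)
        and not math.isnan(chi2_value)
        and prr_value > 2.0
        and chi2_value > 4.0
    )
    return ror_signal, prr_signal


def evaluate_pt(
    events_or_table,
    pt: Optional[str] = None,
    z: float = Z_95,
    correction: bool = False,
    min_a: int = 3,
) -> SignalResult:
    """Full evaluation of one PT: table, estimates, CI, chi-square, flags."""
    if isinstance(events_or_table, ContingencyTable):
        table = events_or_table
        pt = pt if pt is not None else ""
    else:
        if pt is None:
            raise ValueError("pt is required when passing an event list")
        table = build_contingency(events_or_table, pt)
    estimate, lo, hi = ror(table, z=z, correction=correction)
    prr_value = prr(table, correction=correction)
    chi2_value = chi_square(table)
    ror_flag, prr_flag = flag_signals(table, lo, prr_value, chi2_value, min_a=min_a)
    return SignalResult(
        pt=pt,
        table=table,
        ror=estimate,
        ror_ci_low=lo,
        ror_ci_high=hi,
        prr=prr_value,
        chi2=chi2_value,
        ror_signal=ror_flag,
        prr_signal=prr_flag,
    )


def compute_signals(
    events: Sequence[CohortEvent],
    z: float = Z_95,
    correction: bool = False,
    min_a: int = 3,
) -> List[SignalResult]:
    """Evaluate every PT reported at least once for the target drug.

    A single pass builds all 2x2 tables: for PT p,
    a = target events with p, b = (total target events) - a,
    c = background events with p, d = (total background events) - c.
    """
    target_counts: Counter = Counter()
    background_counts: Counter = Counter()
    for ev in events:
        (target_counts if ev.is_target_drug else background_counts)[ev.pt] += 1
    total_target = sum(target_counts.values())
    total_background = sum(background_counts.values())

    results = []
    for pt in sorted(target_counts):
        a = target_counts[pt]
        c = background_counts.get(pt, 0)
        table = ContingencyTable(a, total_target - a, c, total_background - c)
        results.append(evaluate_pt(table, pt=pt, z=z, correction=correction, min_a=min_a))
    return results


_RANK_KEYS = {"ror", "prr", "a"}


def rank_signals(
    results: Sequence[SignalResult],
    key: str = "ror",
    top_n: Optional[int] = None,
) -> List[SignalResult]:
    """Flagged signals (either rule) sorted descending by ``key``.

    Ties break by larger ``a``, then PT alphabetically.  Results whose sort
    key is undefined are excluded.
    """
    if key not in _RANK_KEYS:
        raise ValueError(f"rank key must be one of {sorted(_RANK_KEYS)}, got {key!r}")

    def sort_value(res: SignalResult) -> float:
        return float(res.table.a) if key == "a" else getattr(res, key)

    flagged = [
        res
        for res in results
        if (res.ror_signal or res.prr_signal) and not math.isnan(sort_value(res))
    ]
    flagged.sort(key=lambda res: (-sort_value(res), -res.table.a, res.pt))
    return flagged if top_n is None else flagged[:top_n]


def write_signals(
    results: Sequence[SignalResult],
    path,
    display: Optional[Dict[str, str]] = None,
) -> None:
    """Write ranked signal results as TSV (one row per PT)."""
    display = display or {}

    def fmt(x: float) -> str:
        return "" if math.isnan(x) else format(x, ".6g")

    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "PT\ta\tb\tc\td\tROR\tROR_CI_low\tROR_CI_high\tPRR\tchi2\t"
            "ror_signal\tprr_signal\n"
        )
        for res in results:
            t = res.table
            fh.write(
                f"{display.get(res.pt, res.pt)}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t"
                f"{fmt(res.ror)}\t{fmt(res.ror_ci_low)}\t{fmt(res.ror_ci_high)}\t"
                f"{fmt(res.prr)}\t{fmt(res.chi2)}\t"
                f"{int(res.ror_signal)}\t{int(res.prr_signal)}\n"
            )
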