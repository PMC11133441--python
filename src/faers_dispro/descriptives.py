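"""Descriptive frequency tables for a spontaneous-reporting cohort.

Covers the standard pharmacovigilance summary set: annual report counts,
clinical characteristics (sex, age bands, weight bands, reporter occupation,
top reporting countries), severe-outcome distribution, top-N Preferred-Term
frequencies, System-Organ-Class frequencies, and named PT groupings.

Conventions
-----------
* Percentages are round-half-up (1 decimal for demographic/outcome tables,
  2 decimals for PT and SOC tables by default).
* Demographic denominators are the cohort size, with an explicit N/A row for
  missing values; spontaneous reports are missing demographics at high rates,
  so the N/A row routinely dominates.
* Age bands are 18-64 and >=65; under-18 ages fall into N/A with a logged
  warning.  Weight bands are <80, 80-100 (closed) and >100 kg.
* PT/SOC denominators are event counts (distinct case-PT pairs).  Events
  whose PT is absent from the PT->SOC map are reported as unmapped and
  excluded from the SOC denominator, so the SOC total may be smaller than
  the PT total.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

from faers_dispro.dedup_cohort import CohortEvent, normalize_pt
from faers_dispro.faers_io import DemoRecord, OutcomeRecord, PtSocMap

logger = logging.getLogger(__name__)

OUTCOME_LABELS = {
    "HO": "Hospitalized",
    "DE": "Death",
    "LT": "Life-threatening",
    "DS": "Disability",
    "RI": "Resulted in permanent impairment/disability",
    "CA": "Congenital anomaly",
    "OT": "Other",
}

OCCUPATION_LABELS = {
    "CN": "Consumer",
    "MD": "Physician",
    "HP": "Health-profession",
    "PH": "Pharmacist",
    "OT": "Other health-profession",
    "LW": "Lawyer",
    None: "Unknown",
}


def percent(count: int, denominator: int, digits: int = 1) -> float:
    """Round-half-up percentage ``100 * count / denominator``.

    Uses decimal arithmetic so that ties round away from zero the way the
    printed tables do (e.g. 55.25 -> 55.3 at one decimal), which banker's
    rounding would not.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if count < 0:
        raise ValueError("count must be nonnegative")
    quantum = Decimal(1).scaleb(-digits)
    value = (Decimal(100) * Decimal(count) / Decimal(denominator)).quantize(
        quantum, rounding=ROUND_HALF_UP
    )
    return float(value)


@dataclass(frozen=True, slots=True)
class FrequencyRow:
    category: str
    count: int
    percent: float


@dataclass(slots=True)
class FrequencyTable:
    """Rows plus the denominator their percentages were computed against."""

    rows: List[FrequencyRow]
    denominator: int

    def as_dict(self) -> Dict[str, int]:
        return {row.category: row.count for row in self.rows}


def write_frequency_table(table: FrequencyTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("category\tn\tpercent\n")
        for row in table.rows:
            fh.write(f"{row.category}\t{row.count}\t{row.percent}\n")


def _rows_from_counts(
    counts: Sequence[Tuple[str, int]], denominator: int, digits: int
) -> List[FrequencyRow]:
    return [FrequencyRow(cat, n, percent(n, denominator, digits)) for cat, n in counts]


def demographic_table(
    records: Sequence[DemoRecord],
    top_countries: int = 5,
    digits: int = 1,
) -> Dict[str, FrequencyTable]:
    """Clinical-characteristics tables for a deduplicated cohort.

    Returns tables keyed ``gender``, ``age``, ``weight``, ``reporter`` and
    ``country``; every denominator is the cohort size.  The country table
    lists only the ``top_countries`` most frequent countries, so its rows
    need not sum to the denominator.
    """
    n = len(records)
    if n == 0:
        raise ValueError("empty cohort: no demographic records")

    sex_counts = Counter(rec.sex for rec in records)
    gender = [
        ("Male", sex_counts.get("M", 0)),
        ("Female", sex_counts.get("F", 0)),
        ("N/A", sex_counts.get(None, 0)),
    ]

    age_bands = Counter()
    under_18 = 0
    for rec in records:
        age = rec.age_years
        if age is None:
            age_bands["N/A"] += 1
        elif age < 18:
            under_18 += 1
            age_bands["N/A"] += 1
        elif age <= 64:
            age_bands["18-64"] += 1
        else:
            age_bands[">=65"] += 1
    if under_18:
        logger.warning(
            "%d record(s) with age < 18 years placed in the N/A age band "
            "(the table has no pediatric band)",
            under_18,
        )
    age = [(band, age_bands.get(band, 0)) for band in ("18-64", ">=65", "N/A")]

    weight_bands = Counter()
    for rec in records:
        wt = rec.weight_kg
        if wt is None:
            weight_bands["N/A"] += 1
        elif wt < 80:
            weight_bands["<80"] += 1
        elif wt <= 100:
            weight_bands["80-100"] += 1
        else:
            weight_bands[">100"] += 1
    weight = [(band, weight_bands.get(band, 0)) for band in ("<80", "80-100", ">100", "N/A")]

    occ_counts = Counter(rec.reporter_occupation for rec in records)
    reporter = [
        (OCCUPATION_LABELS.get(code, "Unknown"), cnt)
        for code, cnt in sorted(
            occ_counts.items(), key=lambda kv: (-kv[1], OCCUPATION_LABELS.get(kv[0], "Unknown"))
        )
    ]

    country_counts = Counter(
        rec.reporter_country for rec in records if rec.reporter_country is not None
    )
    country = sorted(country_counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]

    return {
        "gender": FrequencyTable(_rows_from_counts(gender, n, digits), n),
        "age": FrequencyTable(_rows_from_counts(age, n, digits), n),
        "weight": FrequencyTable(_rows_from_counts(weight, n, digits), n),
        "reporter": FrequencyTable(_rows_from_counts(reporter, n, digits), n),
        "country": FrequencyTable(_rows_from_counts(country, n, digits), n),
    }


def outcome_table(records: Sequence[OutcomeRecord], digits: int = 1) -> FrequencyTable:
    """Severe-outcome distribution over distinct (report, outcome-code) instances.

    The denominator is the total number of instances (one report can carry
    several outcome codes; a repeated code within one report counts once).
    All seven outcome codes count as severe-outcome instances.
    """
    instances = {(rec.primary_id, rec.outcome_code) for rec in records}
    denominator = len(instances)
    counts = Counter(code for _, code in instances)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], OUTCOME_LABELS[kv[0]]))
    rows = (
        _rows_from_counts([(OUTCOME_LABELS[c], n) for c, n in ordered], denominator, digits)
        if denominator
        else []
    )
    return FrequencyTable(rows, denominator)


def pt_frequency(
    events: Sequence[CohortEvent],
    top_n: Optional[int] = 15,
    digits: int = 2,
    display: Optional[Dict[str, str]] = None,
) -> FrequencyTable:
    """Top-N Preferred-Term frequencies among target-cohort events.

    Counts are distinct (report, PT) pairs; the percentage denominator is the
    total number of target events.  Ties in count are broken alphabetically.
    """
    target = [ev for ev in events if ev.is_target_drug]
    denominator = len(target)
    counts = Counter(ev.pt for ev in target)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        ordered = ordered[:top_n]
    display = display or {}
    rows = [
        FrequencyRow(display.get(pt, pt), n, percent(n, denominator, digits))
        for pt, n in ordered
    ]
    return FrequencyTable(rows, denominator)


def soc_frequency(
    events: Sequence[CohortEvent],
    pt_soc_map: PtSocMap,
    top_n: Optional[int] = 15,
    digits: int = 2,
) -> Tuple[FrequencyTable, int]:
    """System-Organ-Class frequencies among target-cohort events.

    Events whose PT is absent from the map are excluded from the denominator
    and returned as the unmapped count — which is why the SOC event total can
    be smaller than the PT event total.
    """
    target = [ev for ev in events if ev.is_target_drug]
    counts: Counter = Counter()
    unmapped = 0
    for ev in target:
        soc = pt_soc_map.lookup(ev.pt)
        if soc is None:
            unmapped += 1
        else:
            counts[soc] += 1
    denominator = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        ordered = ordered[:top_n]
    rows = _rows_from_counts(ordered, denominator, digits) if denominator else []
    return FrequencyTable(rows, denominator), unmapped


def annual_distribution(records: Sequence[DemoRecord]) -> Dict[int, int]:
    """Report counts per calendar year of FDA receipt.

    Years with zero reports inside the observed range are included with
    count 0 so plots have no silent gaps.
    """
    counts = Counter(rec.event_year for rec in records)
    if not counts:
        return {}
    lo, hi = min(counts), max(counts)
    return {year: counts.get(year, 0) for year in range(lo, hi + 1)}


def group_pt_counts(
    events: Sequence[CohortEvent],
    groups: Dict[str, Sequence[str]],
    digits: int = 2,
) -> FrequencyTable:
    """Event counts for named groups of Preferred Terms.

    Each group's count is the sum of its member PTs' event counts among
    target events; the percentage denominator is the total target event
    count.  Overlapping groups are allowed but logged.
    """
    target = [ev for ev in events if ev.is_target_drug]
    denominator = len(target)
    pt_counts = Counter(ev.pt for ev in target)

    normalized_groups = {
        name: [normalize_pt(pt) for pt in members] for name, members in groups.items()
    }
    seen: Dict[str, str] = {}
    for name, members in normalized_groups.items():
        for pt in members:
            if pt in seen and seen[pt] != name:
                logger.warning("PT %r appears in groups %r and %r", pt, seen[pt], name)
            seen[pt] = name

    rows = []
    for name, members in normalized_groups.items():
        n = sum(pt_counts.get(pt, 0) for pt in set(members))
        pct = percent(n, denominator, digits) if denominator else 0.0
        rows.append(FrequencyRow(name, n, pct))
    return FrequencyTable(rows, denominator)
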