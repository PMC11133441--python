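"""Case deduplication and primary-suspect cohort extraction.

FAERS stores every version of a safety report; versions of the same case share
``case_id``.  The FDA-recommended rule keeps, per case, the version with the
largest FDA receipt date, breaking ties by the largest ``primary_id``
(compared numerically when both identifiers are digit strings).

The cohort is the set of deduplicated reports carrying at least one drug row
that (a) names the target drug — case-insensitive substring match over the
verbatim drug name and the active-ingredient field, since FAERS names embed
doses and salts — and (b) has the requested role code (primary suspect by
default).  All other deduplicated reports form the background population for
the disproportionality contrast.

The counting unit downstream is the *event*: one distinct (report, PT) pair.
PTs are trimmed and case-folded for matching; the most frequent verbatim
casing is retained for display.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from faers_dispro.faers_io import DemoRecord, DrugRecord, ReactionRecord


def normalize_pt(pt: str) -> str:
    """Trim, collapse internal whitespace and case-fold a Preferred Term."""
    return " ".join(pt.split()).casefold()


@dataclass(slots=True)
class DedupResult:
    """Outcome of deduplication: kept records plus conservation counts."""

    kept: List[DemoRecord]
    removed_count: int
    input_count: int

    def kept_ids(self) -> Set[str]:
        return {rec.primary_id for rec in self.kept}


@dataclass(frozen=True, slots=True)
class CohortEvent:
    """One distinct (report, PT) pair; the unit of all downstream counting."""

    primary_id: str
    case_id: str
    pt: str  # normalised
    is_target_drug: bool


@dataclass(slots=True)
class CohortResult:
    """Target cohort membership and the full deduplicated event list."""

    cohort_ids: Set[str]
    events: List[CohortEvent]
    pt_display: Dict[str, str] = field(default_factory=dict)
    unlinked_reaction_count: int = 0

    @property
    def target_events(self) -> List[CohortEvent]:
        return [ev for ev in self.events if ev.is_target_drug]

    @property
    def background_events(self) -> List[CohortEvent]:
        return [ev for ev in self.events if not ev.is_target_drug]

    def display_pt(self, normalized_pt: str) -> str:
        return self.pt_display.get(normalized_pt, normalized_pt)


def _version_key_newer(a: DemoRecord, b: DemoRecord) -> bool:
    """True if record ``a`` wins over ``b`` under the FDA dedup rule."""
    if a.fda_dt != b.fda_dt:
        return a.fda_dt > b.fda_dt
    pa, pb = a.primary_id, b.primary_id
    if pa.isdigit() and pb.isdigit():
        return int(pa) > int(pb)
    return pa > pb


def deduplicate_demo(records: Sequence[DemoRecord]) -> DedupResult:
    """Keep one report version per case: largest fda_dt, then largest primary_id.

    The result is sorted by ``case_id`` so output is independent of input
    order.  Applying the rule twice is a no-op.
    """
    best: Dict[str, DemoRecord] = {}
    for rec in records:
        cur = best.get(rec.case_id)
        if cur is None or _version_key_newer(rec, cur):
            best[rec.case_id] = rec
    kept = [best[case_id] for case_id in sorted(best)]
    return DedupResult(kept=kept, removed_count=len(records) - len(kept), input_count=len(records))


def match_drug_name(record: DrugRecord, names: Sequence[str]) -> bool:
    """True iff any search string occurs case-insensitively in the drug name
    or the active-ingredient field."""
    if not names:
        raise ValueError("names must be non-empty")
    lowered = [n.casefold() for n in names]
    for field_value in (record.drug_name, record.active_ingredient):
        if field_value is None:
            continue
        hay = field_value.casefold()
        if any(n in hay for n in lowered):
            return True
    return False


def build_cohort(
    dedup: DedupResult,
    drugs: Sequence[DrugRecord],
    reactions: Sequence[ReactionRecord],
    names: Sequence[str],
    role: str = "PS",
) -> CohortResult:
    """Select the target-drug cohort and materialise the deduplicated event list.

    Parameters
    ----------
    dedup : DedupResult
        Deduplicated DEMO records.
    drugs, reactions : sequences
        DRUG and REAC rows, linked to reports by ``primary_id``.
    names : sequence of str
        Search strings for the target drug (substring, case-insensitive).
    role : str
        Drug role code the cohort requires (default ``"PS"``, primary suspect);
        matching mentions in other roles do not admit a report to the cohort.

    Returns
    -------
    CohortResult
        ``cohort_ids`` — kept reports with a matching drug row in ``role``;
        ``events`` — one :class:`CohortEvent` per distinct (primary_id, PT)
        pair over all kept reports, flagged by cohort membership.  Reaction
        rows referencing report versions dropped by deduplication (or absent
        from DEMO) are counted in ``unlinked_reaction_count`` and excluded.
    """
    kept_ids = dedup.kept_ids()
    case_of = {rec.primary_id: rec.case_id for rec in dedup.kept}

    cohort_ids: Set[str] = set()
    for drug in drugs:
        if drug.primary_id in kept_ids and drug.role_code == role and match_drug_name(drug, names):
            cohort_ids.add(drug.primary_id)

    seen: Set[Tuple[str, str]] = set()
    events: List[CohortEvent] = []
    casing: Counter = Counter()
    unlinked = 0
    for reac in reactions:
        if reac.primary_id not in kept_ids:
            unlinked += 1
            continue
        norm = normalize_pt(reac.pt)
        casing[(norm, " ".join(reac.pt.split()))] += 1
        key = (reac.primary_id, norm)
        if key in seen:
            continue
        seen.add(key)
        events.append(
            CohortEvent(
                primary_id=reac.primary_id,
                case_id=case_of[reac.primary_id],
                pt=norm,
                is_target_drug=reac.primary_id in cohort_ids,
            )
        )
    # Deterministic order regardless of input permutation
    events.sort(key=lambda ev: (ev.primary_id, ev.pt))

    display: Dict[str, str] = {}
    counts_per_norm: Dict[str, Tuple[int, str]] = {}
    for (norm, verbatim), n in sorted(casing.items()):
        best = counts_per_norm.get(norm)
        if best is None or n > best[0]:
            counts_per_norm[norm] = (n, verbatim)
    display = {norm: verbatim for norm, (_, verbatim) in counts_per_norm.items()}

    return CohortResult(
        cohort_ids=cohort_ids,
        events=events,
        pt_display=display,
        unlinked_reaction_count=unlinked,
    )


def write_dedup_summary(dedup: DedupResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("input\tkept\tremoved\n")
        fh.write(f"{dedup.input_count}\t{len(dedup.kept)}\t{dedup.removed_count}\n")


def write_event_list(result: CohortResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("primary_id\tcase_id\tpt\tis_target_drug\n")
        for ev in result.events:
            fh.write(
                f"{ev.primary_id}\t{ev.case_id}\t{result.display_pt(ev.pt)}\t"
                f"{int(ev.is_target_drug)}\n"
            )
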