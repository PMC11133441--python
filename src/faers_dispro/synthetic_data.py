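"""FAERS-like synthetic multi-table datasets with planted drug-event signals.

The generator emits the seven quarterly tables for ``n_cases`` independent
cases.  Each case:

* receives a primary-suspect (PS) drug — the target drug with probability
  ``target_drug_prob``, otherwise one of a small comparator vocabulary; a
  concomitant (C) drug row may be added, and occasionally a non-target case
  mentions the target drug in a secondary-suspect (SS) role, which a correct
  role filter must ignore;
* draws K ~ 1 + Poisson(events_per_case - 1) *distinct* Preferred Terms from
  a background multinomial over ``pt_vocabulary``; for target-drug cases the
  weights of the ``planted_signals`` PTs are multiplied by their rate ratio
  rho before renormalisation, so a planted pair reports at elevated relative
  rate;
* draws demographics (sex, age, weight, country, occupation) that are then
  masked at the high missingness rates typical of spontaneous reports;
* with probability ``duplicate_prob`` also emits an earlier version of the
  same case (smaller fda_dt, distinct primary_id, identical content), which
  exercises exactly the FDA deduplication rule and nothing more.

Randomness comes from one root seed spawned into fixed per-purpose streams
(case structure, demographics, reactions, outcomes, duplicates, auxiliary
tables), so extending one table never perturbs the others.  Identical
(config, seed) gives byte-identical output.

``expected_contingency`` returns the analytic expected 2x2 cells under this
sampling model (distinct-PT draws approximated by calibrated thinning: the
per-term inclusion probabilities sum to the number of draws), used to check estimator
consistency: the ROR of a planted PT converges to its rho-derived odds ratio
as the number of cases grows.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from faers_dispro import faers_io
from faers_dispro.faers_io import (
    DemoRecord,
    DrugRecord,
    IndiRecord,
    OutcomeRecord,
    ReactionRecord,
    RpsrRecord,
    TableKind,
    TherRecord,
)

TARGET_DRUG_NAMES = ("XPOVIO 80MG TABLET", "SELINEXOR")
TARGET_ACTIVE_INGREDIENT = "SELINEXOR"

COMPARATOR_DRUGS = (
    "BORTEZOMIB",
    "LENALIDOMIDE",
    "DEXAMETHASONE",
    "DARATUMUMAB",
    "POMALIDOMIDE",
    "CARFILZOMIB",
    "RITUXIMAB",
    "CYCLOPHOSPHAMIDE",
    "METHOTREXATE",
    "ASPIRIN",
)

# Background PT vocabulary: common oncology-cohort terms first (roughly
# Zipf-weighted below), padded with generic investigation/disorder terms.
DEFAULT_PT_VOCABULARY = (
    "Nausea",
    "Fatigue",
    "Decreased appetite",
    "Diarrhoea",
    "Vomiting",
    "Thrombocytopenia",
    "Death",
    "Lethargy",
    "Weight decreased",
    "Platelet count decreased",
    "Anaemia",
    "Constipation",
    "Dizziness",
    "Pneumonia",
    "Dehydration",
    "Asthenia",
    "Pyrexia",
    "Headache",
    "Dyspnoea",
    "Neutropenia",
    "Hyponatraemia",
    "Renal impairment",
    "Hypercreatinaemia",
    "Hypogeusia",
    "Confusional state",
    "Oedema peripheral",
    "Rash",
    "Cough",
    "Insomnia",
    "Pain",
    "Fall",
    "Malaise",
    "Blurred vision",
    "Dry eye",
    "Cataract",
    "Sepsis",
    "Hypotension",
    "Hypertension",
    "Arthralgia",
    "Back pain",
) + tuple(f"Investigation abnormal type {i:02d}" for i in range(1, 41))


def _default_missing_rates() -> Dict[str, float]:
    # Missingness pattern of spontaneous oncology reports: demographics are
    # mostly unreported, reporter fields mostly present.
    return {"sex": 0.697, "age": 0.98, "weight": 0.871, "country": 0.05, "occupation": 0.012}


def _default_outcome_weights() -> Dict[str, float]:
    # About 60% of reports carry a severe outcome; within those, the split
    # mirrors a hospitalisation-dominated oncology profile.
    return {
        "none": 0.40,
        "HO": 0.332,
        "DE": 0.173,
        "LT": 0.014,
        "DS": 0.005,
        "RI": 0.0003,
        "CA": 0.0002,
        "OT": 0.076,
    }


def _default_occupation_weights() -> Dict[str, float]:
    return {"CN": 0.629, "MD": 0.220, "HP": 0.120, "PH": 0.010, "OT": 0.008, "LW": 0.002}


def _default_country_weights() -> Dict[str, float]:
    return {
        "US": 0.748,
        "CN": 0.040,
        "CA": 0.031,
        "IL": 0.027,
        "AU": 0.026,
        "GB": 0.032,
        "FR": 0.032,
        "DE": 0.032,
        "JP": 0.032,
    }


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic FAERS-like generator.

    Defaults emulate a four-year oncology drug extract: ~21% duplicate report
    versions, about four distinct reaction terms per case, and the heavy
    demographic missingness of consumer-filed reports.
    """

    n_cases: int = 20_000
    target_drug_prob: float = 0.05
    pt_vocabulary: Sequence[str] = DEFAULT_PT_VOCABULARY
    pt_weights: Optional[Sequence[float]] = None  # default: Zipf 1/rank
    planted_signals: Sequence[Tuple[str, float]] = (
        ("Thrombocytopenia", 10.0),
        ("Hypercreatinaemia", 10.0),
    )
    events_per_case: float = 4.0
    duplicate_prob: float = 0.21
    outcome_weights: Dict[str, float] = field(default_factory=_default_outcome_weights)
    missing_rates: Dict[str, float] = field(default_factory=_default_missing_rates)
    occupation_weights: Dict[str, float] = field(default_factory=_default_occupation_weights)
    country_weights: Dict[str, float] = field(default_factory=_default_country_weights)
    concomitant_prob: float = 0.30
    target_ss_prob: float = 0.03  # target drug in SS role on non-target cases
    date_range: Tuple[int, int] = (20190701, 20230630)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 0:
            raise ValueError("n_cases must be nonnegative")
        for name in ("target_drug_prob", "duplicate_prob", "concomitant_prob", "target_ss_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {p}")
        if len(self.pt_vocabulary) == 0:
            raise ValueError("pt_vocabulary must be non-empty")
        if len(set(self.pt_vocabulary)) != len(self.pt_vocabulary):
            raise ValueError("pt_vocabulary contains duplicate terms")
        if self.pt_weights is not None:
            if len(self.pt_weights) != len(self.pt_vocabulary):
                raise ValueError("pt_weights length must match pt_vocabulary")
            if any(w < 0 for w in self.pt_weights) or sum(self.pt_weights) <= 0:
                raise ValueError("pt_weights must be nonnegative and not all zero")
        vocab = set(self.pt_vocabulary)
        for pt, rho in self.planted_signals:
            if pt not in vocab:
                raise ValueError(f"planted_signals PT {pt!r} not in pt_vocabulary")
            if rho <= 0:
                raise ValueError(f"planted_signals rate ratio must be > 0, got {rho}")
        if self.events_per_case < 1.0:
            raise ValueError("events_per_case must be >= 1 (each case has at least one PT)")
        for name in ("outcome_weights", "missing_rates", "occupation_weights", "country_weights"):
            weights = getattr(self, name)
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"{name} must be nonnegative")
            if name != "missing_rates" and sum(weights.values()) <= 0:
                raise ValueError(f"{name} must not be all zero")
        if any(not 0 <= p <= 1 for p in self.missing_rates.values()):
            raise ValueError("missing_rates must be probabilities in [0, 1]")
        start, end = self.date_range
        if _to_date(start) > _to_date(end):
            raise ValueError("date_range start must not exceed end")

    def background_weights(self) -> np.ndarray:
        if self.pt_weights is not None:
            w = np.asarray(self.pt_weights, dtype=float)
        else:
            w = 1.0 / np.arange(1, len(self.pt_vocabulary) + 1, dtype=float)
        return w / w.sum()

    def target_weights(self) -> np.ndarray:
        w = self.background_weights().copy()
        index = {pt: i for i, pt in enumerate(self.pt_vocabulary)}
        for pt, rho in self.planted_signals:
            w[index[pt]] *= rho
        return w / w.sum()


def _to_date(yyyymmdd: int) -> datetime.date:
    text = str(yyyymmdd)
    return datetime.date(int(text[:4]), int(text[4:6]), int(text[6:8]))


def _to_int_date(day: datetime.date) -> int:
    return day.year * 10000 + day.month * 100 + day.day


@dataclass
class SyntheticTables:
    """The seven generated tables, in memory, plus the generating config."""

    demo: List[DemoRecord]
    drug: List[DrugRecord]
    reac: List[ReactionRecord]
    outc: List[OutcomeRecord]
    indi: List[IndiRecord]
    ther: List[TherRecord]
    rpsr: List[RpsrRecord]
    config: SyntheticConfig

    def write(self, directory) -> None:
        """Write all seven tables plus a manifest to ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for kind, records in (
            (TableKind.DEMO, self.demo),
            (TableKind.DRUG, self.drug),
            (TableKind.REAC, self.reac),
            (TableKind.OUTC, self.outc),
            (TableKind.INDI, self.indi),
            (TableKind.THER, self.ther),
            (TableKind.RPSR, self.rpsr),
        ):
            faers_io.write_table(records, directory / f"{kind.value}.txt", kind)
        manifest = dataclasses.asdict(self.config)
        manifest["pt_vocabulary"] = list(manifest["pt_vocabulary"])
        manifest["planted_signals"] = [list(p) for p in manifest["planted_signals"]]
        if manifest["pt_weights"] is not None:
            manifest["pt_weights"] = list(manifest["pt_weights"])
        manifest["date_range"] = list(manifest["date_range"])
        with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _weighted_choice(rng: np.random.Generator, weights: Dict[str, float], size: int) -> np.ndarray:
    keys = sorted(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(np.array(keys, dtype=object), size=size, p=probs)


def generate(config: SyntheticConfig) -> SyntheticTables:
    """Generate the seven tables for ``config``; deterministic in config.seed."""
    config.validate()
    n = config.n_cases
    vocab = np.array(config.pt_vocabulary, dtype=object)
    n_vocab = len(vocab)

    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_cases = np.random.default_rng(streams[0])
    rng_demo = np.random.default_rng(streams[1])
    rng_reac = np.random.default_rng(streams[2])
    rng_outc = np.random.default_rng(streams[3])
    rng_dup = np.random.default_rng(streams[4])
    rng_misc = np.random.default_rng(streams[5])

    start_day = _to_date(config.date_range[0])
    span = (_to_date(config.date_range[1]) - start_day).days + 1

    if n == 0:
        return SyntheticTables([], [], [], [], [], [], [], config)

    is_target = rng_cases.random(n) < config.target_drug_prob
    k_counts = 1 + rng_cases.poisson(config.events_per_case - 1.0, size=n)
    k_counts = np.minimum(k_counts, n_vocab)
    day_offsets = rng_cases.integers(0, span, size=n)

    # Distinct-PT draws via Gumbel top-K over the per-case weight vector.
    log_bg = np.log(config.background_weights())
    log_tg = np.log(config.target_weights())
    log_w = np.where(is_target[:, None], log_tg[None, :], log_bg[None, :])
    keys = log_w + rng_reac.gumbel(size=(n, n_vocab))
    order = np.argsort(-keys, axis=1)

    sexes = np.where(rng_demo.random(n) < 0.557, "M", "F")
    ages = np.clip(rng_demo.normal(62.0, 12.0, size=n), 18.0, 90.0).round(0)
    weights_kg = np.clip(rng_demo.normal(78.0, 16.0, size=n), 40.0, 150.0).round(1)
    countries = _weighted_choice(rng_demo, config.country_weights, n)
    occupations = _weighted_choice(rng_demo, config.occupation_weights, n)
    miss = {
        fieldname: rng_demo.random(n) < config.missing_rates.get(fieldname, 0.0)
        for fieldname in ("sex", "age", "weight", "country", "occupation")
    }

    outcome_codes = _weighted_choice(rng_outc, config.outcome_weights, n)

    has_duplicate = rng_dup.random(n) < config.duplicate_prob
    dup_backdays = rng_dup.integers(1, 91, size=n)

    comparator_idx = rng_misc.integers(0, len(COMPARATOR_DRUGS), size=n)
    target_name_idx = rng_misc.integers(0, len(TARGET_DRUG_NAMES), size=n)
    has_concomitant = rng_misc.random(n) < config.concomitant_prob
    conc_idx = rng_misc.integers(0, len(COMPARATOR_DRUGS), size=n)
    has_target_ss = rng_misc.random(n) < config.target_ss_prob
    indications = rng_misc.choice(
        np.array(["Multiple myeloma", "Diffuse large B-cell lymphoma", "Plasma cell myeloma"], dtype=object),
        size=n,
    )
    rpsr_codes = rng_misc.choice(np.array(["FGN", "SDY", "CSM", "HP", "OTH"], dtype=object), size=n)

    demo: List[DemoRecord] = []
    drug: List[DrugRecord] = []
    reac: List[ReactionRecord] = []
    outc: List[OutcomeRecord] = []
    indi: List[IndiRecord] = []
    ther: List[TherRecord] = []
    rpsr: List[RpsrRecord] = []

    for i in range(n):
        case_id = str(10_000_000 + i)
        fda_day = start_day + datetime.timedelta(days=int(day_offsets[i]))
        versions = [(case_id + "2", _to_int_date(fda_day))]
        if has_duplicate[i]:
            earlier = fda_day - datetime.timedelta(days=int(dup_backdays[i]))
            versions.append((case_id + "1", _to_int_date(earlier)))

        pts = vocab[order[i, : k_counts[i]]]
        if is_target[i]:
            ps_name: Optional[str] = TARGET_DRUG_NAMES[target_name_idx[i]]
            ps_ai: Optional[str] = TARGET_ACTIVE_INGREDIENT
        else:
            ps_name = COMPARATOR_DRUGS[comparator_idx[i]]
            ps_ai = ps_name

        for primary_id, fda_dt in versions:
            demo.append(
                DemoRecord(
                    primary_id=primary_id,
                    case_id=case_id,
                    fda_dt=fda_dt,
                    sex=None if miss["sex"][i] else str(sexes[i]),
                    age_years=None if miss["age"][i] else float(ages[i]),
                    weight_kg=None if miss["weight"][i] else float(weights_kg[i]),
                    reporter_occupation=None if miss["occupation"][i] else str(occupations[i]),
                    reporter_country=None if miss["country"][i] else str(countries[i]),
                )
            )
            seq = 1
            drug.append(
                DrugRecord(
                    primary_id=primary_id,
                    drug_seq=seq,
                    role_code="PS",
                    drug_name=ps_name,
                    active_ingredient=ps_ai,
                )
            )
            if not is_target[i] and has_target_ss[i]:
                seq += 1
                drug.append(
                    DrugRecord(
                        primary_id=primary_id,
                        drug_seq=seq,
                        role_code="SS",
                        drug_name=TARGET_DRUG_NAMES[0],
                        active_ingredient=TARGET_ACTIVE_INGREDIENT,
                    )
                )
            if has_concomitant[i]:
                seq += 1
                drug.append(
                    DrugRecord(
                        primary_id=primary_id,
                        drug_seq=seq,
                        role_code="C",
                        drug_name=COMPARATOR_DRUGS[conc_idx[i]],
                        active_ingredient=COMPARATOR_DRUGS[conc_idx[i]],
                    )
                )
            for pt in pts:
                reac.append(ReactionRecord(primary_id=primary_id, pt=str(pt)))
            if outcome_codes[i] != "none":
                outc.append(OutcomeRecord(primary_id=primary_id, outcome_code=str(outcome_codes[i])))
            indi.append(
                IndiRecord(primary_id=primary_id, drug_seq=1, indication_pt=str(indications[i]))
            )
            ther.append(
                TherRecord(
                    primary_id=primary_id,
                    drug_seq=1,
                    start_dt=_to_int_date(fda_day - datetime.timedelta(days=30)),
                )
            )
            rpsr.append(RpsrRecord(primary_id=primary_id, source_code=str(rpsr_codes[i])))

    return SyntheticTables(demo, drug, reac, outc, indi, ther, rpsr, config)


def _poisson_pmf(lam: float, k: np.ndarray) -> np.ndarray:
    from math import lgamma

    log_pmf = -lam + k * math.log(lam) - np.array([lgamma(x + 1) for x in k])
    return np.exp(log_pmf)


def _inclusion_given_k(w: np.ndarray, k: int) -> np.ndarray:
    """P(PT j among k distinct weighted draws without replacement).

    Calibrated-thinning approximation to successive sampling: pi_j =
    1 - exp(-t w_j) with the rate t chosen so the inclusion probabilities sum
    to exactly k (Hajek's approximation).  Exact at k = len(w); solved by
    bisection.
    """
    n = len(w)
    if k >= n:
        return np.ones(n)
    lo, hi = float(k), float(k)
    while (1.0 - np.exp(-hi * w)).sum() < k:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if (1.0 - np.exp(-mid * w)).sum() < k:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    return 1.0 - np.exp(-t * w)


def _inclusion_probability(w: np.ndarray, events_per_case: float, n_vocab: int) -> np.ndarray:
    """P(PT among a case's distinct terms), K ~ 1 + Poisson(events_per_case - 1).

    Mixes the per-K inclusion probabilities over the (vocabulary-clipped) K
    distribution.
    """
    lam = events_per_case - 1.0
    max_k = n_vocab
    if lam == 0.0:
        return _inclusion_given_k(w, 1)
    ks = np.arange(0, max_k)  # K = 1 + ks, before clipping
    pmf = _poisson_pmf(lam, ks)
    pmf[-1] += max(0.0, 1.0 - pmf.sum())  # clip tail mass at K = n_vocab
    result = np.zeros_like(w)
    for weight, k in zip(pmf, ks + 1):
        if weight < 1e-12:
            continue
        result += weight * _inclusion_given_k(w, int(k))
    return result


def expected_contingency(config: SyntheticConfig, pt: str) -> Tuple[float, float, float, float]:
    """Analytic expected (a, b, c, d) cells for ``pt`` under the generator.

    Expectations are per deduplicated case (duplicates are removed before
    counting, so ``duplicate_prob`` does not enter).
    """
    config.validate()
    if pt not in set(config.pt_vocabulary):
        raise ValueError(f"PT {pt!r} not in the generator vocabulary")
    index = {p: i for i, p in enumerate(config.pt_vocabulary)}
    i = index[pt]

    p_t = config.target_drug_prob
    n_target = config.n_cases * p_t
    n_background = config.n_cases * (1.0 - p_t)

    n_vocab = len(config.pt_vocabulary)
    incl_target = _inclusion_probability(config.target_weights(), config.events_per_case, n_vocab)
    incl_background = _inclusion_probability(
        config.background_weights(), config.events_per_case, n_vocab
    )

    a = n_target * incl_target[i]
    b = n_target * (incl_target.sum() - incl_target[i])
    c = n_background * incl_background[i]
    d = n_background * (incl_background.sum() - incl_background[i])
    return (float(a), float(b), float(c), float(d))


def expected_ror(config: SyntheticConfig, pt: str) -> float:
    """Odds ratio implied by the expected cells (the estimand of the ROR)."""
    a, b, c, d = expected_contingency(config, pt)
    if min(a, b, c, d) <= 0:
        return math.nan
    return (a * d) / (b * c)
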