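"""Case assembly, deduplication, cohort selection and baseline summaries.

A spontaneous-report database contains multiple versions of the same case
(follow-up reports share a CASEID but get a new PRIMARYID).  The regulatory
deduplication rule keeps, per case, the version with the latest FDA receipt
date, breaking ties by the numerically highest PRIMARYID.  After dedup, the
study cohort is every case listing the study drug as a primary-suspect (PS)
drug; all remaining cases form the comparator ("rest of database") used for
disproportionality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .faers_io import (
    DemoRecord, DrugRecord, IndicationRecord, OutcomeRecord,
    ReactionRecord, TherapyRecord,
)

log = logging.getLogger(__name__)


def normalize_drug_name(name: str) -> str:
    """Uppercase, trim, collapse internal whitespace (exact matching only)."""
    return " ".join(name.split()).upper()


def round_half_up(x: int | float | Decimal, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, ndigits: int = 1) -> float:
    """count/total as a percentage, rounded half-up (exact rational division)."""
    if total == 0:
        return 0.0
    q = Decimal(1).scaleb(-ndigits)
    return float((Decimal(count * 100) / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CaseReport:
    """One deduplicated safety report with all child records attached."""

    demo: DemoRecord
    drugs: list[DrugRecord] = field(default_factory=list)
    reactions: list[ReactionRecord] = field(default_factory=list)
    outcomes: list[OutcomeRecord] = field(default_factory=list)
    indications: list[IndicationRecord] = field(default_factory=list)
    therapies: list[TherapyRecord] = field(default_factory=list)

    @property
    def primaryid(self) -> str:
        return self.demo.primaryid

    def pts(self) -> set[str]:
        return {r.pt for r in self.reactions}


@dataclass(frozen=True)
class DrugDictionary:
    """Name patterns identifying the study drug (and optional exclusions).

    Matching is exact after normalization — no fuzzy matching, so results
    are reproducible from the dictionary file alone.
    """

    target_names: frozenset
    exclusion_names: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "target_names",
                           frozenset(normalize_drug_name(n) for n in self.target_names if n.strip()))
        object.__setattr__(self, "exclusion_names",
                           frozenset(normalize_drug_name(n) for n in self.exclusion_names if n.strip()))
        if not self.target_names:
            raise ValueError("drug dictionary needs at least one target name")

    def is_target(self, drugname: str) -> bool:
        return normalize_drug_name(drugname) in self.target_names

    @classmethod
    def from_files(cls, target_path, exclusion_path=None) -> "DrugDictionary":
        targets = Path(target_path).read_text().splitlines()
        exclusions = Path(exclusion_path).read_text().splitlines() if exclusion_path else ()
        return cls(frozenset(targets), frozenset(exclusions))


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(demos: Sequence[DemoRecord]) -> list[DemoRecord]:
    """Keep one version per caseid: latest fda_dt, ties by highest primaryid.

    If any version of a case has an unparseable fda_dt the whole case falls
    back to primaryid-only comparison (logged).  Idempotent; output order
    follows first appearance of each caseid.
    """
    groups: dict[str, list[DemoRecord]] = {}
    order: list[str] = []
    for r in demos:
        if r.caseid not in groups:
            order.append(r.caseid)
        groups.setdefault(r.caseid, []).append(r)

    kept = []
    for caseid in order:
        versions = groups[caseid]
        if len(versions) == 1:
            kept.append(versions[0])
            continue
        if any(not v.fda_dt.is_valid for v in versions):
            log.warning("caseid %s has an unparseable fda_dt; comparing by primaryid only", caseid)
            kept.append(max(versions, key=lambda v: int(v.primaryid)))
        else:
            kept.append(max(versions, key=lambda v: (v.fda_dt.sort_key(), int(v.primaryid))))
    return kept


def assemble_cases(
    demos: Sequence[DemoRecord],
    drugs: Iterable[DrugRecord] = (),
    reactions: Iterable[ReactionRecord] = (),
    outcomes: Iterable[OutcomeRecord] = (),
    indications: Iterable[IndicationRecord] = (),
    therapies: Iterable[TherapyRecord] = (),
) -> list[CaseReport]:
    """Join child tables onto demo records by primaryid (demo order kept).

    Therapy start dates are copied onto the matching DrugRecord (same
    primaryid and drug_seq; earliest start wins if several episodes exist).
    Child rows whose primaryid has no demo record (e.g. versions removed by
    dedup) are dropped.
    """
    cases = {d.primaryid: CaseReport(d) for d in demos}
    for r in drugs:
        c = cases.get(r.primaryid)
        if c is not None:
            c.drugs.append(r)
    for r in reactions:
        c = cases.get(r.primaryid)
        if c is not None:
            c.reactions.append(r)
    for r in outcomes:
        c = cases.get(r.primaryid)
        if c is not None:
            c.outcomes.append(r)
    for r in indications:
        c = cases.get(r.primaryid)
        if c is not None:
            c.indications.append(r)
    for r in therapies:
        c = cases.get(r.primaryid)
        if c is not None:
            c.therapies.append(r)

    for c in cases.values():
        starts: dict[int, list] = {}
        for t in c.therapies:
            if t.start_dt.is_valid:
                starts.setdefault(t.drug_seq, []).append(t.start_dt)
        for d in c.drugs:
            cand = starts.get(d.drug_seq)
            if cand:
                d.start_dt = min(cand, key=lambda p: p.sort_key())
    return [cases[d.primaryid] for d in demos]


def select_primary_suspect(
    cases: Sequence[CaseReport], dictionary: DrugDictionary
) -> tuple[list[CaseReport], list[CaseReport]]:
    """Split deduplicated cases into (cohort, comparator).

    A case joins the cohort iff at least one of its drugs has role PS and a
    name matching the dictionary; every other case is the comparator.
    """
    cohort, comparator = [], []
    for c in cases:
        hit = any(d.role == "PS" and dictionary.is_target(d.drugname) for d in c.drugs)
        (cohort if hit else comparator).append(c)
    return cohort, comparator


# ---------------------------------------------------------------------------
# baseline summary (Table-1 style)

#: default bins print as <18 / 18-65 / 65-85 with 65 assigned to 18-65
def age_group_table1(age_years: float | None) -> str:
    if age_years is None:
        return "Unknown"
    if age_years < 18:
        return "<18"
    if age_years <= 65:
        return "18-65"
    if age_years <= 85:
        return "65-85"
    return ">85"


def age_group_coarse(age_years: float | None) -> str:
    """<18 / 18-65 / >65, the convention used for subgroup analyses."""
    if age_years is None:
        return "Unknown"
    if age_years < 18:
        return "<18"
    if age_years <= 65:
        return "18-65"
    return ">65"


REPORTER_LABELS = {
    "CN": "Consumer", "MD": "Physician", "HP": "Health Professional",
    "PH": "Pharmacist", "OT": "Other", "UNK": "Unknown",
}
OUTCOME_LABELS = {
    "HO": "Hospitalization", "DE": "Death", "LT": "Life-Threatening",
    "DS": "Disability", "CA": "Congenital Anomaly",
    "RI": "Required Intervention", "OT": "Other",
}

DIMENSIONS = ("sex", "age_group", "indication", "outcome", "country", "reporter", "year")


@dataclass
class BaselineSummary:
    total: int
    strata: dict  # (dimension, level) -> count

    def count(self, dimension: str, level: str) -> int:
        return self.strata.get((dimension, level), 0)

    def pct(self, dimension: str, level: str) -> float:
        return percent(self.count(dimension, level), self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"dimension": dim, "level": level, "count": n,
             "percent": percent(n, self.total)}
            for (dim, level), n in self.strata.items()
        ]
        return pd.DataFrame(rows, columns=["dimension", "level", "count", "percent"])


def summarize_baseline(
    cases: Sequence[CaseReport], age_group=age_group_table1
) -> BaselineSummary:
    """Tabulate baseline characteristics of a deduplicated, filtered cohort.

    Counts are per case: sex, age group (after unit normalization to years),
    indication of the PS drug(s), outcome codes (once per case per code),
    reporting country, reporter type and receipt year.  Input order never
    affects the counts.
    """
    strata: dict[tuple[str, str], int] = {}

    def bump(dim: str, level: str) -> None:
        strata[(dim, level)] = strata.get((dim, level), 0) + 1

    for c in cases:
        demo = c.demo
        bump("sex", {"M": "Male", "F": "Female"}.get(demo.sex, "Unknown"))
        bump("age_group", age_group(demo.age_years))
        ps_seqs = {d.drug_seq for d in c.drugs if d.role == "PS"}
        indis = {i.indication_pt for i in c.indications if i.drug_seq in ps_seqs and i.indication_pt}
        if indis:
            for term in indis:
                bump("indication", term)
        else:
            bump("indication", "Unknown")
        for code in {o.outcome_code for o in c.outcomes}:
            bump("outcome", OUTCOME_LABELS.get(code, code))
        bump("country", demo.country if demo.country else "Unknown")
        bump("reporter", REPORTER_LABELS.get(demo.reporter, "Unknown"))
        bump("year", str(demo.event_year) if demo.event_year else "Unknown")

    ordered = dict(sorted(strata.items(), key=lambda kv: (DIMENSIONS.index(kv[0][0]), -kv[1], kv[0][1])))
    return BaselineSummary(total=len(cases), strata=ordered)
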