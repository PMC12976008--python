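"""Synthetic spontaneous-reporting databases with known ground truth.

Real pharmacovigilance extracts cannot ship with a package, and their
"truth" (which drug–event pairs are genuinely over-reported) is unknowable.
This generator emits a complete FAERS-dialect file set (DEMO/DRUG/REAC/
THER/INDI/OUTC) plus a :class:`TruthManifest` recording every planted fact,
so each pipeline stage can be checked against a known answer:

* demographics drawn from marginals shaped like a published baseline table
  (sex ≈ 29/33/38% M/F/unknown, mostly-missing ages, US-dominated
  countries, consumer-heavy reporters, a 2019–2025 reporting-year ramp);
* one primary-suspect drug per case plus optional concomitants, with event
  terms assigned independently at heavy-tailed (power-law) background
  rates, except for *planted signals* whose reporting rate is multiplied
  by a chosen relative rate (optionally within one sex only);
* therapy-start and event-onset dates whose difference follows a Weibull
  law (defaults α = 198.63 days, β = 0.63 — an early-failure pattern);
* a fraction of cases emitted in several versions (same CASEID, perturbed
  FDA date / PRIMARYID) to exercise the deduplication rule.

All randomness flows from one ``numpy`` generator seeded by the config, so
a fixed seed reproduces the files byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CaseReport
from .contingency import SocMap
from .faers_io import (
    DemoRecord, DrugRecord, IndicationRecord, OutcomeRecord, PartialDate,
    ReactionRecord, TherapyRecord, normalize_term, parse_partial_date,
    write_table,
)

#: reporting-year marginal (2019–2025 ramp after a 2022 approval expansion)
DEFAULT_YEAR_PROBS = {
    2019: 0.058, 2020: 0.044, 2021: 0.043, 2022: 0.043,
    2023: 0.154, 2024: 0.492, 2025: 0.166,
}
DEFAULT_SEX_PROBS = {"M": 0.292, "F": 0.328, "UNK": 0.380}
DEFAULT_AGE_GROUP_PROBS = {"<18": 0.019, "18-65": 0.112, "65-85": 0.090, None: 0.779}
DEFAULT_COUNTRY_PROBS = {"US": 0.852, "JP": 0.053, "GB": 0.017, "DE": 0.014,
                         "CA": 0.010, "OTHER": 0.054}
DEFAULT_REPORTER_PROBS = {"CN": 0.522, "MD": 0.207, "HP": 0.048, "PH": 0.031, "UNK": 0.192}
DEFAULT_INDICATION_PROBS = {
    "myasthenia gravis": 0.369,
    "paroxysmal nocturnal haemoglobinuria": 0.215,
    "atypical haemolytic uraemic syndrome": 0.106,
    "product used for unknown indication": 0.310,
}
DEFAULT_OUTCOME_PROBS = {"HO": 0.140, "DE": 0.050, "LT": 0.007, "DS": 0.002, None: 0.801}


@dataclass(frozen=True)
class PlantedSignal:
    """One drug–event association with a known relative reporting rate."""

    drug: str
    pt: str
    rr: float
    sex: str | None = None  # restrict the excess reporting to one sex


def default_drug_vocab(n_drugs: int = 20) -> list[str]:
    return [f"DRUG_{i:02d}" for i in range(n_drugs)]


def default_pt_vocab(n_pts: int = 40) -> list[str]:
    return [f"event_{i:02d}" for i in range(n_pts)]


def default_soc_map(pt_vocab: Sequence[str], n_socs: int = 8) -> SocMap:
    return SocMap({pt: f"soc_{i % n_socs}" for i, pt in enumerate(pt_vocab)})


def powerlaw_rates(n_pts: int, mean_events: float = 2.0, exponent: float = 0.8) -> np.ndarray:
    """Heavy-tailed per-term baseline rates, scaled to ``mean_events`` per case."""
    w = (np.arange(1, n_pts + 1, dtype=float)) ** (-exponent)
    return mean_events * w / w.sum()


@dataclass
class SimConfig:
    n_cases: int = 5000
    seed: int = 0
    drug_vocab: list[str] = field(default_factory=default_drug_vocab)
    pt_vocab: list[str] = field(default_factory=default_pt_vocab)
    soc_map: SocMap | None = None
    study_drug: str = "DRUG_00"
    study_drug_share: float = 0.05
    base_rates: np.ndarray | None = None
    rate_overrides: dict = field(default_factory=dict)  # pt -> baseline rate
    planted_signals: tuple[PlantedSignal, ...] = ()
    duplicate_rate: float = 0.10
    tto_scale: float = 198.63
    tto_shape: float = 0.63
    missing_date_rate: float = 0.30
    comed_rate: float = 0.30
    comed_vocab: list[str] | None = None
    year_probs: dict = field(default_factory=lambda: dict(DEFAULT_YEAR_PROBS))
    sex_probs: dict = field(default_factory=lambda: dict(DEFAULT_SEX_PROBS))
    age_group_probs: dict = field(default_factory=lambda: dict(DEFAULT_AGE_GROUP_PROBS))
    country_probs: dict = field(default_factory=lambda: dict(DEFAULT_COUNTRY_PROBS))
    reporter_probs: dict = field(default_factory=lambda: dict(DEFAULT_REPORTER_PROBS))
    indication_probs: dict = field(default_factory=lambda: dict(DEFAULT_INDICATION_PROBS))
    outcome_probs: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PROBS))

    def __post_init__(self):
        self.pt_vocab = [normalize_term(p) for p in self.pt_vocab]
        if self.soc_map is None:
            self.soc_map = default_soc_map(self.pt_vocab)
        if self.base_rates is None:
            self.base_rates = powerlaw_rates(len(self.pt_vocab))
        self.base_rates = np.asarray(self.base_rates, dtype=float).copy()
        if len(self.base_rates) != len(self.pt_vocab):
            raise ValueError("base_rates length must match pt_vocab")
        for pt, rate in self.rate_overrides.items():
            self.base_rates[self._pt_index(pt)] = rate
        if self.study_drug not in self.drug_vocab:
            raise ValueError(f"study drug {self.study_drug!r} not in drug vocabulary")
        for s in self.planted_signals:
            if s.drug not in self.drug_vocab:
                raise ValueError(f"planted drug {s.drug!r} not in vocabulary")
            self._pt_index(s.pt)
            if s.rr < 0:
                raise ValueError("relative rate must be nonnegative")
        if not (0 <= self.duplicate_rate < 1 and 0 <= self.missing_date_rate <= 1):
            raise ValueError("rates must be probabilities")
        missing = self.soc_map.missing_terms(self.pt_vocab)
        if missing:
            raise ValueError(f"soc_map does not cover PTs: {missing}")

    def _pt_index(self, pt: str) -> int:
        try:
            return self.pt_vocab.index(normalize_term(pt))
        except ValueError:
            raise ValueError(f"pt {pt!r} not in vocabulary") from None


@dataclass
class TruthManifest:
    """Ground truth of one simulated database."""

    cases: pd.DataFrame           # one row per underlying case
    versions: pd.DataFrame        # one row per emitted DEMO version
    planted: list[dict]           # drug, pt, rr, sex, true_a
    expected_dedup_count: int
    expected_cohort_count: int

    def write(self, outdir: Path) -> None:
        outdir = Path(outdir)
        self.cases.to_csv(outdir / "manifest_cases.csv", index=False)
        self.versions.to_csv(outdir / "manifest_versions.csv", index=False)
        (outdir / "manifest.json").write_text(json.dumps({
            "planted": self.planted,
            "expected_dedup_count": self.expected_dedup_count,
            "expected_cohort_count": self.expected_cohort_count,
        }, indent=2))


@dataclass
class SimResult:
    config: SimConfig
    demos: list[DemoRecord]
    drugs: list[DrugRecord]
    reactions: list[ReactionRecord]
    therapies: list[TherapyRecord]
    indications: list[IndicationRecord]
    outcomes: list[OutcomeRecord]
    manifest: TruthManifest

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_table(self.demos, outdir / "DEMO.txt", "DEMO")
        write_table(self.drugs, outdir / "DRUG.txt", "DRUG")
        write_table(self.reactions, outdir / "REAC.txt", "REAC")
        write_table(self.therapies, outdir / "THER.txt", "THER")
        write_table(self.indications, outdir / "INDI.txt", "INDI")
        write_table(self.outcomes, outdir / "OUTC.txt", "OUTC")
        self.config.soc_map.to_tsv(outdir / "soc_map.tsv")
        (outdir / "drug_dictionary.txt").write_text(self.config.study_drug + "\n")
        self.manifest.write(outdir)
        return outdir


def _choice(rng: np.random.Generator, probs: dict, size: int) -> np.ndarray:
    keys = list(probs)
    p = np.asarray([probs[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray([keys[i] for i in idx], dtype=object)


def _age_from_group(rng: np.random.Generator, group) -> float | None:
    if group is None:
        return None
    lo, hi = {"<18": (1, 17), "18-65": (18, 65), "65-85": (66, 85), ">85": (86, 99)}[group]
    return float(rng.integers(lo, hi + 1))


def generate(config: SimConfig) -> SimResult:
    """Generate one database; see the module docstring for the model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_pts = len(config.pt_vocab)

    caseids = np.arange(100_000_000, 100_000_000 + n)
    ps_drug = np.where(
        rng.random(n) < config.study_drug_share,
        config.study_drug,
        rng.choice([d for d in config.drug_vocab if d != config.study_drug], size=n),
    )
    sex = _choice(rng, config.sex_probs, n)
    age_groups = _choice(rng, config.age_group_probs, n)
    ages = np.asarray([_age_from_group(rng, g) for g in age_groups], dtype=object)
    country = _choice(rng, config.country_probs, n)
    reporter = _choice(rng, config.reporter_probs, n)
    years = _choice(rng, config.year_probs, n).astype(int)
    indication = _choice(rng, config.indication_probs, n)
    outcome = _choice(rng, config.outcome_probs, n)

    # --- event assignment: independent Bernoulli at base rates, boosted for
    # planted pairs (clipped at 1)
    prob = np.tile(config.base_rates, (n, 1))
    for s in config.planted_signals:
        rows = ps_drug == s.drug
        if s.sex is not None:
            rows = rows & (sex == s.sex)
        prob[rows, config._pt_index(s.pt)] *= s.rr
    np.clip(prob, 0.0, 1.0, out=prob)
    events = rng.random((n, n_pts)) < prob
    empty = ~events.any(axis=1)
    if empty.any():
        # every report must carry at least one reaction; backfill from the
        # baseline term distribution
        fill = rng.choice(n_pts, size=int(empty.sum()),
                          p=config.base_rates / config.base_rates.sum())
        events[np.nonzero(empty)[0], fill] = True

    # --- dates: receipt date within the reporting year; onset precedes
    # receipt by a short reporting lag; therapy start = onset − TTO
    year_start = np.asarray([date(int(y), 1, 1).toordinal() for y in years])
    fda_ord = year_start + rng.integers(0, 365, size=n)
    lag = rng.integers(0, 60, size=n)
    tto = np.maximum(1, np.round(config.tto_scale * rng.weibull(config.tto_shape, size=n))).astype(int)
    event_ord = fda_ord - lag
    start_ord = event_ord - tto
    start_partial = rng.random(n) < config.missing_date_rate

    # --- duplicate versions (same caseid, perturbed fda_dt, higher version
    # number in the primaryid)
    n_dup = int(round(config.duplicate_rate * n))
    dup_idx = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], dtype=int)
    extra_versions = {int(i): int(k) for i, k in zip(dup_idx, rng.integers(2, 5, size=n_dup))}
    fda_offsets = {int(i): rng.integers(-45, 46, size=extra_versions[int(i)] - 1)
                   for i in dup_idx}

    comed_vocab = config.comed_vocab or [d for d in config.drug_vocab if d != config.study_drug]
    n_comed = rng.binomial(2, config.comed_rate, size=n)
    comed_names = [list(rng.choice(comed_vocab, size=k, replace=False)) if k else []
                   for k in n_comed]

    demos: list[DemoRecord] = []
    drugs: list[DrugRecord] = []
    reactions: list[ReactionRecord] = []
    therapies: list[TherapyRecord] = []
    indications: list[IndicationRecord] = []
    outcomes: list[OutcomeRecord] = []
    version_rows = []
    case_rows = []

    event_lists = [np.nonzero(events[i])[0] for i in range(n)]

    for i in range(n):
        caseid = str(caseids[i])
        k = extra_versions.get(i, 1)
        fda_ords = [int(fda_ord[i])]
        if k > 1:
            fda_ords += [int(fda_ord[i] + off) for off in fda_offsets[i]]
        primaryids = [f"{caseid}{v:02d}" for v in range(1, k + 1)]
        survivor = max(range(k), key=lambda v: (fda_ords[v], int(primaryids[v])))

        event_d = date.fromordinal(int(event_ord[i]))
        start_d = date.fromordinal(int(start_ord[i]))
        if start_partial[i]:
            start_pd = parse_partial_date(f"{start_d.year:04d}{start_d.month:02d}")
        else:
            start_pd = PartialDate.from_date(start_d)

        for v in range(k):
            pid = primaryids[v]
            fda_pd = PartialDate.from_date(date.fromordinal(fda_ords[v]))
            demos.append(DemoRecord(
                primaryid=pid, caseid=caseid, fda_dt=fda_pd,
                event_dt=PartialDate.from_date(event_d),
                sex=str(sex[i]),
                age_value=ages[i], age_unit="YR" if ages[i] is not None else "UNK",
                reporter=str(reporter[i]), country=str(country[i]),
            ))
            version_rows.append({"caseid": caseid, "primaryid": pid,
                                 "fda_dt": fda_pd.raw,
                                 "is_survivor": v == survivor})
            drugs.append(DrugRecord(primaryid=pid, drug_seq=1, role="PS",
                                    drugname=str(ps_drug[i])))
            for j, name in enumerate(comed_names[i], start=2):
                drugs.append(DrugRecord(primaryid=pid, drug_seq=j, role="C",
                                        drugname=str(name)))
            for j in event_lists[i]:
                reactions.append(ReactionRecord(primaryid=pid, pt=config.pt_vocab[j]))
            therapies.append(TherapyRecord(primaryid=pid, drug_seq=1,
                                           start_dt=start_pd))
            indications.append(IndicationRecord(primaryid=pid, drug_seq=1,
                                                indication_pt=str(indication[i])))
            if outcome[i] is not None:
                outcomes.append(OutcomeRecord(primaryid=pid, outcome_code=str(outcome[i])))

        case_rows.append({
            "caseid": caseid,
            "survivor_primaryid": primaryids[survivor],
            "n_versions": k,
            "drug": str(ps_drug[i]),
            "is_study": bool(ps_drug[i] == config.study_drug),
            "sex": str(sex[i]),
            "year": int(years[i]),
            "n_events": int(len(event_lists[i])),
            "events": ";".join(config.pt_vocab[j] for j in event_lists[i]),
            "comeds": ";".join(comed_names[i]),
            "tto_days": int(tto[i]),
            "tto_eligible": bool(not start_partial[i]),
        })

    planted = []
    for s in config.planted_signals:
        rows = ps_drug == s.drug
        if s.sex is not None:
            rows = rows & (sex == s.sex)
        true_a = int(events[ps_drug == s.drug, config._pt_index(s.pt)].sum())
        planted.append({"drug": s.drug, "pt": normalize_term(s.pt), "rr": s.rr,
                        "sex": s.sex, "true_a": true_a,
                        "n_exposed": int(rows.sum())})

    manifest = TruthManifest(
        cases=pd.DataFrame(case_rows),
        versions=pd.DataFrame(version_rows),
        planted=planted,
        expected_dedup_count=n,
        expected_cohort_count=int((ps_drug == config.study_drug).sum()),
    )
    return SimResult(config, demos, drugs, reactions, therapies, indications,
                     outcomes, manifest)


# ---------------------------------------------------------------------------
# deterministic fixture reproducing a published baseline table's marginals


TABLE1_TOTAL = 9090
TABLE1_COUNTS = {
    "sex": {"M": 2655, "F": 2983, "UNK": 3452},
    "age": {"<18": 172, "18-65": 1014, "65-85": 820, None: 7084},
    "indication": {"myasthenia gravis": 3351,
                   "paroxysmal nocturnal haemoglobinuria": 1951,
                   "atypical haemolytic uraemic syndrome": 965,
                   None: 2823},
    "outcome": {"HO": 1271, "DE": 454, "LT": 60, "DS": 14, None: 7291},
    "country": {"US": 7744, "JP": 478, "GB": 151, "DE": 125, "CA": 87, "OTHER": 505},
    "reporter": {"CN": 4748, "MD": 1884, "HP": 432, "PH": 282, "UNK": 1744},
    "year": {2019: 525, 2020: 401, 2021: 388, 2022: 395, 2023: 1403,
             2024: 4476, 2025: 1502},
}
_AGE_REPRESENTATIVE = {"<18": 10.0, "18-65": 45.0, "65-85": 72.0}


def _expand(counts: dict) -> list:
    out = []
    for level, k in counts.items():
        out.extend([level] * k)
    return out


def table1_fixture(study_drug: str = "RAVULIZUMAB") -> list[CaseReport]:
    """9,090 deterministic cases whose marginals equal the published
    baseline table (sex, age bins, top indications, outcomes, countries,
    reporter types, reporting years); the joint structure is arbitrary
    (each dimension filled sequentially and independently).
    """
    for dim, counts in TABLE1_COUNTS.items():
        assert sum(counts.values()) == TABLE1_TOTAL, dim
    sex = _expand(TABLE1_COUNTS["sex"])
    age = _expand(TABLE1_COUNTS["age"])
    indication = _expand(TABLE1_COUNTS["indication"])
    outcome = _expand(TABLE1_COUNTS["outcome"])
    country = _expand(TABLE1_COUNTS["country"])
    reporter = _expand(TABLE1_COUNTS["reporter"])
    year = _expand(TABLE1_COUNTS["year"])

    cases = []
    for i in range(TABLE1_TOTAL):
        pid = str(500_000_000 + i)
        age_years = _AGE_REPRESENTATIVE.get(age[i])
        demo = DemoRecord(
            primaryid=pid, caseid=pid,
            fda_dt=parse_partial_date(f"{year[i]:04d}0702"),
            sex=sex[i],
            age_value=age_years, age_unit="YR" if age_years is not None else "UNK",
            reporter=reporter[i], country=country[i],
        )
        case = CaseReport(demo)
        case.drugs.append(DrugRecord(primaryid=pid, drug_seq=1, role="PS",
                                     drugname=study_drug))
        case.reactions.append(ReactionRecord(primaryid=pid, pt="fatigue"))
        if indication[i] is not None:
            case.indications.append(IndicationRecord(primaryid=pid, drug_seq=1,
                                                     indication_pt=indication[i]))
        if outcome[i] is not None:
            case.outcomes.append(OutcomeRecord(primaryid=pid, outcome_code=outcome[i]))
        cases.append(case)
    return cases
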