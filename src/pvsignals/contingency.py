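"""2×2 contingency tables for drug–event pairs, at PT and SOC level.

The counting unit is the unique (report, event term) pair: a report
mentioning the same preferred term twice contributes once, and at SOC level
a report contributes once per distinct organ class.  This makes the grand
total N well defined and the margins additive, which is what the
disproportionality statistics assume.  A per-report counting unit is also
available (``count_unit="reports"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import CaseReport, normalize_drug_name
from .faers_io import normalize_term

PT_LEVEL = "PT"
SOC_LEVEL = "SOC"


class SocMap:
    """Total map from event preferred term to its single primary organ class."""

    def __init__(self, pt_to_soc: Mapping[str, str]):
        self._map = {normalize_term(pt): soc.strip() for pt, soc in pt_to_soc.items()}

    def __getitem__(self, pt: str) -> str:
        return self._map[normalize_term(pt)]

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self):
        return self._map.items()

    def missing_terms(self, pts: Iterable[str]) -> list[str]:
        return sorted({normalize_term(p) for p in pts} - self._map.keys())

    @classmethod
    def from_tsv(cls, path) -> "SocMap":
        mapping = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[parts[0]] = parts[1]
        return cls(mapping)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        path.write_text("".join(f"{pt}\t{soc}\n" for pt, soc in sorted(self._map.items())))
        return path


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the 2×2 table for one (drug, event) pair.

    a: study drug & the event; b: study drug & other events;
    c: other drugs & the event; d: other drugs & other events.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in {self}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """E = (a+b)(a+c)/N, the count expected under independence."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def case_terms(case: CaseReport, level: str = PT_LEVEL, soc_map: SocMap | None = None) -> set[str]:
    """Distinct event terms of one report at the requested level."""
    pts = case.pts()
    if level == PT_LEVEL:
        return pts
    if level == SOC_LEVEL:
        if soc_map is None:
            raise ValueError("soc_map is required at SOC level")
        missing = soc_map.missing_terms(pts)
        if missing:
            raise KeyError(f"PTs missing from SOC map: {missing}")
        return {soc_map[pt] for pt in pts}
    raise ValueError(f"unknown level {level!r}")


def count_pairs(
    cohort: Sequence[CaseReport],
    comparator: Sequence[CaseReport],
    level: str = PT_LEVEL,
    soc_map: SocMap | None = None,
    count_unit: str = "pairs",
) -> dict[str, ContingencyTable]:
    """Build the 2×2 table for every event term in the database.

    With ``count_unit="pairs"`` (default) N is the total number of unique
    (report, term) pairs and a+b is the cohort's pair count, identical for
    every term.  With ``count_unit="reports"`` N is the number of reports
    and b counts cohort reports *without* the term.
    """
    if count_unit not in ("pairs", "reports"):
        raise ValueError(f"unknown count_unit {count_unit!r}")

    if level == SOC_LEVEL and soc_map is not None:
        all_pts = set()
        for c in list(cohort) + list(comparator):
            all_pts |= c.pts()
        missing = soc_map.missing_terms(all_pts)
        if missing:
            raise KeyError(f"PTs missing from SOC map: {missing}")

    a_counts: dict[str, int] = {}
    c_counts: dict[str, int] = {}
    cohort_pairs = 0
    comparator_pairs = 0
    for case in cohort:
        terms = case_terms(case, level, soc_map)
        cohort_pairs += len(terms)
        for t in terms:
            a_counts[t] = a_counts.get(t, 0) + 1
    for case in comparator:
        terms = case_terms(case, level, soc_map)
        comparator_pairs += len(terms)
        for t in terms:
            c_counts[t] = c_counts.get(t, 0) + 1

    tables: dict[str, ContingencyTable] = {}
    terms = set(a_counts) | set(c_counts)
    if count_unit == "pairs":
        n = cohort_pairs + comparator_pairs
        for t in sorted(terms):
            a = a_counts.get(t, 0)
            c = c_counts.get(t, 0)
            b = cohort_pairs - a
            tables[t] = ContingencyTable(a, b, c, n - a - b - c)
    else:
        n = len(cohort) + len(comparator)
        for t in sorted(terms):
            a = a_counts.get(t, 0)
            c = c_counts.get(t, 0)
            tables[t] = ContingencyTable(a, len(cohort) - a, c, len(comparator) - c)
    return tables


def database_cells(
    cases: Sequence[CaseReport],
    level: str = PT_LEVEL,
    soc_map: SocMap | None = None,
) -> pd.DataFrame:
    """Observed and expected counts for every (PS drug, event term) cell.

    Used to fit the empirical-Bayes prior over the whole database: for each
    cell, ``a`` is the unique (report, term) pair count among reports whose
    PS drug is that drug, and ``E = row_total × col_total / N`` under
    independence.  Reports with several PS drugs contribute to each drug's
    row.
    """
    rows = []
    for case in cases:
        ps_drugs = {normalize_drug_name(d.drugname) for d in case.drugs if d.role == "PS"}
        terms = case_terms(case, level, soc_map)
        for g in ps_drugs:
            for t in terms:
                rows.append((g, t))
    if not rows:
        return pd.DataFrame(columns=["drug", "term", "a", "E"])
    df = pd.DataFrame(rows, columns=["drug", "term"])
    cell = df.groupby(["drug", "term"]).size().rename("a").reset_index()
    n = len(df)
    row_tot = df.groupby("drug").size()
    col_tot = df.groupby("term").size()
    cell["E"] = cell.drug.map(row_tot) * cell.term.map(col_tot) / n
    return cell


def tables_to_frame(tables: Mapping[str, ContingencyTable], level: str = PT_LEVEL) -> pd.DataFrame:
    rows = [
        {"term": t, "level": level, "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d}
        for t, tab in tables.items()
    ]
    return pd.DataFrame(rows, columns=["term", "level", "a", "b", "c", "d"])
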