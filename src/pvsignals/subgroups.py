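"""Subgroup re-analysis and concomitant-drug sensitivity analysis.

Subgroup analysis restricts *both* the cohort and the comparator to one
demographic stratum (sex, age group or reporter type) before rebuilding the
contingency tables, so the grand total N and the empirical-Bayes prior are
recomputed within the stratum.  Sensitivity analysis removes every case
that lists any of a set of co-medication names in any drug role, then
reruns signal detection on what remains.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .cohort import CaseReport, age_group_coarse, age_group_table1, normalize_drug_name
from .contingency import PT_LEVEL, SocMap, count_pairs, database_cells
from .disprop import MgpsHyperParams, detect_signals, fit_mgps_prior

AGE_PRESETS = {"table1": age_group_table1, "coarse": age_group_coarse}

_SEX_LEVELS = {"Male": "M", "Female": "F", "Unknown": "UNK"}
_REPORTER_LEVELS = {"Consumer": "CN", "Physician": "MD", "Health Professional": "HP",
                    "Pharmacist": "PH", "Other": "OT", "Unknown": "UNK"}


@dataclass(frozen=True)
class StratumSpec:
    dimension: str  # sex | age_group | reporter
    level: str

    def __post_init__(self):
        valid = {
            "sex": set(_SEX_LEVELS) | set(_SEX_LEVELS.values()),
            "age_group": {"<18", "18-65", "65-85", ">65", ">85", "Unknown"},
            "reporter": set(_REPORTER_LEVELS) | set(_REPORTER_LEVELS.values()),
        }
        if self.dimension not in valid:
            raise ValueError(f"unknown stratum dimension {self.dimension!r}")
        if self.level not in valid[self.dimension]:
            raise ValueError(f"level {self.level!r} invalid for dimension {self.dimension!r}")


def in_stratum(case: CaseReport, spec: StratumSpec, age_bins: str = "coarse") -> bool:
    if spec.dimension == "sex":
        code = _SEX_LEVELS.get(spec.level, spec.level)
        return case.demo.sex == code
    if spec.dimension == "age_group":
        return AGE_PRESETS[age_bins](case.demo.age_years) == spec.level
    code = _REPORTER_LEVELS.get(spec.level, spec.level)
    return case.demo.reporter == code


def subgroup_signals(
    cohort: Sequence[CaseReport],
    comparator: Sequence[CaseReport],
    spec: StratumSpec,
    level: str = PT_LEVEL,
    soc_map: SocMap | None = None,
    prior: MgpsHyperParams | None = None,
    age_bins: str = "coarse",
    count_unit: str = "pairs",
) -> pd.DataFrame:
    """Signal table computed entirely within one demographic stratum.

    When no prior is supplied, the MGPS prior is refitted on the stratum's
    own (drug, term) cells.
    """
    sub_cohort = [c for c in cohort if in_stratum(c, spec, age_bins)]
    sub_comp = [c for c in comparator if in_stratum(c, spec, age_bins)]
    if not sub_cohort or not sub_comp:
        side = "cohort" if not sub_cohort else "comparator"
        raise ValueError(f"stratum {spec.dimension}={spec.level!r} is empty in the {side}")
    tables = count_pairs(sub_cohort, sub_comp, level=level, soc_map=soc_map,
                         count_unit=count_unit)
    if prior is None:
        cells = database_cells(sub_cohort + sub_comp, level=level, soc_map=soc_map)
        prior = fit_mgps_prior(cells["a"], cells["E"])
    df = detect_signals(tables, prior)
    df.insert(1, "stratum", f"{spec.dimension}={spec.level}")
    return df


@dataclass(frozen=True)
class ExclusionSpec:
    """Co-medication names whose presence (any role) removes a case."""

    drug_names: frozenset

    def __post_init__(self):
        object.__setattr__(self, "drug_names",
                           frozenset(normalize_drug_name(n) for n in self.drug_names if n.strip()))
        if not self.drug_names:
            raise ValueError("exclusion list must be nonempty")


@dataclass(frozen=True)
class AttritionReport:
    n_input: int
    n_retained: int
    n_pairs_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def sensitivity_exclude(
    cases: Sequence[CaseReport], spec: ExclusionSpec
) -> tuple[list[CaseReport], AttritionReport]:
    """Drop cases listing any excluded drug (any role); report attrition.

    The pair count in the report is the number of unique (case, PT) pairs
    retained, i.e. the adverse events remaining for analysis.
    """
    kept = [
        c for c in cases
        if not any(normalize_drug_name(d.drugname) in spec.drug_names for d in c.drugs)
    ]
    n_pairs = sum(len(c.pts()) for c in kept)
    return kept, AttritionReport(len(cases), len(kept), n_pairs)
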