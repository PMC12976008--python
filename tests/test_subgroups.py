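"""Stratified re-analysis and co-medication sensitivity filtering."""

import pandas as pd
import pytest

from pvsignals.cohort import CaseReport
from pvsignals.contingency import count_pairs
from pvsignals.disprop import detect_signals
from pvsignals.faers_io import DemoRecord, DrugRecord, ReactionRecord, parse_partial_date
from pvsignals.simulate import PlantedSignal, SimConfig, generate
from pvsignals.subgroups import (
    ExclusionSpec, StratumSpec, in_stratum, sensitivity_exclude,
    subgroup_signals,
)
from pvsignals.cohort import DrugDictionary, assemble_cases, deduplicate, select_primary_suspect


def _case(pid, drugs, pts=("x",), sex="F"):
    demo = DemoRecord(pid, pid, parse_partial_date("20240101"), sex=sex)
    c = CaseReport(demo)
    for seq, (role, name) in enumerate(drugs, start=1):
        c.drugs.append(DrugRecord(pid, seq, role, name))
    c.reactions = [ReactionRecord(pid, p) for p in pts]
    return c


@pytest.fixture(scope="module")
def sexed_db():
    """Simulated database with a signal planted in females only."""
    cfg = SimConfig(
        n_cases=6000, seed=23, duplicate_rate=0.0,
        planted_signals=(PlantedSignal("DRUG_00", "event_25", 12.0, sex="F"),),
        rate_overrides={"event_25": 0.02},
        study_drug_share=0.12,
    )
    res = generate(cfg)
    cases = assemble_cases(deduplicate(res.demos), res.drugs, res.reactions,
                           res.outcomes, res.indications, res.therapies)
    cohort, comp = select_primary_suspect(cases, DrugDictionary(frozenset(["DRUG_00"])))
    return cfg, res, cohort, comp


class TestSubgroupSignals:
    def test_full_data_stratum_identity(self, start_prior):
        cases = [_case(str(i), [("PS", "A" if i < 40 else "B")],
                       pts=["p1", "p2"][: 1 + i % 2]) for i in range(200)]
        cohort = [c for c in cases if c.drugs[0].drugname == "A"]
        comp = [c for c in cases if c.drugs[0].drugname == "B"]
        whole = detect_signals(count_pairs(cohort, comp), start_prior)
        stratum = subgroup_signals(cohort, comp, StratumSpec("sex", "Female"),
                                   prior=start_prior)
        pd.testing.assert_frame_equal(whole, stratum.drop(columns="stratum"))

    def test_sex_specific_planted_signal(self, sexed_db, start_prior):
        _, _, cohort, comp = sexed_db
        female = subgroup_signals(cohort, comp, StratumSpec("sex", "Female"),
                                  prior=start_prior)
        male = subgroup_signals(cohort, comp, StratumSpec("sex", "Male"),
                                prior=start_prior)
        f_row = female[female.term == "event_25"].iloc[0]
        m_row = male[male.term == "event_25"].iloc[0]
        assert f_row.any_signal
        assert f_row.ror > m_row.ror
        assert not m_row.sig_ror

    def test_strata_partition_additivity(self, sexed_db, start_prior):
        _, _, cohort, comp = sexed_db
        total_a = {}
        for level in ["Male", "Female", "Unknown"]:
            df = subgroup_signals(cohort, comp, StratumSpec("sex", level),
                                  prior=start_prior)
            for t in df.itertuples():
                total_a[t.term] = total_a.get(t.term, 0) + t.a
        whole = detect_signals(count_pairs(cohort, comp), start_prior)
        for t in whole.itertuples():
            assert total_a.get(t.term, 0) == t.a

    def test_empty_stratum_raises_with_name(self):
        cohort = [_case("1", [("PS", "A")], sex="F")]
        comp = [_case("2", [("PS", "B")], sex="F")]
        with pytest.raises(ValueError, match="Male"):
            subgroup_signals(cohort, comp, StratumSpec("sex", "Male"))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            StratumSpec("sex", "whatever")
        with pytest.raises(ValueError):
            StratumSpec("height", "tall")

    def test_stratum_membership_age_presets(self):
        c = _case("1", [("PS", "A")])
        c.demo.age_value, c.demo.age_unit = 70.0, "YR"
        assert in_stratum(c, StratumSpec("age_group", ">65"), age_bins="coarse")
        assert in_stratum(c, StratumSpec("age_group", "65-85"), age_bins="table1")


class TestSensitivityExclude:
    def test_concomitant_listing_removes_case(self):
        cases = [
            _case("1", [("PS", "STUDY"), ("C", "Prednisone")]),
            _case("2", [("PS", "STUDY")]),
        ]
        kept, rep = sensitivity_exclude(cases, ExclusionSpec(frozenset(["prednisone"])))
        assert [c.primaryid for c in kept] == ["2"]
        assert rep.n_removed == 1 and rep.n_retained == 1

    def test_any_role_triggers_exclusion(self):
        cases = [_case("1", [("PS", "ECULIZUMAB")])]
        kept, _ = sensitivity_exclude(cases, ExclusionSpec(frozenset(["eculizumab"])))
        assert kept == []

    def test_empty_intersection_keeps_everything(self):
        cases = [_case(str(i), [("PS", "STUDY")]) for i in range(5)]
        kept, rep = sensitivity_exclude(cases, ExclusionSpec(frozenset(["unused"])))
        assert len(kept) == 5 and rep.n_pairs_retained == 5

    def test_exclusion_is_monotone(self, sexed_db):
        _, _, cohort, _ = sexed_db
        names: list[str] = []
        last = len(cohort)
        for extra in ["DRUG_01", "DRUG_02", "DRUG_03"]:
            names.append(extra)
            kept, rep = sensitivity_exclude(cohort, ExclusionSpec(frozenset(names)))
            assert rep.n_retained <= last
            last = rep.n_retained

    def test_generator_manifest_agrees(self, sexed_db):
        cfg, res, cohort, _ = sexed_db
        excl = ExclusionSpec(frozenset(["DRUG_05"]))
        kept, rep = sensitivity_exclude(cohort, excl)
        m = res.manifest.cases
        study = m[m.is_study]
        expected = (~study.comeds.fillna("").str.split(";").apply(
            lambda names: "DRUG_05" in names)).sum()
        assert rep.n_retained == expected
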