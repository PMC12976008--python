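"""Round-trip, parsing and totality guarantees of the ASCII table layer."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pvsignals.faers_io import (
    DAY, INVALID, MONTH, YEAR, DemoRecord, DrugRecord, IndicationRecord,
    OutcomeRecord, PartialDate, ReactionRecord, TherapyRecord, age_to_years,
    parse_partial_date, read_table, write_table,
)


@pytest.mark.parametrize("raw, precision, ymd", [
    ("20240115", DAY, (2024, 1, 15)),
    ("202401", MONTH, (2024, 1, None)),
    ("2024", YEAR, (2024, None, None)),
    ("", INVALID, (None, None, None)),
    ("2024023", INVALID, (None, None, None)),     # 7 digits
    ("20240230", INVALID, (None, None, None)),    # impossible calendar day
    ("202413", INVALID, (None, None, None)),      # month 13
    ("n/a", INVALID, (None, None, None)),
])
def test_parse_partial_date(raw, precision, ymd):
    pd_ = parse_partial_date(raw)
    assert pd_.precision == precision
    assert (pd_.year, pd_.month, pd_.day) == ymd
    assert pd_.raw == raw.strip()


def test_partial_date_ordering_places_invalid_first():
    dates = [parse_partial_date(s) for s in ["20240601", "", "2023", "202402"]]
    ordered = sorted(dates, key=lambda p: p.sort_key())
    assert [p.raw for p in ordered] == ["", "2023", "202402", "20240601"]


@pytest.mark.parametrize("value, unit, years", [
    (45, "YR", 45.0),
    (6, "MON", 0.5),
    (52.14, "WK", 1.0),
    (365.25, "DY", 1.0),
    (7, "DEC", 70.0),
    (None, "YR", None),
    (30, "UNK", None),
])
def test_age_normalization(value, unit, years):
    out = age_to_years(value, unit)
    assert out == pytest.approx(years) if years is not None else out is None


def _sample_records():
    d = parse_partial_date
    return {
        "DEMO": [
            DemoRecord("100101", "1001", d("20240301"), d("20240210"), "F",
                       34.0, "YR", "MD", "US"),
            DemoRecord("100201", "1002", d("202401"), d(""), "UNK",
                       None, "UNK", "CN", "JP"),
        ],
        "DRUG": [
            DrugRecord("100101", 1, "PS", "RAVULIZUMAB"),
            DrugRecord("100101", 2, "C", "PREDNISONE"),
        ],
        "REAC": [ReactionRecord("100101", "Fatigue"), ReactionRecord("100101", "headache")],
        "OUTC": [OutcomeRecord("100101", "HO")],
        "INDI": [IndicationRecord("100101", 1, "myasthenia gravis")],
        "THER": [TherapyRecord("100101", 1, d("20240101"), d("20240401"))],
    }


@pytest.mark.parametrize("kind", ["DEMO", "DRUG", "REAC", "OUTC", "INDI", "THER"])
def test_round_trip_identity(tmp_path, kind):
    records = _sample_records()[kind]
    path = write_table(records, tmp_path / f"{kind}.txt", kind)
    back = read_table(path, kind)
    assert back == records


def test_reader_counts_and_totality(tmp_path):
    """Every data line yields exactly one record; bad dates are flagged, not dropped."""
    path = tmp_path / "DEMO.txt"
    path.write_text(
        "primaryid$caseid$fda_dt$event_dt$sex$age$age_cod$occp_cod$reporter_country\n"
        "1$1$20240101$$M$40$YR$MD$US\n"
        "2$2$2024023$$F$$$CN$US\n"
    )
    records = read_table(path, "DEMO")
    assert len(records) == 2
    assert records[0].fda_dt.precision == DAY
    assert records[1].fda_dt.precision == INVALID
    assert records[1].fda_dt.raw == "2024023"


def test_unknown_columns_ignored(tmp_path):
    path = tmp_path / "REAC.txt"
    path.write_text("primaryid$drug_rec_act$pt\n7$$Nausea\n")
    (rec,) = read_table(path, "REAC")
    assert rec.primaryid == "7" and rec.pt == "nausea"


def test_missing_required_column_is_hard_error(tmp_path):
    path = tmp_path / "REAC.txt"
    path.write_text("primaryid$term\n1$x\n")
    with pytest.raises(ValueError, match="pt"):
        read_table(path, "REAC")


def test_write_empty_gives_header_only(tmp_path):
    path = write_table([], tmp_path / "OUTC.txt", "OUTC")
    assert path.read_text() == "primaryid$outc_cod\n"


def test_write_two_demo_records_gives_three_lines(tmp_path):
    path = write_table(_sample_records()["DEMO"], tmp_path / "DEMO.txt", "DEMO")
    assert len(path.read_text().splitlines()) == 3


def test_delimiter_in_field_rejected(tmp_path):
    rec = ReactionRecord("1", "weird$term")
    with pytest.raises(ValueError, match=r"\$"):
        write_table([rec], tmp_path / "REAC.txt", "REAC")


def test_mixed_record_types_rejected(tmp_path):
    with pytest.raises(TypeError):
        write_table([ReactionRecord("1", "x"), OutcomeRecord("1", "HO")],
                    tmp_path / "REAC.txt", "REAC")


def test_latin1_fallback(tmp_path):
    path = tmp_path / "REAC.txt"
    path.write_bytes(b"primaryid$pt\n1$d\xe9j\xe0 vu\n")  # not valid UTF-8
    (rec,) = read_table(path, "REAC")
    assert rec.pt == "déjà vu"


@given(st.lists(
    st.tuples(st.integers(1, 10**7), st.sampled_from(["HO", "DE", "LT", "DS", "OT"])),
    max_size=40))
def test_round_trip_property_outc(tmp_path_factory, rows):
    """read ∘ write is the identity and preserves order on arbitrary tables."""
    records = [OutcomeRecord(str(pid), code) for pid, code in rows]
    path = tmp_path_factory.mktemp("rt") / "OUTC.txt"
    write_table(records, path, "OUTC")
    assert read_table(path, "OUTC") == records
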