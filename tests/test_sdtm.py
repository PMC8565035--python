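"""Reading and writing SDTM-style domain files."""

import copy

import pytest

from omopmap.config import MappingConfig
from omopmap.dates import PartialDate
from omopmap.sdtm import read_study, write_study


def write_minimal_study(dir_path, ae_rows=""):
    (dir_path / "DM.csv").write_text(
        "USUBJID,BRTHDTC,SEX,RFSTDTC\n"
        "P1,1960,F,2015-01-10\n"
        "P2,1955,M,2015-02-01\n"
    )
    (dir_path / "AE.csv").write_text(
        "USUBJID,AESEQ,AEPTCD,AETERM,AESTDTC,AEOCCUR\n"
        "P1,1,10057688,,2015-06,\n"
        "P2,1,,headache noted 15 Jun 2016,not a date,\n"
        "P2,2,10038428,,2015-07-01,N\n"
        + ae_rows
    )


def test_reads_one_table_per_domain_file(tmp_path):
    write_minimal_study(tmp_path)
    study = read_study(tmp_path)
    assert set(study.tables) == {"DM", "AE"}
    assert len(study.tables["AE"]) == 3


def test_iso_prefix_dates_and_flags_are_parsed(tmp_path):
    write_minimal_study(tmp_path)
    study = read_study(tmp_path)
    first, second, third = study.tables["AE"].records
    assert first.start_date == PartialDate(2015, 6)
    assert first.coded_term == ("MedDRA", "10057688")
    assert third.occur_flag == "N" and third.is_non_event


def test_unparseable_dates_are_preserved_verbatim_and_flagged(tmp_path):
    write_minimal_study(tmp_path)
    study = read_study(tmp_path)
    rec = study.tables["AE"].records[1]
    assert rec.start_date is None
    assert rec.date_parse_errors == [("AESTDTC", "not a date")]
    assert rec.values["AESTDTC"] == "not a date"


def test_missing_dm_is_fatal(tmp_path):
    (tmp_path / "AE.csv").write_text("USUBJID,AESEQ\nP1,1\n")
    with pytest.raises(FileNotFoundError):
        read_study(tmp_path)


def test_unknown_domain_loads_with_warning(tmp_path):
    write_minimal_study(tmp_path)
    (tmp_path / "ZZ.csv").write_text("USUBJID,ZZSEQ\nP1,1\n")
    with pytest.warns(UserWarning, match="unknown domain"):
        study = read_study(tmp_path)
    assert "ZZ" in study.tables


def test_orphan_patient_reference_is_rejected(tmp_path):
    write_minimal_study(tmp_path, ae_rows="P9,1,10057688,,2015-01-01,\n")
    with pytest.raises(ValueError, match="absent from DM"):
        read_study(tmp_path)


def test_write_read_round_trip_is_lossless(tmp_path, small_study):
    _, study, _ = small_study
    first = tmp_path / "a"
    second = tmp_path / "b"
    write_study(study, first)
    config = MappingConfig(study_id=study.study_id, design=study.design,
                           study_end_date=study.study_end_date)
    reread = read_study(first, config)
    write_study(reread, second)
    for domain in study.tables:
        assert (first / f"{domain}.csv").read_bytes() == (
            second / f"{domain}.csv"
        ).read_bytes()
    assert reread.violator_ids == study.violator_ids


def test_reading_never_mutates_records(tmp_path):
    write_minimal_study(tmp_path)
    study = read_study(tmp_path)
    snapshot = copy.deepcopy(
        [r.values for r in study.tables["AE"].records]
    )
    # parsing views exist alongside, values stay verbatim
    _ = [r.start_date for r in study.tables["AE"].records]
    assert [r.values for r in study.tables["AE"].records] == snapshot


def test_variable_overrides_apply(tmp_path):
    (tmp_path / "DM.csv").write_text("USUBJID,BRTHDTC\nP1,1960\n")
    (tmp_path / "AE.csv").write_text(
        "USUBJID,AESEQ,AESDTC\nP1,1,2015-06-11\n"
    )
    config = MappingConfig(variable_overrides={"AE": {"start": "AESDTC"}})
    study = read_study(tmp_path, config)
    assert study.tables["AE"].records[0].start_date == PartialDate(2015, 6, 11)
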