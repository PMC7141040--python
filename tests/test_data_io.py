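"""Record table parsing, validation and cell summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semrec import (
    Cell,
    CrabRecord,
    StudyTable,
    read_study_table,
    summarize_cell,
    write_study_table,
)
from semrec.errors import MissingCellError, RowError, SchemaError, ValidationError

HEADER = (
    "crab_id,temperature_c,food,period_days,electroejaculated,"
    "carapace_length_mm,vd_dry_weight_mg,hep_dry_weight_g,body_dry_weight_g,season"
)


def _write(tmp_path, rows, name="t.csv"):
    path = tmp_path / name
    path.write_text("\n".join([HEADER, *rows]) + "\n")
    return path


def test_reads_valid_rows_verbatim(tmp_path):
    path = _write(
        tmp_path,
        [
            "c1,NA,none,0,false,98.6,84.2,0.61,10.2,NA",
            "c2,16,deprived,30,true,97.0,104.8,0.45,9.8,NA",
        ],
    )
    table = read_study_table(path)
    assert len(table) == 2
    assert table.provenance == str(path)
    r1, r2 = table.records
    assert r1.temperature is None and r1.food == "none" and not r1.electroejaculated
    assert r2.cell == Cell.recovery(16, "deprived", 30)
    assert r2.vd_dry_weight == 104.8


def test_invalid_food_enum_cites_row(tmp_path):
    path = _write(tmp_path, ["c1,12,sometimes,15,true,98,60,0.5,10,NA"])
    with pytest.raises(RowError, match="row 2.*sometimes"):
        read_study_table(path)


def test_missing_column_named_in_error(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("crab_id,food\nc1,none\n")
    with pytest.raises(SchemaError, match="temperature_c"):
        read_study_table(path)


def test_schema_mapping_resolves_renamed_columns(tmp_path):
    path = tmp_path / "t.csv"
    renamed = HEADER.replace("vd_dry_weight_mg", "VDW")
    path.write_text(renamed + "\nc1,NA,none,0,false,98.6,84.2,0.61,10.2,NA\n")
    table = read_study_table(path, schema={"vd_dry_weight_mg": "VDW"})
    assert table.records[0].vd_dry_weight == 84.2


def test_duplicate_ids_rejected(tmp_path):
    path = _write(
        tmp_path,
        [
            "c1,NA,none,0,false,98,84,0.6,10,NA",
            "c1,NA,none,0,true,97,52,0.6,10,NA",
        ],
    )
    with pytest.raises(ValidationError, match="duplicate"):
        read_study_table(path)


def test_organ_heavier_than_body_rejected(tmp_path):
    path = _write(tmp_path, ["c1,NA,none,0,false,98,84,11.0,10.0,NA"])
    with pytest.raises(RowError, match="row 2"):
        read_study_table(path)


def test_write_read_round_trip(tmp_path, study_table):
    path = tmp_path / "rt.csv"
    write_study_table(study_table, path)
    back = read_study_table(path)
    assert len(back) == len(study_table)
    for a, b in zip(study_table.records, back.records):
        assert a.crab_id == b.crab_id
        assert a.cell == b.cell
        assert a.carapace_length == pytest.approx(b.carapace_length)
        assert a.vd_dry_weight == pytest.approx(b.vd_dry_weight)
        assert a.hep_dry_weight == pytest.approx(b.hep_dry_weight)
        assert a.body_dry_weight == pytest.approx(b.body_dry_weight)


def _baseline(values, ee=False, ids=None):
    recs = [
        CrabRecord(
            crab_id=ids[i] if ids else f"x{i}",
            temperature=None,
            food="none",
            period_days=0,
            electroejaculated=ee,
            carapace_length=98.0,
            vd_dry_weight=v,
            hep_dry_weight=0.6,
            body_dry_weight=10.0,
        )
        for i, v in enumerate(values)
    ]
    return StudyTable(records=recs, provenance="test")


def test_summarize_mean_se_hand_values():
    # {80, 88}: SD = 5.657, SE = 4.0 — the mean +- SE reporting convention
    s = summarize_cell(_baseline([80.0, 88.0]), Cell.control_t0(), "vd_dry_weight")
    assert s.n == 2
    assert s.mean == pytest.approx(84.0)
    assert s.se == pytest.approx(4.0)


def test_summarize_constant_sample_has_zero_se():
    s = summarize_cell(_baseline([52.0] * 3), Cell.control_t0(), "vd_dry_weight")
    assert s.mean == pytest.approx(52.0)
    assert s.se == 0.0


def test_summarize_empty_and_singleton_cells_error():
    with pytest.raises(MissingCellError):
        summarize_cell(_baseline([80.0, 88.0]), Cell.depleted_t0(), "vd_dry_weight")
    with pytest.raises(MissingCellError):
        summarize_cell(_baseline([80.0]), Cell.control_t0(), "vd_dry_weight")


@given(
    values=st.lists(st.floats(min_value=1.0, max_value=500.0), min_size=2, max_size=12),
    shift=st.floats(min_value=0.0, max_value=100.0),
    seed=st.integers(min_value=0, max_value=10_000),
)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_summary_invariances(values, shift, seed):
    """Mean is order-invariant; SE is invariant under a constant shift."""
    import random

    base = summarize_cell(_baseline(values), Cell.control_t0(), "vd_dry_weight")
    shuffled = list(values)
    random.Random(seed).shuffle(shuffled)
    perm = summarize_cell(_baseline(shuffled), Cell.control_t0(), "vd_dry_weight")
    assert perm.mean == pytest.approx(base.mean, rel=1e-12)
    shifted = summarize_cell(
        _baseline([v + shift for v in values]), Cell.control_t0(), "vd_dry_weight"
    )
    assert shifted.se == pytest.approx(base.se, rel=1e-9, abs=1e-9)
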