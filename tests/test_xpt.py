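"""Transport-file codec: IBM float arithmetic, round trips, error handling."""

import math
import random
import subprocess
import sys

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nhaneskit.xpt import (
    MISSING_CODES,
    XptCorruptionError,
    XptFormatError,
    XptTable,
    XptTruncationError,
    XptVariable,
    ibm_to_ieee,
    ieee_to_ibm,
    read_xpt,
    to_dataframe,
    write_xpt,
)


@pytest.mark.parametrize(
    "word,expected",
    [
        ("4110000000000000", 1.0),  # 16^1 * 1/16
        ("4220000000000000", 32.0),  # 16^2 * 1/8
        ("C110000000000000", -1.0),
        ("0000000000000000", 0.0),
        ("2E00000000000000", "."),
        ("5F00000000000000", "._"),
        ("4100000000000000", ".A"),
        ("5A00000000000000", ".Z"),
    ],
)
def test_ibm_decoding_closed_forms(word, expected):
    assert ibm_to_ieee(bytes.fromhex(word)) == expected


@pytest.mark.parametrize(
    "value,word",
    [(0.0, "0000000000000000"), (1.0, "4110000000000000"), (-1.0, "C110000000000000")],
)
def test_ibm_encoding_closed_forms(value, word):
    assert ieee_to_ibm(value) == bytes.fromhex(word)


def test_ibm_round_trip_random_draws():
    """10^4 random doubles survive ieee->ibm->ieee within 2^-52 relative."""
    rng = random.Random(12345)
    for _ in range(10_000):
        x = rng.gauss(0, 1) * 10 ** rng.uniform(-60, 60)
        y = ibm_to_ieee(ieee_to_ibm(x))
        assert abs(y - x) <= abs(x) * 2**-52


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(allow_nan=False, allow_infinity=False, min_value=-1e70, max_value=1e70))
def test_ibm_round_trip_property(x):
    if x != 0 and abs(x) < 1e-70:
        x = 0.0
    y = ibm_to_ieee(ieee_to_ibm(x))
    assert y == x or abs(y - x) <= abs(x) * 2**-52


def test_missing_codes_round_trip():
    for code in MISSING_CODES:
        assert ibm_to_ieee(ieee_to_ibm(code)) == code


def test_nan_and_inf_rejected():
    for bad in (float("nan"), float("inf"), -float("inf")):
        with pytest.raises(ValueError):
            ieee_to_ibm(bad)


def _small_table():
    return XptTable(
        member_name="DEMO",
        variables=[
            XptVariable("SEQN", "Respondent sequence number"),
            XptVariable("NAME", "a label", "character", 7, 1),
        ],
        rows=[[1.0, "ab"], [2.5, "cdefghi"], [".", ""]],
    )


def test_write_read_round_trip_identity():
    t = _small_table()
    assert read_xpt(write_xpt(t)) == t


def test_empty_table_round_trips():
    t = XptTable("E", [XptVariable("X")], [])
    out = write_xpt(t)
    assert len(out) % 80 == 0
    assert read_xpt(out) == t


def test_character_padding_stripped():
    t = XptTable("C", [XptVariable("S", "", "character", 7)], [["abc"], [""], ["xy"]])
    back = read_xpt(write_xpt(t))
    assert [r[0] for r in back.rows] == ["abc", "", "xy"]


def test_thousand_row_output_deterministic():
    rng = random.Random(1)
    rows = [[rng.random(), rng.gauss(0, 1)] for _ in range(1000)]
    t = XptTable("BIG", [XptVariable("A"), XptVariable("B", "", "numeric", 8, 1)], rows)
    b1, b2 = write_xpt(t), write_xpt(t)
    assert b1 == b2
    assert len(b1) % 80 == 0
    assert read_xpt(b1) == t


def test_short_numeric_storage_zero_extended():
    t = XptTable("S", [XptVariable("X", "", "numeric", 4)], [[1.0], [32.0], ["."]])
    back = read_xpt(write_xpt(t))
    assert [r[0] for r in back.rows] == [1.0, 32.0, "."]


def test_malformed_magic_rejected():
    with pytest.raises(XptFormatError):
        read_xpt(b"X" * 800)


def test_v8_header_rejected_with_clear_message():
    blob = bytearray(write_xpt(_small_table()))
    blob[:80] = b"HEADER RECORD*******LIBV8   HEADER RECORD!!!!!!!".ljust(80)
    with pytest.raises(XptFormatError, match="v8"):
        read_xpt(bytes(blob))


def test_namestr_count_mismatch_detected():
    blob = bytearray(write_xpt(_small_table()))
    # overstate the variable count in the NAMESTR header
    assert blob[560:640].startswith(b"HEADER RECORD*******NAMESTR")
    blob[614:618] = b"0009"
    with pytest.raises(XptCorruptionError):
        read_xpt(bytes(blob))


def test_truncated_final_record_names_offset():
    vars3 = [XptVariable("A"), XptVariable("B", "", "numeric", 8, 1), XptVariable("C", "", "numeric", 8, 2)]
    t = XptTable("T", vars3, [[1.0, 2.0, 3.0]])  # 24-byte records
    blob = bytearray(write_xpt(t))
    # an extra 80-byte record whose tail is a partial (16-byte) fourth row
    blob += b" " * 64 + b"\x41\x10\x00\x00\x00\x00\x00\x00" * 2
    with pytest.raises(XptTruncationError, match="offset"):
        read_xpt(bytes(blob))

    # and a file that is not a multiple of 80 bytes at all
    with pytest.raises(XptTruncationError):
        read_xpt(bytes(write_xpt(t)) + b"x")


def test_demo_like_fixture_has_expected_variables(config):
    from nhaneskit.catalog import fetch_table

    table = fetch_table("DEMO_J", config)
    names = set(table.names)
    assert {"SEQN", "RIAGENDR", "RIDRETH1", "RIDAGEYR"} <= names


def test_reader_agrees_with_independent_reference(tmp_path):
    """R's foreign::read.xport decodes our output cell-for-cell."""
    if subprocess.run(["which", "Rscript"], capture_output=True).returncode != 0:
        pytest.skip("Rscript unavailable")
    rng = random.Random(7)
    rows = [
        [float(i + 1), round(rng.gauss(100, 15), 6) if i % 7 else ".", f"g{i % 3}"]
        for i in range(25)
    ]
    t = XptTable(
        "FIX",
        [
            XptVariable("SEQN"),
            XptVariable("VAL", "value", "numeric", 8, 1),
            XptVariable("GRP", "group", "character", 6, 2),
        ],
        rows,
    )
    path = tmp_path / "fix.xpt"
    path.write_bytes(write_xpt(t))
    out = tmp_path / "fix.csv"
    res = subprocess.run(
        ["Rscript", "-e", f'write.csv(foreign::read.xport("{path}"), "{out}", row.names=FALSE)'],
        capture_output=True,
        text=True,
    )
    assert res.returncode == 0, res.stderr
    import pandas as pd

    r = pd.read_csv(out)
    for i, row in enumerate(rows):
        assert r.SEQN[i] == row[0]
        if row[1] == ".":
            assert pd.isna(r.VAL[i])
        else:
            assert r.VAL[i] == row[1]
        assert r.GRP[i] == row[2]


def test_to_dataframe_maps_sentinels_to_nan():
    import numpy as np

    df = to_dataframe(_small_table())
    assert np.isnan(df["SEQN"].iloc[2])
    assert df["SEQN"].iloc[0] == 1.0
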