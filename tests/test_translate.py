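"""Code-to-label translation, skip-fill, and coarsening detection."""

import numpy as np
import pandas as pd
import pytest

from nhaneskit.catalog import fetch_codebook, fetch_table
from nhaneskit.codebook import CodebookEntry, ValueCodeRow, codebook_for_variable
from nhaneskit.translate import (
    SkipFillRule,
    StructuralError,
    apply_skip_fill,
    flag_coarsened,
    is_translatable,
    load_datatable,
    save_datatable,
    suggest_skip_rules,
    translate_table,
)
from nhaneskit.xpt import XptTable, XptVariable


def _entry(rows):
    return CodebookEntry("V", value_rows=[ValueCodeRow(*r) for r in rows])


def test_pure_coded_categorical_is_translatable():
    entry = _entry([("1", "Male", 10, 10), ("2", "Female", 12, 22), (".", "Missing", 0, 22)])
    assert is_translatable(entry)


def test_mixed_range_variable_is_not_translatable():
    entry = _entry(
        [("0 to 79", "Range of Values", 90, 90), ("80", "80 years of age and over", 5, 95), (".", "Missing", 0, 95)]
    )
    assert not is_translatable(entry)


def test_empty_and_single_row_entries_not_translatable():
    assert not is_translatable(_entry([]))
    assert not is_translatable(_entry([("1", "Yes", 5, 5), (".", "Missing", 0, 5)]))


def test_gender_codes_become_labels(demo_translated):
    col = demo_translated.df["RIAGENDR"]
    assert isinstance(col.dtype, pd.CategoricalDtype)
    assert list(col.cat.categories) == ["Male", "Female"]
    assert set(col.dropna().unique()) <= {"Male", "Female"}


def test_ethnicity_categories_keep_code_order(demo_translated):
    from nhaneskit.fixtures import ETHNICITY_LABELS

    assert list(demo_translated.df["RIDRETH1"].cat.categories) == list(ETHNICITY_LABELS)


def test_untranslated_mode_is_identity(config):
    raw = fetch_table("DEMO_J", config)
    cb = fetch_codebook("DEMO_J", config)
    from nhaneskit.xpt import to_dataframe

    dt = translate_table(raw, cb, translated=False)
    pd.testing.assert_frame_equal(dt.df, to_dataframe(raw))


def test_translation_is_lossless(config, demo_translated):
    """Labels plus the recorded code map reconstruct the raw integers exactly."""
    raw = fetch_table("DEMO_J", config)
    from nhaneskit.xpt import to_dataframe

    raw_df = to_dataframe(raw)
    for col, cmap in demo_translated.provenance["code_maps"].items():
        inverse = {label: float(code) for code, label in cmap.items()}
        assert len(inverse) == len(cmap)  # bijection on mapped codes
        rebuilt = demo_translated.df[col].map(inverse).astype(float)
        pd.testing.assert_series_equal(rebuilt, raw_df[col], check_names=False)


def _toy_table(values, member="TOY"):
    rows = [[float(i + 1), v] for i, v in enumerate(values)]
    return XptTable(
        member, [XptVariable("SEQN"), XptVariable("RIAGENDR", "Gender", "numeric", 8, 1)], rows
    )


def _toy_codebook():
    from nhaneskit.codebook import Codebook

    entry = CodebookEntry(
        "RIAGENDR",
        sas_label="Gender",
        value_rows=[
            ValueCodeRow("1", "Male", 1, 1),
            ValueCodeRow("2", "Female", 1, 2),
            ValueCodeRow(".", "Missing", 0, 2),
        ],
    )
    seqn = CodebookEntry("SEQN", sas_label="Respondent sequence number")
    return Codebook("TOY", {"SEQN": seqn, "RIAGENDR": entry})


def test_unmapped_code_kept_as_literal_with_warning():
    with pytest.warns(UserWarning, match="code 3"):
        dt = translate_table(_toy_table([1.0, 2.0, 3.0]), _toy_codebook())
    assert list(dt.df["RIAGENDR"]) == ["Male", "Female", "3"]
    assert list(dt.df["RIAGENDR"].cat.categories) == ["Male", "Female", "3"]


def test_special_answers_collapsed_when_requested():
    cb = _toy_codebook()
    cb.entries["RIAGENDR"].value_rows.insert(
        2, ValueCodeRow("7", "Refused", 0, 2)
    )
    dt = translate_table(_toy_table([1.0, 7.0]), cb, special_as_missing=True)
    assert dt.df["RIAGENDR"].isna().iloc[1]
    assert "Refused" not in dt.df["RIAGENDR"].cat.categories


def test_missing_seqn_and_duplicate_seqn_rejected():
    cb = _toy_codebook()
    no_seqn = XptTable("X", [XptVariable("RIAGENDR")], [[1.0]])
    with pytest.raises(StructuralError):
        translate_table(no_seqn, cb)
    dup = XptTable(
        "X",
        [XptVariable("SEQN"), XptVariable("RIAGENDR", "", "numeric", 8, 1)],
        [[1.0, 1.0], [1.0, 2.0]],
    )
    with pytest.raises(StructuralError):
        translate_table(dup, cb)


# --- skip fill -------------------------------------------------------------

RULE = SkipFillRule("BPQ020", ("No", "Don't know"), "BPQ030", "No")


def test_skip_fill_conserves_cells(bpq_translated, bpq_codebook, truth):
    before = int(bpq_translated.df["BPQ030"].isna().sum())
    filled = apply_skip_fill(bpq_translated, bpq_codebook, [RULE])
    after = int(filled.df["BPQ030"].isna().sum())
    n_filled = filled.provenance["skip_fill"]["BPQ020->BPQ030"]
    assert before == after + n_filled  # cell-count conservation
    assert n_filled == truth["bpq"]["structural_missing"]
    assert after == truth["bpq"]["nonstructural_missing"]


def test_skip_fill_never_touches_nonmissing_or_out_of_gate(bpq_translated, bpq_codebook):
    original = bpq_translated.df.copy()
    filled = apply_skip_fill(bpq_translated, bpq_codebook, [RULE])
    yes_rows = original["BPQ020"] == "Yes"
    pd.testing.assert_series_equal(filled.df.loc[yes_rows, "BPQ030"], original.loc[yes_rows, "BPQ030"])
    nonmissing = original["BPQ030"].notna()
    pd.testing.assert_series_equal(filled.df.loc[nonmissing, "BPQ030"], original.loc[nonmissing, "BPQ030"])


def test_skip_fill_with_inapplicable_gate_fills_nothing(bpq_translated, bpq_codebook):
    rule = SkipFillRule("BPQ040A", ("No",), "BPQ030", "No")  # gate answers never missing-inducing
    filled = apply_skip_fill(bpq_translated, bpq_codebook, [SkipFillRule("BPQ020", ("Never happens",), "BPQ030", "No")])
    assert filled.provenance["skip_fill"]["BPQ020->BPQ030"] == 0


def test_skip_fill_rejects_unknown_fill_label(bpq_translated, bpq_codebook):
    with pytest.raises(ValueError, match="not a category"):
        apply_skip_fill(bpq_translated, bpq_codebook, [SkipFillRule("BPQ020", ("No",), "BPQ030", "Nope")])


def test_suggested_rules_derived_from_skip_links(bpq_codebook):
    suggestions = suggest_skip_rules(bpq_codebook)
    assert any(
        s["gate"] == "BPQ020" and "BPQ030" in s["skipped"] and set(s["gate_values"]) == {"No", "Don't know"}
        for s in suggestions
    )


# --- coarsening ------------------------------------------------------------


def test_topcoded_age_and_pir_ceiling_reported(config, truth):
    raw = translate_table(fetch_table("DEMO_J", config), fetch_codebook("DEMO_J", config), translated=False)
    flags = {(f.variable, f.code_value): f.count for f in flag_coarsened(raw, fetch_codebook("DEMO_J", config))}
    assert flags[("RIDAGEYR", 80.0)] == truth["topcoded_age_rows"]
    assert flags[("INDFMPIR", 5.0)] == truth["pir_ceiling_rows"]


def test_pure_range_variable_not_flagged(config):
    raw = translate_table(fetch_table("BPX_J", config), fetch_codebook("BPX_J", config), translated=False)
    flags = flag_coarsened(raw, fetch_codebook("BPX_J", config))
    assert all(f.variable != "BPXDI1" for f in flags)


# --- serialization ---------------------------------------------------------


def test_csv_sidecar_round_trip_preserves_categories(tmp_path, demo_translated):
    path = tmp_path / "demo.csv"
    save_datatable(demo_translated, path)
    back = load_datatable(path)
    assert list(back.df["RIDRETH1"].cat.categories) == list(
        demo_translated.df["RIDRETH1"].cat.categories
    )
    assert back.provenance["translated"] is True
    assert (back.df["SEQN"] == demo_translated.df["SEQN"]).all()
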