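"""Code-to-label translation and remediation of survey-delivery artifacts.

Raw NHANES columns store categorical answers as integer codes; the
codebook maps each code to a description ("1" -> "Male"). Translating
matters beyond readability: an untranslated categorical fed to a
regression is silently treated as continuous. This module also handles
two structural quirks of questionnaire data: skip-pattern missingness
(a gate answer routes respondents past later questions, leaving
structural missing values) and coarsening (top-coded ages, the
income-to-poverty ratio capped at 5).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .codebook import Codebook, CodebookEntry, ValueCodeRow, codebook_for_variable
from .xpt import XptTable, to_dataframe

__all__ = [
    "DataTable",
    "SkipFillRule",
    "CoarseningFlag",
    "StructuralError",
    "is_translatable",
    "translate_table",
    "apply_skip_fill",
    "suggest_skip_rules",
    "flag_coarsened",
    "save_datatable",
    "load_datatable",
]

SPECIAL_LABELS = ("Refused", "Don't know")
_EXCLUDED_DESCRIPTIONS = {"range of values", "missing"}


class StructuralError(ValueError):
    """SEQN absent or duplicated — the table cannot be keyed."""


@dataclass
class DataTable:
    """A SEQN-keyed columnar table with provenance.

    Columns are numeric-with-missing, labeled-categorical (pandas
    ``Categorical`` whose categories come verbatim from the codebook),
    or text. ``provenance`` records source tables, the translation flag,
    the cycle, and any skip-fill counts.
    """

    name: str
    df: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def cycle(self) -> Optional[str]:
        return self.provenance.get("cycle")

    @property
    def n_rows(self) -> int:
        return len(self.df)

    def copy(self) -> "DataTable":
        return DataTable(self.name, self.df.copy(), json.loads(json.dumps(self.provenance)))


@dataclass
class SkipFillRule:
    gate: str
    gate_values: tuple
    target: str
    fill_label: str


@dataclass
class CoarseningFlag:
    variable: str
    code_value: float
    count: int
    description: str = ""


def _single_code_rows(entry: CodebookEntry) -> list[ValueCodeRow]:
    return [
        r
        for r in entry.value_rows
        if not r.is_range
        and r.code_or_value.strip() not in ("", ".")
        and r.description.strip().lower() not in _EXCLUDED_DESCRIPTIONS
    ]


def is_translatable(entry: CodebookEntry) -> bool:
    """True iff the variable is a pure coded categorical.

    Requires at least two single-valued code rows whose descriptions are
    not "Range of Values"/"Missing", and no range row at all — a variable
    mixing a numeric range with special codes (top-coded age, capped
    income ratio) stays numeric and is handled by :func:`flag_coarsened`.
    """
    if entry.doc_only:
        return False
    if any(r.is_range or r.description.strip().lower() == "range of values" for r in entry.value_rows):
        return False
    return len(_single_code_rows(entry)) >= 2


def _code_as_float(code: str) -> Optional[float]:
    try:
        return float(code)
    except ValueError:
        return None


def translate_table(
    raw: XptTable,
    cb: Codebook,
    translated: bool = True,
    special_as_missing: bool = False,
) -> DataTable:
    """Decode an XPT table into a :class:`DataTable`, translating coded columns.

    With ``translated=False`` all columns keep their raw numeric values.
    ``special_as_missing=True`` converts "Refused"/"Don't know" answers to
    missing instead of keeping them as explicit categories. Observed codes
    absent from the codebook are kept as their literal numeral string with
    a warning. Categories keep codebook (code-ascending) order so ordinal
    variables remain ordered.
    """
    df = to_dataframe(raw)
    if "SEQN" not in df.columns:
        raise StructuralError(f"table {raw.member_name} has no SEQN column")
    if df["SEQN"].duplicated().any():
        dupes = df.loc[df["SEQN"].duplicated(), "SEQN"].head(3).tolist()
        raise StructuralError(f"duplicate SEQN in {raw.member_name}: {dupes}")

    code_maps: dict[str, dict[str, str]] = {}
    if translated:
        for col in df.columns:
            if col == "SEQN":
                continue
            entry = cb.entries.get(col) or cb.entries.get(col.upper())
            if entry is None:
                warnings.warn(f"column {col} absent from codebook; passed through untranslated")
                continue
            if not is_translatable(entry):
                continue
            rows = _single_code_rows(entry)
            mapping: dict[float, str] = {}
            for r in rows:
                code = _code_as_float(r.code_or_value)
                if code is not None:
                    mapping[code] = r.description
            if special_as_missing:
                mapping = {c: d for c, d in mapping.items() if d not in SPECIAL_LABELS}
            categories = [mapping[c] for c in sorted(mapping)]
            values = df[col]
            observed = set(values.dropna().unique())
            unmapped = sorted(observed - set(mapping))
            extra_labels: dict[float, str] = {}
            for code in unmapped:
                if special_as_missing:
                    entry_row = next(
                        (r for r in entry.value_rows if _code_as_float(r.code_or_value) == code), None
                    )
                    if entry_row is not None and entry_row.description in SPECIAL_LABELS:
                        continue  # collapsed to missing
                label = str(int(code)) if float(code).is_integer() else str(code)
                extra_labels[code] = label
                warnings.warn(f"{col}: observed code {label} not in codebook; kept as literal")
            full_map = {**mapping, **extra_labels}
            labels = values.map(full_map)
            df[col] = pd.Categorical(
                labels, categories=categories + [extra_labels[c] for c in sorted(extra_labels)]
            )
            code_maps[col] = {repr(c): d for c, d in full_map.items()}

    provenance = {
        "sources": [raw.member_name],
        "translated": translated,
        "special_as_missing": special_as_missing,
        "code_maps": code_maps,
    }
    try:
        from .catalog import cycle_from_table_name

        provenance["cycle"] = cycle_from_table_name(raw.member_name).label
    except Exception:
        provenance["cycle"] = None
    return DataTable(name=raw.member_name, df=df, provenance=provenance)


def apply_skip_fill(
    data: DataTable,
    cb: Codebook,
    rules: Sequence[Union[SkipFillRule, tuple]],
) -> DataTable:
    """Deterministically fill gate-induced structural missings.

    For each rule, rows whose gate answer is in ``gate_values`` and whose
    target is missing get ``fill_label``. Non-missing cells and rows
    outside the gate set are never touched; per-rule fill counts land in
    ``provenance['skip_fill']``.
    """
    out = data.copy()
    counts: dict[str, int] = dict(out.provenance.get("skip_fill", {}))
    for rule in rules:
        if not isinstance(rule, SkipFillRule):
            rule = SkipFillRule(rule[0], tuple(rule[1]), rule[2], rule[3])
        for colname in (rule.gate, rule.target):
            if colname not in out.df.columns:
                raise KeyError(f"skip-fill rule references unknown column {colname}")
        target = out.df[rule.target]
        if isinstance(target.dtype, pd.CategoricalDtype):
            if rule.fill_label not in target.cat.categories:
                raise ValueError(
                    f"fill label {rule.fill_label!r} is not a category of {rule.target} "
                    f"(categories: {list(target.cat.categories)})"
                )
        gate = out.df[rule.gate]
        mask = gate.isin(rule.gate_values) & target.isna()
        out.df.loc[mask, rule.target] = rule.fill_label
        key = f"{rule.gate}->{rule.target}"
        counts[key] = counts.get(key, 0) + int(mask.sum())
    out.provenance["skip_fill"] = counts
    return out


def suggest_skip_rules(cb: Codebook) -> list[dict]:
    """Derive candidate skip-fill rules from codebook "Skip to Item" links.

    Suggestions name the gate, the gate answers that trigger the skip, and
    the questions skipped over (everything between the gate and the skip
    target in codebook order). They are never applied automatically: the
    fill label is an analyst judgment.
    """
    names = list(cb.entries)
    suggestions = []
    for i, (gate_name, entry) in enumerate(cb.entries.items()):
        skip_rows = [r for r in entry.value_rows if r.skip_to]
        if not skip_rows:
            continue
        by_target: dict[str, list[str]] = {}
        for r in skip_rows:
            by_target.setdefault(r.skip_to, []).append(r.description)
        for target, gate_values in by_target.items():
            if target in names:
                skipped = names[i + 1 : names.index(target)]
            else:
                skipped = names[i + 1 :]
            if skipped:
                suggestions.append(
                    {"gate": gate_name, "gate_values": gate_values, "skipped": skipped}
                )
    return suggestions


def flag_coarsened(data: DataTable, cb: Codebook) -> list[CoarseningFlag]:
    """Report top/bottom-coded numeric variables and how many rows they affect.

    A variable is coarsened when its codebook mixes a "Range of Values"
    row with single-coded categories (e.g. age recorded as 80 for anyone
    older; income-to-poverty ratio recorded as 5 for any ratio >= 5).
    """
    flags: list[CoarseningFlag] = []
    for col in data.df.columns:
        entry = cb.entries.get(col) or cb.entries.get(col.upper())
        if entry is None or not pd.api.types.is_numeric_dtype(data.df[col]):
            continue
        has_range = any(
            r.is_range or r.description.strip().lower() == "range of values"
            for r in entry.value_rows
        )
        if not has_range:
            continue
        for r in _single_code_rows(entry):
            code = _code_as_float(r.code_or_value)
            if code is None:
                continue
            count = int((data.df[col] == code).sum())
            flags.append(CoarseningFlag(col, code, count, r.description))
    return flags


# ---------------------------------------------------------------------------
# CSV + sidecar serialization


def save_datatable(data: DataTable, path: Union[str, Path]) -> None:
    """Write CSV plus a .meta.json sidecar preserving categorical typing."""
    path = Path(path)
    data.df.to_csv(path, index=False)
    meta = {
        "name": data.name,
        "provenance": data.provenance,
        "categories": {
            col: list(data.df[col].cat.categories)
            for col in data.df.columns
            if isinstance(data.df[col].dtype, pd.CategoricalDtype)
        },
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_datatable(path: Union[str, Path]) -> DataTable:
    """Inverse of :func:`save_datatable`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
    df = pd.read_csv(path)
    for col, cats in meta["categories"].items():
        df[col] = pd.Categorical(df[col], categories=cats)
    return DataTable(name=meta["name"], df=df, provenance=meta["provenance"])
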