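"""Merging tables within a cycle and aligning them across cycles.

Within one cycle, tables describe the same respondents and join on SEQN.
Across cycles, respondents are disjoint and tables are row-stacked — but
variable names and question wording drift between cycles, and the
combined pre-pandemic (P_) release carries weights that are not
cycle-additive, so cross-cycle alignment performs explicit compatibility
checks instead of silent unions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .translate import DataTable, StructuralError

__all__ = [
    "AlignmentReport",
    "CrossCycleError",
    "PrepandemicGuardError",
    "merge_within_cycle",
    "align_across_cycles",
]


class CrossCycleError(ValueError):
    pass


class PrepandemicGuardError(ValueError):
    pass


@dataclass
class AlignmentReport:
    shared_variables: list[str]
    per_cycle_only: dict[str, list[str]]  # cycle label -> variables unique to it
    category_mismatches: dict[str, dict[str, list[str]]]  # var -> cycle -> labels
    tables: list[tuple[str, Optional[str], int]]  # (name, cycle, n_rows)


def _check_seqn(dt: DataTable) -> None:
    if "SEQN" not in dt.df.columns:
        raise StructuralError(f"table {dt.name} has no SEQN column")
    if dt.df["SEQN"].duplicated().any():
        raise StructuralError(f"duplicate SEQN in {dt.name}")


def merge_within_cycle(
    left: DataTable, right: DataTable, join: str = "full"
) -> DataTable:
    """Join two same-cycle tables on SEQN (``inner``, ``left`` or ``full``)."""
    if join not in ("inner", "left", "full"):
        raise ValueError(f"join must be inner/left/full, got {join!r}")
    _check_seqn(left)
    _check_seqn(right)
    if left.cycle and right.cycle and left.cycle != right.cycle:
        raise CrossCycleError(
            f"{left.name} ({left.cycle}) and {right.name} ({right.cycle}) are from "
            "different cycles; use align_across_cycles for cross-cycle work"
        )
    overlap = (set(left.df.columns) & set(right.df.columns)) - {"SEQN"}
    if overlap:
        warnings.warn(
            f"columns {sorted(overlap)} appear in both tables; disambiguated by table name"
        )
    how = {"full": "outer", "inner": "inner", "left": "left"}[join]
    merged = pd.merge(
        left.df,
        right.df,
        on="SEQN",
        how=how,
        suffixes=(f"_{left.name}", f"_{right.name}"),
    )
    provenance = {
        "sources": left.provenance.get("sources", [left.name])
        + right.provenance.get("sources", [right.name]),
        "translated": left.provenance.get("translated") and right.provenance.get("translated"),
        "cycle": left.cycle or right.cycle,
        "join": join,
        "code_maps": {
            **left.provenance.get("code_maps", {}),
            **right.provenance.get("code_maps", {}),
        },
    }
    return DataTable(name=f"{left.name}+{right.name}", df=merged, provenance=provenance)


def align_across_cycles(
    tables: Sequence[DataTable],
    variables: Optional[Sequence[str]] = None,
    strict: bool = False,
    allow_prepandemic: bool = False,
) -> tuple[DataTable, AlignmentReport]:
    """Row-stack the selected variables across cycles, adding a cycle column.

    Pre-pandemic (P_) tables refuse to mix with regular cycles unless
    ``allow_prepandemic=True`` — their weights cover 2017-March 2020 and
    are not combinable with 2-year cycle weights without re-derivation.
    With ``strict=True`` a variable absent in any cycle raises; otherwise
    it is missing there. Differing categorical label sets are reported,
    never silently reconciled.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to align across cycles")
    cycles = [t.cycle for t in tables]
    if len(set(cycles)) != len(cycles):
        raise CrossCycleError(f"cycles are not pairwise distinct: {cycles}")
    prepandemic = [t for t in tables if t.cycle == "2017-March 2020" or t.name.upper().startswith("P_")]
    if prepandemic and len(prepandemic) != len(tables) and not allow_prepandemic:
        raise PrepandemicGuardError(
            f"{[t.name for t in prepandemic]} are pre-pandemic releases with special "
            "weights; pass allow_prepandemic=True only after re-deriving weights"
        )

    all_vars: list[str] = []
    for t in tables:
        for c in t.df.columns:
            if c not in all_vars:
                all_vars.append(c)
    shared = [c for c in all_vars if all(c in t.df.columns for t in tables)]
    per_cycle_only = {
        str(t.cycle): [c for c in t.df.columns if c not in shared] for t in tables
    }
    selected = list(variables) if variables is not None else [c for c in shared]
    if "SEQN" in all_vars and "SEQN" not in selected:
        selected = ["SEQN"] + selected

    mismatches: dict[str, dict[str, list[str]]] = {}
    for var in selected:
        label_sets: dict[str, list[str]] = {}
        for t in tables:
            if var in t.df.columns and isinstance(t.df[var].dtype, pd.CategoricalDtype):
                label_sets[str(t.cycle)] = list(t.df[var].cat.categories)
        if len({tuple(v) for v in label_sets.values()}) > 1:
            mismatches[var] = label_sets
            warnings.warn(f"category labels for {var} differ across cycles: {label_sets}")

    frames = []
    for t in tables:
        missing = [v for v in selected if v not in t.df.columns]
        if missing and strict:
            raise KeyError(
                f"variables {missing} absent from {t.name} (cycle {t.cycle}) under strict alignment"
            )
        sub = t.df.reindex(columns=selected).copy()
        sub["cycle"] = str(t.cycle)
        frames.append(sub)
    stacked = pd.concat(frames, ignore_index=True)
    stacked["cycle"] = pd.Categorical(stacked["cycle"], categories=[str(t.cycle) for t in tables])

    report = AlignmentReport(
        shared_variables=shared,
        per_cycle_only=per_cycle_only,
        category_mismatches=mismatches,
        tables=[(t.name, t.cycle, t.n_rows) for t in tables],
    )
    provenance = {
        "sources": sum((t.provenance.get("sources", [t.name]) for t in tables), []),
        "translated": all(t.provenance.get("translated") for t in tables),
        "cycle": None,
        "stacked": True,
    }
    return DataTable(name="+".join(t.name for t in tables), df=stacked, provenance=provenance), report
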