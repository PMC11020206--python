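"""Synthetic NHANES-dialect fixtures with known ground truth.

Everything downstream (XPT decoding, codebook parsing, translation,
merging, design-based estimation) is testable offline against fixtures
generated here: a finite synthetic population with strata and PSUs, an
informative two-stage sample whose weights are exact inverse inclusion
probabilities, and the corresponding XPT files, codebook HTML pages and
manifest page written in the dialects the real site uses.

The sampling is deliberately informative — minority groups are sampled
at higher rates, as NHANES oversamples them — so the unweighted mean of
the outcome is biased for the population mean while the weighted
(design-based) estimator recovers it. The accompanying truth record
stores the population parameters so estimators can be validated by
parameter recovery.
"""

from __future__ import annotations

import html as html_mod
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .xpt import XptTable, XptVariable, write_xpt

__all__ = [
    "PopulationSpec",
    "ETHNICITY_LABELS",
    "draw_population",
    "draw_sample",
    "generate_demo_like",
    "generate_bpx_like",
    "generate_bpq_like",
    "generate_manifest",
    "install_fixtures",
    "render_codebook_html",
]

#: Reported-ethnicity labels (codes 1-5) as printed in the survey's tables.
ETHNICITY_LABELS = (
    "Mexican American",
    "Other Hispanic",
    "Non-Hispanic White",
    "Non-Hispanic Black",
    "Other race—including multiracial",
)


@dataclass(frozen=True)
class PopulationSpec:
    """Parameters of the synthetic finite population and its sampling design.

    Defaults emulate a masked public-use design: 15 pseudo-strata, 4
    population PSUs each of which 2 are sampled, a diastolic-blood-
    pressure-like outcome (mmHg) with ethnicity-level means, top-coded
    age, a capped income-to-poverty ratio, and a gated questionnaire
    item producing structural skip missingness.
    """

    n_population: int = 24000
    n_strata: int = 15
    psus_per_stratum: int = 4  # population PSUs per stratum
    psus_sampled: int = 2  # first-stage sample per stratum
    ethnicity_probs: tuple = (0.15, 0.10, 0.45, 0.20, 0.10)
    gender_probs: tuple = (0.5, 0.5)
    outcome_means: tuple = (74.0, 73.5, 71.0, 76.0, 74.0)  # per ethnicity, mmHg
    outcome_sd: float = 9.0
    psu_sd: float = 1.5  # PSU-level intercept spread
    age_slope: float = 0.05  # mmHg per year away from 45
    age_low: int = 0
    age_high: int = 95
    age_topcode: int = 80
    pir_cap: float = 5.0
    base_rate: float = 0.12  # second-stage Bernoulli sampling rate
    rate_multipliers: tuple = (2.0, 1.6, 0.55, 1.6, 1.0)  # oversampling by ethnicity
    age_rate_multipliers: tuple = (1.4, 0.8, 1.6)  # oversampling: <20, 20-59, >=60
    gate_yes_prob: float = 0.35  # questionnaire gate prevalence
    followup_probs: tuple = (0.60, 0.35, 0.05)  # Yes / No / Don't know given gate Yes
    gate_missing_rate: float = 0.01  # item nonresponse on the gate itself
    seed: int = 20240

    def validate(self) -> None:
        if abs(sum(self.ethnicity_probs) - 1) > 1e-9 or abs(sum(self.gender_probs) - 1) > 1e-9:
            raise ValueError("group probabilities must sum to 1")
        if self.psus_sampled < 2 or self.psus_sampled > self.psus_per_stratum:
            raise ValueError("need 2 <= psus_sampled <= psus_per_stratum")
        if self.n_population < self.n_strata * self.psus_per_stratum:
            raise ValueError("population too small for the stratum/PSU allocation")
        rates = (
            self.base_rate
            * np.asarray(self.rate_multipliers)[:, None]
            * np.asarray(self.age_rate_multipliers)[None, :]
        )
        if (rates <= 0).any() or (rates > 1).any():
            raise ValueError("per-group sampling rates must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Population and sample


def draw_population(spec: PopulationSpec) -> pd.DataFrame:
    """The synthetic finite population, deterministic in ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_population
    # near-equal allocation of persons to strata, then to PSUs within strata
    stratum = np.repeat(np.arange(1, spec.n_strata + 1), np.diff(np.linspace(0, n, spec.n_strata + 1).astype(int)))
    psu = np.zeros(n, dtype=int)
    for h in range(1, spec.n_strata + 1):
        idx = np.flatnonzero(stratum == h)
        psu[idx] = 1 + (np.arange(len(idx)) % spec.psus_per_stratum)
    eth = rng.choice(np.arange(1, 6), size=n, p=spec.ethnicity_probs)
    gender = rng.choice(np.array([1, 2]), size=n, p=spec.gender_probs)
    age = rng.integers(spec.age_low, spec.age_high + 1, size=n)
    pir_raw = rng.lognormal(mean=0.4, sigma=0.7, size=n)
    pir = np.minimum(np.round(pir_raw, 2), spec.pir_cap)

    psu_effect = {
        (h, j): rng.normal(0.0, spec.psu_sd)
        for h in range(1, spec.n_strata + 1)
        for j in range(1, spec.psus_per_stratum + 1)
    }
    means = np.asarray(spec.outcome_means)[eth - 1]
    y = (
        means
        + spec.age_slope * (age - 45)
        + np.array([psu_effect[(h, j)] for h, j in zip(stratum, psu)])
        + rng.normal(0.0, spec.outcome_sd, size=n)
    )
    age_band = np.where(age < 20, 0, np.where(age < 60, 1, 2))
    rate = (
        spec.base_rate
        * np.asarray(spec.rate_multipliers)[eth - 1]
        * np.asarray(spec.age_rate_multipliers)[age_band]
    )
    return pd.DataFrame(
        {
            "stratum": stratum,
            "psu": psu,
            "gender": gender,
            "eth": eth,
            "age": age,
            "pir": pir,
            "y": np.round(y, 6),
            "rate": rate,
        }
    )


def draw_sample(
    pop: pd.DataFrame, spec: PopulationSpec, rng: np.random.Generator
) -> pd.DataFrame:
    """One two-stage draw: SRS of PSUs per stratum, Bernoulli persons within.

    Weights are exact inverse inclusion probabilities,
    w = (M/m) / rate, with no calibration or nonresponse adjustment.
    """
    keep = np.zeros(len(pop), dtype=bool)
    released_psu = np.zeros(len(pop), dtype=int)
    for h in range(1, spec.n_strata + 1):
        chosen = rng.choice(np.arange(1, spec.psus_per_stratum + 1), size=spec.psus_sampled, replace=False)
        for rank, j in enumerate(sorted(chosen), start=1):
            idx = np.flatnonzero((pop["stratum"].to_numpy() == h) & (pop["psu"].to_numpy() == j))
            keep[idx] = rng.random(len(idx)) < pop["rate"].to_numpy()[idx]
            released_psu[idx] = rank  # masked PSU id 1..m as released
    sample = pop.loc[keep].copy()
    sample["released_psu"] = released_psu[keep]
    sample["weight"] = (spec.psus_per_stratum / spec.psus_sampled) / sample["rate"]
    sample = sample.sort_values(["stratum", "released_psu"]).reset_index(drop=True)
    sample["SEQN"] = np.arange(100001, 100001 + len(sample), dtype=float)
    return sample


def _drawn(spec: PopulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    pop = draw_population(spec)
    rng = np.random.default_rng(spec.seed + 1)
    return pop, draw_sample(pop, spec, rng)


# ---------------------------------------------------------------------------
# Codebook HTML rendering (the modern NHANES doc dialect)


def render_codebook_html(table_name: str, entries: Sequence[dict]) -> str:
    """Render variable blocks + value tables in the anchored-div dialect."""
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'/>",
        f"<title>{table_name} Documentation</title></head><body>",
        f"<h1>{table_name}</h1>",
    ]
    esc = html_mod.escape
    for e in entries:
        parts.append(f"<div class='pagebreak'><h3 id='{esc(e['name'])}'>{esc(e['name'])} - {esc(e['label'])}</h3>")
        parts.append("<dl>")
        for key, val in (
            ("Variable Name:", e["name"]),
            ("SAS Label:", e["label"]),
            ("English Text:", e.get("english", e["label"])),
            ("Target:", e.get("target", "Both males and females 0 YEARS - 150 YEARS")),
        ):
            parts.append(f"<dt>{esc(key)}</dt><dd>{esc(val)}</dd>")
        parts.append("</dl>")
        rows = e.get("rows", [])
        if rows:
            has_skip = any(len(r) > 4 and r[4] for r in rows)
            hdr = "<th>Code or Value</th><th>Value Description</th><th>Count</th><th>Cumulative</th>"
            if has_skip:
                hdr += "<th>Skip to Item</th>"
            parts.append(f"<table class='values'><tr>{hdr}</tr>")
            for r in rows:
                cells = [esc(str(r[0])), esc(str(r[1])), str(r[2]), str(r[3])]
                if has_skip:
                    cells.append(esc(str(r[4])) if len(r) > 4 and r[4] else "")
                parts.append("<tr>" + "".join(f"<td>{c}</td>" for c in cells) + "</tr>")
            parts.append("</table>")
        parts.append("</div>")
    parts.append("</body></html>")
    return "\n".join(parts)


def _count_rows(values: pd.Series, codes: Sequence[tuple]) -> list[list]:
    """Build (code, description, count, cumulative[, skip]) rows with real counts."""
    out: list[list] = []
    cum = 0
    for item in codes:
        code, desc = item[0], item[1]
        skip = item[2] if len(item) > 2 else ""
        if code == ".":
            cnt = int(values.isna().sum())
        elif isinstance(code, str) and " to " in code:
            lo, hi = (float(x) for x in code.split(" to "))
            cnt = int(((values >= lo) & (values <= hi)).sum())
        else:
            cnt = int((values == float(code)).sum())
        cum += cnt
        out.append([code, desc, cnt, cum, skip])
    return out


# ---------------------------------------------------------------------------
# Table generators


def _to_xpt(df: pd.DataFrame, member: str, labels: dict[str, str]) -> XptTable:
    variables = [
        XptVariable(name=c, label=labels.get(c, ""), var_type="numeric", storage_length=8, position=i)
        for i, c in enumerate(df.columns)
    ]
    rows = [
        ["." if pd.isna(v) else float(v) for v in rec]
        for rec in df.itertuples(index=False)
    ]
    return XptTable(member_name=member, variables=variables, rows=rows)


def generate_demo_like(
    spec: PopulationSpec, table_name: str = "DEMO_J"
) -> tuple[XptTable, str, dict]:
    """Demographics-family fixture: ids, gender, ethnicity, age, income ratio,
    and the masked design columns (stratum, PSU, examination weight).

    Returns the XPT table, its codebook HTML, and a truth record holding
    the population parameters the sample was drawn from.
    """
    pop, sample = _drawn(spec)
    df = pd.DataFrame(
        {
            "SEQN": sample["SEQN"],
            "RIAGENDR": sample["gender"].astype(float),
            "RIDRETH1": sample["eth"].astype(float),
            "RIDAGEYR": np.minimum(sample["age"], spec.age_topcode).astype(float),
            "INDFMPIR": sample["pir"].astype(float),
            "SDMVSTRA": sample["stratum"].astype(float),
            "SDMVPSU": sample["released_psu"].astype(float),
            "WTMEC2YR": sample["weight"].astype(float),
        }
    )
    labels = {
        "SEQN": "Respondent sequence number",
        "RIAGENDR": "Gender",
        "RIDRETH1": "Race/Hispanic origin",
        "RIDAGEYR": "Age in years at screening",
        "INDFMPIR": "Ratio of family income to poverty",
        "SDMVSTRA": "Masked variance pseudo-stratum",
        "SDMVPSU": "Masked variance pseudo-PSU",
        "WTMEC2YR": "Full sample 2 year MEC exam weight",
    }
    xpt = _to_xpt(df, table_name, labels)

    age_hi = f"{spec.age_topcode} years of age and over"
    entries = [
        {"name": "SEQN", "label": labels["SEQN"],
         "rows": _count_rows(df["SEQN"], [(f"{df.SEQN.min():.0f} to {df.SEQN.max():.0f}", "Range of Values"), (".", "Missing")])},
        {"name": "RIAGENDR", "label": labels["RIAGENDR"], "english": "Gender of the participant.",
         "rows": _count_rows(df["RIAGENDR"], [(1, "Male"), (2, "Female"), (".", "Missing")])},
        {"name": "RIDRETH1", "label": labels["RIDRETH1"], "english": "Recode of reported race and Hispanic origin.",
         "rows": _count_rows(df["RIDRETH1"], [(i + 1, lab) for i, lab in enumerate(ETHNICITY_LABELS)] + [(".", "Missing")])},
        {"name": "RIDAGEYR", "label": labels["RIDAGEYR"], "english": "Age in years of the participant at the time of screening.",
         "rows": _count_rows(df["RIDAGEYR"], [(f"0 to {spec.age_topcode - 1}", "Range of Values"), (spec.age_topcode, age_hi), (".", "Missing")])},
        {"name": "INDFMPIR", "label": labels["INDFMPIR"], "english": "A ratio of family income to poverty guidelines.",
         "rows": _count_rows(df["INDFMPIR"], [(f"0 to {spec.pir_cap - 0.01:.2f}", "Range of Values"), (spec.pir_cap, f"Value greater than or equal to {spec.pir_cap:.2f}"), (".", "Missing")])},
        {"name": "SDMVSTRA", "label": labels["SDMVSTRA"],
         "rows": _count_rows(df["SDMVSTRA"], [(f"1 to {spec.n_strata}", "Range of Values"), (".", "Missing")])},
        {"name": "SDMVPSU", "label": labels["SDMVPSU"],
         "rows": _count_rows(df["SDMVPSU"], [(f"1 to {spec.psus_sampled}", "Range of Values"), (".", "Missing")])},
        {"name": "WTMEC2YR", "label": labels["WTMEC2YR"],
         "rows": _count_rows(df["WTMEC2YR"], [(f"{df.WTMEC2YR.min():.0f} to {df.WTMEC2YR.max():.0f}".replace(".0 ", " "), "Range of Values"), (".", "Missing")])},
    ]
    html = render_codebook_html(table_name, entries)

    eth_labels = dict(zip(range(1, 6), ETHNICITY_LABELS))
    over40 = pop["age"] > 40
    truth = {
        "seed": spec.seed,
        "n_population": int(len(pop)),
        "n_sample": int(len(sample)),
        "pop_mean_y": float(pop["y"].mean()),
        "pop_mean_y_by_ethnicity": {eth_labels[e]: float(pop.loc[pop.eth == e, "y"].mean()) for e in range(1, 6)},
        "pop_mean_y_over40": float(pop.loc[over40, "y"].mean()),
        "pop_mean_y_over40_by_ethnicity": {
            eth_labels[e]: float(pop.loc[over40 & (pop.eth == e), "y"].mean()) for e in range(1, 6)
        },
        "topcoded_age_rows": int((df["RIDAGEYR"] == spec.age_topcode).sum()),
        "pir_ceiling_rows": int((df["INDFMPIR"] == spec.pir_cap).sum()),
    }
    return xpt, html, truth


def generate_bpx_like(
    spec: PopulationSpec, demo: Optional[XptTable] = None, table_name: str = "BPX_J"
) -> tuple[XptTable, str, dict]:
    """Examination-family fixture carrying the continuous outcome (BPXDI1).

    A small fraction of persons miss the exam entirely and a further
    fraction have a missing reading, mirroring exam nonresponse.
    """
    _, sample = _drawn(spec)
    rng = np.random.default_rng(spec.seed + 2)
    examined = rng.random(len(sample)) >= 0.03
    y = sample["y"].to_numpy().copy()
    y[rng.random(len(sample)) < 0.04] = np.nan
    df = pd.DataFrame({"SEQN": sample["SEQN"], "BPXDI1": np.round(y, 2)}).loc[examined].reset_index(drop=True)
    if demo is not None:
        demo_seqn = {row[0] for row in demo.rows}
        if not set(df["SEQN"]).issubset(demo_seqn):
            raise ValueError("BPX fixture SEQN not a subset of the demo table")
    labels = {"SEQN": "Respondent sequence number", "BPXDI1": "Diastolic: Blood pressure (1st rdg) mmHg"}
    xpt = _to_xpt(df, table_name, labels)
    entries = [
        {"name": "SEQN", "label": labels["SEQN"],
         "rows": _count_rows(df["SEQN"], [(f"{df.SEQN.min():.0f} to {df.SEQN.max():.0f}", "Range of Values"), (".", "Missing")])},
        {"name": "BPXDI1", "label": labels["BPXDI1"], "english": "Diastolic blood pressure, first reading.",
         "rows": _count_rows(df["BPXDI1"], [("0 to 140", "Range of Values"), (".", "Missing")])},
    ]
    truth = {"n_rows": int(len(df)), "n_missing_y": int(df["BPXDI1"].isna().sum())}
    return xpt, render_codebook_html(table_name, entries), truth


def generate_bpq_like(
    spec: PopulationSpec, demo: XptTable, table_name: str = "BPQ_J"
) -> tuple[XptTable, str, dict]:
    """Questionnaire-family fixture with a skip pattern.

    The gate question (ever told high blood pressure) routes "No" and
    "Don't know" respondents past the follow-up (told 2+ times), which
    is therefore structurally missing for exactly those rows; the
    codebook records the routing in its Skip-to-Item column.
    """
    seqn = np.array([row[0] for row in demo.rows], dtype=float)
    n = len(seqn)
    rng = np.random.default_rng(spec.seed + 3)
    gate = np.where(rng.random(n) < spec.gate_yes_prob, 1.0, np.where(rng.random(n) < 0.06, 9.0, 2.0))
    gate[rng.random(n) < spec.gate_missing_rate] = np.nan  # item nonresponse
    followup = np.full(n, np.nan)  # asked only when the gate answer is Yes
    yes = gate == 1.0
    followup[yes] = rng.choice([1.0, 2.0, 9.0], size=int(yes.sum()), p=spec.followup_probs)
    closing = rng.choice([1.0, 2.0], size=n, p=[0.4, 0.6])

    df = pd.DataFrame({"SEQN": seqn, "BPQ020": gate, "BPQ030": followup, "BPQ040A": closing})
    labels = {
        "SEQN": "Respondent sequence number",
        "BPQ020": "Ever told you had high blood pressure",
        "BPQ030": "Told had high blood pressure - 2+ times",
        "BPQ040A": "Taking prescription for hypertension",
    }
    xpt = _to_xpt(df, table_name, labels)
    entries = [
        {"name": "SEQN", "label": labels["SEQN"],
         "rows": _count_rows(df["SEQN"], [(f"{seqn.min():.0f} to {seqn.max():.0f}", "Range of Values"), (".", "Missing")])},
        {"name": "BPQ020", "label": labels["BPQ020"],
         "english": "Has a doctor ever told you that you had high blood pressure?",
         "rows": _count_rows(df["BPQ020"], [(1, "Yes"), (2, "No", "BPQ040A"), (9, "Don't know", "BPQ040A"), (".", "Missing")])},
        {"name": "BPQ030", "label": labels["BPQ030"],
         "english": "Were you told on 2 or more different visits that you had high blood pressure?",
         "rows": _count_rows(df["BPQ030"], [(1, "Yes"), (2, "No"), (9, "Don't know"), (".", "Missing")])},
        {"name": "BPQ040A", "label": labels["BPQ040A"],
         "english": "Are you now taking prescribed medicine for high blood pressure?",
         "rows": _count_rows(df["BPQ040A"], [(1, "Yes"), (2, "No"), (".", "Missing")])},
    ]
    truth = {
        "n_rows": int(n),
        "structural_missing": int(((gate == 2.0) | (gate == 9.0)).sum()),
        "nonstructural_missing": int(np.isnan(gate).sum()),
        "total_missing_followup": int(np.isnan(followup).sum()),
    }
    return xpt, render_codebook_html(table_name, entries), truth


# ---------------------------------------------------------------------------
# Manifest


def generate_manifest(rows: Sequence[dict]) -> str:
    """Render a manifest HTML page; each row dict has name/description/
    component/date and optional years and withdrawn flag."""
    from .catalog import cycle_from_table_name

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'/><title>Data manifest</title></head><body>",
        "<table id='manifest'><tr><th>Table</th><th>Description</th><th>Years</th>"
        "<th>Doc File</th><th>Data File</th><th>Date Published</th><th>Component</th></tr>",
    ]
    esc = html_mod.escape
    for r in rows:
        name = r["name"].upper()
        years = r.get("years") or cycle_from_table_name(name).label
        if r.get("withdrawn"):
            doc = data = "Withdrawn"
        else:
            doc = f"<a href='{name}.htm'>{name} Doc</a>"
            data = f"<a href='{name}.xpt'>{name} Data</a>"
        parts.append(
            "<tr>"
            f"<td>{esc(name)}</td><td>{esc(r.get('description', name))}</td><td>{esc(years)}</td>"
            f"<td>{doc}</td><td>{data}</td><td>{esc(r.get('date', '2020-02-01'))}</td>"
            f"<td>{esc(r.get('component', 'questionnaire'))}</td></tr>"
        )
    parts.append("</table></body></html>")
    return "\n".join(parts)


DEFAULT_MANIFEST_ROWS = [
    {"name": "DEMO", "description": "Demographic Variables", "component": "demographics"},
    {"name": "DEMO_B", "description": "Demographic Variables", "component": "demographics"},
    {"name": "DEMO_C", "description": "Demographic Variables", "component": "demographics"},
    {"name": "P_DEMO", "description": "Demographic Variables (pre-pandemic)", "component": "demographics"},
    {"name": "SSAFB_A", "description": "Aflatoxin B1 (surplus sera)", "component": "laboratory"},
    {"name": "SSOL_A", "description": "Surplus sera (withdrawn)", "component": "laboratory", "withdrawn": True},
    {"name": "DEMO_J", "description": "Demographic Variables and Sample Weights", "component": "demographics"},
    {"name": "BPX_J", "description": "Blood Pressure", "component": "examination"},
    {"name": "BPQ_J", "description": "Blood Pressure & Cholesterol", "component": "questionnaire"},
]


def install_fixtures(cache_dir: str | Path, spec: Optional[PopulationSpec] = None) -> dict:
    """Write the full fixture set into a cache directory.

    Produces DEMO_J/BPX_J/BPQ_J .xpt + .htm files, a manifest page, and a
    truth.json; returns the combined truth record. The files are byte-
    reproducible for a fixed spec.
    """
    spec = spec or PopulationSpec()
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    demo_xpt, demo_html, truth = generate_demo_like(spec)
    bpx_xpt, bpx_html, bpx_truth = generate_bpx_like(spec, demo_xpt)
    bpq_xpt, bpq_html, bpq_truth = generate_bpq_like(spec, demo_xpt)
    for xpt, doc in ((demo_xpt, demo_html), (bpx_xpt, bpx_html), (bpq_xpt, bpq_html)):
        (cache / f"{xpt.member_name}.xpt").write_bytes(write_xpt(xpt))
        (cache / f"{xpt.member_name}.htm").write_text(doc, encoding="utf-8")
    (cache / "manifest.htm").write_text(generate_manifest(DEFAULT_MANIFEST_ROWS), encoding="utf-8")
    truth = {**truth, "bpx": bpx_truth, "bpq": bpq_truth}
    (cache / "truth.json").write_text(json.dumps(truth, indent=1))
    return truth
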