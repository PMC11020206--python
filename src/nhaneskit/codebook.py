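"""Parsing of NHANES-dialect HTML documentation ("codebook") pages.

Every NHANES data table ships with an HTML doc file describing each
variable: its SAS label, the question wording, the target population,
and — for coded variables — a value table mapping integer codes to
descriptions, with per-code respondent counts and optional
"Skip to Item" routing used by the questionnaire logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

from lxml import html as lxml_html

__all__ = [
    "ValueCodeRow",
    "CodebookEntry",
    "Codebook",
    "CodebookParseError",
    "VariableNotFoundError",
    "END_OF_SECTION",
    "parse_codebook",
    "codebook_for_variable",
    "codebook_to_text",
    "codebook_from_text",
]

#: Sentinel for skip targets like "End of Section" (any capitalisation).
END_OF_SECTION = "END_OF_SECTION"


class CodebookParseError(Exception):
    pass


class VariableNotFoundError(KeyError):
    def __init__(self, name: str, suggestions: list[str]):
        self.name = name
        self.suggestions = suggestions
        hint = f"; did you mean {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"variable {name!r} not in codebook{hint}")


@dataclass
class ValueCodeRow:
    code_or_value: str  # "1", "0 to 79", or "." for missing
    description: str  # "Male", "Range of Values", "Missing", ...
    count: int = 0
    cumulative: int = 0
    skip_to: Optional[str] = None  # item name or END_OF_SECTION

    @property
    def is_range(self) -> bool:
        return " to " in self.code_or_value.lower()


@dataclass
class CodebookEntry:
    variable_name: str
    sas_label: str = ""
    english_text: str = ""
    target: str = ""
    value_rows: list[ValueCodeRow] = field(default_factory=list)
    doc_only: bool = False  # CHECK ITEM blocks etc. with no data column


@dataclass
class Codebook:
    table_name: str
    entries: dict[str, CodebookEntry] = field(default_factory=dict)
    source: str = ""

    def __contains__(self, name: str) -> bool:
        return name.upper() in {k.upper() for k in self.entries}

    def variable_names(self) -> list[str]:
        return list(self.entries)


# ---------------------------------------------------------------------------
# HTML parsing


def _clean(text: Optional[str]) -> str:
    return " ".join((text or "").split())


def _lenient_int(text: str, context: str) -> int:
    text = text.replace(",", "").replace(" ", "").strip()
    if not text:
        return 0
    try:
        return int(float(text))
    except ValueError:
        warnings.warn(f"non-numeric count {text!r} in {context}; recorded as 0")
        return 0


def _normalize_skip(text: str) -> Optional[str]:
    text = _clean(text)
    if not text:
        return None
    if text.lower().replace(".", "") == "end of section":
        return END_OF_SECTION
    return text


def _parse_value_table(tbl, varname: str) -> Optional[list[ValueCodeRow]]:
    """Return value rows, or None if the table's headers are unrecognized."""
    header_cells = [
        _clean(th.text_content()).lower() for th in tbl.xpath(".//tr[1]/th | .//tr[1]/td")
    ]
    if not header_cells:
        return None

    def col(*names: str) -> Optional[int]:
        for i, h in enumerate(header_cells):
            if any(n in h for n in names):
                return i
        return None

    c_code = col("code or value")
    c_desc = col("value description", "description")
    if c_code is None or c_desc is None:
        return None
    c_count = col("count")
    c_cum = col("cumulative")
    c_skip = col("skip to item")

    rows: list[ValueCodeRow] = []
    for tr in tbl.xpath(".//tr[position()>1]"):
        cells = [_clean(td.text_content()) for td in tr.xpath("./td | ./th")]
        if not cells or len(cells) <= max(c_code, c_desc):
            continue
        rows.append(
            ValueCodeRow(
                code_or_value=cells[c_code],
                description=cells[c_desc],
                count=_lenient_int(cells[c_count], varname) if c_count is not None and c_count < len(cells) else 0,
                cumulative=_lenient_int(cells[c_cum], varname) if c_cum is not None and c_cum < len(cells) else 0,
                skip_to=_normalize_skip(cells[c_skip]) if c_skip is not None and c_skip < len(cells) else None,
            )
        )
    return rows


def _entry_from_block(block) -> Optional[CodebookEntry]:
    info: dict[str, str] = {}
    for dl in block.xpath(".//dl"):
        dts = dl.xpath("./dt")
        dds = dl.xpath("./dd")
        for dt, dd in zip(dts, dds):
            key = _clean(dt.text_content()).rstrip(":").lower()
            info[key] = _clean(dd.text_content())
    name = info.get("variable name", "")
    if not name:
        title = block.xpath(".//h3 | .//h4")
        if title:
            name = _clean(title[0].text_content()).split(" - ")[0].split()[0]
    if not name:
        return None
    entry = CodebookEntry(
        variable_name=name,
        sas_label=info.get("sas label", ""),
        english_text=info.get("english text", info.get("english instructions", "")),
        target=info.get("target", ""),
    )
    if "check item" in entry.sas_label.lower() or "check item" in entry.english_text.lower():
        entry.doc_only = True
    for tbl in block.xpath(".//table"):
        rows = _parse_value_table(tbl, name)
        if rows is None:
            warnings.warn(f"unrecognized code-table headers for {name}; value rows dropped")
            continue
        entry.value_rows = rows
        break
    return entry


def parse_codebook(document: Union[str, bytes], table_name: str = "", source: str = "") -> Codebook:
    """Parse an NHANES doc page into a :class:`Codebook`.

    Accepts the modern dialect (one anchored block per variable holding a
    definition list plus an optional code table) and falls back to scanning
    bare code tables when no blocks are found.
    """
    if isinstance(document, bytes):
        try:
            document = document.decode("utf-8")
        except UnicodeDecodeError:
            document = document.decode("latin-1")
    root = lxml_html.fromstring(document)

    blocks = root.xpath("//div[contains(@class,'pagebreak')]")
    if not blocks:
        # fallback: any element containing a 'Variable Name' definition list
        blocks = [dl.getparent() for dl in root.xpath("//dl[dt]") if dl.getparent() is not None]
    entries: dict[str, CodebookEntry] = {}
    for block in blocks:
        entry = _entry_from_block(block)
        if entry is not None and entry.variable_name not in entries:
            entries[entry.variable_name] = entry
    if not entries:
        body = _clean(root.text_content())[:200]
        raise CodebookParseError(f"no variable blocks found; body begins: {body!r}")
    if not table_name:
        h1 = root.xpath("//h1 | //title")
        if h1:
            table_name = _clean(h1[0].text_content()).split()[0]
    return Codebook(table_name=table_name, entries=entries, source=source)


# ---------------------------------------------------------------------------
# Lookup


def _edit_distance(a: str, b: str, cap: int = 3) -> int:
    if abs(len(a) - len(b)) > cap:
        return cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def codebook_for_variable(cb: Codebook, name: str) -> CodebookEntry:
    """Case-insensitive entry lookup; unknown names get near-match suggestions."""
    wanted = name.upper()
    for key, entry in cb.entries.items():
        if key.upper() == wanted:
            return entry
    near = [k for k in cb.entries if _edit_distance(k.upper(), wanted, 2) <= 2]
    raise VariableNotFoundError(name, sorted(near))


# ---------------------------------------------------------------------------
# Text serialization (cache format)

_ESC = {"\\": "\\\\", "|": "\\p", "\n": "\\n"}
_UNESC = {"\\\\": "\\", "\\p": "|", "\\n": "\n"}


def _esc(s: str) -> str:
    for k, v in _ESC.items():
        s = s.replace(k, v)
    return s


def _unesc(s: str) -> str:
    out, i = [], 0
    while i < len(s):
        if s[i] == "\\" and i + 1 < len(s):
            out.append(_UNESC.get(s[i : i + 2], s[i + 1]))
            i += 2
        else:
            out.append(s[i])
            i += 1
    return "".join(out)


def codebook_to_text(cb: Codebook) -> str:
    """Serialize to the plain-text cache format (one file per table)."""
    lines = ["# nhaneskit codebook v1", f"table: {cb.table_name}", f"source: {cb.source}", ""]
    for entry in cb.entries.values():
        lines.append(f"[{entry.variable_name}]")
        lines.append(f"sas_label: {_esc(entry.sas_label)}")
        lines.append(f"english_text: {_esc(entry.english_text)}")
        lines.append(f"target: {_esc(entry.target)}")
        lines.append(f"doc_only: {str(entry.doc_only).lower()}")
        for r in entry.value_rows:
            skip = _esc(r.skip_to) if r.skip_to else ""
            lines.append(
                f"row: {_esc(r.code_or_value)} | {_esc(r.description)} | {r.count} | {r.cumulative} | {skip}"
            )
        lines.append("")
    return "\n".join(lines)


def codebook_from_text(text: str) -> Codebook:
    """Inverse of :func:`codebook_to_text`."""
    cb = Codebook(table_name="")
    entry: Optional[CodebookEntry] = None
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            entry = CodebookEntry(variable_name=line[1:-1])
            cb.entries[entry.variable_name] = entry
            continue
        key, _, value = line.partition(":")
        key = key.strip()
        if value.startswith(" "):
            value = value[1:]  # exactly one separator space; cell text may be blank
        if entry is None:
            if key == "table":
                cb.table_name = value
            elif key == "source":
                cb.source = value
            continue
        if key == "sas_label":
            entry.sas_label = _unesc(value)
        elif key == "english_text":
            entry.english_text = _unesc(value)
        elif key == "target":
            entry.target = _unesc(value)
        elif key == "doc_only":
            entry.doc_only = value == "true"
        elif key == "row":
            parts = [p.strip() for p in value.split(" | ")]
            parts += [""] * (5 - len(parts))
            entry.value_rows.append(
                ValueCodeRow(
                    code_or_value=_unesc(parts[0]),
                    description=_unesc(parts[1]),
                    count=int(parts[2] or 0),
                    cumulative=int(parts[3] or 0),
                    skip_to=_unesc(parts[4]) or None,
                )
            )
    return cb
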