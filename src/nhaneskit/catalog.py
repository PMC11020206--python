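"""Table-name conventions, manifest parsing, search, and cached retrieval.

Continuous NHANES releases data in 2-year cycles. Table names carry a
cycle suffix (_B for 2001-2002, _C for 2003-2004, ...); the inaugural
1999-2000 cycle mostly omits the _A suffix, a few tables (SSAFB_A,
SSOL_A) keep it, and the combined pre-pandemic 2017-March 2020 release
uses a P_ prefix instead. These conventions are not perfectly uniform,
so the suffix rule is backed by an extensible overrides list and
unparseable names raise instead of guessing.
"""

from __future__ import annotations

import hashlib
import logging
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from lxml import html as lxml_html

from .codebook import Codebook, parse_codebook
from .config import Config
from .xpt import XptTable, read_xpt

__all__ = [
    "Cycle",
    "TableRecord",
    "VariableRecord",
    "COMPONENTS",
    "ClassificationError",
    "ManifestParseError",
    "CacheMissError",
    "FetchError",
    "cycle_from_table_name",
    "parse_manifest",
    "search_table_names",
    "search_variables",
    "search_tables_by_variable",
    "build_variable_index",
    "fetch_table",
    "fetch_codebook",
    "DEFAULT_OVERRIDES",
]

logger = logging.getLogger(__name__)

COMPONENTS = ("demographics", "dietary", "examination", "laboratory", "questionnaire")


class ClassificationError(ValueError):
    """A table name that cannot be mapped to a cycle."""


class ManifestParseError(Exception):
    pass


class CacheMissError(FileNotFoundError):
    pass


class FetchError(Exception):
    def __init__(self, url: str, status: Optional[int], msg: str):
        self.url, self.status = url, status
        super().__init__(f"fetch of {url} failed ({msg}); retriable")


@dataclass(frozen=True)
class Cycle:
    start_year: int
    end_year: int
    suffix_letter: Optional[str] = None
    prepandemic: bool = False

    @property
    def label(self) -> str:
        if self.prepandemic:
            return "2017-March 2020"
        return f"{self.start_year}-{self.end_year}"

    @property
    def url_years(self) -> str:
        # pre-pandemic files live under the 2017-2018 path on the CDC server
        if self.prepandemic:
            return "2017-2018"
        return f"{self.start_year}-{self.end_year}"


@dataclass
class TableRecord:
    table_name: str
    description: str
    cycle: Cycle
    data_url: str = ""
    doc_url: str = ""
    date_published: str = ""
    component: Optional[str] = None


@dataclass
class VariableRecord:
    variable_name: str
    description: str
    table_name: str
    begin_year: int
    end_year: int
    component: str

    def __post_init__(self):
        if self.component not in COMPONENTS:
            raise ValueError(f"component {self.component!r} not in {COMPONENTS}")


#: Irregularly named tables mapped to cycles directly (user-extensible).
DEFAULT_OVERRIDES: dict[str, Cycle] = {
    "DEMO": Cycle(1999, 2000),
    "SSAFB_A": Cycle(1999, 2000, "A"),
    "SSOL_A": Cycle(1999, 2000, "A"),
}

_NAME_RE = re.compile(r"^[A-Z][A-Z0-9]*(?:_[A-Z0-9]+)*$")


def cycle_from_table_name(
    name: str, overrides: Optional[dict[str, Cycle]] = None
) -> Cycle:
    """Map a table name to its survey cycle via suffix conventions.

    Suffix letter L at alphabet position k means start year 1999 + 2(k-1);
    no suffix means 1999-2000; a P_ prefix means the pre-pandemic combined
    2017-March 2020 release. Overrides are consulted first; anything else
    raises :class:`ClassificationError` rather than guessing.
    """
    lookup = dict(DEFAULT_OVERRIDES)
    if overrides:
        lookup.update(overrides)
    key = name.strip().upper()
    if key in lookup:
        return lookup[key]
    if not key or not _NAME_RE.match(key):
        raise ClassificationError(f"cannot classify table name {name!r}")
    if key.startswith("P_"):
        return Cycle(2017, 2020, None, prepandemic=True)
    m = re.search(r"_([A-Z])$", key)
    if m is None:
        if key.endswith("_"):
            raise ClassificationError(f"cannot classify table name {name!r}")
        return Cycle(1999, 2000)
    letter = m.group(1)
    k = ord(letter) - ord("A")  # A -> 0
    start = 1999 + 2 * k
    return Cycle(start, start + 1, letter)


# ---------------------------------------------------------------------------
# Manifest parsing


def _clean(s: str) -> str:
    return " ".join((s or "").split())


def parse_manifest(
    document: Union[str, bytes],
    overrides: Optional[dict[str, Cycle]] = None,
) -> list[TableRecord]:
    """Parse an HTML manifest listing data files into :class:`TableRecord` s.

    Rows whose data link is withdrawn or limited-access are excluded (and
    logged); duplicate table names are an error.
    """
    if isinstance(document, bytes):
        document = document.decode("utf-8", "replace")
    root = lxml_html.fromstring(document)
    table = None
    header: list[str] = []
    for tbl in root.xpath("//table"):
        hdr = [_clean(th.text_content()).lower() for th in tbl.xpath(".//tr[1]/th | .//tr[1]/td")]
        if any("doc" in h for h in hdr) and any("data" in h for h in hdr):
            table, header = tbl, hdr
            break
    if table is None:
        raise ManifestParseError("no manifest table found in document")

    def col(*names: str) -> Optional[int]:
        for i, h in enumerate(header):
            if any(n in h for n in names):
                return i
        return None

    c_name = col("table", "data file name", "name")
    c_desc = col("description")
    c_years = col("year")
    c_doc = col("doc")
    c_data = col("data file", "data")
    c_date = col("date published", "published")
    c_comp = col("component")
    if c_name is None or c_data is None:
        raise ManifestParseError(f"unrecognized manifest headers: {header}")

    records: list[TableRecord] = []
    seen: set[str] = set()
    for tr in table.xpath(".//tr[position()>1]"):
        cells = tr.xpath("./td | ./th")
        if len(cells) <= max(i for i in (c_name, c_data) if i is not None):
            continue
        texts = [_clean(c.text_content()) for c in cells]
        raw_name = texts[c_name]
        name = raw_name.split()[0].upper() if raw_name else ""
        if not name:
            continue
        data_text = texts[c_data]
        if re.search(r"withdrawn|rdc only|limited access|not available", data_text, re.I):
            logger.info("manifest row %s excluded: %s", name, data_text)
            continue
        if name in seen:
            raise ManifestParseError(f"duplicate table name {name} in manifest")
        seen.add(name)

        def href(idx: Optional[int]) -> str:
            if idx is None or idx >= len(cells):
                return ""
            links = cells[idx].xpath(".//a/@href")
            return links[0] if links else ""

        records.append(
            TableRecord(
                table_name=name,
                description=texts[c_desc] if c_desc is not None and c_desc < len(texts) else raw_name,
                cycle=cycle_from_table_name(name, overrides),
                data_url=href(c_data),
                doc_url=href(c_doc),
                date_published=texts[c_date] if c_date is not None and c_date < len(texts) else "",
                component=texts[c_comp].lower() if c_comp is not None and c_comp < len(texts) and texts[c_comp] else None,
            )
        )
    if not records:
        raise ManifestParseError("manifest contains zero data rows")
    return records


# ---------------------------------------------------------------------------
# Search


def search_table_names(
    pattern: str,
    manifest: Sequence[TableRecord],
    details: bool = False,
    regex: bool = False,
) -> list:
    """Case-insensitive substring (or regex) match over manifest table names."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if regex:
        rx = re.compile(pattern, re.I)
        hits = [r for r in manifest if rx.search(r.table_name)]
    else:
        pat = pattern.upper()
        hits = [r for r in manifest if pat in r.table_name.upper()]
    return hits if details else [r.table_name for r in hits]


def search_variables(
    pattern: str,
    index: Sequence[VariableRecord],
    fields: Sequence[str] = ("description",),
    component: Optional[str] = None,
    regex: bool = False,
) -> list[VariableRecord]:
    """Match a pattern against variable descriptions and/or names."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if regex:
        rx = re.compile(pattern, re.I)
        match = rx.search
    else:
        pat = pattern.lower()
        match = lambda s: pat in s.lower()  # noqa: E731
    out = []
    for rec in index:
        if component is not None and rec.component != component:
            continue
        haystacks = []
        if "description" in fields:
            haystacks.append(rec.description)
        if "variable_name" in fields or "name" in fields:
            haystacks.append(rec.variable_name)
        if any(match(h) for h in haystacks):
            out.append(rec)
    return out


def search_tables_by_variable(
    varname: str, index: Sequence[VariableRecord]
) -> list[VariableRecord]:
    """Exact (case-insensitive) variable-name match, sorted by cycle start year."""
    wanted = varname.upper()
    hits = [r for r in index if r.variable_name.upper() == wanted]
    return sorted(hits, key=lambda r: (r.begin_year, r.table_name))


def build_variable_index(
    manifest: Sequence[TableRecord],
    codebooks: dict[str, Codebook],
    default_component: str = "questionnaire",
) -> list[VariableRecord]:
    """Assemble the searchable variable index from manifests plus codebooks."""
    index: list[VariableRecord] = []
    for rec in manifest:
        cb = codebooks.get(rec.table_name)
        if cb is None:
            continue
        for name, entry in cb.entries.items():
            index.append(
                VariableRecord(
                    variable_name=name,
                    description=entry.sas_label or entry.english_text,
                    table_name=rec.table_name,
                    begin_year=rec.cycle.start_year,
                    end_year=rec.cycle.end_year,
                    component=rec.component or default_component,
                )
            )
    return index


# ---------------------------------------------------------------------------
# Retrieval


def _download(url: str, dest: Path) -> None:
    try:
        with urllib.request.urlopen(url, timeout=60) as resp:
            payload = resp.read()
    except urllib.error.HTTPError as e:
        raise FetchError(url, e.code, f"HTTP {e.code}") from e
    except urllib.error.URLError as e:
        raise FetchError(url, None, str(e.reason)) from e
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_bytes(payload)
    dest.with_suffix(dest.suffix + ".sha256").write_text(
        hashlib.sha256(payload).hexdigest() + "\n"
    )


def _cached_fetch(
    name: str, ext: str, config: Config, offline: Optional[bool]
) -> Path:
    name = name.upper()
    offline = config.offline if offline is None else offline
    path = Path(config.cache_dir) / f"{name}.{ext}"
    if path.exists():
        return path
    if offline:
        raise CacheMissError(
            f"{name}.{ext} not cached and offline mode forbids download; expected {path}"
        )
    cycle = cycle_from_table_name(name)
    url = config.base_url.format(years=cycle.url_years, table=name, ext=ext.upper() if ext == "xpt" else ext)
    logger.info("downloading %s -> %s", url, path)
    _download(url, path)
    return path


def fetch_table(
    name: str,
    config: Optional[Config] = None,
    offline: Optional[bool] = None,
) -> XptTable:
    """Return the decoded XPT table, downloading into the cache if permitted."""
    config = config or Config()
    path = _cached_fetch(name, "xpt", config, offline)
    return read_xpt(path.read_bytes())


def fetch_codebook(
    name: str,
    config: Optional[Config] = None,
    offline: Optional[bool] = None,
) -> Codebook:
    """Return the parsed codebook for a table, via the same cache."""
    config = config or Config()
    path = _cached_fetch(name, "htm", config, offline)
    return parse_codebook(path.read_bytes(), table_name=name.upper(), source=str(path))
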