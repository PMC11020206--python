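"""Parse a codebook page and search a table manifest, fully offline.

Generates the synthetic fixture set into a cache directory, then uses the
same parsing/search paths that real downloaded pages go through.
"""

import tempfile
from pathlib import Path

from nhaneskit.catalog import cycle_from_table_name, parse_manifest, search_table_names
from nhaneskit.codebook import codebook_for_variable
from nhaneskit.config import Config
from nhaneskit.catalog import fetch_codebook
from nhaneskit.fixtures import install_fixtures

cache = Path(tempfile.mkdtemp())
truth = install_fixtures(cache)
cfg = Config(cache_dir=cache, offline=True)

manifest = parse_manifest((cache / "manifest.htm").read_text())
print("tables matching 'DEMO':", search_table_names("DEMO", manifest))
for name in ("DEMO", "DEMO_C", "SSAFB_A", "P_DEMO"):
    print(f"  {name:<8} -> cycle {cycle_from_table_name(name).label}")
# The suffix letter advances two years per cycle; DEMO (no suffix) is the
# inaugural 1999-2000 release and P_ marks the combined 2017-March 2020 one.

cb = fetch_codebook("DEMO_J", cfg)
entry = codebook_for_variable(cb, "riagendr")  # lookup is case-insensitive
print(f"\n{entry.variable_name}: {entry.sas_label}")
for row in entry.value_rows:
    print(f"  code {row.code_or_value or '(blank)':>2} -> {row.description:<8} (count {row.count})")
# The counts come from the generated sample, so they sum to the row count.
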