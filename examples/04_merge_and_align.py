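"""Join tables on SEQN within a cycle; stack across cycles with guards."""

import tempfile
from pathlib import Path

import pandas as pd

from nhaneskit.assemble import PrepandemicGuardError, align_across_cycles, merge_within_cycle
from nhaneskit.catalog import fetch_codebook, fetch_table
from nhaneskit.config import Config
from nhaneskit.fixtures import install_fixtures
from nhaneskit.translate import DataTable, translate_table

cache = Path(tempfile.mkdtemp())
install_fixtures(cache)
cfg = Config(cache_dir=cache, offline=True)

demo = translate_table(fetch_table("DEMO_J", cfg), fetch_codebook("DEMO_J", cfg))
bpx = translate_table(fetch_table("BPX_J", cfg), fetch_codebook("BPX_J", cfg))
merged = merge_within_cycle(demo, bpx, join="full")
print(f"demographics {demo.n_rows} rows + exam {bpx.n_rows} rows "
      f"-> full join {merged.n_rows} rows (the SEQN union)")

def fake_cycle(name, cycle, n):
    df = demo.df[["SEQN", "RIAGENDR"]].head(n).copy()
    return DataTable(name, df, {"translated": True, "cycle": cycle})

a, b, c = fake_cycle("DEMO", "1999-2000", 100), fake_cycle("DEMO_B", "2001-2002", 120), fake_cycle("DEMO_C", "2003-2004", 80)
stacked, report = align_across_cycles([a, b, c], variables=["RIAGENDR"])
print(f"stacked {[t[2] for t in report.tables]} rows -> {stacked.n_rows} with a cycle column:")
print(stacked.df["cycle"].value_counts(sort=False).to_string())

p = fake_cycle("P_DEMO", "2017-March 2020", 10)
try:
    align_across_cycles([p, a])
except PrepandemicGuardError as e:
    print(f"\npre-pandemic guard: {e}")
# The combined 2017-March 2020 release carries special weights, so mixing
# it with regular cycles is an error unless explicitly overridden.
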