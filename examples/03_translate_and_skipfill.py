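"""Translate integer codes to labels, fill skip-pattern missingness, and
flag top-coded (coarsened) variables.
"""

import tempfile
from pathlib import Path

from nhaneskit.catalog import fetch_codebook, fetch_table
from nhaneskit.config import Config
from nhaneskit.fixtures import install_fixtures
from nhaneskit.translate import SkipFillRule, apply_skip_fill, flag_coarsened, suggest_skip_rules, translate_table

cache = Path(tempfile.mkdtemp())
install_fixtures(cache)
cfg = Config(cache_dir=cache, offline=True)

demo = translate_table(fetch_table("DEMO_J", cfg), fetch_codebook("DEMO_J", cfg))
print(demo.df[["SEQN", "RIAGENDR", "RIDRETH1", "RIDAGEYR"]].head(4).to_string(index=False))
# Gender/ethnicity arrive as integer codes in the raw XPT; after translation
# they are labeled categoricals whose category order follows the codebook,
# so ordinal variables stay ordinal in downstream models.

bpq_cb = fetch_codebook("BPQ_J", cfg)
bpq = translate_table(fetch_table("BPQ_J", cfg), bpq_cb)
print("\nsuggested skip rules from the codebook's Skip-to-Item links:")
for s in suggest_skip_rules(bpq_cb):
    print(" ", s)

before = int(bpq.df["BPQ030"].isna().sum())
filled = apply_skip_fill(bpq, bpq_cb, [SkipFillRule("BPQ020", ("No", "Don't know"), "BPQ030", "No")])
after = int(filled.df["BPQ030"].isna().sum())
print(f"follow-up missing before fill: {before}; after: {after} "
      f"(filled {filled.provenance['skip_fill']['BPQ020->BPQ030']} structurally skipped cells)")
# Respondents routed past the follow-up are filled in as 'No'; the few
# remaining missings are genuine item nonresponse on the gate.

demo_raw = translate_table(fetch_table("DEMO_J", cfg), fetch_codebook("DEMO_J", cfg), translated=False)
for f in flag_coarsened(demo_raw, fetch_codebook("DEMO_J", cfg)):
    print(f"coarsened: {f.variable} recorded as {f.code_value:g} for {f.count} rows ({f.description})")
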