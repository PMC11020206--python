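"""Raw vs adjusted diastolic blood pressure by ethnicity, real 2017-2018 data.

Requires network access on first run: downloads DEMO_J (demographics,
design columns) and BPX_J (blood pressure exam) from the CDC server into
the cache, then reproduces the published comparison for ages over 40.
"""

from nhaneskit.config import Config
from nhaneskit.recipes import blood_pressure_by_ethnicity

cfg = Config(offline=False)  # cache defaults to ~/.cache/nhaneskit
result = blood_pressure_by_ethnicity(cfg, demo_table="DEMO_J", bpx_table="BPX_J")
print(result)
# The gap between the raw and adjusted columns is what ignoring the survey
# weights costs: subgroups are deliberately oversampled, so unweighted
# means do not estimate population means.
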