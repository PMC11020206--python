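"""End-to-end worked analyses combining the toolkit's pieces.

The flagship recipe reproduces the classic raw-vs-adjusted comparison:
merge a cycle's demographics (design columns, ethnicity, age) with its
blood-pressure exam, restrict to respondents over 40, and contrast the
unweighted per-ethnicity mean of first diastolic pressure with the
design-based (weighted, Taylor-linearized) estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .assemble import merge_within_cycle
from .catalog import fetch_codebook, fetch_table
from .config import Config
from .survey import make_design, naive_mean_by, subset_design, svy_mean, svy_mean_by
from .translate import translate_table

__all__ = ["BloodPressureResult", "blood_pressure_by_ethnicity"]


@dataclass
class BloodPressureResult:
    table: pd.DataFrame  # per-group: raw mean, adjusted mean, SE, n
    overall_adjusted: float
    overall_se: float
    age_rule: str  # 'strict (>40)' or 'inclusive (>=40)'

    def __str__(self) -> str:
        lines = [f"{'Group':<34}{'Raw':>10}{'Adjusted':>11}{'SE':>10}{'n':>7}"]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['group']:<34}{r['raw_mean']:>10.5f}{r['adj_mean']:>11.5f}"
                f"{r['se']:>10.5f}{int(r['n']):>7d}"
            )
        lines.append(
            f"overall adjusted mean {self.overall_adjusted:.5f} (SE {self.overall_se:.5f}); "
            f"age rule: {self.age_rule}"
        )
        return "\n".join(lines)


def blood_pressure_by_ethnicity(
    config: Optional[Config] = None,
    demo_table: str = "DEMO_J",
    bpx_table: str = "BPX_J",
    y: str = "BPXDI1",
    group: str = "RIDRETH1",
    age_var: str = "RIDAGEYR",
    age_over: float = 40,
    inclusive: bool = False,
    offline: Optional[bool] = None,
) -> BloodPressureResult:
    """Raw vs design-adjusted mean of ``y`` by ``group`` for ages over ``age_over``.

    The survey design (strata/PSU/weight columns named in ``config``) is
    frozen on the *full* merged table before the age restriction, which is
    applied as a domain mask. The unweighted comparison deliberately uses
    the naive row subset instead.
    """
    config = config or Config()
    demo = translate_table(fetch_table(demo_table, config, offline), fetch_codebook(demo_table, config, offline))
    bpx = translate_table(fetch_table(bpx_table, config, offline), fetch_codebook(bpx_table, config, offline))
    merged = merge_within_cycle(demo, bpx, join="full")

    design = make_design(
        merged, config.strata_var, config.psu_var, config.weight_var, lonely_psu="centered"
    )
    age = pd.to_numeric(design.df[age_var], errors="coerce")
    mask = (age >= age_over) if inclusive else (age > age_over)
    mask = (mask & age.notna()).to_numpy()
    domain = subset_design(design, mask)

    raw = naive_mean_by(design.df.loc[mask], y, group)
    adj = svy_mean_by(domain, y, group)
    overall = svy_mean(domain, y)
    rows = []
    for (g, m, n), est in zip(raw, adj):
        rows.append({"group": g, "raw_mean": m, "adj_mean": est.estimate, "se": est.se, "n": est.n_obs})
    return BloodPressureResult(
        table=pd.DataFrame(rows),
        overall_adjusted=overall.estimate,
        overall_se=overall.se,
        age_rule="inclusive (>=%g)" % age_over if inclusive else "strict (>%g)" % age_over,
    )
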