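"""Design-based estimation for stratified, clustered, weighted samples.

NHANES draws a stratified multi-stage cluster sample and releases
masked pseudo-strata, pseudo-PSUs and person-level weights w_i (the
number of population members each respondent represents). A valid
population estimate weights by w_i, and a valid standard error must
respect the clustering: this module implements the weighted (ratio)
mean with Taylor-linearized variance under the with-replacement
first-stage approximation,

    ybar_w = sum_D w_i y_i / sum_D w_i,
    u_i    = w_i (y_i - ybar_w) / W          (i in domain D, else 0),
    z_hj   = sum over PSU j of stratum h of u_i,
    Var    = sum_h n_h/(n_h - 1) * sum_j (z_hj - zbar_h)^2,

where n_h counts the PSUs of the FULL design. Subpopulation ("domain")
estimates therefore keep every row: subsetting edits only a mask, never
the stratum/PSU census — deleting rows first would understate the
variance by dropping PSUs whose domain contribution is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .translate import DataTable

__all__ = [
    "SurveyDesign",
    "EstimateResult",
    "LonelyPsuError",
    "EmptyDomainError",
    "make_design",
    "subset_design",
    "svy_mean",
    "svy_mean_by",
    "naive_mean",
    "naive_mean_by",
]


class LonelyPsuError(ValueError):
    """A stratum with a single PSU has no between-PSU variance estimate."""


class EmptyDomainError(ValueError):
    pass


@dataclass
class EstimateResult:
    estimate: float
    se: float
    n_obs: int
    group_label: Optional[str] = None

    @property
    def empty(self) -> bool:
        return self.n_obs == 0


@dataclass
class SurveyDesign:
    """Frozen design: data plus strata/PSU/weight columns and a domain mask."""

    df: pd.DataFrame
    strata_var: str
    psu_var: str
    weight_var: str
    nested: bool = True
    lonely_psu: str = "error"  # 'error' | 'centered' | 'certainty'
    domain_mask: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_psu_cells(self) -> int:
        return self._cells().nunique()

    def _cells(self) -> pd.Series:
        s = self.df[self.strata_var].astype(str)
        p = self.df[self.psu_var].astype(str)
        return s + "\x1f" + p


def make_design(
    data: Union[DataTable, pd.DataFrame],
    strata_var: str,
    psu_var: str,
    weight_var: str,
    nested: bool = True,
    lonely_psu: str = "error",
) -> SurveyDesign:
    """Freeze the survey design over the *full* dataset.

    Must be called before any subsetting: the stratum/PSU census recorded
    here is what variance estimation uses, whatever domain is analyzed
    later. Rows with missing weight are dropped (counted, warned); a
    nonpositive weight is an error, as is a repeated PSU id across strata
    when ``nested=False``.
    """
    df = data.df if isinstance(data, DataTable) else data
    for col in (strata_var, psu_var, weight_var):
        if col not in df.columns:
            raise KeyError(f"design column {col} not in data")
    if lonely_psu not in ("error", "centered", "certainty"):
        raise ValueError(f"unknown lonely-PSU policy {lonely_psu!r}")
    w = pd.to_numeric(df[weight_var], errors="coerce")
    n_missing = int(w.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} rows with missing weight excluded from the design")
        df = df.loc[~w.isna()].reset_index(drop=True)
        w = w.dropna().reset_index(drop=True)
    if (w <= 0).any():
        raise ValueError(f"{int((w <= 0).sum())} rows have nonpositive weight")
    if df[strata_var].isna().any() or df[psu_var].isna().any():
        raise ValueError("missing stratum or PSU identifiers")
    if not nested:
        psu_strata = df.groupby(df[psu_var].astype(str))[strata_var].nunique()
        repeated = psu_strata[psu_strata > 1]
        if len(repeated):
            raise ValueError(
                f"PSU ids {list(repeated.index)[:5]} repeat across strata; "
                "set nested=True if PSU ids are nested within strata"
            )
    design = SurveyDesign(
        df=df.reset_index(drop=True),
        strata_var=strata_var,
        psu_var=psu_var,
        weight_var=weight_var,
        nested=nested,
        lonely_psu=lonely_psu,
        domain_mask=np.ones(len(df), dtype=bool),
    )
    if lonely_psu == "error":
        counts = design.df.groupby(design.df[strata_var].astype(str))[psu_var].nunique()
        lonely = counts[counts < 2]
        if len(lonely):
            raise LonelyPsuError(
                f"strata {list(lonely.index)[:5]} contain a single PSU; choose a "
                "lonely_psu policy ('centered' or 'certainty') or collapse strata"
            )
    return design


def subset_design(
    design: SurveyDesign,
    predicate: Union[Callable[[pd.DataFrame], pd.Series], np.ndarray, pd.Series],
) -> SurveyDesign:
    """Restrict the analysis domain without touching the design structure."""
    if callable(predicate):
        mask = np.asarray(predicate(design.df), dtype=bool)
    else:
        mask = np.asarray(predicate, dtype=bool)
    if mask.shape != design.domain_mask.shape:
        raise ValueError("predicate mask length differs from design rows")
    new_mask = design.domain_mask & mask
    if not new_mask.any():
        raise EmptyDomainError("predicate selects zero rows of the domain")
    return replace(design, domain_mask=new_mask)


def _taylor_variance(design: SurveyDesign, u: np.ndarray) -> float:
    """Between-PSU variance of the score totals, stratum by stratum."""
    df = design.df
    cells = pd.DataFrame(
        {
            "h": df[design.strata_var].astype(str),
            "cell": design._cells(),
            "u": u,
        }
    )
    z = cells.groupby(["h", "cell"], sort=True)["u"].sum()  # all PSUs, zero scores included
    grand_mean = float(z.mean())
    variance = 0.0
    for h, zh in z.groupby(level="h"):
        zh = zh.to_numpy()
        n_h = len(zh)
        if n_h == 1:
            if design.lonely_psu == "certainty":
                continue
            if design.lonely_psu == "centered":
                variance += float((zh[0] - grand_mean) ** 2)
                continue
            raise LonelyPsuError(f"stratum {h} has a single PSU")
        variance += n_h / (n_h - 1) * float(((zh - zh.mean()) ** 2).sum())
    return variance


def svy_mean(
    design: SurveyDesign, y: str, group_label: Optional[str] = None
) -> EstimateResult:
    """Design-based mean of a numeric column over the current domain."""
    if y not in design.df.columns:
        raise KeyError(f"column {y} not in design data")
    yv = pd.to_numeric(design.df[y], errors="coerce").to_numpy(dtype=float)
    w = pd.to_numeric(design.df[design.weight_var], errors="coerce").to_numpy(dtype=float)
    in_domain = design.domain_mask & ~np.isnan(yv)
    n_obs = int(in_domain.sum())
    if n_obs == 0:
        raise EmptyDomainError(f"no in-domain rows with non-missing {y}")
    W = float(w[in_domain].sum())
    estimate = float((w[in_domain] * yv[in_domain]).sum() / W)
    u = np.zeros(len(yv))
    u[in_domain] = w[in_domain] * (yv[in_domain] - estimate) / W
    variance = _taylor_variance(design, u)
    return EstimateResult(estimate=estimate, se=float(np.sqrt(variance)), n_obs=n_obs, group_label=group_label)


def svy_mean_by(design: SurveyDesign, y: str, group: str) -> list[EstimateResult]:
    """Domain mean of ``y`` for each category of ``group`` (category order)."""
    col = design.df[group]
    if isinstance(col.dtype, pd.CategoricalDtype):
        categories = list(col.cat.categories)
    else:
        categories = sorted(col.dropna().unique())
    results = []
    for g in categories:
        mask = (col == g).to_numpy()
        try:
            sub = subset_design(design, mask)
            results.append(svy_mean(sub, y, group_label=str(g)))
        except (EmptyDomainError,):
            results.append(EstimateResult(np.nan, np.nan, 0, group_label=str(g)))
    return results


def naive_mean(data: Union[DataTable, pd.DataFrame], y: str) -> tuple[float, int]:
    """Unweighted mean ignoring the survey design (for contrast only)."""
    df = data.df if isinstance(data, DataTable) else data
    yv = pd.to_numeric(df[y], errors="coerce")
    return float(yv.mean()), int(yv.notna().sum())


def naive_mean_by(
    data: Union[DataTable, pd.DataFrame], y: str, group: str
) -> list[tuple[str, float, int]]:
    """Per-category unweighted means, in category order."""
    df = data.df if isinstance(data, DataTable) else data
    col = df[group]
    if isinstance(col.dtype, pd.CategoricalDtype):
        categories = list(col.cat.categories)
    else:
        categories = sorted(col.dropna().unique())
    out = []
    for g in categories:
        sub = df.loc[col == g]
        yv = pd.to_numeric(sub[y], errors="coerce")
        out.append((str(g), float(yv.mean()) if yv.notna().any() else float("nan"), int(yv.notna().sum())))
    return out
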