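"""Design-based estimation: closed forms, brute-force oracle, invariances."""

import math

import numpy as np
import pandas as pd
import pytest

from nhaneskit.survey import (
    EmptyDomainError,
    LonelyPsuError,
    make_design,
    naive_mean_by,
    subset_design,
    svy_mean,
    svy_mean_by,
)


def brute_force_mean_and_variance(df, strata, psu, weight, y, mask=None):
    """Independent term-by-term evaluation of the linearized variance.

    Deliberately written with explicit Python loops and dictionaries,
    sharing no code with the implementation under test.
    """
    n = len(df)
    mask = [True] * n if mask is None else list(mask)
    rows = []
    for i in range(n):
        yi = df[y].iloc[i]
        rows.append(
            {
                "h": str(df[strata].iloc[i]),
                "j": str(df[psu].iloc[i]),
                "w": float(df[weight].iloc[i]),
                "y": float(yi) if yi == yi else None,
                "in": bool(mask[i]),
            }
        )
    W = sum(r["w"] for r in rows if r["in"] and r["y"] is not None)
    est = sum(r["w"] * r["y"] for r in rows if r["in"] and r["y"] is not None) / W
    z: dict[tuple, float] = {}
    for r in rows:
        cell = (r["h"], r["j"])
        u = r["w"] * (r["y"] - est) / W if (r["in"] and r["y"] is not None) else 0.0
        z[cell] = z.get(cell, 0.0) + u
    strata_ids = sorted({h for h, _ in z})
    var = 0.0
    for h in strata_ids:
        zs = [v for (hh, _), v in z.items() if hh == h]
        n_h = len(zs)
        zbar = sum(zs) / n_h
        var += n_h / (n_h - 1) * sum((v - zbar) ** 2 for v in zs)
    return est, var


def _design_frame(n=300, n_strata=3, n_psu=2, seed=99, informative=True):
    rng = np.random.default_rng(seed)
    strata = rng.integers(1, n_strata + 1, size=n)
    psu = rng.integers(1, n_psu + 1, size=n)
    w = rng.uniform(0.5, 5.0, size=n)
    y = rng.normal(50, 8, size=n) + (3.0 * w if informative else 0.0)
    y[rng.random(n) < 0.05] = np.nan
    return pd.DataFrame({"STRA": strata, "PSU": psu, "W": w, "Y": y})


def test_degenerate_design_matches_classical_sem():
    """Single stratum, singleton PSUs, equal weights: se == sd/sqrt(n)."""
    y = [1.0, 2.0, 3.0]
    df = pd.DataFrame({"STRA": [1, 1, 1], "PSU": [1, 2, 3], "W": [2.0, 2.0, 2.0], "Y": y})
    est = svy_mean(make_design(df, "STRA", "PSU", "W"), "Y")
    assert est.estimate == pytest.approx(2.0, abs=0)
    sem = np.std(y, ddof=1) / math.sqrt(3)
    assert est.se == pytest.approx(sem, rel=1e-12)
    assert est.se == pytest.approx(1 / math.sqrt(3), rel=1e-12)


def test_weighted_mean_arithmetic():
    df = pd.DataFrame({"STRA": [1, 1], "PSU": [1, 2], "W": [1.0, 3.0], "Y": [10.0, 20.0]})
    est = svy_mean(make_design(df, "STRA", "PSU", "W"), "Y")
    assert est.estimate == pytest.approx(17.5, abs=0)


def test_variance_matches_brute_force_oracle():
    df = _design_frame()
    design = make_design(df, "STRA", "PSU", "W")
    est = svy_mean(design, "Y")
    oracle_est, oracle_var = brute_force_mean_and_variance(df, "STRA", "PSU", "W", "Y")
    assert est.estimate == pytest.approx(oracle_est, rel=1e-12)
    assert est.se**2 == pytest.approx(oracle_var, rel=1e-10)


def test_domain_variance_matches_brute_force_oracle():
    df = _design_frame(seed=7)
    design = make_design(df, "STRA", "PSU", "W")
    mask = (df["Y"].fillna(0) > 45).to_numpy()
    sub = subset_design(design, mask)
    est = svy_mean(sub, "Y")
    oracle_est, oracle_var = brute_force_mean_and_variance(df, "STRA", "PSU", "W", "Y", mask)
    assert est.estimate == pytest.approx(oracle_est, rel=1e-12)
    assert est.se**2 == pytest.approx(oracle_var, rel=1e-10)


def test_weight_scale_invariance():
    df = _design_frame(seed=3)
    e1 = svy_mean(make_design(df, "STRA", "PSU", "W"), "Y")
    df2 = df.assign(W=df["W"] * 37.5)
    e2 = svy_mean(make_design(df2, "STRA", "PSU", "W"), "Y")
    assert e2.estimate == pytest.approx(e1.estimate, rel=1e-12)
    assert e2.se == pytest.approx(e1.se, rel=1e-12)


def test_domain_differs_from_row_deletion():
    """Deleting out-of-domain rows empties a PSU and changes the variance.

    This is exactly why the design must be frozen before subsetting.
    """
    df = pd.DataFrame(
        {
            "STRA": [1, 1, 1, 1, 2, 2, 2, 2],
            "PSU": [1, 1, 2, 2, 1, 1, 2, 2],
            "W": [1.0] * 8,
            "Y": [5.0, 7.0, 6.0, 9.0, 4.0, 8.0, 10.0, 12.0],
            "D": [1, 1, 1, 1, 1, 1, 0, 0],  # domain misses stratum 2 / PSU 2 entirely
        }
    )
    full = make_design(df, "STRA", "PSU", "W")
    domain_est = svy_mean(subset_design(full, (df["D"] == 1).to_numpy()), "Y")
    deleted = df.loc[df["D"] == 1]
    deleted_est = svy_mean(
        make_design(deleted, "STRA", "PSU", "W", lonely_psu="certainty"), "Y"
    )
    assert domain_est.estimate == pytest.approx(deleted_est.estimate, rel=1e-12)
    assert domain_est.se != pytest.approx(deleted_est.se, rel=1e-6)


def test_all_true_predicate_is_identity():
    df = _design_frame(seed=11)
    design = make_design(df, "STRA", "PSU", "W")
    same = subset_design(design, np.ones(len(df), dtype=bool))
    e1, e2 = svy_mean(design, "Y"), svy_mean(same, "Y")
    assert (e1.estimate, e1.se) == (e2.estimate, e2.se)


def test_chained_subsets_commute():
    df = _design_frame(seed=13)
    design = make_design(df, "STRA", "PSU", "W")
    a = (df["W"] > 2).to_numpy()
    b = (df["Y"].fillna(0) > 48).to_numpy()
    e_ab = svy_mean(subset_design(subset_design(design, a), b), "Y")
    e_ba = svy_mean(subset_design(subset_design(design, b), a), "Y")
    e_and = svy_mean(subset_design(design, a & b), "Y")
    assert e_ab == e_ba == e_and


def test_grouped_estimates_equal_manual_subsets():
    df = _design_frame(seed=17)
    df["G"] = pd.Categorical(np.where(df["W"] > 2.5, "high", "low"), categories=["low", "high"])
    design = make_design(df, "STRA", "PSU", "W")
    by = svy_mean_by(design, "Y", "G")
    for est in by:
        manual = svy_mean(subset_design(design, (df["G"] == est.group_label).to_numpy()), "Y")
        assert est.estimate == manual.estimate and est.se == manual.se
    assert [e.group_label for e in by] == ["low", "high"]


def test_empty_group_flagged_not_fatal():
    df = _design_frame(seed=19)
    df["G"] = pd.Categorical(["a"] * len(df), categories=["a", "b"])
    by = svy_mean_by(make_design(df, "STRA", "PSU", "W"), "Y", "G")
    assert by[1].empty and by[1].n_obs == 0 and math.isnan(by[1].estimate)


def test_naive_mean_by_is_unweighted():
    df = pd.DataFrame(
        {"G": pd.Categorical(["a", "a", "b"]), "Y": [1.0, 3.0, 10.0], "W": [9.0, 1.0, 1.0]}
    )
    out = naive_mean_by(df, "Y", "G")
    assert out == [("a", 2.0, 2), ("b", 10.0, 1)]


def test_design_validation():
    df = _design_frame(seed=23)
    with pytest.raises(KeyError):
        make_design(df, "STRA", "PSU", "NOPE")
    df0 = df.assign(W=0.0)
    with pytest.raises(ValueError, match="nonpositive"):
        make_design(df0, "STRA", "PSU", "W")
    dfm = df.copy()
    dfm.loc[:4, "W"] = np.nan
    with pytest.warns(UserWarning, match="missing weight"):
        d = make_design(dfm, "STRA", "PSU", "W")
    assert len(d.df) == len(df) - 5


def test_psu_census_15_by_2(config, demo_translated):
    design = make_design(demo_translated, config.strata_var, config.psu_var, config.weight_var)
    assert design.n_psu_cells == 30


def test_lonely_psu_policies():
    df = pd.DataFrame(
        {"STRA": [1, 1, 2], "PSU": [1, 2, 1], "W": [1.0, 1.0, 1.0], "Y": [1.0, 2.0, 3.0]}
    )
    with pytest.raises(LonelyPsuError):
        make_design(df, "STRA", "PSU", "W")
    centered = svy_mean(make_design(df, "STRA", "PSU", "W", lonely_psu="centered"), "Y")
    certainty = svy_mean(make_design(df, "STRA", "PSU", "W", lonely_psu="certainty"), "Y")
    assert centered.estimate == certainty.estimate
    assert centered.se >= certainty.se


def test_non_nested_psu_ids_must_not_repeat():
    df = pd.DataFrame(
        {"STRA": [1, 1, 2, 2], "PSU": [1, 2, 1, 3], "W": [1.0] * 4, "Y": [1.0, 2.0, 3.0, 4.0]}
    )
    with pytest.raises(ValueError, match="repeat across strata"):
        make_design(df, "STRA", "PSU", "W", nested=False)


def test_empty_domain_raises():
    df = _design_frame(seed=29)
    design = make_design(df, "STRA", "PSU", "W")
    with pytest.raises(EmptyDomainError):
        subset_design(design, np.zeros(len(df), dtype=bool))
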