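import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beanheat.traits import (
    TraitError,
    aggregate_genotype_traits,
    ancova_adjusted_response,
    correlation_matrix,
    derive_traits,
    instantaneous_wue,
    leaf_temp_differential,
    quadrant_classify,
    stomatal_limitation,
)


def test_wue_arithmetic():
    assert instantaneous_wue(24.0, 8.0) == 3.0
    assert instantaneous_wue(0.0, 5.0) == 0.0
    assert instantaneous_wue(22.2, 5.9) == pytest.approx(22.2 / 5.9, rel=1e-12)
    with pytest.raises(TraitError):
        instantaneous_wue(10.0, 0.0)


@given(a=st.floats(-5, 40), e=st.floats(0.1, 20), c=st.floats(0.1, 100))
@settings(max_examples=50, deadline=None)
def test_wue_scale_invariance(a, e, c):
    assert instantaneous_wue(a * c, e * c) == pytest.approx(
        instantaneous_wue(a, e), rel=1e-9, abs=1e-12)


def test_stomatal_limitation_values():
    assert stomatal_limitation(400.0, 400.0) == 0.0
    assert stomatal_limitation(0.0, 400.0) == 1.0
    assert stomatal_limitation(300.0, 400.0) == pytest.approx(0.25)
    # supersaturation returns a negative value, no exception
    assert stomatal_limitation(500.0, 400.0) < 0


@given(ci=st.floats(0, 800), ca=st.floats(1, 800))
@settings(max_examples=50, deadline=None)
def test_glim_and_ci_ratio_sum_to_one(ci, ca):
    assert stomatal_limitation(ci, ca) + ci / ca == pytest.approx(1.0, abs=1e-12)


def test_ltd_sign_convention():
    assert leaf_temp_differential(30.0, 30.0) == 0.0
    assert leaf_temp_differential(28.0, 30.0) == -2.0   # transpiration cooling
    assert leaf_temp_differential(31.0, 30.0) == 1.0


def test_derive_traits_appends_columns(gas_exchange_df):
    out = derive_traits(gas_exchange_df)
    assert out["WUE"].iloc[0] == 3.0
    assert out["g_lim"].iloc[0] == pytest.approx(0.25)
    assert out["LTD"].iloc[0] == -1.5


def test_aggregate_closed_forms():
    df = pd.DataFrame({
        "genotype_id": ["g"] * 3 + ["h"] * 3,
        "A": [2.0, 4.0, 6.0, 5.0, 5.0, 5.0],
    })
    out = aggregate_genotype_traits(df, traits=["A"]).set_index("genotype_id")
    assert out.loc["g", "A_mean"] == 4.0
    assert out.loc["g", "A_se"] == pytest.approx(2.0 / np.sqrt(3))
    assert out.loc["h", "A_se"] == 0.0


def test_aggregate_single_observation_se_missing():
    df = pd.DataFrame({"genotype_id": ["g"], "A": [2.0]})
    out = aggregate_genotype_traits(df, traits=["A"])
    assert np.isnan(out["A_se"].iloc[0])


def test_aggregate_matches_groupby_oracle(rng):
    df = pd.DataFrame({
        "genotype_id": rng.choice(list("abcde"), 100),
        "A": rng.normal(20, 3, 100),
        "E": rng.uniform(2, 9, 100),
    })
    out = aggregate_genotype_traits(df, traits=["A", "E"]).set_index("genotype_id")
    for g, sub in df.groupby("genotype_id"):
        assert out.loc[g, "A_mean"] == pytest.approx(sub["A"].mean(), rel=1e-12)
        assert out.loc[g, "E_se"] == pytest.approx(
            sub["E"].std(ddof=1) / np.sqrt(len(sub)), rel=1e-12)


def test_quadrants_against_brute_force(rng):
    summary = pd.DataFrame({
        "genotype_id": [f"g{i}" for i in range(10)],
        "A_mean": rng.normal(22, 3, 10),
        "GY_mean": rng.normal(950, 150, 10),
    })
    out = quadrant_classify(summary, "A_mean", "GY_mean")
    xbar = summary["A_mean"].mean()
    ybar = summary["GY_mean"].mean()
    for _, row in out.iterrows():
        expected = {(True, True): "I", (False, True): "II",
                    (False, False): "III", (True, False): "IV"}[
            (row["A_mean"] >= xbar, row["GY_mean"] >= ybar)]
        assert row["quadrant"] == expected


def test_quadrant_tie_rule_upper_right():
    summary = pd.DataFrame({
        "genotype_id": ["g1", "g2"],
        "x": [1.0, 1.0], "y": [2.0, 2.0],
    })
    out = quadrant_classify(summary, "x", "y")
    assert set(out["quadrant"]) == {"I"}   # exactly on both means -> I


def test_quadrant_affine_invariance(rng):
    summary = pd.DataFrame({
        "genotype_id": [f"g{i}" for i in range(8)],
        "x": rng.normal(size=8), "y": rng.normal(size=8),
    })
    base = quadrant_classify(summary, "x", "y")["quadrant"]
    scaled = summary.assign(x=3.0 * summary["x"] - 7.0)
    assert (quadrant_classify(scaled, "x", "y")["quadrant"] == base).all()


def _ancova_oracle(df, response, tref):
    """Explicit normal-equations solve of response ~ genotype + Tair."""
    genos = sorted(df["genotype_id"].unique())
    X = np.column_stack(
        [(df["genotype_id"] == g).to_numpy(float) for g in genos]
        + [df["Tair"].to_numpy(float)])
    beta, *_ = np.linalg.lstsq(X, df[response].to_numpy(float), rcond=None)
    return {g: beta[i] + beta[-1] * tref for i, g in enumerate(genos)}


def test_ancova_common_line_reduces_to_tref_value(rng):
    t = rng.uniform(25, 35, 30)
    df = pd.DataFrame({
        "genotype_id": np.repeat(["a", "b", "c"], 10),
        "Tair": t, "A": 2.0 * t,
    })
    res = ancova_adjusted_response(df, "A", tref=27.74)
    np.testing.assert_allclose(
        res.adjusted_means["A_adjusted"], 2.0 * 27.74, rtol=1e-9)
    assert res.common_slope == pytest.approx(2.0, rel=1e-9)


def test_ancova_parallel_offset_preserved(rng):
    t = rng.uniform(25, 35, 20)
    df = pd.DataFrame({
        "genotype_id": np.repeat(["a", "b"], 20),
        "Tair": np.concatenate([t, t]),
        "A": np.concatenate([1.5 * t, 1.5 * t + 5.0]),
    })
    res = ancova_adjusted_response(df, "A", tref=30.0)
    vals = res.adjusted_means.set_index("genotype_id")["A_adjusted"]
    assert vals["b"] - vals["a"] == pytest.approx(5.0, abs=1e-9)


def test_ancova_matches_normal_equations_oracle(rng):
    df = pd.DataFrame({
        "genotype_id": rng.choice(["a", "b", "c", "d"], 60),
        "Tair": rng.uniform(24, 34, 60),
    })
    df["A"] = 30 - 0.8 * df["Tair"] + rng.normal(0, 1, 60)
    res = ancova_adjusted_response(df, "A", tref=27.74)
    oracle = _ancova_oracle(df, "A", 27.74)
    for _, row in res.adjusted_means.iterrows():
        assert row["A_adjusted"] == pytest.approx(
            oracle[row["genotype_id"]], rel=1e-8)


def test_ancova_zero_slope_gives_raw_means(rng):
    df = pd.DataFrame({
        "genotype_id": np.repeat(["a", "b"], 10),
        "Tair": np.tile(rng.uniform(25, 35, 10), 2),
        "A": np.repeat([20.0, 25.0], 10),
    })
    res = ancova_adjusted_response(df, "A", tref=50.0)
    vals = res.adjusted_means.set_index("genotype_id")["A_adjusted"]
    assert vals["a"] == pytest.approx(20.0, abs=1e-9)
    assert vals["b"] == pytest.approx(25.0, abs=1e-9)


def test_correlation_matrix_properties_and_oracle(rng):
    df = pd.DataFrame(rng.normal(size=(20, 6)),
                      columns=list("abcdef"))
    df["g"] = -df["a"]
    for method in ("pearson", "spearman"):
        rm, pm = correlation_matrix(df, method=method)
        np.testing.assert_allclose(rm.to_numpy(), rm.to_numpy().T)
        np.testing.assert_allclose(np.diag(rm), 1.0)
        assert rm.loc["a", "g"] == pytest.approx(-1.0)
        assert (rm.abs().to_numpy() <= 1 + 1e-12).all()
    # brute-force product-moment formula for one pair
    x, y = df["a"].to_numpy(), df["b"].to_numpy()
    rxy = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
    rm, _ = correlation_matrix(df, method="pearson")
    assert rm.loc["a", "b"] == pytest.approx(rxy, rel=1e-12)


def test_correlation_zero_variance_flagged_nan():
    df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
    rm, _ = correlation_matrix(df)
    assert np.isnan(rm.loc["a", "b"])
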