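import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beanheat.stress import (
    StressIndexError,
    compute_stress_table,
    genotype_stress_index,
    geometric_mean,
    stress_intensity,
    yield_reduction,
)

positive_vec = st.lists(st.floats(1.0, 5000.0), min_size=2, max_size=12)


def test_geometric_mean_examples():
    assert geometric_mean([4.0, 9.0]) == pytest.approx(6.0, rel=1e-12)
    assert geometric_mean([7.0, 7.0, 7.0]) == pytest.approx(7.0, rel=1e-12)
    with pytest.raises(StressIndexError):
        geometric_mean([1.0, 0.0])


@given(v=positive_vec)
@settings(max_examples=50, deadline=None)
def test_geometric_mean_log_oracle_and_am_bound(v):
    gm = geometric_mean(v)
    assert gm == pytest.approx(float(np.exp(np.mean(np.log(v)))), rel=1e-12)
    assert gm <= np.mean(v) + 1e-9


def test_yield_reduction_properties():
    y = pd.Series([800.0, 900, 1000, 1100, 1200],
                  index=list("abcde"))
    yr = yield_reduction(y)
    # genotype at the experiment geometric mean has YR = 1
    gm = geometric_mean(y)
    assert yield_reduction(pd.Series([gm, *y]))[0] == pytest.approx(1.0, rel=1e-12)
    # within-experiment geometric mean of YR is exactly 1
    assert geometric_mean(yr) == pytest.approx(1.0, rel=1e-12)
    # scale invariance
    np.testing.assert_allclose(yield_reduction(3.7 * y), yr, rtol=1e-12)
    # hand computation for the toy table
    np.testing.assert_allclose(yr, y / gm, rtol=1e-12)


def test_stress_intensity_values():
    assert stress_intensity([100.0, 100], [100.0, 100]) == 0.0
    assert stress_intensity([100.0, 100], [80.0, 80]) == pytest.approx(0.2)


def test_gsi_closed_forms():
    assert genotype_stress_index(1.0, 1.0, 0.2, "literal") == 0.0
    assert genotype_stress_index(1.0, 1.0, 0.2, "oriented") == 0.0
    assert genotype_stress_index(1.21, 1.0, 0.1, "oriented") == pytest.approx(
        (np.sqrt(1.21) - 1) / 0.1, rel=1e-12)
    with pytest.raises(StressIndexError):
        genotype_stress_index(1.0, 1.0, 0.0)
    with pytest.raises(StressIndexError):
        genotype_stress_index(-1.0, 1.0, 0.2)


@given(yr1=st.floats(0.2, 5.0), yr2=st.floats(0.2, 5.0),
       sii=st.floats(0.05, 0.6))
@settings(max_examples=100, deadline=None)
def test_literal_is_negated_oriented(yr1, yr2, sii):
    lit = genotype_stress_index(yr1, yr2, sii, "literal")
    ori = genotype_stress_index(yr1, yr2, sii, "oriented")
    assert lit == pytest.approx(-ori, rel=1e-12, abs=1e-15)


def _random_yield_table(rng, n=10):
    rows = []
    for g in range(n):
        for year in ("year1", "year2"):
            rows.append({"genotype_id": f"g{g:02d}", "year": year,
                         "yield": float(rng.uniform(300, 1700))})
    return pd.DataFrame(rows)


def test_stress_table_matches_one_line_oracle(rng):
    df = _random_yield_table(rng)
    out = compute_stress_table(df).set_index("genotype_id")
    y1 = df[df["year"] == "year1"].set_index("genotype_id")["yield"]
    y2 = df[df["year"] == "year2"].set_index("genotype_id")["yield"]
    gm1, gm2 = geometric_mean(y1), geometric_mean(y2)
    sii = 1 - gm2 / gm1
    for g in y1.index:
        yr1, yr2 = y1[g] / gm1, y2[g] / gm2
        lit = (1 - np.sqrt(yr1 * yr2)) / sii
        assert out.loc[g, "gsi_literal"] == pytest.approx(lit, rel=1e-12)
        assert out.loc[g, "gsi_oriented"] == pytest.approx(-lit, rel=1e-12)
    # within-year geometric means of YR are exactly 1
    assert geometric_mean(out["yr_year1"]) == pytest.approx(1.0, rel=1e-12)
    assert geometric_mean(out["yr_year2"]) == pytest.approx(1.0, rel=1e-12)


def test_stress_table_rescaling_invariance(rng):
    df = _random_yield_table(rng)
    base = compute_stress_table(df)
    scaled = df.assign(yield_=df["yield"] * 2.5).drop(columns="yield").rename(
        columns={"yield_": "yield"})
    out = compute_stress_table(scaled)
    np.testing.assert_allclose(out["gsi_literal"], base["gsi_literal"], rtol=1e-10)


def test_stress_table_year_role_mapping(rng):
    df = _random_yield_table(rng)
    second = compute_stress_table(df, stressed_year_role="second")
    first = compute_stress_table(df, stressed_year_role="first")
    s2, s1 = second["sii"].iloc[0], first["sii"].iloc[0]
    # SII = 1 - GM(stressed)/GM(reference): roles swap the ratio
    assert (1 - s2) * (1 - s1) == pytest.approx(1.0, rel=1e-12)


def test_stress_table_missing_year_excluded(rng):
    df = _random_yield_table(rng)
    df = df.drop(df[(df["genotype_id"] == "g00")
                    & (df["year"] == "year2")].index)
    out = compute_stress_table(df).set_index("genotype_id")
    assert np.isnan(out.loc["g00", "gsi_literal"])
    assert out["gsi_literal"].notna().sum() == 9


def test_stress_table_requires_two_years(rng):
    df = _random_yield_table(rng)
    with pytest.raises(StressIndexError):
        compute_stress_table(df[df["year"] == "year1"])
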