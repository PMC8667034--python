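import dataclasses

import numpy as np
import pandas as pd
import pytest

from beanheat.fvcb import fvcb_model
from beanheat.light import light_response_model
from beanheat.segmented import two_segment_predict
from beanheat.simulate import (
    ACI_GRID,
    DEFAULT_PROFILES,
    LIGHT_GRID,
    GeneratorSpec,
    gen_aci_curves,
    gen_gas_exchange_records,
    gen_light_curves,
    gen_segmented_dataset,
    gen_trait_table,
    gen_weather_series,
    gen_yield_table,
)
from beanheat.stress import compute_stress_table


def test_default_profiles_shape():
    assert [p.name for p in DEFAULT_PROFILES] == ["EUW", "WUE", "OEUW"]
    assert [p.size for p in DEFAULT_PROFILES] == [14, 30, 20]
    assert sum(p.size for p in DEFAULT_PROFILES) == 64


@pytest.mark.parametrize("gen,args", [
    (gen_light_curves, {}),
    (gen_aci_curves, {}),
    (gen_trait_table, {}),
    (gen_yield_table, {}),
    (gen_segmented_dataset, {"n": 50}),
    (gen_weather_series, {"n_years": 2}),
])
def test_seed_determinism(gen, args):
    spec = GeneratorSpec(seed=42)
    out1 = gen(spec, **args)
    out2 = gen(spec, **args)
    df1 = out1[0] if isinstance(out1, tuple) else out1
    df2 = out2[0] if isinstance(out2, tuple) else out2
    pd.testing.assert_frame_equal(df1, df2)
    # a different seed changes the draw
    out3 = gen(spec.with_seed(43), **args)
    df3 = out3[0] if isinstance(out3, tuple) else out3
    assert not df1.select_dtypes("number").equals(df3.select_dtypes("number"))


def test_noiseless_light_curves_on_model():
    spec = GeneratorSpec(seed=5, light_noise_sd=0.0)
    curves, truth = gen_light_curves(spec, n_curves=3)
    for _, t in truth.iterrows():
        sub = curves[curves["genotype_id"] == t["genotype_id"]]
        np.testing.assert_allclose(
            sub["A"], light_response_model(sub["Q"], t["amax"], t["phi"], t["rd"]),
            rtol=1e-12)


def test_noiseless_aci_curves_on_model():
    spec = GeneratorSpec(seed=5, aci_noise_sd=0.0)
    curves, truth = gen_aci_curves(spec, n_curves=3)
    for _, t in truth.iterrows():
        sub = curves[curves["genotype_id"] == t["genotype_id"]]
        a, _ = fvcb_model(sub["Ci"].to_numpy(), t["vcmax"], t["jmax"], t["rd"])
        np.testing.assert_allclose(sub["A"], a, rtol=1e-12)


def test_curve_noise_calibration():
    """Empirical residual sd over many curves matches the configured sd."""
    spec = GeneratorSpec(seed=6, light_noise_sd=0.5)
    curves, truth = gen_light_curves(spec, n_curves=500)
    t = truth.set_index("genotype_id")
    resid = []
    for gid, sub in curves.groupby("genotype_id"):
        model = light_response_model(sub["Q"], t.loc[gid, "amax"],
                                     t.loc[gid, "phi"], t.loc[gid, "rd"])
        resid.extend(sub["A"] - model)
    assert np.std(resid) == pytest.approx(0.5, rel=0.05)


def test_trait_table_group_structure():
    spec = GeneratorSpec(seed=3)
    table, labels = gen_trait_table(spec)
    assert len(table) == 64
    assert labels.value_counts().to_dict() == {"WUE": 30, "OEUW": 20, "EUW": 14}
    # scale -> 0 puts every genotype exactly at its group means
    z = dataclasses.replace(spec, trait_scale=0.0)
    table0, labels0 = gen_trait_table(z)
    for p in DEFAULT_PROFILES:
        sub = table0[labels0 == p.name]
        for trait, mean in p.means.items():
            np.testing.assert_allclose(sub[trait], mean, rtol=1e-12)


def test_yield_table_stress_truth():
    # zero noise, zero genotype effects: SII exact, GSI identically 0
    spec = GeneratorSpec(seed=1, genotype_effect_sd=0.0, yield_noise_sd=0.0,
                         year2_multiplier=0.8)
    yields, truth = gen_yield_table(spec)
    table = compute_stress_table(yields)
    assert table["sii"].iloc[0] == pytest.approx(0.2, rel=1e-12)
    np.testing.assert_allclose(table["gsi_oriented"], 0.0, atol=1e-12)
    assert truth["implied_sii"] == pytest.approx(0.2)


def test_yield_sii_recovery_unbiased():
    errs = []
    for s in range(40):
        spec = GeneratorSpec(seed=500 + s)
        yields, truth = gen_yield_table(spec)
        table = compute_stress_table(yields)
        errs.append(table["sii"].iloc[0] - truth["implied_sii"])
    assert abs(np.mean(errs)) < 0.01   # within Monte-Carlo error of zero


def test_segmented_dataset_truth_is_continuous():
    spec = GeneratorSpec(seed=2, segmented_noise_sd=0.0)
    data, truth = gen_segmented_dataset(spec, n=100)
    np.testing.assert_allclose(
        data["A"], two_segment_predict(data["Tair"], truth), rtol=1e-12)


def test_weather_series_physical_invariants():
    spec = GeneratorSpec(seed=9)
    wx = gen_weather_series(spec, n_years=3, start_year=2000)
    assert (wx["tmax"] >= wx["tmin"]).all()
    assert wx["rh"].between(40, 100).all()
    assert len(wx) == 365 + 365 + 366   # 2000 is a leap year
    # amplitude 0, noise 0 -> constant series
    flat = dataclasses.replace(spec, tmax_amplitude=0.0, tmin_amplitude=0.0,
                               weather_noise_sd=0.0)
    wx0 = gen_weather_series(flat, n_years=1)
    assert wx0["tmax"].nunique() == 1


def test_gas_exchange_records_valid_and_complete():
    from beanheat.io import validate_gas_exchange
    spec = GeneratorSpec(seed=4)
    records, labels = gen_gas_exchange_records(spec)
    assert len(records) == 64 * spec.n_replicates
    validate_gas_exchange(records)   # raises on any invariant breach
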