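"""Synthetic-data generators for every input the pipeline consumes.

Each generator is a pure function of its spec and seed (same spec + seed
gives byte-identical output) and emits its generating truth alongside the
data so that parameter-recovery tests consume only generated artifacts.

The typology profiles (group trait means ± SE and group sizes 14/30/20 out
of 64 genotypes) encode the three water-use strategies observed in
heat-stressed common bean: EUW (effective use of water — water spenders
with high gs, E and transpiration cooling), WUE (water-use efficient —
water savers with high stomatal limitation) and OEUW (opportunistic
intermediates with high Rd, LCP and Vcmax). Trait draws are independent
across traits by default; real trait profiles are strongly correlated, a
documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fvcb import KineticConstants, fvcb_model
from .light import light_response_model
from .segmented import SegmentedFit, two_segment_predict

#: A/PAR measurement grid: ten irradiance steps from darkness to 2000
LIGHT_GRID = np.array([0.0, 25, 50, 100, 250, 500, 750, 1000, 1500, 2000])

#: A/Ci measurement grid: 15 CO2 steps from 50 up to 1600 ppm
ACI_GRID = np.array([50.0, 100, 150, 200, 250, 300, 400, 500, 600,
                     700, 800, 1000, 1200, 1400, 1600])


@dataclass(frozen=True)
class TypologyProfile:
    """Per-group trait means and standard errors with group size."""

    name: str
    size: int
    means: dict[str, float]
    ses: dict[str, float]


#: trait order used throughout the typology stage
PROFILE_TRAITS = ["GY", "A", "LSP", "Rd", "LCP", "PhiPAR", "Vcmax", "Jmax",
                  "RD", "g_lim", "gs", "Ci", "WUE", "E", "LTD"]


def _profile(name, size, means, ses):
    return TypologyProfile(name, size,
                           dict(zip(PROFILE_TRAITS, means)),
                           dict(zip(PROFILE_TRAITS, ses)))


#: default group profiles: mean and SE per trait for the three typologies
DEFAULT_PROFILES = [
    _profile("EUW", 14,
             [1182.5, 24.1, 965.1, 1.0, 26.3, 1.6, 34.0, 51.3, 18.2,
              0.19, 863.1, 297.4, 2.6, 9.8, -1.37],
             [84.6, 1.0, 65.1, 0.1, 2.8, 0.1, 6.6, 6.2, 1.5,
              0.01, 78.3, 4.6, 0.2, 0.8, 0.5]),
    _profile("WUE", 30,
             [835.3, 20.8, 913.9, 0.6, 18.2, 1.8, 41.7, 71.7, 17.3,
              0.58, 199.6, 175.4, 5.5, 4.1, 0.81],
             [52.8, 1.0, 72.1, 0.1, 2.3, 0.1, 4.6, 6.5, 1.0,
              0.04, 18.9, 12.7, 0.4, 0.3, 0.2]),
    _profile("OEUW", 20,
             [990.3, 22.9, 958.1, 1.8, 45.6, 1.7, 61.5, 60.2, 15.4,
              0.35, 357.4, 235.5, 3.7, 6.0, -0.04],
             [67.2, 1.4, 52.6, 0.1, 3.0, 0.1, 8.2, 5.2, 1.3,
              0.02, 33.2, 10.0, 0.2, 0.5, 0.2]),
]


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic study, with the study-design defaults.

    64 genotypes in three typology groups, three replicates, two trial
    years with a 20% geometric stress contrast, Gaussian measurement noise
    on curves (sd in assimilation units), and a two-segment thermal truth
    with join point 27.74 °C and upper slope 0.63.
    """

    seed: int = 0
    n_genotypes: int = 64
    n_replicates: int = 3
    # curve noise (µmol CO2 m⁻² s⁻¹)
    light_noise_sd: float = 0.5
    aci_noise_sd: float = 0.5
    # light-curve truth ranges (uniform draws)
    amax_range: tuple[float, float] = (20.0, 35.0)
    phi_range: tuple[float, float] = (0.03, 0.07)
    rd_range: tuple[float, float] = (0.5, 2.5)
    # FvCB truth ranges
    vcmax_range: tuple[float, float] = (30.0, 90.0)
    jmax_factor_range: tuple[float, float] = (1.5, 2.2)  # Jmax / Vcmax
    rd_day_range: tuple[float, float] = (0.5, 2.0)
    # trait-table draw scale: per-genotype sd = scale · SE · sqrt(group n);
    # calibrated by the k-selection recovery study (see docs/methods.md)
    trait_scale: float = 0.45
    # two-segment truth
    gamma: float = 27.74
    beta0: float = -30.5
    beta1: float = 2.0
    beta2: float = 0.63
    temp_range: tuple[float, float] = (22.0, 34.0)
    segmented_noise_sd: float = 1.0
    # yield model (log scale)
    yield_mu: float = float(np.log(957.0))
    genotype_effect_sd: float = 0.30
    year2_multiplier: float = 0.80
    yield_noise_sd: float = 0.10
    # weather model (tropical lowland; °C, %, mm); defaults reproduce the
    # study's seasonal risk profile: ~1/3 of seasons see a >30 °C day in
    # the 20–60 days-after-sowing window, every season sees >20 °C nights
    tmax_mean: float = 28.8
    tmax_amplitude: float = 1.8
    tmin_mean: float = 21.0
    tmin_amplitude: float = 1.0
    weather_noise_sd: float = 1.2
    rh_mean: float = 85.0
    rh_sd: float = 6.0
    kinetics: KineticConstants = field(default_factory=KineticConstants)

    def with_seed(self, seed: int) -> "GeneratorSpec":
        return replace(self, seed=seed)


def _genotype_ids(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def gen_light_curves(spec: GeneratorSpec, n_curves: int | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Light-response curves on the ten-step PAR grid, plus their truth.

    Returns (curves, truth): curves in long format (genotype_id, Q, A),
    truth one row per curve (amax, phi, rd).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genotypes if n_curves is None else n_curves
    ids = _genotype_ids(n)
    amax = rng.uniform(*spec.amax_range, n)
    phi = rng.uniform(*spec.phi_range, n)
    rd = rng.uniform(*spec.rd_range, n)
    rows = []
    for i, gid in enumerate(ids):
        a = light_response_model(LIGHT_GRID, amax[i], phi[i], rd[i])
        a = a + rng.normal(0.0, spec.light_noise_sd, LIGHT_GRID.size)
        for q, av in zip(LIGHT_GRID, a):
            rows.append({"genotype_id": gid, "Q": q, "A": av})
    curves = pd.DataFrame(rows)
    truth = pd.DataFrame({"genotype_id": ids, "amax": amax, "phi": phi, "rd": rd})
    return curves, truth


def gen_aci_curves(spec: GeneratorSpec, n_curves: int | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A/Ci curves on the 15-step CO2 grid, plus their FvCB truth."""
    rng = np.random.default_rng(spec.seed + 1)
    n = spec.n_genotypes if n_curves is None else n_curves
    ids = _genotype_ids(n)
    vcmax = rng.uniform(*spec.vcmax_range, n)
    jmax = vcmax * rng.uniform(*spec.jmax_factor_range, n)
    rd = rng.uniform(*spec.rd_day_range, n)
    rows = []
    for i, gid in enumerate(ids):
        a, _ = fvcb_model(ACI_GRID, vcmax[i], jmax[i], rd[i], spec.kinetics)
        a = a + rng.normal(0.0, spec.aci_noise_sd, ACI_GRID.size)
        for ci, av in zip(ACI_GRID, a):
            rows.append({"genotype_id": gid, "Ci": ci, "A": av})
    curves = pd.DataFrame(rows)
    truth = pd.DataFrame({"genotype_id": ids, "vcmax": vcmax,
                          "jmax": jmax, "rd": rd})
    return curves, truth


def gen_trait_table(spec: GeneratorSpec,
                    profiles: list[TypologyProfile] | None = None
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Genotype trait table drawn from the typology profiles.

    Each genotype's trait vector is drawn independently per trait from
    Normal(group mean, trait_scale · SE · sqrt(group n)) — the SE·sqrt(n)
    factor converts the reported group-level standard errors back to
    between-genotype standard deviations. Returns (table, true labels).
    """
    if profiles is None:
        profiles = DEFAULT_PROFILES
    sizes = [p.size for p in profiles]
    if sum(sizes) != spec.n_genotypes:
        raise ValueError(
            f"profile sizes {sizes} must sum to n_genotypes={spec.n_genotypes}"
        )
    rng = np.random.default_rng(spec.seed + 2)
    ids = _genotype_ids(spec.n_genotypes)
    rows, labels = [], []
    idx = 0
    for p in profiles:
        for _ in range(p.size):
            row = {"genotype_id": ids[idx]}
            for t in PROFILE_TRAITS:
                sd = spec.trait_scale * p.ses[t] * np.sqrt(p.size)
                row[t] = rng.normal(p.means[t], sd)
            rows.append(row)
            labels.append(p.name)
            idx += 1
    table = pd.DataFrame(rows)
    return table, pd.Series(labels, index=table.index, name="true_group")


def gen_yield_table(spec: GeneratorSpec) -> tuple[pd.DataFrame, dict]:
    """Two-year genotype yield table with a global stress contrast.

    Y(g, year) = exp(µ + genotype effect + year effect + noise); the
    second year's multiplicative effect implements the stress intensity
    (with zero noise, SII = 1 − year2_multiplier exactly). Truth carries
    the effects and the implied SII.
    """
    rng = np.random.default_rng(spec.seed + 3)
    ids = _genotype_ids(spec.n_genotypes)
    geno_eff = rng.normal(0.0, spec.genotype_effect_sd, spec.n_genotypes)
    year_eff = {"year1": 0.0, "year2": float(np.log(spec.year2_multiplier))}
    rows = []
    for year, eff in year_eff.items():
        noise = rng.normal(0.0, spec.yield_noise_sd, spec.n_genotypes)
        y = np.exp(spec.yield_mu + geno_eff + eff + noise)
        for gid, yv in zip(ids, y):
            rows.append({"genotype_id": gid, "year": year, "yield": yv})
    truth = {
        "genotype_effects": dict(zip(ids, geno_eff)),
        "implied_sii": 1.0 - spec.year2_multiplier,
    }
    return pd.DataFrame(rows), truth


def gen_segmented_dataset(spec: GeneratorSpec, n: int = 500
                          ) -> tuple[pd.DataFrame, SegmentedFit]:
    """Temperature–assimilation scatter from the continuous two-segment truth."""
    rng = np.random.default_rng(spec.seed + 4)
    x = rng.uniform(*spec.temp_range, n)
    truth = SegmentedFit(beta0=spec.beta0, beta1=spec.beta1, beta2=spec.beta2,
                         gamma=spec.gamma, sse=0.0, mode="continuous")
    y = two_segment_predict(x, truth) + rng.normal(0.0, spec.segmented_noise_sd, n)
    return pd.DataFrame({"Tair": x, "A": y}), truth


def gen_weather_series(spec: GeneratorSpec, n_years: int = 30,
                       start_year: int = 1984) -> pd.DataFrame:
    """Multi-year daily weather: annual sinusoid plus day-to-day noise.

    tmax > tmin is enforced (a hot night never exceeds its day maximum);
    relative humidity is clipped to [40, 100]. Calendar dates handle leap
    years; the sinusoid phase peaks in early austral-northern transition
    (day ~260) to mimic the bimodal hot periods of a tropical lowland site.
    """
    rng = np.random.default_rng(spec.seed + 5)
    dates = pd.date_range(f"{start_year}-01-01",
                          f"{start_year + n_years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    phase = 2.0 * np.pi * (doy - 260.0) / 365.25
    tmax = (spec.tmax_mean + spec.tmax_amplitude * np.cos(phase)
            + rng.normal(0.0, spec.weather_noise_sd, dates.size))
    tmin = (spec.tmin_mean + spec.tmin_amplitude * np.cos(phase)
            + rng.normal(0.0, spec.weather_noise_sd, dates.size))
    tmin = np.minimum(tmin, tmax - 0.1)
    rh = np.clip(rng.normal(spec.rh_mean, spec.rh_sd, dates.size), 40.0, 100.0)
    rain = np.round(rng.gamma(0.6, 12.0, dates.size), 1)
    return pd.DataFrame({
        "date": dates, "tmax": tmax, "tmin": tmin, "rh": rh, "rain": rain,
    })


def gen_gas_exchange_records(spec: GeneratorSpec,
                             profiles: list[TypologyProfile] | None = None
                             ) -> tuple[pd.DataFrame, pd.Series]:
    """Replicate-level instantaneous gas-exchange records.

    Builds on :func:`gen_trait_table`: each genotype's group-profile trait
    vector becomes the replicate mean, ambient temperature varies across
    replicates, and assimilation responds to temperature through the
    two-segment truth (centred at the join point) so that downstream
    covariance adjustment and breakpoint stages see the structure they
    assume. Returns (records, true group labels per genotype).
    """
    table, labels = gen_trait_table(spec, profiles)
    rng = np.random.default_rng(spec.seed + 6)
    truth = SegmentedFit(beta0=spec.beta0, beta1=spec.beta1, beta2=spec.beta2,
                         gamma=spec.gamma, sse=0.0, mode="continuous")
    a_at_gamma = two_segment_predict(spec.gamma, truth)
    rows = []
    for i, row in table.iterrows():
        for rep in range(1, spec.n_replicates + 1):
            tair = rng.uniform(*spec.temp_range)
            a_temp = two_segment_predict(tair, truth) - a_at_gamma
            a = max(row["A"] + a_temp + rng.normal(0.0, 0.5), 0.1)
            e = max(row["E"] + rng.normal(0.0, 0.3), 0.2)
            gs = max(row["gs"] + rng.normal(0.0, 20.0), 5.0)
            ci = float(np.clip(row["Ci"] + rng.normal(0.0, 10.0), 5.0, 395.0))
            rows.append({
                "genotype_id": row["genotype_id"], "replicate": rep,
                "A": a, "gs": gs, "E": e, "Ci": ci, "Ca": 400.0,
                "Tair": tair, "Tleaf": tair + row["LTD"] + rng.normal(0.0, 0.2),
                "PAR": 1300.0, "RH": float(np.clip(rng.normal(85.0, 5.0), 0, 100)),
            })
    return pd.DataFrame(rows), labels
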