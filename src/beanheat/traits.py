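"""Leaf-level gasometric traits and genotype summaries.

Derived per observation:

* instantaneous water-use efficiency  WUE = A/E  (mmol CO2 mol⁻¹ H2O),
* stomatal limitation                 g_lim = 1 − Ci/Ca  (dimensionless),
* leaf temperature differential       LTD = Tleaf − Tair  (°C, negative
  when transpiration cools the leaf below air temperature).

Genotype summaries report mean ± standard error per trait; adjusted genotype
responses at a reference ambient temperature come from a fixed-effects
analysis of covariance (response ~ genotype + Tair, common slope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAIT_COLUMNS = ["A", "gs", "E", "Ci", "WUE", "g_lim", "LTD"]


class TraitError(ValueError):
    """A trait is undefined for a record (e.g. WUE with E = 0)."""


def instantaneous_wue(A, E):
    """WUE = A/E; errors on E = 0 where the ratio is undefined."""
    A = np.asarray(A, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(E <= 0):
        raise TraitError("transpiration must be > 0 to define WUE")
    return A / E


def stomatal_limitation(Ci, Ca):
    """g_lim = 1 − Ci/Ca. Values are negative under supersaturation
    (Ci > Ca); callers may inspect the sign, no exception is raised."""
    Ci = np.asarray(Ci, dtype=float)
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca <= 0):
        raise TraitError("ambient CO2 must be positive")
    if np.any(Ci < 0):
        raise TraitError("sub-stomatal CO2 must be non-negative")
    return 1.0 - Ci / Ca


def leaf_temp_differential(Tleaf, Tair):
    """LTD = Tleaf − Tair; negative means the leaf is cooler than the air."""
    return np.asarray(Tleaf, dtype=float) - np.asarray(Tair, dtype=float)


def derive_traits(records: pd.DataFrame, ca_reference: float | None = None) -> pd.DataFrame:
    """Append WUE, g_lim and LTD columns to a validated gas-exchange table.

    When the table has no Ca column, ``ca_reference`` supplies the chamber
    set point.
    """
    out = records.copy()
    if "Ca" not in out.columns:
        if ca_reference is None:
            raise TraitError("no Ca column and no ca_reference supplied")
        out["Ca"] = float(ca_reference)
    out["WUE"] = instantaneous_wue(out["A"], out["E"])
    out["g_lim"] = stomatal_limitation(out["Ci"], out["Ca"])
    out["LTD"] = leaf_temp_differential(out["Tleaf"], out["Tair"])
    return out


def aggregate_genotype_traits(records: pd.DataFrame,
                              traits: list[str] | None = None) -> pd.DataFrame:
    """Per-genotype mean and standard error for each trait.

    SE = sample sd / sqrt(n); for n = 1 the SE is reported as missing,
    never as zero. Output is wide: one row per genotype with
    ``<trait>_mean``, ``<trait>_se`` columns plus ``n``.
    """
    if traits is None:
        traits = [t for t in TRAIT_COLUMNS if t in records.columns]
    g = records.groupby("genotype_id", sort=True)
    out = pd.DataFrame(index=g.size().index)
    out["n"] = g.size()
    for t in traits:
        out[f"{t}_mean"] = g[t].mean()
        sd = g[t].std(ddof=1)
        out[f"{t}_se"] = sd / np.sqrt(out["n"])
    return out.reset_index()


QUADRANT_LABELS = {
    (True, True): "I",    # >= x mean, >= y mean
    (False, True): "II",
    (False, False): "III",
    (True, False): "IV",
}


def quadrant_classify(summary: pd.DataFrame, x: str, y: str) -> pd.DataFrame:
    """Assign each genotype to a quadrant relative to the population means.

    Boundaries are the across-genotype means of the two traits; points on
    a boundary go to the upper/right side (>= rule). Returns columns
    genotype_id, x, y, quadrant.
    """
    if summary["genotype_id"].nunique() < 2:
        raise ValueError("need at least 2 genotypes to define quadrants")
    xv = summary[x].to_numpy(dtype=float)
    yv = summary[y].to_numpy(dtype=float)
    xbar, ybar = xv.mean(), yv.mean()
    labels = [QUADRANT_LABELS[(xi >= xbar, yi >= ybar)] for xi, yi in zip(xv, yv)]
    return pd.DataFrame({
        "genotype_id": summary["genotype_id"],
        x: xv, y: yv, "quadrant": labels,
    })


@dataclass
class AncovaResult:
    """Covariance-adjusted genotype means at a reference temperature."""

    adjusted_means: pd.DataFrame   # genotype_id, expected value at Tref
    common_slope: float
    slope_se: float
    response: str
    tref: float


def ancova_adjusted_response(records: pd.DataFrame, response: str,
                             tref: float, covariate: str = "Tair") -> AncovaResult:
    """Expected genotype responses at ``tref`` from a common-slope ANCOVA.

    Fits the fixed-effects model response ~ genotype + covariate by ordinary
    least squares and evaluates each genotype's fitted line at the reference
    temperature. Requires at least two distinct covariate values overall.
    """
    import statsmodels.formula.api as smf

    df = records[["genotype_id", covariate, response]].dropna().copy()
    if df[covariate].nunique() < 2:
        raise ValueError("ANCOVA needs >= 2 distinct covariate values")
    model = smf.ols(f"{response} ~ C(genotype_id) + {covariate}", data=df).fit()
    slope = float(model.params[covariate])
    slope_se = float(model.bse[covariate])
    genos = sorted(df["genotype_id"].unique())
    pred = model.predict(pd.DataFrame({
        "genotype_id": genos, covariate: tref,
    }))
    means = pd.DataFrame({
        "genotype_id": genos,
        f"{response}_adjusted": pred.to_numpy(dtype=float),
    })
    return AncovaResult(adjusted_means=means, common_slope=slope,
                        slope_se=slope_se, response=response, tref=tref)


def correlation_matrix(df: pd.DataFrame, traits: list[str] | None = None,
                       method: str = "pearson") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise trait correlations with two-sided p-values.

    ``method`` is 'pearson' or 'spearman'. Zero-variance traits yield NaN
    coefficients for their pairs (flagged by the NaN itself). Returns
    (r matrix, p matrix), both symmetric with unit diagonal / zero diagonal.
    """
    if traits is None:
        traits = [c for c in df.columns
                  if c != "genotype_id" and pd.api.types.is_numeric_dtype(df[c])]
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x = df[traits[i]].to_numpy(dtype=float)
            y = df[traits[j]].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            x, y = x[ok], y[ok]
            if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij = np.nan, np.nan
            elif method == "pearson":
                rij, pij = stats.pearsonr(x, y)
            else:
                rij, pij = stats.spearmanr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rm = pd.DataFrame(r, index=traits, columns=traits)
    pm = pd.DataFrame(p, index=traits, columns=traits)
    return rm, pm


def correlation_edge_list(rm: pd.DataFrame, pm: pd.DataFrame) -> pd.DataFrame:
    """Long-format (trait_a, trait_b, r, p) export for chord-style plots."""
    rows = []
    traits = list(rm.columns)
    for i, a in enumerate(traits):
        for b in traits[i + 1:]:
            rows.append({"trait_a": a, "trait_b": b,
                         "r": rm.loc[a, b], "p": pm.loc[a, b]})
    return pd.DataFrame(rows)
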