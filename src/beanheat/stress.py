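"""Genotype stress index (GSI) for two-year yield trials.

The index is built in three steps on a genotype × year grain-yield table:

1. Yield ratio per experiment:  YR_j = Y_j / Ÿ, where Ÿ is the geometric
   mean yield of all genotypes in that experiment. By construction the
   geometric mean of YR within each experiment is exactly 1.
2. Stress intensity across experiments:  SII = 1 − Ÿ_stressed / Ÿ_reference,
   the relative drop of the stressed year's geometric mean. Which year
   plays the stressed role is an explicit configuration choice.
3. Genotype stress index:
       literal   GSI = (1 − GM(YR_year1, YR_year2)) / SII
       oriented  GSI = (GM(YR_year1, YR_year2) − 1) / SII
   The literal form is the printed composite; it is negative for genotypes
   whose yield sits above the population average. The oriented form flips
   the sign so that larger GSI means more stress-resistant, which matches
   how rankings built on this index are read. Both are reported;
   ``oriented`` is the default ordering. literal = −oriented identically.

YR is kept on the ratio scale internally (the "1 −" in step 3 is only
dimensionally coherent for ratios); percent is a formatting option.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class StressIndexError(ValueError):
    pass


def geometric_mean(values) -> float:
    """exp(mean(log x)); requires strictly positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StressIndexError("geometric mean of empty set")
    if np.any(v <= 0):
        raise StressIndexError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def yield_reduction(yields: pd.Series) -> pd.Series:
    """YR_j = Y_j / geometric mean of the experiment's yields."""
    gm = geometric_mean(yields)
    return yields / gm


def stress_intensity(reference_yields, stressed_yields) -> float:
    """SII = 1 − GM(stressed) / GM(reference)."""
    return 1.0 - geometric_mean(stressed_yields) / geometric_mean(reference_yields)


def genotype_stress_index(yr1, yr2, sii: float, mode: str = "oriented"):
    """Composite index from the two per-year yield ratios and the SII.

    ``mode='literal'`` evaluates (1 − GM(yr1, yr2))/SII as printed;
    ``mode='oriented'`` returns the negated value so larger = more
    resistant.
    """
    yr1 = np.asarray(yr1, dtype=float)
    yr2 = np.asarray(yr2, dtype=float)
    if np.any(yr1 <= 0) or np.any(yr2 <= 0):
        raise StressIndexError("yield ratios must be positive")
    if sii == 0:
        raise StressIndexError("SII = 0: stress index undefined")
    gm = np.sqrt(yr1 * yr2)
    literal = (1.0 - gm) / sii
    if mode == "literal":
        return literal
    if mode == "oriented":
        return -literal
    raise ValueError("mode must be 'literal' or 'oriented'")


def compute_stress_table(yields: pd.DataFrame,
                         stressed_year_role: str = "second",
                         mode: str = "oriented") -> pd.DataFrame:
    """Full YR → SII → GSI computation from a long yield table.

    ``yields`` must have columns genotype_id, year, yield with exactly two
    distinct year labels (sorted ascending; 'first'/'second' refer to that
    order). Genotypes missing a year are excluded from the index and
    returned with NaN GSI. Output columns: genotype_id, yr_<y1>, yr_<y2>,
    sii, gsi_literal, gsi_oriented, sorted by oriented GSI descending.
    """
    years = sorted(yields["year"].unique(), key=str)
    if len(years) != 2:
        raise StressIndexError(f"need exactly two years, found {years}")
    y1, y2 = years
    ref_year, stress_year = (y1, y2) if stressed_year_role == "second" else (y2, y1)

    per_year = {}
    for yr in years:
        sub = yields[yields["year"] == yr].groupby("genotype_id")["yield"].mean()
        per_year[yr] = yield_reduction(sub)
    sii = stress_intensity(
        yields.loc[yields["year"] == ref_year, "yield"],
        yields.loc[yields["year"] == stress_year, "yield"],
    )

    all_genos = sorted(set(yields["genotype_id"]))
    out = pd.DataFrame({"genotype_id": all_genos})
    out[f"yr_{y1}"] = out["genotype_id"].map(per_year[y1])
    out[f"yr_{y2}"] = out["genotype_id"].map(per_year[y2])
    out["sii"] = sii
    complete = out[[f"yr_{y1}", f"yr_{y2}"]].notna().all(axis=1)
    out["gsi_literal"] = np.nan
    out["gsi_oriented"] = np.nan
    if sii != 0:
        lit = genotype_stress_index(
            out.loc[complete, f"yr_{y1}"], out.loc[complete, f"yr_{y2}"],
            sii, mode="literal",
        )
        out.loc[complete, "gsi_literal"] = lit
        out.loc[complete, "gsi_oriented"] = -lit
    else:
        # degenerate: equal geometric means across years; a genotype exactly
        # at the population average still has a well-defined index of 0
        gm = np.sqrt(out.loc[complete, f"yr_{y1}"] * out.loc[complete, f"yr_{y2}"])
        at_avg = complete & np.isclose(gm.reindex(out.index), 1.0)
        out.loc[at_avg, ["gsi_literal", "gsi_oriented"]] = 0.0
    out["mode"] = mode
    key = "gsi_oriented" if mode == "oriented" else "gsi_literal"
    return out.sort_values(key, ascending=False, na_position="last").reset_index(drop=True)
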