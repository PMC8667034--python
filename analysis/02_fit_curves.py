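#!/usr/bin/env python
"""Fit the photosynthesis models to every simulated curve.

Per genotype: the A/PAR rectangular hyperbola (Amax, Φ, Rd, with derived
LCP/LSP) and the FvCB A/Ci model (Vcmax, Jmax, RD, Ci transition).
Compares the fits with the emitted generating truth and reports median
absolute relative errors.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from beanheat.fvcb import fit_aci
from beanheat.light import fit_light_response
from beanheat.io import read_delimited, write_results_table

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"

light = read_delimited(DATA / "light_curves.csv")
rows = []
for gid, grp in light.groupby("genotype_id", sort=True):
    p = fit_light_response(grp["Q"], grp["A"], genotype_id=gid)
    rows.append({"genotype_id": gid, "amax": p.amax, "phi": p.phi,
                 "rd": p.rd, "lcp": p.lcp, "lsp": p.lsp, "rmse": p.rmse})
light_fits = pd.DataFrame(rows)
write_results_table(light_fits, ROOT / "light_fits.csv")

aci = read_delimited(DATA / "aci_curves.csv")
rows = []
for gid, grp in aci.groupby("genotype_id", sort=True):
    q = fit_aci(grp["Ci"], grp["A"], genotype_id=gid)
    rows.append({"genotype_id": gid, "vcmax": q.vcmax, "jmax": q.jmax,
                 "rd_day": q.rd, "ci_transition": q.ci_transition,
                 "rmse": q.rmse, "flags": ";".join(q.flags)})
aci_fits = pd.DataFrame(rows)
write_results_table(aci_fits, ROOT / "aci_fits.csv")

lt = read_delimited(DATA / "light_curves_truth.csv").set_index("genotype_id")
at = read_delimited(DATA / "aci_curves_truth.csv").set_index("genotype_id")
lf = light_fits.set_index("genotype_id")
af = aci_fits.set_index("genotype_id")
amax_err = np.median(np.abs(lf["amax"] / lt["amax"] - 1))
vcmax_err = np.median(np.abs(af["vcmax"] / at["vcmax"] - 1))
print(f"fitted {len(lf)} light curves and {len(af)} A/Ci curves")
print(f"  median |rel err|: Amax {100 * amax_err:.2f}%, "
      f"Vcmax {100 * vcmax_err:.2f}%")
print(f"  mean LSP {lf['lsp'].mean():.0f} umol m-2 s-1, "
      f"mean Ci transition {af['ci_transition'].mean():.0f} ppm")
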