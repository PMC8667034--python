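#!/usr/bin/env python
"""Compute the genotype stress index from the two-year yield trial.

Builds the YR → SII → GSI table, reports the realized stress intensity
against the generator's implied value, and lists the most and least
heat-resistant genotypes by oriented GSI.
"""

from pathlib import Path

from beanheat.io import read_yield_table, write_results_table
from beanheat.stress import compute_stress_table

ROOT = Path(__file__).resolve().parents[1] / "results"

yields = read_yield_table(ROOT / "data" / "yields.csv", require_two_years=True)
table = compute_stress_table(yields)
write_results_table(table, ROOT / "stress_index.csv")

sii = table["sii"].iloc[0]
top = table.head(3)[["genotype_id", "gsi_oriented"]]
bottom = table.tail(3)[["genotype_id", "gsi_oriented"]]
print(f"stress intensity SII = {sii:.3f} "
      f"(generator's implied value 0.200)")
print("most resistant:", ", ".join(
    f"{r.genotype_id} ({r.gsi_oriented:+.2f})" for r in top.itertuples()))
print("least resistant:", ", ".join(
    f"{r.genotype_id} ({r.gsi_oriented:+.2f})" for r in bottom.itertuples()))
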