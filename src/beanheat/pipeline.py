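"""End-to-end orchestration: simulate → fit curves → traits → stress index
→ breakpoint → typology → climatology, from one configuration.

Every stage writes delimited text under the output directory and registers
its files in a JSON manifest; a config snapshot plus the seed is enough to
re-run the pipeline byte-identically.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate, fvcb, light, segmented, simulate, stress, traits, typology
from .config import AnalysisConfig
from .io import write_results_table

log = logging.getLogger("beanheat")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class PipelineRun:
    config: dict
    seed: int
    outdir: Path
    manifest: dict[str, str] = field(default_factory=dict)  # file -> stage
    stage_status: dict[str, str] = field(default_factory=dict)
    version: str = "0.1.0"

    def register(self, path: Path, stage: str) -> None:
        self.manifest[str(path.name)] = stage

    def write_manifest(self) -> Path:
        out = self.outdir / "run_manifest.json"
        out.write_text(json.dumps({
            "config": self.config, "seed": self.seed,
            "manifest": self.manifest, "stage_status": self.stage_status,
            "version": self.version,
        }, indent=2, default=str))
        return out


def _timed(run: PipelineRun, stage: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            status = "ok" if exc_type is None else f"failed: {exc}"
            run.stage_status[stage] = status
            log.info("stage %-12s %-28s %.2fs", stage, status, dt)
            return False
    return _Ctx()


def run_pipeline(cfg: AnalysisConfig, outdir: str | Path,
                 spec: simulate.GeneratorSpec | None = None) -> PipelineRun:
    """Run the full synthetic analysis and write all stage outputs.

    ``spec`` overrides the synthetic-study design; by default it follows
    the configured seed with the study-design defaults.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if spec is None:
        spec = simulate.GeneratorSpec(seed=cfg.seed)
    run = PipelineRun(config=cfg.to_dict(), seed=cfg.seed, outdir=outdir)

    # -- simulate ---------------------------------------------------------
    with _timed(run, "simulate"):
        light_curves, light_truth = simulate.gen_light_curves(spec)
        aci_curves, aci_truth = simulate.gen_aci_curves(spec)
        records, true_groups = simulate.gen_gas_exchange_records(spec)
        yields, yield_truth = simulate.gen_yield_table(spec)
        seg_data, seg_truth = simulate.gen_segmented_dataset(spec)
        weather = simulate.gen_weather_series(spec)
        for name, df in [("light_curves.csv", light_curves),
                         ("light_truth.csv", light_truth),
                         ("aci_curves.csv", aci_curves),
                         ("aci_truth.csv", aci_truth),
                         ("gas_exchange.csv", records),
                         ("yields.csv", yields),
                         ("segmented_data.csv", seg_data),
                         ("weather.csv", weather)]:
            run.register(write_results_table(df, outdir / name), "simulate")

    # -- curve fits -------------------------------------------------------
    with _timed(run, "fit_curves"):
        light_rows = []
        for gid, grp in light_curves.groupby("genotype_id", sort=True):
            p = light.fit_light_response(grp["Q"], grp["A"],
                                         lsp_fraction=cfg.lsp_fraction,
                                         genotype_id=gid)
            light_rows.append({"genotype_id": gid, "amax": p.amax,
                               "phi": p.phi, "rd": p.rd, "lcp": p.lcp,
                               "lsp": p.lsp, "rmse": p.rmse})
        light_fits = pd.DataFrame(light_rows)
        run.register(write_results_table(light_fits, outdir / "light_fits.csv"),
                     "fit_curves")
        aci_rows = []
        for gid, grp in aci_curves.groupby("genotype_id", sort=True):
            p = fvcb.fit_aci(grp["Ci"], grp["A"], spec.kinetics, genotype_id=gid)
            aci_rows.append({"genotype_id": gid, "vcmax": p.vcmax,
                             "jmax": p.jmax, "rd_day": p.rd,
                             "ci_transition": p.ci_transition,
                             "rmse": p.rmse, "flags": ";".join(p.flags)})
        aci_fits = pd.DataFrame(aci_rows)
        run.register(write_results_table(aci_fits, outdir / "aci_fits.csv"),
                     "fit_curves")

    # -- traits -----------------------------------------------------------
    with _timed(run, "traits"):
        trait_records = traits.derive_traits(records, cfg.ca_reference)
        summary = traits.aggregate_genotype_traits(trait_records)
        run.register(write_results_table(summary, outdir / "trait_summary.csv"),
                     "traits")
        basis = (summary.set_index("genotype_id")
                 .filter(like="_mean").rename(columns=lambda c: c[:-5])
                 .reset_index()
                 if cfg.correlation_granularity == "genotypes"
                 else trait_records)
        for method in ("pearson", "spearman"):
            rm, pm = traits.correlation_matrix(
                basis, traits=[t for t in traits.TRAIT_COLUMNS], method=method)
            edges = traits.correlation_edge_list(rm, pm)
            run.register(write_results_table(
                edges, outdir / f"correlations_{method}.csv"), "traits")
        adj_frames = []
        for response in ("A", "gs"):
            res = traits.ancova_adjusted_response(
                trait_records, response, cfg.reference_temperature)
            adj_frames.append(res.adjusted_means.set_index("genotype_id"))
        adjusted = pd.concat(adj_frames, axis=1).reset_index()
        run.register(write_results_table(adjusted, outdir / "adjusted_means.csv"),
                     "traits")

    # -- stress index ------------------------------------------------------
    with _timed(run, "stress_index"):
        gsi = stress.compute_stress_table(
            yields, stressed_year_role=cfg.stressed_year_role)
        run.register(write_results_table(gsi, outdir / "stress_index.csv"),
                     "stress_index")

    # -- breakpoint --------------------------------------------------------
    with _timed(run, "breakpoint"):
        fit = segmented.fit_two_segment(
            seg_data["Tair"], seg_data["A"],
            grid_step=cfg.gamma_grid_step, margin=cfg.gamma_margin)
        bp = pd.DataFrame([{
            "gamma": fit.gamma, "beta0": fit.beta0, "beta1": fit.beta1,
            "beta2": fit.beta2, "sse": fit.sse,
            "single_line_sse": fit.single_line_sse,
            "slope2_se": fit.slope2_se, "flags": ";".join(fit.flags),
        }])
        run.register(write_results_table(bp, outdir / "breakpoint.csv"),
                     "breakpoint")
        profile = pd.DataFrame({"gamma": fit.profile[0], "sse": fit.profile[1]})
        run.register(write_results_table(profile, outdir / "breakpoint_profile.csv"),
                     "breakpoint")

    # -- typology ----------------------------------------------------------
    with _timed(run, "typology"):
        trait_table, _ = simulate.gen_trait_table(spec)
        X = typology.standardize_traits(trait_table, simulate.PROFILE_TRAITS)
        sel = typology.select_k(X, kmax=cfg.kmax)
        labels, Z = typology.ward_cluster(X, sel.k)
        label_df = pd.DataFrame({"genotype_id": trait_table["genotype_id"],
                                 "cluster": labels,
                                 "true_group": true_groups.values})
        run.register(write_results_table(label_df, outdir / "typology_labels.csv"),
                     "typology")
        linkage_df = pd.DataFrame(Z, columns=["left", "right", "height", "size"])
        run.register(write_results_table(linkage_df, outdir / "typology_linkage.csv"),
                     "typology")
        pres = typology.pca(X)
        scores = pd.DataFrame(pres.scores[:, :2], columns=["PC1", "PC2"])
        scores.insert(0, "genotype_id", trait_table["genotype_id"])
        run.register(write_results_table(scores, outdir / "pca_scores.csv"),
                     "typology")
        perm = typology.between_group_test(X, labels,
                                           n_permutations=cfg.permutations,
                                           seed=cfg.seed)
        perm_df = pd.DataFrame([{
            "statistic": perm.statistic, "n_permutations": perm.n_permutations,
            "p_value": perm.p_value, "seed": perm.seed,
            "k": sel.k, "silhouette": sel.silhouettes[sel.k],
        }])
        run.register(write_results_table(perm_df, outdir / "typology_test.csv"),
                     "typology")

    # -- climatology -------------------------------------------------------
    with _timed(run, "climatology"):
        years = sorted(weather["date"].dt.year.unique())
        windows = [climate.SeasonWindow(
            year=int(y), sowing=Date(int(y), 1, 1) + pd.Timedelta(
                days=cfg.sowing_doy - 1).to_pytimedelta(),
            start_offset=cfg.window_start, end_offset=cfg.window_end)
            for y in years]
        risk = climate.season_risk_summary(
            weather, windows, day_threshold=cfg.day_threshold,
            night_threshold=cfg.night_threshold,
            reference_tmax=cfg.reference_temperature)
        run.register(write_results_table(risk["per_season"],
                                         outdir / "season_risk.csv"),
                     "climatology")
        run.register(write_results_table(risk["annual_days_above_reference"],
                                         outdir / "annual_hot_days.csv"),
                     "climatology")
        fr = pd.DataFrame([{
            "fraction_seasons_day_exceed": risk["fraction_seasons_day_exceed"],
            "fraction_seasons_night_exceed": risk["fraction_seasons_night_exceed"],
        }])
        run.register(write_results_table(fr, outdir / "season_fractions.csv"),
                     "climatology")
        vpd = climate.add_vpd(weather)
        run.register(write_results_table(
            vpd[["date", "vpd"]], outdir / "daily_vpd.csv"), "climatology")

    run.write_manifest()
    return run
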