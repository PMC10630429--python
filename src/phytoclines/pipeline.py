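"""Pipeline orchestration: simulate -> derive -> regress -> ordinate ->
perform, with config handling, seed management, and run manifests.

A single seed governs every stochastic stage; stages derive independent
child streams from it by a counter, so any stage can be rerun alone and
reproduce its outputs byte-for-byte.  Each stage writes its result files
plus a manifest entry recording inputs, options, and a content hash of
every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import derived, ordination, performance, regression, simulate
from .datamodel import (
    PerformanceCell,
    read_newick,
    read_site_info,
    read_species_info,
    read_trait_definitions,
    read_trait_table,
)

__all__ = ["RunConfig", "run_pipeline", "end_to_end_check"]

STAGES = ("simulate", "derive", "regress", "ordinate", "perform")


@dataclass
class RunConfig:
    """Declarative run configuration; round-trips losslessly through YAML."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    input_dir: str = "inputs"
    output_dir: str = "outputs"
    seed: int = 0
    n_species: int = 10
    n_sites: int = 4
    n_traits: int = 53
    kleaf_min_gradient: float = 0.3
    fvfm_threshold: float = 0.7
    use_phylogeny: bool = True
    lrt_cutoff: float = 0.5
    m_total: int = 106
    alpha: float = 0.05

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _preflight(cfg: RunConfig) -> None:
    """Check referenced inputs exist before any stage runs."""
    needs_inputs = [s for s in cfg.stages if s != "simulate"]
    if "simulate" in cfg.stages or not needs_inputs:
        return
    indir = Path(cfg.input_dir)
    required = ["trait_table.csv", "tree.nwk", "sites.csv", "species.csv",
                "predictions.csv", "performance.csv"]
    missing = [f for f in required if not (indir / f).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files before run: {missing}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in order and write a run manifest.

    Identical (config, seed) pairs reproduce identical result files.
    A stage failure halts the pipeline; the manifest marks the run invalid.
    """
    unknown = [s for s in cfg.stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    _preflight(cfg)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = Path(cfg.input_dir)
    manifest: dict = {"seed": cfg.seed, "config": dataclasses.asdict(cfg),
                      "stages": {}, "valid": False}
    manifest_path = outdir / "manifest.json"

    def record(stage: str, outputs: list[Path], options: dict, t0: float) -> None:
        manifest["stages"][stage] = {
            "options": options,
            "wall_time_s": round(time.time() - t0, 3),
            "outputs": {str(p): _sha256(p) for p in outputs},
        }

    try:
        for stage in [s for s in STAGES if s in cfg.stages]:
            t0 = time.time()
            if stage == "simulate":
                sim_cfg = simulate.SimulationConfig(
                    n_species=cfg.n_species, n_sites=cfg.n_sites,
                    traits=simulate.default_traits(cfg.n_traits), seed=cfg.seed,
                )
                paths = simulate.write_study(sim_cfg, indir)
                record(stage, [Path(p) for p in paths.values()],
                       {"n_traits": cfg.n_traits}, t0)
            elif stage == "derive":
                outputs = _stage_derive(cfg, indir, outdir)
                record(stage, outputs, {"fvfm_threshold": cfg.fvfm_threshold,
                                        "kleaf_min_gradient": cfg.kleaf_min_gradient}, t0)
            elif stage == "regress":
                outputs = _stage_regress(cfg, indir, outdir)
                record(stage, outputs, {"use_phylogeny": cfg.use_phylogeny,
                                        "lrt_cutoff": cfg.lrt_cutoff,
                                        "m_total": cfg.m_total}, t0)
            elif stage == "ordinate":
                outputs = _stage_ordinate(cfg, indir, outdir)
                record(stage, outputs, {}, t0)
            elif stage == "perform":
                outputs = _stage_perform(cfg, indir, outdir)
                record(stage, outputs, {"alpha": cfg.alpha}, t0)
        manifest["valid"] = True
    finally:
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage bodies
# ---------------------------------------------------------------------------


def _stage_derive(cfg: RunConfig, indir: Path, outdir: Path) -> list[Path]:
    """Derived traits from the raw measurement streams, with a QC log."""
    qc: list[dict] = []
    rows: dict[str, float] = {}

    d = pd.read_csv(indir / "raw_drying.csv")
    series = derived.DryingSeries(
        time_h=d["time_h"].to_numpy(), leaf_mass_g=d["leaf_mass_g"].to_numpy(),
        fvfm=d["fvfm"].to_numpy(), rh=float(d["rh"].iloc[0]),
        temp_c=float(d["temp_c"].iloc[0]),
        pressure_kpa=float(d["pressure_kpa"].iloc[0]),
        leaf_area_m2=float(d["leaf_area_m2"].iloc[0]),
    )
    g = derived.compute_gmin(series, fvfm_threshold=cfg.fvfm_threshold)
    qc.append({"trait": "g_min", "ok": g.ok, "reason": g.reason,
               "warnings": "; ".join(g.warnings)})
    if g.ok:
        rows["g_min"] = g.value

    fp = pd.read_csv(indir / "raw_flow_pressure.csv")
    ks = derived.compute_kstem(
        derived.FlowPressureSeries(
            flow_g_s=fp["flow_g_s"].to_numpy(),
            pressure_gradient_mpa_mm=fp["pressure_gradient_mpa_mm"].to_numpy(),
            temp_c=float(fp["temp_c"].iloc[0]),
            xylem_area_mm2=float(fp["xylem_area_mm2"].iloc[0]),
        )
    )
    qc.append({"trait": "K_stem", "ok": ks.ok, "reason": ks.reason, "warnings": ""})
    if ks.ok:
        rows["K_stem"] = ks.value

    v = pd.read_csv(indir / "raw_vessels.csv")
    sample = derived.VesselSample(
        diameters_um=v["diameter_um"].to_numpy(),
        counted_area_mm2=float(v["counted_area_mm2"].iloc[0]),
    )
    rows["D_h"] = derived.hydraulic_diameter(sample)
    rows["K_stem_theo"] = derived.theoretical_conductivity(sample)
    qc.append({"trait": "D_h", "ok": True, "reason": "", "warnings": ""})

    r = pd.read_csv(indir / "raw_roots.csv")
    _, summary = derived.impute_root_mass(derived.RootSegmentTable(r))
    rows["root_mass_total"] = summary["total_mass_g"]
    qc.append({"trait": "root_mass_total", "ok": True,
               "reason": f"imputed_fraction={summary['imputed_fraction']:.4f}",
               "warnings": ""})

    gr = pd.read_csv(indir / "raw_growth.csv")
    rows["RGR_mass"] = derived.relative_growth_rate(
        derived.GrowthSeries(day=gr["day"].to_numpy(),
                             value=gr["geometric_mean_mass_g"].to_numpy())
    )
    qc.append({"trait": "RGR_mass", "ok": True, "reason": "", "warnings": ""})

    out_csv = outdir / "derived_traits.csv"
    pd.DataFrame([rows]).to_csv(out_csv, index=False)
    qc_csv = outdir / "derived_qc.csv"
    pd.DataFrame(qc).to_csv(qc_csv, index=False)
    return [out_csv, qc_csv]


def _load_study(indir: Path):
    defs = read_trait_definitions(indir / "predictions.csv")
    tt = read_trait_table(indir / "trait_table.csv", defs)
    tree = read_newick(indir / "tree.nwk")
    sites = read_site_info(indir / "sites.csv")
    species = read_species_info(indir / "species.csv")
    tt.validate_against(species, sites)
    return tt, tree, sites, species, defs


def _stage_regress(cfg: RunConfig, indir: Path, outdir: Path) -> list[Path]:
    tt, tree, sites, species, defs = _load_study(indir)
    results = []
    skipped = []
    for trait_id in tt.trait_ids:
        try:
            results.append(
                regression.select_model(
                    trait_id, tt, tree, sites, species,
                    use_phylogeny=cfg.use_phylogeny, lrt_cutoff=cfg.lrt_cutoff,
                )
            )
        except ValueError as exc:
            skipped.append({"trait_id": trait_id, "reason": str(exc)})
    tally = regression.tally_agreement(
        results, defs, m_total=cfg.m_total, alpha=cfg.alpha
    )
    rows = []
    for r in results:
        for pred in regression.PREDICTORS:
            c = r.coefficients[pred]
            rows.append(
                {
                    "trait_id": r.trait_id, "predictor": pred, "form": r.form,
                    "transform": r.transform.value, "estimate": c["estimate"],
                    "se": c["se"], "p": c["p"],
                    "p_adjusted": r.adjusted_p.get(pred, np.nan),
                    "r2_total": r.r2_total,
                    "partial_r2": r.partial_r2.get(pred, np.nan),
                    "retained_effects": "+".join(r.retained_effects),
                    "aic": r.aic, "n_obs": r.n_obs,
                    "verdict": r.verdicts.get(pred, ""),
                    "weight": r.tally_weights.get(pred, np.nan),
                }
            )
    out_csv = outdir / "regression_results.csv"
    pd.DataFrame(rows).to_csv(out_csv, index=False)
    tally_json = outdir / "tally_report.json"
    tally_json.write_text(
        json.dumps(
            {
                "pct_agree": tally.pct_agree,
                "pct_significant_agree": tally.pct_significant_agree,
                "n_traits": tally.n_traits,
                "skipped": skipped,
            },
            indent=1, sort_keys=True,
        )
    )
    return [out_csv, tally_json]


def _stage_ordinate(cfg: RunConfig, indir: Path, outdir: Path) -> list[Path]:
    tt, tree, sites, species, defs = _load_study(indir)
    # orient trait columns by predicted direction so "adaptive" sectors are
    # interpretable: a trait predicted to decrease is entered negated
    oriented = tt.data.copy()
    for d in defs:
        if d.predicted_direction < 0 and d.trait_id in oriented:
            oriented[d.trait_id] = -oriented[d.trait_id]
    tt_o = type(tt)(data=oriented, definitions=tt.definitions, excluded=tt.excluded)
    ordn = ordination.run_pca(tt_o)
    ordination.project_gradients(ordn, sites, species)
    ordination.classify_sectors(ordn)
    norms = ordination.pc_reaction_norms(ordn, sites, species)
    loadings_csv = outdir / "pca_loadings.csv"
    ordn.loadings.to_csv(loadings_csv)
    scores_csv = outdir / "pca_scores.csv"
    ordn.scores.to_csv(scores_csv)
    sectors_csv = outdir / "pca_sectors.csv"
    ordn.sectors.to_frame().to_csv(sectors_csv)
    summary = {
        "two_axis_variance_pct": float(100 * ordn.variance_fraction[:2].sum()),
        "gradient_angle_deg": ordn.gradient_angle_deg,
        "site_slope_mean": norms.site_slope_mean,
        "site_slope_sd": norms.site_slope_sd,
        "species_slope_mean": norms.species_slope_mean,
        "species_slope_sd": norms.species_slope_sd,
        "slope_ratio": norms.slope_ratio,
        "per_species_ratio_mean": norms.per_species_ratio_mean,
        "common_slope_p": norms.common_slope_p,
        "n_imputed_cells": ordn.n_imputed_cells,
    }
    summary_json = outdir / "ordination_summary.json"
    summary_json.write_text(json.dumps(summary, indent=1, sort_keys=True))
    return [loadings_csv, scores_csv, sectors_csv, summary_json]


def _stage_perform(cfg: RunConfig, indir: Path, outdir: Path) -> list[Path]:
    sites = read_site_info(indir / "sites.csv")
    species = read_species_info(indir / "species.csv")
    perf = pd.read_csv(indir / "performance.csv")
    cells = [
        PerformanceCell(
            species_id=str(r.species_id), site_id=str(r.site_id),
            n_planted=int(r.n_planted), n_survived=int(r.n_survived),
            n_measured=int(r.n_measured),
            trait_mean=float(r.trait_mean) if pd.notna(r.trait_mean) else 0.0,
            trait_sd=float(r.trait_sd),
        )
        for r in perf.itertuples()
    ]
    growth = [performance.realized_growth(c) for c in cells]
    pair_frames = []
    for site_id in sorted({c.site_id for c in cells}):
        site_growth = [g for g in growth if g.site_id == site_id]
        try:
            pairs, _ = performance.compare_realized(site_growth, alpha=cfg.alpha)
            pairs.insert(0, "site_id", site_id)
            pair_frames.append(pairs)
        except ValueError:
            pass
    report = performance.detect_crossover(growth, sites, species)
    growth_csv = outdir / "realized_growth.csv"
    pd.DataFrame(
        [
            {"species_id": g.species_id, "site_id": g.site_id,
             "h_star": g.h_star, "se": g.se, "p_hat": g.p_hat,
             "letters": g.letters}
            for g in growth
        ]
    ).to_csv(growth_csv, index=False)
    pairs_csv = outdir / "pairwise_h_star.csv"
    pd.concat(pair_frames, ignore_index=True).to_csv(pairs_csv, index=False)
    cross_json = outdir / "crossover_report.json"
    cross_json.write_text(
        json.dumps(
            {
                "crossover": report.crossover,
                "rho_driest": report.rho_driest,
                "rho_wettest": report.rho_wettest,
                "driest_site": report.driest_site,
                "wettest_site": report.wettest_site,
                "top_species_local": report.top_species_local,
            },
            indent=1, sort_keys=True,
        )
    )
    return [growth_csv, pairs_csv, cross_json]


# ---------------------------------------------------------------------------
# End-to-end check
# ---------------------------------------------------------------------------


def end_to_end_check(seed: int = 0, workdir: str | Path = "e2e_check") -> dict:
    """Run the default synthetic study and assert its acceptance properties:
    generative slopes recovered, tally agreement matching the planted
    directions, and the planted cross-over detected.

    Returns a verdict dict; raises AssertionError naming the first failing
    property.
    """
    workdir = Path(workdir)
    cfg = RunConfig(
        input_dir=str(workdir / "inputs"), output_dir=str(workdir / "outputs"),
        seed=seed, n_traits=12,
    )
    run_pipeline(cfg)
    verdict: dict = {}

    truth = json.loads((workdir / "inputs" / "truth.json").read_text())
    res = pd.read_csv(workdir / "outputs" / "regression_results.csv")
    merged_ok = []
    for trait_id, t in truth["traits"].items():
        sub = res[res["trait_id"] == trait_id]
        b_site = float(sub[sub["predictor"] == "ln_site_pe"]["estimate"].iloc[0])
        b_species = float(sub[sub["predictor"] == "ln_species_pe"]["estimate"].iloc[0])
        merged_ok.append(
            np.sign(b_site) == np.sign(t["b_site"])
            and np.sign(b_species) == np.sign(t["b_species"])
        )
    verdict["slope_signs_recovered"] = float(np.mean(merged_ok))
    assert np.mean(merged_ok) >= 0.9, "parameter recovery: slope signs not recovered"

    tally = json.loads((workdir / "outputs" / "tally_report.json").read_text())
    verdict["pct_agree_site"] = tally["pct_agree"]["ln_site_pe"]
    verdict["pct_agree_species"] = tally["pct_agree"]["ln_species_pe"]
    assert tally["pct_agree"]["ln_site_pe"] >= 90.0, "tally: site agreement below planted level"
    assert tally["pct_agree"]["ln_species_pe"] >= 90.0, "tally: species agreement below planted level"

    cross = json.loads((workdir / "outputs" / "crossover_report.json").read_text())
    verdict["crossover"] = cross["crossover"]
    assert cross["crossover"], "cross-over: planted rank reversal not detected"
    verdict["ok"] = True
    return verdict
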