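"""Config-driven orchestration of the modelling and genetics tracks.

A :class:`RunConfig` fully determines a run: synthetic-data configurations,
one global seed, the rarefaction/permutation effort, and the output
directory. The global seed is expanded into per-stage child seeds by a
deterministic rule (SHA-256 of ``"<seed>:<stage>"`` modulo 2^31), so any
stage can be rerun in isolation.

Stages, in order: landscape -> occurrences -> spatial pruning ->
pseudo-absences -> monotone BRT with latitudinal-band CV -> threshold ->
present and glacial predictions -> refugium raster and range report ->
sites/genotypes -> diversity, differentiation, network, Evanno summaries ->
diversity-versus-distance-to-refugium join. Every artifact lands in the run
directory and is listed in a manifest with SHA-256 checksums; a JSON-lines
log records per-stage timings and record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import allele_network, popgen, sdm, structure_summary, synthdata
from .io_formats import write_cluster_runs, write_genotypes, write_membership, write_raster, write_site_table
from .synthdata import GenotypeSimConfig, LandscapeConfig


def child_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of "<seed>:<stage>" mod 2^31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int
    outdir: str
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    genotypes: GenotypeSimConfig = field(default_factory=GenotypeSimConfig)
    n_occurrences: int = 800
    n_sites: int = 40
    # the demo landscape is gradient-dominated, so predictors stay
    # autocorrelated across any tested range; capping the scanned classes
    # bounds the fallback pruning distance at a workable record density
    pruning_max_classes: int = 2
    rarefaction_reps: int = 2000
    rarefaction_g: Optional[int] = None  # None -> smallest-usable-sample rule
    network_permutations: int = 2000
    structure_true_k: int = 2
    structure_k_max: int = 6
    structure_replicates: int = 10
    sdm_hyper_grid: str = "default"  # "default" | "full"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("run config must carry an explicit seed")

    # ------------------------------------------------------------------ yaml
    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["landscape"]["niche"] = {k: list(v) for k, v in payload["landscape"]["niche"].items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "seed" not in payload or payload["seed"] is None:
            raise ValueError("run config must carry an explicit seed")
        land = payload.pop("landscape", {})
        if "niche" in land:
            land["niche"] = {k: tuple(v) for k, v in land["niche"].items()}
        geno = payload.pop("genotypes", {})
        return cls(landscape=LandscapeConfig(**land), genotypes=GenotypeSimConfig(**geno), **payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the full demo pipeline; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logfile = outdir / "run_log.jsonl"
    manifest: Dict = {"config": str(outdir / "config.yaml"), "artifacts": {}, "stages": []}
    config.to_yaml(outdir / "config.yaml")

    def log_stage(stage: str, t0: float, **counts) -> None:
        entry = {"stage": stage, "seconds": round(time.time() - t0, 3), **counts}
        manifest["stages"].append(entry)
        with open(logfile, "a") as fh:
            fh.write(json.dumps(entry) + "\n")

    def register(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    state: Dict = {}
    try:
        stage = "landscape"
        t0 = time.time()
        land_cfg = dataclasses.replace(config.landscape, seed=child_seed(config.seed, "landscape"))
        present, lgm = synthdata.generate_landscape(land_cfg)
        for label, stk in (("present", present), ("lgm", lgm)):
            p = outdir / f"suitability_input_{label}_bathymetry.asc"
            write_raster(stk.bathymetry, p, stk.lon, stk.lat)
            register(f"{label}_bathymetry", p)
        state.update(present=present, lgm=lgm, land_cfg=land_cfg)
        log_stage(stage, t0, cells=int(np.prod(present.shape)))

        stage = "occurrences"
        t0 = time.time()
        occ = synthdata.generate_occurrences(present, land_cfg, config.n_occurrences, child_seed(config.seed, "occurrences"))
        occ.data.to_csv(outdir / "occurrences.csv", index=False)
        register("occurrences", outdir / "occurrences.csv")
        log_stage(stage, t0, records=len(occ.data))

        stage = "pruning"
        t0 = time.time()
        pruned, prune_km, correlogram = sdm.correlogram_prune(
            occ,
            present,
            seed=child_seed(config.seed, "pruning"),
            class_width_km=present.resolution * 111.32,
            n_classes=config.pruning_max_classes,
        )
        correlogram.to_csv(outdir / "correlogram.csv", index=False)
        register("correlogram", outdir / "correlogram.csv")
        log_stage(stage, t0, kept=len(pruned.data), pruning_km=prune_km)

        stage = "pseudo_absences"
        t0 = time.time()
        training = sdm.sample_pseudo_absences(pruned, present, seed=child_seed(config.seed, "pseudo_absences"))
        training.data.to_csv(outdir / "training_points.csv", index=False)
        register("training_points", outdir / "training_points.csv")
        log_stage(stage, t0, presences=len(training.presences), absences=len(training.absences))

        stage = "sdm_fit"
        t0 = time.time()
        table = sdm.training_table(training, present)
        grid = sdm.full_hyper_grid() if config.sdm_hyper_grid == "full" else sdm.default_hyper_grid()
        fitted = sdm.fit_brt_cv(table, hyper_grid=grid, seed=child_seed(config.seed, "sdm_fit"))
        retained, removal_log = sdm.stepwise_reduce(
            table, fitted.predictors, fitted.hypers, seed=child_seed(config.seed, "stepwise")
        )
        if set(retained) != set(fitted.predictors):
            refit = sdm.fit_brt_cv(table, predictors=retained, hyper_grid=grid, seed=child_seed(config.seed, "sdm_fit"))
        else:
            refit = fitted
        contrib = sdm.relative_contributions(table, refit.predictors, refit.hypers, seed=child_seed(config.seed, "contrib"))
        limits = sdm.response_tolerance_limits(refit)
        report = pd.DataFrame(
            {
                "cv_auc_mean": [refit.cv_auc_mean],
                "cv_auc_sd": [refit.cv_auc_sd],
                "cv_sens_mean": [refit.cv_sens_mean],
                "cv_sens_sd": [refit.cv_sens_sd],
                "final_auc": [refit.final_auc],
                "final_sensitivity": [refit.final_sensitivity],
                "threshold": [refit.threshold],
            }
        )
        report.to_csv(outdir / "sdm_performance.csv", index=False)
        contrib.rename("contribution_pct").to_csv(outdir / "sdm_contributions.csv")
        limits.to_csv(outdir / "sdm_tolerance_limits.csv")
        removal_log.to_csv(outdir / "sdm_stepwise_log.csv", index=False)
        for name in ("sdm_performance", "sdm_contributions", "sdm_tolerance_limits", "sdm_stepwise_log"):
            register(name, outdir / f"{name}.csv")
        state["model"] = refit
        log_stage(stage, t0, predictors=len(refit.predictors), cv_auc=refit.cv_auc_mean)

        stage = "predict"
        t0 = time.time()
        suit_p, bin_p = sdm.predict_and_binarize(refit, present)
        suit_l, bin_l = sdm.predict_and_binarize(refit, lgm)
        for label, (suit, binary, stk) in {
            "present": (suit_p, bin_p, present),
            "lgm": (suit_l, bin_l, lgm),
        }.items():
            write_raster(suit, outdir / f"suitability_{label}.asc", stk.lon, stk.lat)
            write_raster(binary.astype(float), outdir / f"binary_{label}.asc", stk.lon, stk.lat)
            register(f"suitability_{label}", outdir / f"suitability_{label}.asc")
            register(f"binary_{label}", outdir / f"binary_{label}.asc")
        state.update(bin_p=bin_p, bin_l=bin_l)
        log_stage(stage, t0, present_cells=int(bin_p.sum()), lgm_cells=int(bin_l.sum()))

        stage = "sites"
        t0 = time.time()
        sites = synthdata.generate_sites(present, lgm, land_cfg, n_sites=config.n_sites, seed=child_seed(config.seed, "sites"))
        write_site_table(sites, outdir / "sites.csv")
        register("sites", outdir / "sites.csv")
        log_stage(stage, t0, sites=len(sites))

        stage = "range_report"
        t0 = time.time()
        regions = {
            g: _region_mask(present, sites[sites["region"] == g]) for g in sorted(sites["region"].unique())
        }
        report = sdm.area_and_change(bin_l, bin_p, present.lat, present.resolution, regions)
        report.to_csv(outdir / "range_report.csv")
        register("range_report", outdir / "range_report.csv")
        refugium = bin_l
        write_raster(refugium.astype(float), outdir / "refugium.asc", present.lon, present.lat)
        register("refugium", outdir / "refugium.asc")
        log_stage(stage, t0, refugium_cells=int(refugium.sum()))

        stage = "genotypes"
        t0 = time.time()
        geno_cfg = dataclasses.replace(
            config.genotypes, n_sites=len(sites), seed=child_seed(config.seed, "genotypes")
        )
        genotypes = synthdata.generate_genotypes(geno_cfg, sites)
        write_genotypes(genotypes, outdir / "genotypes.csv", "csv")
        write_genotypes(genotypes, outdir / "genotypes.gen", "genepop")
        register("genotypes_csv", outdir / "genotypes.csv")
        register("genotypes_genepop", outdir / "genotypes.gen")
        log_stage(stage, t0, individuals=genotypes.n_individuals)

        stage = "popgen"
        t0 = time.time()
        freqs = popgen.allele_frequencies(genotypes)
        he = popgen.gene_diversity(freqs)
        div = popgen.rarefied_diversity(
            freqs,
            g=config.rarefaction_g,
            reps=config.rarefaction_reps,
            seed=child_seed(config.seed, "rarefaction"),
        )
        div["He"] = he
        div.to_csv(outdir / "diversity.csv")
        register("diversity", outdir / "diversity.csv")
        groups = dict(zip(sites["site_id"], sites["level1"].astype(str)))
        d_matrix = popgen.josts_d(freqs, groups)
        d_matrix.to_csv(outdir / "josts_d_level1.csv")
        register("josts_d_level1", outdir / "josts_d_level1.csv")
        state.update(freqs=freqs, div=div)
        log_stage(stage, t0, sites=len(div))

        stage = "network"
        t0 = time.time()
        sim = allele_network.shared_allele_similarity(freqs)
        net = allele_network.percolate(sim)
        p_val = allele_network.modularity_permutation_test(
            net, n_perm=config.network_permutations, seed=child_seed(config.seed, "network")
        )
        cent, hubs = allele_network.centrality_hubs(net)
        allele_network.write_edge_list(net, outdir / "network_edges.csv")
        summary = pd.DataFrame(
            {
                "site": net.sites,
                "community": net.communities,
                "centrality": cent.to_numpy(),
                "hub": [s in hubs for s in net.sites],
            }
        )
        summary.to_csv(outdir / "network_summary.csv", index=False)
        register("network_edges", outdir / "network_edges.csv")
        register("network_summary", outdir / "network_summary.csv")
        log_stage(stage, t0, communities=net.n_communities, modularity=net.modularity, p_value=p_val)

        stage = "structure"
        t0 = time.time()
        runs = synthdata.generate_structure_runs(
            config.structure_true_k,
            config.structure_k_max,
            config.structure_replicates,
            seed=child_seed(config.seed, "structure"),
        )
        write_cluster_runs(runs, outdir / "structure_runs.csv")
        register("structure_runs", outdir / "structure_runs.csv")
        dk = structure_summary.delta_k(runs)
        dk.table.to_csv(outdir / "delta_k.csv", index=False)
        register("delta_k", outdir / "delta_k.csv")
        membership = synthdata.synthetic_membership(
            sites,
            dict(zip(sites["site_id"], sites["level1"])),
            seed=child_seed(config.seed, "membership"),
        )
        write_membership(membership, outdir / "membership.csv")
        register("membership", outdir / "membership.csv")
        assign = structure_summary.assign_and_flag(membership)
        assign.to_csv(outdir / "assignments.csv")
        register("assignments", outdir / "assignments.csv")
        log_stage(stage, t0, selected_k=dk.selected_k)

        stage = "refugia_join"
        t0 = time.time()
        table, binned, trends = popgen.diversity_vs_refugia(
            state["div"], sites, state["bin_l"], present.lon, present.lat
        )
        table.to_csv(outdir / "diversity_vs_refugia.csv")
        binned.to_csv(outdir / "diversity_vs_refugia_binned.csv", index=False)
        register("diversity_vs_refugia", outdir / "diversity_vs_refugia.csv")
        register("diversity_vs_refugia_binned", outdir / "diversity_vs_refugia_binned.csv")
        trend_path = outdir / "refugia_trends.json"
        trend_path.write_text(json.dumps({k: {"rho": v[0], "p": v[1]} for k, v in trends.items()}, indent=2))
        register("refugia_trends", trend_path)
        log_stage(stage, t0, **{f"rho_{k}": v[0] for k, v in trends.items()})
    except Exception as exc:  # noqa: BLE001 - abort with stage name + partial manifest
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _region_mask(stack, region_sites: pd.DataFrame) -> np.ndarray:
    """Cells whose latitude falls within the region's site latitude span."""
    mask = np.zeros(stack.shape, dtype=bool)
    lo, hi = region_sites["lat"].min(), region_sites["lat"].max()
    rows = (stack.lat >= lo - stack.resolution) & (stack.lat <= hi + stack.resolution)
    mask[rows, :] = True
    return mask
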