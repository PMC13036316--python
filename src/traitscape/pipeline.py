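"""End-to-end pipeline: simulate -> impute -> model -> diversity -> prioritize -> report.

Every stage writes flat CSV/JSON artifacts into a run directory so any
stage can be inspected, or replaced by real data in the same formats.
All randomness derives deterministically from the single master seed, so a
rerun with an identical config is bit-identical; completed stages are
skipped on rerun when the stored config checksum matches (resume).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    diversity,
    importance as importance_mod,
    jsdm,
    occurrences as occ,
    phylogeny,
    prioritization as prio,
    synthetic_data as synth,
    traits as traits_mod,
)

log = logging.getLogger("traitscape")


@dataclass
class PipelineConfig:
    """All pipeline parameters; the defaults reproduce the analysis settings
    (20 abundance draws, 98.5% coverage, 10 CV folds, 15 imputation
    iterations, boundary penalty 0.003, edge factor 0.5, budgets 20%/35%
    for targets 30%/70%)."""

    # synthetic landscape
    n_species: int = 40
    n_x: int = 8
    n_y: int = 8
    missing_rate: float = 0.30
    master_seed: int = 0
    # which traits get their own co-occurrence model run
    model_traits: tuple = ("leaf_length", "red")
    variants: tuple = occ.VARIANTS
    # model evaluation
    cv_folds: int = 10
    # imputation
    imputation_iterations: int = 15
    n_eigenvectors: int = 10
    # diversity
    n_draws: int = 20
    coverage_target: float = 0.985
    # prioritization
    boundary_penalty: float = 0.003
    edge_factor: float = 0.5
    scenarios: tuple = ((0.30, 0.20), (0.70, 0.35))  # (target, budget) pairs
    ensemble_size: int = 100
    cost_jitter_sd: float = 0.3
    locked_in: tuple = ()
    # stage toggles
    stages: tuple = (
        "simulate", "impute", "datasets", "models", "evaluate",
        "diversity", "prioritize", "importance", "report",
    )

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in data.items()})

    def to_dict(self) -> dict:
        return asdict(self)

    def checksum(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def validate(config: PipelineConfig) -> list[str]:
    """Collect configuration problems (empty list = valid)."""
    issues = []
    if config.n_species < 4:
        issues.append("n_species must be at least 4")
    if config.n_x * config.n_y < 4:
        issues.append("grid must have at least 4 planning units")
    if not (0 <= config.missing_rate < 0.7):
        issues.append("missing_rate must lie in [0, 0.7)")
    if config.cv_folds < 2:
        issues.append("cv_folds must be >= 2")
    if not (0 < config.coverage_target <= 1):
        issues.append("coverage_target must lie in (0, 1]")
    for target, budget in config.scenarios:
        if not (0 < target <= 1):
            issues.append(f"target {target} outside (0, 1]")
        if not (0 < budget <= 1):
            issues.append(f"budget {budget} outside (0, 1]")
    known = set(traits_mod.CONTINUOUS_TRAITS + traits_mod.HABIT_TRAITS + traits_mod.COLOR_TRAITS)
    for t in config.model_traits:
        if t not in known:
            issues.append(f"unknown model trait {t!r}")
    for v in config.variants:
        if v not in occ.VARIANTS:
            issues.append(f"unknown dataset variant {v!r}")
    if config.ensemble_size < 1:
        issues.append("ensemble_size must be >= 1")
    M = config.n_x * config.n_y
    if any(not (0 <= int(u) < M) for u in config.locked_in):
        issues.append("locked_in units outside the grid")
    return issues


def _stage_seed(master: int, stage: str) -> int:
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, artifact: str, message: str):
        super().__init__(f"stage {stage!r} failed ({artifact}): {message}")
        self.stage = stage
        self.artifact = artifact


def run(config: PipelineConfig, outdir, resume: bool = False) -> Path:
    """Execute the pipeline, writing versioned artifacts under ``outdir``."""
    issues = validate(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    checksum = config.checksum()
    marker = out / "config.json"
    if marker.exists():
        prev = json.loads(marker.read_text())
        if resume and prev.get("checksum") != checksum:
            resume = False
    marker.write_text(
        json.dumps({"checksum": checksum, "config": config.to_dict()},
                   indent=2, default=list)
    )

    def done(stage: str) -> bool:
        return resume and (out / f".{stage}.done").exists()

    def mark(stage: str):
        (out / f".{stage}.done").write_text(checksum)

    state: dict = {}

    # ---- simulate ----------------------------------------------------------
    sim_cfg = synth.SimConfig(
        n_species=config.n_species, n_x=config.n_x, n_y=config.n_y,
        missing_rate=config.missing_rate,
        seed=_stage_seed(config.master_seed, "simulate"),
    )
    tree = synth.gen_phylogeny(sim_cfg.n_species, seed=sim_cfg.seed)
    landscape = synth.gen_landscape(sim_cfg)
    true_traits = synth.gen_traits(tree, synth.SimConfig(
        n_species=config.n_species, n_x=config.n_x, n_y=config.n_y,
        missing_rate=0.0, seed=sim_cfg.seed,
    ))
    sim = synth.gen_occurrences(tree, true_traits, landscape, sim_cfg)
    state.update(tree=tree, landscape=landscape, sim=sim)
    if "simulate" in config.stages and not done("simulate"):
        phylogeny.write_newick(tree, out / "phylogeny.nwk")
        sim.records.to_csv(out / "occurrence_records.csv", index=False)
        landscape.env_candidates.to_csv(out / "env_candidates.csv", index=False)
        landscape.cost_components.to_csv(out / "cost_components.csv", index=False)
        pd.DataFrame({
            "unit_id": landscape.grid.unit_ids,
            "carbon": landscape.carbon,
            "deforestation_prob": landscape.deforestation_prob,
            "elev_min": landscape.elevation_range[:, 0],
            "elev_max": landscape.elevation_range[:, 1],
        }).to_csv(out / "unit_layers.csv", index=False)
        synth.write_truth(sim.truth, out / "truth.json")
        mark("simulate")
        log.info("simulate: %d species, %d units", config.n_species,
                 landscape.grid.n_units)

    # observed traits carry missingness; impute them
    obs_traits = synth.gen_traits(tree, sim_cfg)
    cov, labels = phylogeny.phylo_covariance(tree)
    eig, _ = phylogeny.phylo_eigenvectors(
        tree, k=min(config.n_eigenvectors, config.n_species - 1)
    )

    # ---- impute ------------------------------------------------------------
    imputed = traits_mod.ensemble_impute(
        obs_traits, cov, eig,
        iterations=config.imputation_iterations,
        seed=_stage_seed(config.master_seed, "impute"),
        rf_kwargs={"n_estimators": 50},
    )
    state["traits"] = imputed
    if "impute" in config.stages and not done("impute"):
        imputed.data.to_csv(out / "traits_imputed.csv")
        obs_traits.data.to_csv(out / "traits_observed.csv")
        mark("impute")
        log.info("impute: %d missing entries filled",
                 int(obs_traits.mask.to_numpy().sum()))

    # ---- datasets: presence-background variants + env selection -------------
    species = imputed.species
    elev_rng = {
        sp: (grp["elevation_m"].min(), grp["elevation_m"].max())
        for sp, grp in sim.records.groupby("species")
    }
    variants = occ.make_variants(
        sim.records, landscape.grid, landscape.elevation_range, elev_rng, species
    )
    variants = {v: variants[v] for v in config.variants}
    env_sel = occ.env_select_pca(landscape.env_candidates)
    env = landscape.env_candidates[env_sel.selected]
    quartiles = occ.rarity_quartiles(variants)
    state.update(variants=variants, env=env, quartiles=quartiles)
    if "datasets" in config.stages and not done("datasets"):
        for name, pm in variants.items():
            pm.to_frame().to_csv(out / f"presence_{name}.csv")
        quartiles.to_csv(out / "rarity_quartiles.csv")
        (out / "env_selection.json").write_text(json.dumps({
            "selected": env_sel.selected,
            "variance_explained": env_sel.variance_explained.tolist(),
        }, indent=2))
        mark("datasets")
        log.info("datasets: mean presences %.1f", occ.mean_presences(variants))

    # ---- models ------------------------------------------------------------
    Sigma_spp = cov
    Sigma_m = jsdm.spatial_covariance(landscape.grid)
    fit_opts = jsdm.FitOptions()
    specs = [jsdm.ModelSpec(trait=None)] + [
        jsdm.ModelSpec(trait=t) for t in config.model_traits
    ]
    surfaces, fits = {}, {}
    model_seed = _stage_seed(config.master_seed, "models")
    for spec in specs:
        for vname, pm in variants.items():
            spec_v = jsdm.ModelSpec(spec.trait, spec.include_interactions, vname)
            design = jsdm.build_design(spec_v, imputed, env)
            f = jsdm.fit(pm.matrix, design, Sigma_spp, Sigma_m, opts=fit_opts,
                         spec=spec_v)
            key = (spec.trait or "null", vname)
            fits[key] = f
            surfaces[key] = jsdm.predict(f)
    averaged = jsdm.average_runs(
        [s for (t, _), s in surfaces.items() if t != "null"]
    )
    state.update(fits=fits, surfaces=surfaces, averaged=averaged)
    if "models" in config.stages and not done("models"):
        reports = {f"{t}|{v}": fr.report() for (t, v), fr in fits.items()}
        (out / "model_fits.json").write_text(json.dumps(reports, indent=2))
        pd.DataFrame(
            averaged, index=pd.Index(species, name="species"),
            columns=[f"unit_{u}" for u in range(averaged.shape[1])],
        ).to_csv(out / "occurrence_probability.csv")
        mark("models")
        log.info("models: %d fits", len(fits))

    # ---- evaluate ----------------------------------------------------------
    if "evaluate" in config.stages:
        rmse_trait, rmse_null, cpo_trait, cpo_null = {}, {}, {}, {}
        for (t, vname), f in fits.items():
            pm = variants[vname]
            spec_v = jsdm.ModelSpec(None if t == "null" else t, variant=vname)
            design = jsdm.build_design(spec_v, imputed, env)
            r = jsdm.cross_validate(
                pm.matrix, design, Sigma_spp, Sigma_m,
                k=config.cv_folds, seed=model_seed, opts=fit_opts,
                init_variances=f.variances,
            )
            c = jsdm.cpo(f).reshape(len(species), -1)
            if t == "null":
                rmse_null[vname], cpo_null[vname] = r, c
            else:
                rmse_trait[(t, vname)], cpo_trait[(t, vname)] = r, c
        evaluation = jsdm.delta_metrics(
            rmse_trait, rmse_null, cpo_trait, cpo_null, quartiles, species
        )
        state["evaluation"] = evaluation
        if not done("evaluate"):
            evaluation.rmse_table.to_csv(out / "rmse_table.csv", index=False)
            evaluation.delta_cpo_species.to_csv(out / "delta_cpo.csv", index=False)
            evaluation.quartile_summary.to_csv(out / "cpo_quartiles.csv")
            mark("evaluate")
            log.info("evaluate: mean delta RMSE %.3f",
                     evaluation.rmse_table.query("model != 'null'")["delta_rmse"].mean())

    # ---- diversity ----------------------------------------------------------
    gower = traits_mod.gower_matrix(imputed)
    layers = diversity.build_layers(
        averaged, gower, K=config.n_draws, target=config.coverage_target,
        seed=_stage_seed(config.master_seed, "diversity"),
    )
    state["layers"] = layers
    if "diversity" in config.stages and not done("diversity"):
        pd.DataFrame(
            {"unit_id": landscape.grid.unit_ids, **layers.to_dict()}
        ).to_csv(out / "diversity_layers.csv", index=False)
        (out / "diversity_provenance.json").write_text(
            json.dumps(layers.provenance, indent=2)
        )
        mark("diversity")
        log.info("diversity: tau=%.3f", layers.provenance["tau"])

    # ---- prioritize + importance --------------------------------------------
    cost = prio.build_cost(landscape)
    bio_features = layers.to_dict()
    extra_features = {
        **bio_features,
        "carbon": landscape.carbon,
        "deforestation": landscape.deforestation_prob,
    }
    report: dict = {"scenarios": {}}
    imp_seed = _stage_seed(config.master_seed, "importance")
    for target, budget in config.scenarios:
        for label, feats in [("biodiversity", bio_features),
                             ("biodiversity_carbon_defor", extra_features)]:
            problem = prio.Problem(
                features=feats, cost=cost, grid=landscape.grid,
                budget_fraction=budget, target_fraction=target,
                boundary_penalty=config.boundary_penalty,
                edge_factor=config.edge_factor,
                locked_in=frozenset(int(u) for u in config.locked_in),
            )
            key = f"target{int(target * 100)}_{label}"
            if "prioritize" in config.stages:
                sol = prio.solve_milp(problem, mip_gap=1e-6)
                pd.DataFrame({
                    "unit_id": landscape.grid.unit_ids,
                    "selected": sol.selected.astype(int),
                }).to_csv(out / f"solution_{key}.csv", index=False)
                report["scenarios"][key] = sol.summary()
            if "importance" in config.stages:
                imps = {}
                for fname in feats:
                    ens = importance_mod.scenario_ensemble(
                        problem, fname, K=config.ensemble_size,
                        seed=imp_seed, cost_jitter_sd=config.cost_jitter_sd,
                    )
                    imps[fname] = importance_mod.importance_scores(
                        ens, problem.features[fname]
                    )
                impact = importance_mod.trait_impact(
                    imps["trait_alpha"].scores, imps["species_alpha"].scores,
                    imps["trait_beta"].scores, imps["species_beta"].scores,
                )
                impact.to_frame().to_csv(out / f"trait_impact_{key}.csv")
                pd.DataFrame(
                    {n: s.scores for n, s in imps.items()}
                ).rename_axis("unit_id").to_csv(out / f"importance_{key}.csv")
                report["scenarios"].setdefault(key, {})
                report["scenarios"][key]["priority_classes"] = impact.counts()
                if "carbon" in imps:
                    comparison = importance_mod.compare_feature_importance(
                        impact, imps["carbon"].scores, imps["deforestation"].scores,
                        n_boot=2000, seed=imp_seed,
                    )
                    comparison.to_csv(
                        out / f"importance_comparison_{key}.csv", index=False
                    )
                    report["scenarios"][key]["comparison"] = json.loads(
                        comparison.to_json(orient="records")
                    )

    # ---- report --------------------------------------------------------------
    if "report" in config.stages:
        report["seed"] = config.master_seed
        report["checksum"] = checksum
        if "evaluation" in state:
            report["delta_rmse_by_trait"] = (
                state["evaluation"].delta_rmse_by_trait.to_dict()
            )
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        mark("report")
    return out
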