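"""End-to-end pipeline: simulate -> networks -> metrics -> features ->
select -> models -> stats, driven by one configuration with a master seed.

Each stage receives a child seed derived by hashing the stage name against
the master seed, so a stage's output is reproducible independently of the
order in which stages run. All tabular artifacts are TSV with header rows,
all metadata JSON; re-running with the same configuration is bit-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import Cohort, CohortConfig, read_cohort, simulate_cohort, write_cohort
from .efficiency import efficiency_profile, write_profile
from .integration import compute_feature_table, select_by_variance
from .models import evaluate, fit_random_tree, margin_curve, predict_phenotype
from .networks import (DEFAULT_SPARSITY_GRID, functional_connectivity_matrix,
                       structural_covariance_matrix, write_matrix)
from .stats import (compare_regions, comparisons_frame, correlations_frame,
                    phenotype_correlations)

logger = logging.getLogger("mpmri")

STAGES = ("simulate", "networks", "metrics", "features", "select", "models", "stats")


@dataclass
class RunConfig:
    """Pipeline configuration (parameter blocks per stage + master seed)."""

    out_dir: str = "run"
    cohort_dir: str | None = None           # existing cohort when simulate=False
    simulate: bool = True
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sparsity_grid: tuple = DEFAULT_SPARSITY_GRID
    n_random: int = 20
    z_threshold: float = 2.3
    variance_threshold: float = 0.95
    kfold: int = 10
    split_fraction: float = 0.8
    prediction_scores: tuple = ("ados_module", "iq_full", "adir_total")
    master_seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        if "sparsity_grid" in d:
            d["sparsity_grid"] = tuple(d["sparsity_grid"])
        if "prediction_scores" in d:
            d["prediction_scores"] = tuple(d["prediction_scores"])
        return cls(**d)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (stage-name hashing, < 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage in dependency order and write a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "master_seed": config.master_seed,
                      "config": config.to_dict(), "stages": {}}

    # --- simulate -----------------------------------------------------------
    if config.simulate:
        cohort_cfg = dataclasses.replace(config.cohort,
                                         seed=stage_seed(config.master_seed, "simulate"))
        cohort = simulate_cohort(cohort_cfg)
        cohort_dir = write_cohort(cohort, out / "cohort")
    else:
        if not config.cohort_dir or not Path(config.cohort_dir).exists():
            raise FileNotFoundError(
                f"simulate disabled and cohort path missing: {config.cohort_dir!r}")
        cohort_dir = Path(config.cohort_dir)
        cohort = read_cohort(cohort_dir)
    manifest["stages"]["simulate"] = {"output": str(cohort_dir),
                                      "n_subjects": len(cohort.subjects)}
    logger.info("simulate: %d subjects", len(cohort.subjects))

    # --- networks -----------------------------------------------------------
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    struct = {}
    for group in ("TD", "ASD"):
        m = structural_covariance_matrix(cohort, "thickness", group)
        struct[group] = m
        write_matrix(m, net_dir / f"thickness_covariance_{group}.tsv")
    example_fc = functional_connectivity_matrix(cohort.subjects[0].timeseries,
                                                cohort.roi_names)
    write_matrix(example_fc, net_dir / f"functional_{cohort.subjects[0].id}.tsv")
    manifest["stages"]["networks"] = {"output": str(net_dir)}
    logger.info("networks: structural covariance per group written")

    # --- metrics ------------------------------------------------------------
    met_dir = out / "metrics"
    met_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.master_seed, "metrics")
    profiles = {}
    for group, m in struct.items():
        p = efficiency_profile(m, grid=config.sparsity_grid,
                               n_random=config.n_random, seed=seed)
        profiles[group] = p
        write_profile(p, met_dir / f"thickness_efficiency_{group}.tsv")
    manifest["stages"]["metrics"] = {"output": str(met_dir)}
    logger.info("metrics: efficiency profiles over %d sparsities",
                len(config.sparsity_grid))

    # --- features -----------------------------------------------------------
    table = compute_feature_table(cohort, z_threshold=config.z_threshold)
    feat_path = table.write(out / "features.tsv")
    manifest["stages"]["features"] = {"output": str(feat_path),
                                      "n_features": len(table.feature_names)}
    logger.info("features: %d x %d table", *table.data.shape)

    # --- select -------------------------------------------------------------
    labels = (table.groups == "ASD").astype(int).to_numpy()
    selection = select_by_variance(table, labels,
                                   threshold=config.variance_threshold)
    sel_path = selection.to_json(out / "selection.json")
    manifest["stages"]["select"] = {"output": str(sel_path), "k": selection.k,
                                    "selected": selection.selected}
    logger.info("select: k=%d -> %s", selection.k, selection.selected)

    # --- models (classification + prediction) ------------------------------
    mod_dir = out / "models"
    mod_dir.mkdir(exist_ok=True)
    seed = stage_seed(config.master_seed, "models")
    X = table.data[selection.selected].to_numpy(dtype=float)
    reports = {}
    for name, protocol, param in (("full_dataset", "full_dataset", None),
                                  ("kfold", "kfold", config.kfold),
                                  ("split", "percentage_split", config.split_fraction)):
        rep = evaluate(X, labels, protocol, param, seed=seed)
        reports[name] = {"protocol": rep.protocol, "param": rep.param,
                         "accuracy": rep.accuracy,
                         "fold_accuracies": rep.fold_accuracies}
    model = fit_random_tree(X, labels, seed=seed)
    margin_curve(model, X, labels).frame().to_csv(mod_dir / "margin_curve.tsv",
                                                  sep="\t", index=False)
    predictions = {}
    phen = cohort.phenotype_frame()
    for score in config.prediction_scores:
        if score not in phen.columns:
            continue
        _, r, slope = predict_phenotype(table, selection, phen[score],
                                        protocol="full_dataset", seed=seed)
        predictions[score] = {"r": r, "slope": slope}
    (mod_dir / "report.json").write_text(json.dumps(
        {"classification": reports, "prediction": predictions}, indent=1))
    manifest["stages"]["models"] = {"output": str(mod_dir / "report.json"),
                                    **{k: v["accuracy"] for k, v in reports.items()}}
    logger.info("models: %s", {k: round(v["accuracy"], 3) for k, v in reports.items()})

    # --- stats --------------------------------------------------------------
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    td_vol = cohort.volume_matrix("TD", normalized=True)
    asd_vol = cohort.volume_matrix("ASD", normalized=True)
    rows = compare_regions(td_vol, asd_vol)
    td_th = pd.DataFrame(cohort.thickness_matrix("TD"), columns=cohort.cortical_regions)
    asd_th = pd.DataFrame(cohort.thickness_matrix("ASD"), columns=cohort.cortical_regions)
    rows += compare_regions(td_th, asd_th)
    comparisons_frame(rows).to_csv(stats_dir / "regions.tsv", sep="\t", index=False)
    phen_asd = cohort.phenotype_frame("ASD")
    corr = phenotype_correlations(
        table.data.loc[phen_asd.index], phen_asd)
    correlations_frame(corr).to_csv(stats_dir / "phenocorr.tsv", sep="\t", index=False)
    manifest["stages"]["stats"] = {"output": str(stats_dir)}
    logger.info("stats: %d region rows, %d correlation rows", len(rows), len(corr))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
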