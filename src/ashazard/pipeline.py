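"""End-to-end pipeline: simulate → prepare → model → evaluate → map → exposure.

One master seed deterministically derives a seed for every stage (stable
hash of ``"<master>:<stage>"``), so a rerun with the same configuration
reproduces every artifact bit-for-bit.  Each stage writes its outputs into
the artifact directory and records row/cell counts in a manifest so the
bookkeeping (raw points → aggregated points → modeled rows → train/test)
can be audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    ConfusionMatrix2x2,
    confusion_stats,
    find_cutoff,
    render_confusion_report,
    roc_auc,
)
from .exposure import ExposureConfig, exposed_population, hazard_map, regional_summary
from .forest import (
    ForestSpec,
    fit_forest,
    predict_prob_raster,
    predict_prob_table,
    save_forest,
    stratified_split,
    tune_mtry,
)
from .grids import write_ascii_grid
from .prep import build_modeling_table
from .synthetic import (
    paper_like_scenario,
    sample_arsenic_points,
    generate_landscape,
    write_landscape,
    ExceedanceModelSpec,
    LandscapeConfig,
    SamplingConfig,
)
from .variable_analysis import (
    binned_exceedance_correlation,
    importance_table,
    normalize_importance,
    sturges_bins,
)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "derive_seed"]

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Every knob of the end-to-end run, with the study's standard defaults.

    ``scenario`` selects the synthetic study region: ``paper_like`` (the
    full-size frozen scenario) or ``small`` (a fast, reduced variant for
    smoke runs).  Tree counts below the 10,001 default trade nothing but
    Monte-Carlo smoothness of the probability estimates for speed.
    """

    outdir: str = "artifacts"
    scenario: str = "paper_like"
    threshold_ug_l: float = 10.0
    train_fraction: float = 0.8
    n_trees: int = 10_001
    n_trees_tuning: int = 501
    mtry: int | None = None  # None = tune by OOB accuracy
    mtry_candidates: list[int] | None = None
    cutoff_grid_size: int = 100
    rural_use_rate: float = 0.637
    urban_use_rate: float = 0.238
    importance_repeats: int = 5
    seed: int = 0
    write_rasters: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class PipelineResult:
    """In-memory handles to everything the run produced."""

    config: PipelineConfig
    landscape: object
    points: pd.DataFrame
    table: object
    model: object
    selected_mtry: int
    stats: object
    test_auc: float
    cutoff_sens_spec: object
    cutoff_ppv_npv: object
    importance: pd.DataFrame
    correlations: dict
    prob_raster: object
    report: pd.DataFrame
    manifest: dict


def _scenario(config: PipelineConfig, seed: int):
    if config.scenario == "paper_like":
        return paper_like_scenario(seed)
    if config.scenario == "small":
        landscape_cfg = LandscapeConfig(
            grid_shape=(80, 80),
            n_continuous=6,
            categorical_levels=(4,),
            correlation_length=5.0,
            seed=seed,
        )
        model = ExceedanceModelSpec(
            intercept=-0.4,
            linear_coefficients={"field_00": 1.5, "field_01": -1.2},
            peaked_terms={"field_02": (0.4, 0.5, 1.0)},
        )
        sampling = SamplingConfig(
            n_points=4000, clustering_factor=2.0, hotspot_fraction=0.3, seed=seed + 1
        )
        return landscape_cfg, model, sampling
    raise ValueError(f"unknown scenario {config.scenario!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order; returns handles and writes the artifact dir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    def stage_seed(name: str) -> int:
        s = derive_seed(config.seed, name)
        manifest["stages"].setdefault(name, {})["seed"] = s
        return s

    try:
        # -- simulate ------------------------------------------------------
        sim_seed = stage_seed("simulate")
        landscape_cfg, mech, sampling = _scenario(config, sim_seed)
        landscape = generate_landscape(landscape_cfg)
        points = sample_arsenic_points(landscape, mech, sampling)
        points[["lon", "lat", "as_ugL"]].to_csv(outdir / "points.csv", index=False)
        if config.write_rasters:
            write_landscape(landscape, outdir / "landscape")
        manifest["stages"]["simulate"].update(
            n_raw_points=len(points), grid_shape=list(landscape.grid.shape)
        )

        # -- prepare -------------------------------------------------------
        stage_seed("prepare")
        table = build_modeling_table(
            points,
            landscape.grid,
            landscape.predictors,
            categorical=landscape.categorical,
            threshold=config.threshold_ug_l,
        )
        table.frame.to_csv(outdir / "modeling_table.csv", index=False)
        exceed_frac = float(table.labels.mean())
        manifest["stages"]["prepare"].update(
            n_aggregated=len(table),
            n_dropped=len(points) - len(table),
            exceedance_fraction=exceed_frac,
        )

        # -- train ---------------------------------------------------------
        train_seed = stage_seed("train")
        split = stratified_split(table, config.train_fraction, seed=train_seed)
        if config.mtry is None:
            selected_mtry, trace = tune_mtry(
                split.train,
                candidates=config.mtry_candidates,
                n_trees_tuning=config.n_trees_tuning,
                seed=train_seed,
            )
            trace.to_csv(outdir / "mtry_trace.csv", index=False)
        else:
            selected_mtry = config.mtry
        model = fit_forest(
            split.train,
            ForestSpec(n_trees=config.n_trees, mtry=selected_mtry, seed=train_seed),
        )
        save_forest(model, outdir / "model.joblib")
        manifest["stages"]["train"].update(
            n_train=len(split.train),
            n_test=len(split.test),
            selected_mtry=selected_mtry,
            oob_accuracy=model.oob_accuracy,
        )

        # -- evaluate ------------------------------------------------------
        stage_seed("evaluate")
        test_prob = predict_prob_table(model, split.test)
        test_pred = (test_prob > 0.5).astype(int)
        matrix = ConfusionMatrix2x2.from_labels(test_pred, split.test.labels)
        stats = confusion_stats(matrix)
        auc = roc_auc(test_prob, split.test.labels)
        (outdir / "confusion_report.txt").write_text(
            render_confusion_report(matrix, stats)
        )
        (outdir / "stats.json").write_text(
            json.dumps({**stats.as_dict(), "auc": auc}, indent=2)
        )
        # cutoff analysis uses all available data (train + test)
        full_prob = predict_prob_table(model, table)
        cut_ss = find_cutoff(
            full_prob, table.labels, "sens_spec", config.cutoff_grid_size
        )
        cut_pn = find_cutoff(
            full_prob, table.labels, "ppv_npv", config.cutoff_grid_size
        )
        cut_ss.curves.to_csv(outdir / "cutoff_curves.csv", index=False)
        manifest["stages"]["evaluate"].update(
            test_accuracy=stats.accuracy,
            test_auc=auc,
            cutoff_sens_spec=cut_ss.cutoff,
            cutoff_ppv_npv=cut_pn.cutoff,
        )

        # -- importance & correlations --------------------------------------
        imp_seed = stage_seed("importance")
        imp = importance_table(
            model, split.test, n_repeats=config.importance_repeats, seed=imp_seed
        )
        try:
            imp_out = imp.join(normalize_importance(imp).add_suffix("_normalized"))
        except ValueError:
            # a measure with no positive value cannot be max-normalized
            # (e.g. a near-informationless model); keep the raw importances
            logger.warning("importance not normalizable; writing raw values only")
            imp_out = imp
        imp_out.to_csv(outdir / "importance.csv")

        stage_seed("correlate")
        n_bins = sturges_bins(len(table))
        correlations = {}
        corr_rows = []
        for name in table.predictor_cols:
            if name in table.categorical_cols:
                continue  # the binned diagnostic applies to continuous predictors
            corr = binned_exceedance_correlation(
                table.frame[name].to_numpy(), table.labels, n_bins
            )
            correlations[name] = corr
            corr_rows.append(
                {
                    "predictor": name,
                    "tau_b": corr.tau_b,
                    "p_value": corr.p_value,
                    "significant": corr.significant,
                    "pearson_r": corr.pearson_r,
                    "pearson_p": corr.pearson_p,
                }
            )
        pd.DataFrame(corr_rows).to_csv(outdir / "correlations.csv", index=False)
        manifest["stages"]["correlate"].update(n_bins=n_bins)

        # -- map -------------------------------------------------------------
        stage_seed("map")
        prob_raster = predict_prob_raster(model, landscape.predictors)
        if config.write_rasters:
            write_ascii_grid(prob_raster, outdir / "probability.asc")

        # -- exposure --------------------------------------------------------
        stage_seed("exposure")
        exp_cfg = ExposureConfig(
            rural_use_rate=config.rural_use_rate,
            urban_use_rate=config.urban_use_rate,
            cutoffs=(cut_ss.cutoff, cut_pn.cutoff),
        )
        report = regional_summary(
            prob_raster, landscape.population, landscape.urban, landscape.regions, exp_cfg
        )
        report.to_csv(outdir / "exposure_report.csv", index=False)
        if config.write_rasters:
            for c in sorted(set(exp_cfg.cutoffs)):
                write_ascii_grid(
                    hazard_map(prob_raster, c), outdir / f"hazard_{c:.2f}.asc"
                )
                _, expo = exposed_population(
                    prob_raster, c, landscape.population, landscape.urban, exp_cfg
                )
                write_ascii_grid(expo, outdir / f"exposure_{c:.2f}.asc")
        total_row = report[report["region"] == "Total"].iloc[0]
        manifest["stages"]["exposure"].update(
            population_low=float(total_row["population_low"]),
            population_high=float(total_row["population_high"]),
            pct_area_low=float(total_row["pct_area_low"]),
            pct_area_high=float(total_row["pct_area_high"]),
        )
    except Exception as err:  # abort with the stage name and a partial manifest
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed in stage '{failed}': {err}") from err

    # data-artifact checksums (excludes the manifest itself)
    manifest["checksums"] = {
        p.name: _sha256(p)
        for p in sorted(outdir.glob("*.csv")) + sorted(outdir.glob("*.asc"))
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        config=config,
        landscape=landscape,
        points=points,
        table=table,
        model=model,
        selected_mtry=selected_mtry,
        stats=stats,
        test_auc=auc,
        cutoff_sens_spec=cut_ss,
        cutoff_ppv_npv=cut_pn,
        importance=imp,
        correlations=correlations,
        prob_raster=prob_raster,
        report=report,
        manifest=manifest,
    )
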