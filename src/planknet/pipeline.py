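"""End-to-end orchestration: synthetic inputs (or user files) through
preprocessing, network inference, community typing, classification with
cross-validation, gridded prediction and trend estimation.

Every run writes its resolved configuration and a provenance manifest
(input hashes, seeds, package versions) next to the outputs, and each stage
can be rerun from the cached upstream files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import classify, community_typing, network, preprocess, spacetime, synthetic_data
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input schema or configuration problem (CLI exit code 2)."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema checks on user-supplied input files.

    Returns a machine-readable list of error strings (empty = valid).
    Checks: the 17 parameter columns in the feature table, coordinate
    ranges in the metadata, and count integrality in the OTU table.
    """
    errors: list[str] = []
    for key, p in paths.items():
        if p is not None and not Path(p).exists():
            errors.append(f"missing file: {key}={p}")
    if errors:
        return errors

    if paths.get("features_csv"):
        features = pd.read_csv(paths["features_csv"])
        for name in classify.SATELLITE_FEATURES:
            if name not in features.columns:
                errors.append(f"missing parameter: {name}")
    if paths.get("meta_csv"):
        meta = pd.read_csv(paths["meta_csv"])
        missing_cols = [c for c in preprocess.META_COLUMNS if c not in meta.columns]
        if missing_cols:
            errors.append(f"metadata missing columns: {missing_cols}")
        else:
            if ((meta["latitude"] < -90) | (meta["latitude"] > 90)).any():
                errors.append("latitude out of range [-90, 90]")
            if ((meta["longitude"] <= -180) | (meta["longitude"] > 180)).any():
                errors.append("longitude out of range (-180, 180]")
    if paths.get("otu_tsv"):
        table = pd.read_csv(paths["otu_tsv"], sep="\t", index_col=0)
        values = table.to_numpy()
        if (values < 0).any():
            errors.append("negative read counts in OTU table")
        if not np.allclose(values, np.round(values)):
            errors.append("non-integer read counts in OTU table (pre-binning)")
    return errors


def _load_or_simulate(config: PipelineConfig, out: Path):
    if config.simulate:
        world = synthetic_data.WorldConfig(
            n_samples=config.n_samples,
            n_otus_per_module=config.n_otus_per_module,
            n_modules=config.n_modules,
            n_noise_otus=config.n_noise_otus,
            read_depth=config.read_depth,
            gradient_strength=config.gradient_strength,
            feature_noise_sd=config.feature_noise_sd,
            spatial_cluster_km=config.spatial_cluster_km,
            shallow_frac=config.shallow_frac,
            seed=config.seed,
        )
        table, meta, features, truth = synthetic_data.generate_world(world)
        inputs = out / "inputs"
        inputs.mkdir(parents=True, exist_ok=True)
        table.to_tsv(inputs / "otu_table.tsv")
        meta.to_csv(inputs / "sample_meta.csv", index=False)
        features.to_csv(inputs / "satellite_features.csv", index=False)
        pd.DataFrame(
            {
                "sample_id": list(truth.sample_type),
                "true_type": list(truth.sample_type.values()),
                "latent_gradient": list(truth.latent_gradient.values()),
            }
        ).to_csv(inputs / "ground_truth_samples.csv", index=False)
        return table, meta, features
    paths = {
        "otu_tsv": config.otu_tsv,
        "meta_csv": config.meta_csv,
        "features_csv": config.features_csv,
    }
    if any(v is None for v in paths.values()):
        raise ValidationError("simulate=False requires otu_tsv, meta_csv and features_csv")
    errors = validate_inputs(paths)
    if errors:
        raise ValidationError("; ".join(errors))
    table = preprocess.OtuTable.read_tsv(config.otu_tsv)
    meta = pd.read_csv(config.meta_csv)
    features = pd.read_csv(config.features_csv)
    return table, meta, features


def run_preprocess(config: PipelineConfig, table, meta, features, out: Path):
    """Fixed-order preprocessing: rarefy -> bin -> open-ocean filter ->
    missing-feature drop -> thin -> OTU filter -> clr."""
    out.mkdir(parents=True, exist_ok=True)
    meta = preprocess.validate_meta(meta)
    if config.size_fractions:
        keep = meta["size_fraction"].isin(config.size_fractions)
        meta = meta.loc[keep].reset_index(drop=True)
        table = preprocess.subset_table(table, list(meta["sample_id"]))

    table = preprocess.rarefy(table, config.rarefaction_depth, seed=config.seed)
    meta = meta[meta["sample_id"].isin(table.sample_ids)].reset_index(drop=True)
    table = preprocess.subset_table(table, list(meta["sample_id"]))

    table, meta = preprocess.bin_samples(table, meta, cell_arcmin=config.bin_arcmin)
    # bin the per-sample features with the same membership
    feat = features.set_index("sample_id")
    feature_cols = [c for c in feat.columns]
    binned_feature_rows = [
        feat.loc[members.split(";"), feature_cols].mean(axis=0)
        for members in meta["members"]
    ]
    features = pd.DataFrame(binned_feature_rows).reset_index(drop=True)
    features.insert(0, "sample_id", list(meta["sample_id"]))

    meta = preprocess.filter_open_ocean(meta, config.min_seafloor_m)

    # drop samples with any missing satellite feature
    features = features.set_index("sample_id")
    complete = ~features.isna().any(axis=1)
    n_missing = int((~complete).sum())
    if n_missing:
        logger.warning("dropping %d samples with missing satellite features", n_missing)
    meta = meta[meta["sample_id"].map(complete).fillna(False)].reset_index(drop=True)

    meta = preprocess.thin_spatial(meta, config.thin_min_km, seed=config.seed)
    table = preprocess.subset_table(table, list(meta["sample_id"]))
    features = features.loc[list(meta["sample_id"])].reset_index()

    table = preprocess.filter_otus(
        table, config.otu_min_frac, config.otu_min_prevalence,
        depth=config.rarefaction_depth,
    )
    clr = preprocess.clr_transform(table, config.clr_pseudocount)

    table.to_tsv(out / "analysis_table.tsv")
    meta.to_csv(out / "analysis_meta.csv", index=False)
    features.to_csv(out / "analysis_features.csv", index=False)
    clr_frame = clr.to_frame()
    clr_frame.index.name = "sample_id"
    clr_frame.to_csv(out / "clr_matrix.csv")
    return table, meta, features, clr


def run_network(config: PipelineConfig, clr, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    net = network.infer_network(
        clr, alpha=config.network_alpha,
        max_conditioning=config.network_max_conditioning,
    )
    candidates = [
        network.detect_modules(net, algorithm=alg, seed=config.module_seed)
        for alg in config.module_algorithms
    ]
    part = network.select_partition(candidates, config.min_module_size)
    net.to_edgelist_tsv(out / "network_edges.tsv")
    part.to_csv(out / "module_partition.csv")
    summary = {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "modularity_Q": part.Q,
        "n_modules": len(part.modules()),
        "candidate_Q": {alg: c.Q for alg, c in zip(config.module_algorithms, candidates)},
    }
    (out / "network_summary.json").write_text(json.dumps(summary, indent=2))
    return net, part


def run_typecall(config: PipelineConfig, clr, net, part, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    weights = community_typing.node_weights(
        clr, scale=config.sigmoid_scale, offset=config.sigmoid_offset
    )
    es = community_typing.edge_satisfaction(net, part, weights)
    labels = community_typing.assign_types(es)
    es.to_csv(out / "edge_satisfaction.csv")
    es.to_long_frame().to_csv(out / "edge_satisfaction_long.csv", index=False)
    labels.to_csv(out / "community_types.csv", index=False)
    return es, labels


def _feature_matrix(config: PipelineConfig, features: pd.DataFrame, meta: pd.DataFrame):
    names = list(classify.FEATURE_SETS[config.feature_set])
    if config.feature_set == "position":
        encoded = np.array(
            [classify.encode_position(la, lo)
             for la, lo in zip(meta["latitude"], meta["longitude"])]
        )
        return encoded, names
    X = features.set_index("sample_id").loc[list(meta["sample_id"]), names].to_numpy()
    return X, names


def run_classifier(config: PipelineConfig, features, meta, labels, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    X, names = _feature_matrix(config, features, meta)
    y = labels.set_index("sample_id").loc[list(meta["sample_id"]), "community_type"].to_numpy()
    coords = meta[["latitude", "longitude"]].to_numpy(dtype=float)

    loo = classify.loo_cv(
        X, y, algorithm=config.classifier_algorithm,
        inner_folds=config.inner_folds, seed=config.seed,
    )
    buffered = classify.buffered_cv(
        X, y, coords, radius_km=config.buffer_km,
        algorithm=config.classifier_algorithm,
        inner_folds=config.inner_folds, seed=config.seed,
    )
    grid = np.arange(
        config.threshold_grid_start,
        config.threshold_grid_stop + 1e-12,
        config.threshold_grid_step,
    )
    threshold = classify.select_threshold(loo.prob, loo.y_true, loo.classes, grid)

    model = classify.train(
        X, y, algorithm=config.classifier_algorithm,
        inner_folds=config.inner_folds, seed=config.seed, feature_names=names,
    )
    model.probability_threshold = threshold
    importance = classify.permutation_importance(
        model, X, y, n_repeats=config.permutation_repeats, seed=config.seed
    )

    model.save(out / "model")
    loo.per_sample_frame().to_csv(out / "cv_loo_per_sample.csv", index=False)
    buffered.per_sample_frame().to_csv(out / "cv_buffered_per_sample.csv", index=False)
    report = {
        "feature_set": config.feature_set,
        "algorithm": config.classifier_algorithm,
        "best_params": model.best_params,
        "probability_threshold": float(threshold),
        "loo": loo.summary(),
        "buffered": buffered.summary(),
        "permutation_importance_auc_drop": importance,
    }
    (out / "cv_report.json").write_text(json.dumps(report, indent=2))
    return model, loo, buffered


def run_spacetime(config: PipelineConfig, model, out: Path):
    out.mkdir(parents=True, exist_ok=True)
    import xarray as xr

    if config.grid_netcdf:
        field = xr.open_dataset(config.grid_netcdf)
    else:
        field = synthetic_data.generate_grid_series(
            n_years=config.grid_years,
            grid_shape=(config.grid_rows, config.grid_cols),
            trend_per_year=config.grid_trend_per_year,
            missing_rate=config.grid_missing_rate,
            seed=config.seed,
        )
    field = spacetime.downsample_grid(field, config.downsample_factor)
    pred = spacetime.predict_map(model, field)
    pred.to_frame().to_csv(out / "grid_predictions.csv", index=False)
    areas = spacetime.area_series(pred)
    areas.to_csv(out / "area_series.csv", index=False)
    trends = spacetime.area_trends(areas, alpha=config.trend_alpha)
    trends.to_csv(out / "area_trends.csv", index=False)
    return pred, areas, trends


STAGES = ("inputs", "preprocess", "network", "typecall", "classify", "spacetime")


def run_pipeline(config: PipelineConfig, out_dir, stop_after: str | None = None) -> Path:
    """Execute the stages in order under ``out_dir``; returns the run
    directory. ``stop_after`` ends the run after the named stage. Failures
    leave partial outputs in place, with the manifest marking the failed
    stage."""
    if stop_after is not None and stop_after not in STAGES:
        raise ValidationError(f"unknown stage {stop_after!r}; choose from {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    manifest: dict = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "stages": [],
    }

    def _finish_stage(name) -> bool:
        manifest["stages"].append(name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return name == stop_after

    try:
        done = False
        table, meta, features = _load_or_simulate(config, out)
        done = _finish_stage("inputs")
        if not done:
            table, meta, features, clr = run_preprocess(
                config, table, meta, features, out / "preprocess"
            )
            done = _finish_stage("preprocess")
        if not done:
            net, part = run_network(config, clr, out / "network")
            done = _finish_stage("network")
        if not done:
            es, labels = run_typecall(config, clr, net, part, out / "typecall")
            done = _finish_stage("typecall")
        if not done:
            model, loo, buffered = run_classifier(
                config, features, meta, labels, out / "classify"
            )
            done = _finish_stage("classify")
        if not done:
            pred, areas, trends = run_spacetime(config, model, out / "spacetime")
            _finish_stage("spacetime")
    except ValidationError:
        manifest["failed"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    except Exception as exc:
        manifest["failed"] = True
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise

    inputs_dir = out / "inputs"
    if inputs_dir.exists():
        manifest["input_hashes"] = {
            p.name: _sha256(p) for p in sorted(inputs_dir.iterdir()) if p.is_file()
        }
    manifest["complete"] = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
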