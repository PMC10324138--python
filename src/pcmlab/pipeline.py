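"""End-to-end pipeline: data -> descriptors -> filters -> models -> ensembles -> reports.

Runs the proteochemometric stages in a fixed order with seeded
reproducibility, writing per-stage artifacts, a machine-readable summary and
a hash manifest into a run directory. Every stochastic stage receives an
explicit seed derived from the run seed, so re-running a config reproduces
all numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import chem, ensemble, features, modeling, synthetic_data, validation
from .protein import BindingSite, zscale_block

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("pcmlab")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the offending entity."""

    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    Defaults mirror the reference protocol: 512-length radius-2 Morgan count
    fingerprints, 30/1 near-zero-variance and 0.95 correlation cut-offs,
    stratified 70/30 split, 10-fold shared CV, greedy ensembles with 1000
    iterations. ``grids`` may override the per-algorithm hyperparameter grid
    (``None`` uses the defaults of :func:`pcmlab.modeling.default_grid`).
    """

    # data source: synthetic block, or explicit input paths
    synthetic: dict[str, Any] | None = field(default_factory=dict)
    bioactivity_csv: str | None = None
    smiles_file: str | None = None
    site_files: list[str] | None = None

    fingerprint_radius: int = 2
    fingerprint_length: int = 512
    physchem_provider: str = "rdkit-minimal"
    include_protein: bool = True

    freq_ratio_cut: float = 30.0
    corr_cutoff: float = 0.95
    preprocess_scope: str = "train"  # "train" (no leakage) or "all" (legacy)

    split_ratio: float = 0.7
    split_bins: int = 4

    cv_k: int = 10
    algorithms: tuple[str, ...] = ("RF", "SVM-RBF", "GBM")
    grids: dict[str, list[dict[str, Any]]] | None = None

    ensemble_n_iter: int = 1000
    meta_kinds: tuple[str, ...] = ("linear", "elastic-net", "SVM-linear", "SVM-RBF")

    sigma: float = validation.DEFAULT_SIGMA
    bounds_n_sim: int = 1000

    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_jsonable(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("algorithms", "meta_kinds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig, outdir: Path):
    """Stage 1: synthetic generation, or loading user-supplied tables."""
    if config.synthetic is not None:
        syn = synthetic_data.SyntheticConfig(
            seed=config.seed, **(config.synthetic or {})
        )
        compounds, sites, dataset, truth = synthetic_data.generate_dataset(syn)
        synthetic_data.write_dataset(outdir / "data", compounds, sites, dataset, truth)
        return compounds, sites, dataset
    if config.bioactivity_csv is None or config.smiles_file is None:
        raise ValueError("either a synthetic block or input paths are required")
    dataset = chem.BioactivityDataset.from_csv(config.bioactivity_csv)
    raw = chem.read_smiles_file(config.smiles_file)
    compounds, report = chem.standardize_library(raw)
    (outdir / "data").mkdir(parents=True, exist_ok=True)
    with open(outdir / "data" / "standardization_report.json", "w") as fh:
        json.dump({"n_input": report.n_input, "removals": report.removals}, fh, indent=1)
    sites = None
    if config.include_protein:
        if not config.site_files:
            raise ValueError("include_protein=True requires site_files")
        sites = tuple(BindingSite.from_json(p) for p in config.site_files)
    return compounds, sites, dataset


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages and return the machine-readable run summary.

    Writes matrices, split assignment, model manifests and out-of-fold
    predictions, ensemble weights, validation tables, Williams-plot data, the
    effective config, a summary JSON and a content-hash manifest under
    ``outdir``. Any stage error is re-raised as :class:`PipelineError` naming
    the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    summary: dict[str, Any] = {"seed": config.seed, "stages": {}}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrap

    # -- data ---------------------------------------------------------------
    compounds, sites, dataset = stage("data")(_load_inputs, config, outdir)
    summary["stages"]["data"] = {
        "n_compounds": len(compounds),
        "n_pairs": len(dataset),
        "targets": sorted(dataset.pairs["target_id"].unique()),
    }

    # -- descriptors --------------------------------------------------------
    def _descriptors():
        fp_block = chem.morgan_fingerprint_block(
            compounds, radius=config.fingerprint_radius, length=config.fingerprint_length
        )
        pc_block, failed = chem.physchem_descriptors(compounds, config.physchem_provider)
        lig = chem.LigandDescriptorBlock.concat([fp_block, pc_block])
        prot = zscale_block(list(sites)) if (config.include_protein and sites) else None
        return lig, prot, failed

    lig_block, prot_block, pc_failed = stage("descriptors")(_descriptors)
    summary["stages"]["descriptors"] = {
        "n_ligand_descriptors": len(lig_block.names),
        "n_protein_descriptors": 0 if prot_block is None else prot_block[0].shape[1],
        "physchem_failures": pc_failed,
    }

    # -- matrix + filters ---------------------------------------------------
    def _matrix():
        raw = features.build_pair_matrix(dataset, lig_block, prot_block)
        imputed, all_na = features.impute_features(raw)
        nzv, removed_nzv = features.remove_near_zero_variance(
            imputed, config.freq_ratio_cut
        )
        filtered, removed_corr = features.remove_highly_correlated(
            nzv, config.corr_cutoff
        )
        counts = {
            "raw": raw.n_columns,
            "post_nzv": nzv.n_columns,
            "post_correlation": filtered.n_columns,
        }
        assert counts["raw"] >= counts["post_nzv"] >= counts["post_correlation"]
        return raw, filtered, counts, removed_nzv, removed_corr, all_na

    raw_m, filtered_m, counts, removed_nzv, removed_corr, all_na = stage("features")(_matrix)
    summary["stages"]["features"] = {
        "column_counts": counts,
        "columns_by_provenance": filtered_m.column_counts_by_provenance(),
        "n_all_na_columns": len(all_na),
    }

    # -- split + scaling ----------------------------------------------------
    def _split_scale():
        y = pd.Series(
            dataset.pairs["pic50"].to_numpy(),
            index=filtered_m.values.index,
            name="pic50",
        )
        split = features.stratified_split(
            y, ratio=config.split_ratio, n_bins=config.split_bins, seed=config.seed + 10
        )
        fit_keys = (
            split.train_keys
            if config.preprocess_scope == "train"
            else list(filtered_m.values.index)
        )
        # a column can survive the global filters yet be constant within the
        # training rows; it carries no fittable signal, so drop it here
        train_sd = filtered_m.values.loc[fit_keys].std(ddof=1)
        degenerate = list(train_sd.index[train_sd == 0])
        usable = filtered_m.with_columns(
            [c for c in filtered_m.values.columns if c not in set(degenerate)],
            state="filtered",
        )
        scaler = features.fit_center_scale(usable, fit_keys)
        scaled = scaler.transform(usable)
        split.to_csv(outdir / "split.csv")
        scaled.to_csv(outdir / "matrix_scaled.csv")
        return y, split, scaled, degenerate

    y, split, scaled, degenerate = stage("split")(_split_scale)
    summary["stages"]["split"] = {
        "n_train": len(split.train_keys),
        "n_test": len(split.test_keys),
        "n_train_constant_columns_dropped": len(degenerate),
    }

    X_train = scaled.values.loc[split.train_keys]
    X_test = scaled.values.loc[split.test_keys]
    y_train = y.loc[split.train_keys].to_numpy()
    y_test = y.loc[split.test_keys].to_numpy()
    train_var = float(np.mean((y_train - y_train.mean()) ** 2))

    # -- base learners ------------------------------------------------------
    def _train():
        scheme = modeling.make_cv_folds(len(X_train), k=config.cv_k, seed=config.seed + 20)
        models = {}
        for algo in config.algorithms:
            grid = (config.grids or {}).get(algo)
            models[algo] = modeling.train_model(
                algo, X_train, y_train, grid=grid, scheme=scheme, seed=config.seed + 30
            )
            log.info("trained %s: cv_rmse=%.4f chosen=%s", algo,
                     models[algo].cv_rmse, models[algo].chosen)
        (outdir / "models").mkdir(exist_ok=True)
        for algo, m in models.items():
            with open(outdir / "models" / f"{algo}.manifest.json", "w") as fh:
                json.dump(_jsonable(m.manifest()), fh, indent=1)
            oof = pd.DataFrame(
                {
                    "fold": m.scheme.assignment,
                    "prediction": m.oof_predictions,
                },
                index=X_train.index,
            )
            oof.reset_index().to_csv(outdir / "models" / f"{algo}.oof.csv", index=False)
        return scheme, models

    scheme, models = stage("train")(_train)

    # -- ensembles ----------------------------------------------------------
    def _ensembles():
        order = list(models)
        oof = np.column_stack([models[a].oof_predictions for a in order])
        test_preds = np.column_stack(
            [modeling.predict(models[a], X_test) for a in order]
        )
        greedy = ensemble.greedy_ensemble(oof, y_train, n_iter=config.ensemble_n_iter)
        combiners: dict[str, Any] = {"EN greedy": greedy}
        for kind in config.meta_kinds:
            combiners[f"EN stacking {kind}"] = ensemble.stack_ensemble(oof, y_train, kind)
        with open(outdir / "ensemble_weights.json", "w") as fh:
            json.dump(_jsonable(greedy.to_dict()), fh, indent=1)
        return order, oof, test_preds, combiners

    order, oof, test_preds, combiners = stage("ensemble")(_ensembles)
    summary["stages"]["ensemble"] = {
        "model_order": order,
        "greedy_weights": combiners["EN greedy"].weights.tolist(),
    }

    # -- validation ---------------------------------------------------------
    def _validate():
        reports: dict[str, validation.ValidationReport] = {}
        for algo in order:
            m = models[algo]
            rep = validation.regression_metrics(
                y_test, modeling.predict(m, X_test), y_train.mean(), train_var
            )
            rep.r2_cv, rep.rmse_cv = validation.internal_metrics(
                y_train, m.oof_predictions
            )
            reports[algo] = rep
        for name, comb in combiners.items():
            pred = ensemble.ensemble_predict(comb, test_preds)
            rep = validation.regression_metrics(y_test, pred, y_train.mean(), train_var)
            cv_pred = ensemble.ensemble_predict(comb, oof)
            rep.r2_cv, rep.rmse_cv = validation.internal_metrics(y_train, cv_pred)
            reports[name] = rep
        table = pd.DataFrame(
            {name: _jsonable(rep.to_dict()) for name, rep in reports.items()}
        ).drop(index=["criteria_pass"])
        table.to_csv(outdir / "validation_table.csv")
        bounds = validation.theoretical_bounds(
            y_test, sigma=config.sigma, n_sim=config.bounds_n_sim, seed=config.seed + 40
        )
        with open(outdir / "theoretical_bounds.json", "w") as fh:
            json.dump(_jsonable(bounds.to_dict()), fh, indent=1)
        return reports, bounds

    reports, bounds = stage("validate")(_validate)
    summary["stages"]["validate"] = {
        name: {
            "r2_cv": rep.r2_cv,
            "rmse_cv": rep.rmse_cv,
            "r2_test": rep.r2_test,
            "r2_0_test": rep.r2_0_test,
            "q2_f1": rep.q2_f1,
            "q2_f2": rep.q2_f2,
            "q2_f3": rep.q2_f3,
            "rmse_test": rep.rmse_test,
            "mae": rep.mae,
            "k_slope": rep.k_slope,
            "criteria_pass": rep.criteria_pass,
        }
        for name, rep in reports.items()
    }
    summary["stages"]["theoretical_bounds"] = _jsonable(bounds.to_dict())

    # -- applicability domain (for the best single model by CV RMSE) --------
    def _ad():
        best = min(order, key=lambda a: models[a].cv_rmse)
        m = models[best]
        Xtr = X_train.to_numpy(float)
        Xq = np.vstack([Xtr, X_test.to_numpy(float)])
        # out-of-fold residuals give the honest residual scale: flexible
        # learners nearly interpolate the training rows, so resubstitution
        # residuals would understate the SD and flag most points as outliers
        res_train = y_train - m.oof_predictions
        res_test = y_test - modeling.predict(m, X_test)
        ad = validation.leverage_ad(
            Xtr, Xq, np.concatenate([res_train, res_test]),
            training_residuals=res_train,
        )
        williams = pd.DataFrame(
            {
                "compound_id": [k[0] for k in split.train_keys + split.test_keys],
                "target_id": [k[1] for k in split.train_keys + split.test_keys],
                "set": ["train"] * len(split.train_keys) + ["test"] * len(split.test_keys),
                "leverage": ad.leverage,
                "std_residual": ad.std_residual,
            }
        )
        williams["h_star"] = ad.h_star
        williams.to_csv(outdir / "williams_plot.csv", index=False)
        return best, ad

    best, ad = stage("ad")(_ad)
    summary["stages"]["ad"] = {
        "model": best,
        "h_star": ad.h_star,
        "flag_counts": ad.flag_counts(),
        "train_leverage_sum": ad.train_leverage_sum,
        "design_rank": ad.design_rank,
    }

    # -- summary + manifest -------------------------------------------------
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(summary), fh, indent=1)
    manifest = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return summary
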