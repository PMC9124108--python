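"""End-to-end pipeline: preprocess -> gene selection -> ANFIS -> tuning -> metrics.

A run is fully described by a :class:`PipelineConfig`.  Every stage draws its
random seed deterministically from the master seed and the stage name (plus
the fold index where applicable), so no stage consumes another stage's random
stream and the whole run is reproducible bit-for-bit from its manifest.

Protocol evaluation trains an independent pipeline per train/test split and
pools the held-out predictions; a final model is then fit on the full dataset
to produce the exported gene list and serialized classifier.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .anfis import fit_consequents_ls, init_model, predict_f, predict_label, save_model
from .coa import CoaConfig, tune_anfis, write_trace
from .datasets import ExpressionDataset, load_dataset, zscore_normalize
from .evaluation import (
    ConfusionMatrix2x2,
    MetricsReport,
    evaluate,
    format_report,
    report_as_dict,
)
from .exceptions import GwanfisError, InvalidConfigError
from .igwo_fs import AbhcConfig, FeatureSubset, GWOConfig, WrapperConfig, run_igwo_fs

__all__ = ["PipelineConfig", "PipelineResult", "stage_seed", "run_pipeline"]


def stage_seed(master_seed: int, stage: str, fold: int | None = None) -> int:
    """Deterministic per-stage seed: a pure function of master seed and stage name."""
    tag = f"{master_seed}:{stage}" if fold is None else f"{master_seed}:{stage}:{fold}"
    digest = hashlib.sha256(tag.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Complete, reproducible description of one pipeline run."""

    data_path: str | None = None
    orientation: str = "samples-rows"
    label_column: str = "label"
    protocol: str = "kfold"
    folds: int = 5
    test_fraction: float = 0.3
    normalize_per_fold: bool = False
    pack_size: int = 10
    fs_iters: int = 100
    alpha_weight: float = 0.9
    binarize_threshold: float = 0.5
    abhc_k: float = 4.0
    abhc_beta_rate: float = 0.05
    abhc_inner_iters: int = 30
    n_rules: int = 4
    coa_population: int = 20
    coa_iters: int = 40
    mode: str = "hybrid"
    seed: int = 0
    out_dir: str | None = None

    def gwo_config(self, seed: int) -> GWOConfig:
        return GWOConfig(
            pack_size=self.pack_size,
            max_iter=self.fs_iters,
            alpha_weight=self.alpha_weight,
            beta_weight=1.0 - self.alpha_weight,
            binarize_threshold=self.binarize_threshold,
            seed=seed,
        )

    def abhc_config(self) -> AbhcConfig:
        return AbhcConfig(
            K=self.abhc_k, beta_rate=self.abhc_beta_rate,
            inner_iters=self.abhc_inner_iters,
        )


@dataclass
class PipelineResult:
    report: MetricsReport
    cm: ConfusionMatrix2x2
    subset: FeatureSubset
    model: object
    fs_history: dict
    tune_history: list[float]
    manifest: dict
    out_dir: Path | None = None


def _fit_stage(ds: ExpressionDataset, config: PipelineConfig, fold: int | None):
    """Select genes on ``ds`` then train + tune an ANFIS on the selected columns."""
    fs_seed = stage_seed(config.seed, "feature-selection", fold)
    subset, history = run_igwo_fs(
        ds,
        config.gwo_config(fs_seed),
        config.abhc_config(),
        WrapperConfig(seed=stage_seed(config.seed, "wrapper-cv", fold)),
    )
    X = ds.values[:, subset.mask]
    y = ds.labels.astype(float)
    n_rules = min(config.n_rules, ds.n_samples)
    model = init_model(X, ds.labels, n_rules, stage_seed(config.seed, "anfis-init", fold))
    model = fit_consequents_ls(model, X, y)
    coa_cfg = CoaConfig(
        population=config.coa_population,
        max_iter=config.coa_iters,
        seed=stage_seed(config.seed, "coa-tuning", fold),
    )
    model, trace = tune_anfis(model, X, y, coa_cfg, mode=config.mode)
    return subset, model, history, trace


def run_pipeline(
    config: PipelineConfig, dataset: ExpressionDataset | None = None
) -> PipelineResult:
    """Execute all four stages and (optionally) write run artifacts.

    ``dataset`` may be passed directly; otherwise ``config.data_path`` is
    loaded.  Artifacts (gene list, model, metrics, traces, manifest) are
    written to ``config.out_dir`` when set.
    """
    if dataset is None:
        if config.data_path is None:
            raise InvalidConfigError("either a dataset or data_path is required")
        try:
            dataset = load_dataset(
                config.data_path, config.orientation, config.label_column
            )
        except (OSError, GwanfisError) as exc:
            raise GwanfisError(f"[stage: load] {exc}") from exc

    try:
        full = dataset if config.normalize_per_fold else zscore_normalize(dataset)
    except GwanfisError as exc:
        raise GwanfisError(f"[stage: preprocess] {exc}") from exc

    def fit_predict(train_ds: ExpressionDataset, X_test: np.ndarray, fold: int):
        if config.normalize_per_fold:
            mu = train_ds.values.mean(axis=0)
            sigma = train_ds.values.std(axis=0)
            sigma = np.where(sigma > 0, sigma, 1.0)
            train_ds = dataclasses.replace(
                train_ds, values=(train_ds.values - mu) / sigma
            )
            X_test = (X_test - mu) / sigma
        subset, model, _, _ = _fit_stage(train_ds, config, fold)
        f = predict_f(model, X_test[:, subset.mask])
        return predict_label(f)

    try:
        report, cm = evaluate(
            full,
            fit_predict,
            protocol=config.protocol,
            k=config.folds,
            test_fraction=config.test_fraction,
            seed=stage_seed(config.seed, "protocol-split"),
        )
    except GwanfisError as exc:
        raise GwanfisError(f"[stage: evaluate] {exc}") from exc

    # Final exported artifacts come from a fit on the full normalized matrix.
    norm_full = zscore_normalize(dataset) if config.normalize_per_fold else full
    try:
        subset, model, fs_history, trace = _fit_stage(norm_full, config, fold=None)
    except GwanfisError as exc:
        raise GwanfisError(f"[stage: final-fit] {exc}") from exc

    manifest = {
        "package": "gwanfis",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": {
            s: stage_seed(config.seed, s)
            for s in ("protocol-split", "feature-selection", "wrapper-cv",
                      "anfis-init", "coa-tuning")
        },
        "n_samples": norm_full.n_samples,
        "n_genes": norm_full.n_genes,
        "n_selected": subset.n_selected,
        "fs_final_fitness": subset.fitness,
        "pooled_confusion": [list(r) for r in cm.counts],
    }
    result = PipelineResult(
        report=report, cm=cm, subset=subset, model=model,
        fs_history=fs_history, tune_history=trace.history,
        manifest=manifest,
    )
    if config.out_dir is not None:
        result.out_dir = _write_artifacts(result, norm_full, trace, config)
    return result


def _write_artifacts(result: PipelineResult, ds, trace, config: PipelineConfig) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    idx = result.subset.gene_indices()
    # rank genes by how confidently they were selected (descending position proxy)
    with open(out / "selected_genes.tsv", "w") as fh:
        fh.write("gene_id\trank\n")
        for rank, j in enumerate(idx, start=1):
            fh.write(f"{ds.gene_ids[j]}\t{rank}\n")
    save_model(result.model, out / "anfis_model.json")
    with open(out / "metrics.txt", "w") as fh:
        fh.write(format_report(result.report, result.cm) + "\n")
    with open(out / "metrics.json", "w") as fh:
        json.dump(report_as_dict(result.report), fh, indent=1)
        fh.write("\n")
    write_trace(trace, out / "coa_trace.tsv")
    with open(out / "fs_trace.tsv", "w") as fh:
        fh.write("iteration\tbest_fitness\n")
        for i, v in enumerate(result.fs_history["best_fitness_per_iter"]):
            fh.write(f"{i}\t{v!r}\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out
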