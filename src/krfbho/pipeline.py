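"""End-to-end run: preprocess -> KeRF ranking -> BHO refinement -> boosted
classification -> metrics, with explicit seeds and a JSON run manifest.

Stage order is fixed. The KeRF stage ranks features by split frequency and
optionally pre-filters to the top K (K = all features by default, which
disables the filter); the black-hole search then refines the mask within the
retained features; the boosted stage is trained on the 80% split with
stratified 5-fold cross-validation and scored once on the held-out 20%.
All stage seeds are derived deterministically from the single run seed, so
identical (input, config) reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from . import __version__
from .bho import BhoConfig, FitnessSpec, run_bho
from .errors import StageError, ValidationError
from .evaluate import (
    BoostParams,
    compute_metrics,
    confusion_counts,
    kfold_5,
    split_80_20,
    train_boosted,
)
from .kerf import KerfParams, rank_and_filter
from .preprocessing import (
    CONTINUOUS,
    DISCRETE,
    FeatureTable,
    encode_presence,
    impute_missing_knn,
    normalize_minmax,
    read_fused_csv,
    remove_redundant_features,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "preprocess_table"]


@dataclass
class RunConfig:
    """Everything one pipeline run needs; seeds are explicit, never wall-clock."""

    input_path: Union[str, Path, FeatureTable]
    target_column: str = "target"
    impute_k: int = 5
    scale_continuous: bool = True
    encode_binary: bool = True
    redundancy_threshold: float = 0.95
    kerf: KerfParams = field(default_factory=KerfParams)
    keep_features: Optional[int] = None
    bho: BhoConfig = field(default_factory=BhoConfig)
    boost: BoostParams = field(default_factory=BoostParams)
    seed: int = 0
    out_dir: Optional[Union[str, Path]] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kerf = KerfParams(**raw.pop("kerf", {}))
        bho_raw = raw.pop("bho", {})
        fitness = FitnessSpec(**bho_raw.pop("fitness", {}))
        bho = BhoConfig(fitness=fitness, **bho_raw)
        boost = BoostParams(**raw.pop("boost", {}))
        return cls(kerf=kerf, bho=bho, boost=boost, **raw)

    def to_dict(self) -> dict:
        cfg = dataclasses.asdict(self)
        if isinstance(self.input_path, FeatureTable):
            cfg["input_path"] = "<in-memory table>"
        else:
            cfg["input_path"] = str(self.input_path)
        if self.out_dir is not None:
            cfg["out_dir"] = str(self.out_dir)
        return cfg


@dataclass
class RunManifest:
    """Audit record of one pipeline run (JSON-serializable)."""

    config: dict
    seed: int
    kerf_ranked: list[str]
    selected_features: list[str]
    bho_summary: dict
    cv_metrics: list[dict]
    cv_mean_accuracy: float
    test_metrics: dict
    majority_baseline: float
    version: str = __version__
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    def comparable(self) -> dict:
        """Manifest content with volatile fields (timings) removed."""
        d = self.to_dict()
        d.pop("timings", None)
        return d


@contextmanager
def _stage(name: str, timings: dict):
    logger.info("[%s] starting", name)
    t0 = time.perf_counter()
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        raise StageError(name, exc) from exc
    timings[name] = time.perf_counter() - t0
    logger.info("[%s] done in %.2fs", name, timings[name])


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed + offset) % (2**31 - 1))


def preprocess_table(table: FeatureTable, config: RunConfig) -> FeatureTable:
    """Impute, encode, scale, and de-duplicate one table."""
    if table.missing_mask.any():
        table = impute_missing_knn(table, config.impute_k)
    values = table.values.copy()
    for j, kind in enumerate(table.column_kinds):
        col = values[:, j]
        if kind == DISCRETE and config.encode_binary:
            observed = np.unique(col)
            if observed.size <= 2 and not set(observed) <= {0.0, 1.0}:
                values[:, j], _ = encode_presence(col)
        elif kind == CONTINUOUS and config.scale_continuous:
            values[:, j] = normalize_minmax(col)
    table = FeatureTable(
        list(table.column_names), list(table.column_kinds), values,
        table.target, table.target_name,
    )
    table, dropped = remove_redundant_features(table, config.redundancy_threshold)
    for kept, gone, r in dropped:
        logger.info("[preprocess] dropped %s (|r|=%.3f with %s)", gone, abs(r), kept)
    return table


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages and return the run manifest.

    Reproducible: stage seeds are (seed, seed+1, seed+2, seed+3) for the
    KeRF fit, the BHO population, the BHO fitness split, and the 80/20
    split respectively.
    """
    timings: dict = {}

    with _stage("load", timings):
        if isinstance(config.input_path, FeatureTable):
            table = config.input_path
        else:
            table = read_fused_csv(config.input_path, config.target_column)
        if table.target is None:
            raise ValidationError("input must carry the target column")

    with _stage("preprocess", timings):
        table = preprocess_table(table, config)

    with _stage("kerf_rank", timings):
        kerf_params = dataclasses.replace(
            config.kerf, seed=_derive_seed(config.seed, 0)
        )
        keep = config.keep_features or table.n_features
        ranked = rank_and_filter(table, kerf_params, keep)
        retained = table.select_columns(ranked)
        ranked_names = [table.column_names[j] for j in ranked]

    with _stage("bho_select", timings):
        bho_config = dataclasses.replace(
            config.bho,
            seed=_derive_seed(config.seed, 1),
            fitness=dataclasses.replace(
                config.bho.fitness, seed=_derive_seed(config.seed, 2)
            ),
        )
        result = run_bho(retained, bho_config)
        selected_local = np.flatnonzero(result.best_mask)
        selected_names = [retained.column_names[j] for j in selected_local]
        final = retained.select_columns(selected_local.tolist())

    with _stage("classify", timings):
        split_seed = _derive_seed(config.seed, 3)
        plan = split_80_20(final.n_samples, final.target, split_seed)
        folds = kfold_5(plan.train_indices, final.target, split_seed)
        X, y = final.values, final.target
        cv_metrics = []
        for fit_idx, val_idx in folds:
            model = train_boosted(
                (X[fit_idx], y[fit_idx]), config.boost,
                validation=(X[val_idx], y[val_idx]),
            )
            counts = confusion_counts(y[val_idx], model.predict(X[val_idx]))
            cv_metrics.append(compute_metrics(counts).to_dict())
        cv_mean_accuracy = float(np.mean([m["accuracy"] for m in cv_metrics]))
        model = train_boosted((X[plan.train_indices], y[plan.train_indices]),
                              config.boost)
        y_test = y[plan.test_indices]
        counts = confusion_counts(y_test, model.predict(X[plan.test_indices]))
        test_metrics = compute_metrics(counts).to_dict()
        majority = float(max(np.mean(y_test), 1.0 - np.mean(y_test)))

    manifest = RunManifest(
        config=config.to_dict(),
        seed=config.seed,
        kerf_ranked=ranked_names,
        selected_features=selected_names,
        bho_summary={
            "best_fitness": result.best_fitness,
            "n_selected": int(result.best_mask.sum()),
            "n_evaluations": result.n_evaluations,
            "trajectory": result.trajectory,
        },
        cv_metrics=cv_metrics,
        cv_mean_accuracy=cv_mean_accuracy,
        test_metrics=test_metrics,
        majority_baseline=majority,
        timings=timings,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.save(out / "manifest.json")
        (out / "metrics.json").write_text(
            json.dumps({"cv": cv_metrics, "test": test_metrics}, indent=2),
            encoding="utf-8",
        )
    return manifest
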