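"""End-to-end experiment orchestration: config validation, seeding, stages.

``run_experiment`` reproduces the full comparison grid on phantom data:
simulate -> preprocess -> LOSO per model -> band attribution -> Top-k ->
LOSO per spectral configuration -> comparison tables plus a run manifest.
One master seed expands deterministically into per-stage seeds, all recorded
in the manifest; two runs with the same configuration hash produce identical
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError
import yaml

from . import __version__
from .band_importance import (
    importance_table,
    make_subset,
    occlusion_importance,
    rank_consensus,
    smoothgrad_importance,
    apply_subset,
)
from .dataset import CohortDataset
from .evaluation import EvalReport, run_loso
from .models import CnnConfig, CnnSpec, LassoSpec, MeanPredictorSpec, TrainConfig
from .phantom import PhantomParams, TimeCourse, generate_cohort
from .preprocess import build_dataset_from_cohort

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Declarative configuration
# ---------------------------------------------------------------------------


class PhantomSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_subjects: int = Field(8, gt=0)
    acquisition_days: list[float] = [0, 1, 2, 3, 4, 5, 6, 8, 10, 13, 16, 20]
    image_rows: int = Field(64, ge=4)
    image_cols: int = Field(64, ge=4)
    n_bands: int = Field(60, ge=2)
    radius_base: float = Field(10.0, gt=0)
    heterogeneity_amp: float = Field(0.35, ge=0)
    noise_mult_sd: float = Field(0.01, ge=0)
    noise_add_sd: float = Field(0.005, ge=0)
    visibility_threshold: float = Field(0.0, ge=0)

    def to_params(self, seed: int) -> PhantomParams:
        return PhantomParams(
            n_subjects=self.n_subjects,
            acquisition_days=tuple(self.acquisition_days),
            image_size=(self.image_rows, self.image_cols),
            n_bands=self.n_bands,
            radius_base=self.radius_base,
            heterogeneity_amp=self.heterogeneity_amp,
            noise_mult_sd=self.noise_mult_sd,
            noise_add_sd=self.noise_add_sd,
            visibility_threshold=self.visibility_threshold,
            time_course=TimeCourse(),
            seed=seed,
        )


class PreprocessSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patch_size: int = Field(48, gt=0)
    mask_source: str = "truth"  # truth | builtin
    min_contrast: float = Field(0.01, ge=0)


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    learning_rate: float = Field(3e-3, gt=0)
    batch_size: int = Field(4, gt=0)
    weight_decay: float = Field(1e-5, ge=0)
    max_epochs: int = Field(8, gt=0)
    patience: int = Field(3, gt=0)
    min_delta: float = Field(0.01, ge=0)
    augment_flips: bool = True
    grad_clip: float = Field(2.0, ge=0)
    bn_recalibration_samples: int = Field(16, ge=0)

    def to_config(self, seed: int = 0) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            weight_decay=self.weight_decay,
            max_epochs=self.max_epochs,
            patience=self.patience,
            min_delta=self.min_delta,
            augment_flips=self.augment_flips,
            grad_clip=self.grad_clip,
            bn_recalibration_samples=self.bn_recalibration_samples,
            seed=seed,
        )


class ExperimentConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    phantom: PhantomSection = PhantomSection()
    preprocess: PreprocessSection = PreprocessSection()
    train: TrainSection = TrainSection()
    models: list[str] = ["mean", "lasso", "cnn"]
    subsets: list[str] = ["full", "topk"]
    k: int = Field(20, gt=0)
    seed: int = 1
    n_val_subjects: int = Field(2, gt=0)
    attribution_samples: int = Field(32, gt=0)
    smoothgrad_draws: int = Field(25, gt=0)

    def hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]

    def check_consistency(self) -> list[str]:
        errors = []
        if self.k > self.phantom.n_bands:
            errors.append(f"k: k={self.k} exceeds phantom.n_bands={self.phantom.n_bands}")
        for m in self.models:
            if m not in ("mean", "lasso", "cnn"):
                errors.append(f"models: unknown model {m!r}")
        for s in self.subsets:
            if s not in ("rgb", "physio", "full", "topk"):
                errors.append(f"subsets: unknown subset {s!r}")
        if self.preprocess.patch_size > min(self.phantom.image_rows, self.phantom.image_cols):
            errors.append("preprocess.patch_size: exceeds phantom image size")
        return errors


def validate_config(path: str | Path | None) -> tuple[ExperimentConfig | None, list[str]]:
    """Load and exhaustively validate a YAML config; empty file -> defaults.

    Returns ``(config, [])`` on success or ``(None, errors)`` with every
    problem listed (unknown keys are named explicitly).
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    try:
        config = ExperimentConfig.model_validate(raw)
    except ValidationError as err:
        return None, [
            f"{'.'.join(str(loc) for loc in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
    errors = config.check_consistency()
    return (config, []) if not errors else (None, errors)


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def fit_attribution_model(
    dataset: CohortDataset,
    train_cfg: TrainConfig,
    seed: int,
    n_val_subjects: int = 2,
    cnn_config: CnnConfig | None = None,
):
    """Fit one CNN on a tuning split (all subjects minus a validation pair).

    Used for band attribution, mirroring the use of a single tuning-split
    model for the importance spectrum rather than per-fold attribution.
    Returns ``(fitted, held_out_validation_dataset)``.
    """
    subjects = dataset.subjects
    rng = np.random.default_rng(seed)
    n_val = min(n_val_subjects, len(subjects) - 1)
    val_subjects = sorted(rng.choice(subjects, size=n_val, replace=False))
    train_ds = dataset.subset_by_subjects([s for s in subjects if s not in val_subjects])
    val_ds = dataset.subset_by_subjects(val_subjects)
    spec = CnnSpec(cnn_config=cnn_config, train_config=train_cfg)
    fitted = spec.fit(train_ds, val_ds, seed=seed)
    return fitted, val_ds


def compute_band_importance(
    fitted,
    eval_ds: CohortDataset,
    train_ds_for_fill: CohortDataset | None = None,
    n_draws: int = 25,
    max_samples: int = 32,
    seed: int = 0,
    k: int = 20,
):
    """SmoothGrad + occlusion consensus on a held-out evaluation set.

    Occlusion re-evaluates the model once per band and uses the full
    evaluation set; the gradient-based scores are averaged over a
    ``max_samples`` subset (per-sample gradients are expensive and stable).
    """
    patches = eval_ds.patches()
    truths = eval_ds.ages()
    sg_patches = patches
    if len(sg_patches) > max_samples:
        idx = np.random.default_rng(seed).choice(len(patches), size=max_samples, replace=False)
        sg_patches = patches[idx]
    sg = smoothgrad_importance(fitted, sg_patches, n_draws=n_draws, seed=seed)
    fill = (
        train_ds_for_fill.patches().mean(axis=(0, 2, 3))
        if train_ds_for_fill is not None
        else None
    )
    occ = occlusion_importance(fitted, patches, truths, replacement_values=fill)
    consensus = rank_consensus(sg, occ)
    subset = make_subset("topk", eval_ds.axis, k=k, consensus=consensus)
    return sg, occ, consensus, subset


def comparison_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """One row per configuration with overall and stage-wise metrics."""
    rows = []
    for name, report in reports.items():
        row = {"configuration": name}
        row.update({f"pooled_{k}": v for k, v in report.pooled.as_dict().items()})
        row.update(
            {f"fold_mean_{k}": v for k, v in report.mean_over_folds.as_dict().items()}
        )
        for stage in ("early", "middle", "late"):
            mae, n = report.stage_mae.get(stage, (np.nan, 0))
            row[f"mae_{stage}"] = mae
            row[f"n_{stage}"] = n
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The experiment runner
# ---------------------------------------------------------------------------


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns reports and writes tables + manifest."""
    errors = config.check_consistency()
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "config": json.loads(config.model_dump_json()),
        "package_version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }

    def _stage(name):
        seed = stage_seed(config.seed, name)
        manifest["stages"][name] = {"seed": seed}
        manifest["last_stage"] = name
        logger.info("stage %s (seed %d)", name, seed)
        return seed

    def _fail(err: Exception):
        # persist partial outputs, then surface the failing stage by name
        manifest["failed_stage"] = manifest.get("last_stage")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"stage {manifest.get('last_stage')!r} failed: {err}") from err

    try:
        # 1. simulate
        seed = _stage("simulate")
        cohort = generate_cohort(config.phantom.to_params(seed))
        manifest["stages"]["simulate"]["n_samples"] = len(cohort)

        # 2. preprocess
        _stage("preprocess")
        patches_ds, exclusions = build_dataset_from_cohort(
            cohort,
            patch_size=config.preprocess.patch_size,
            mask_source=config.preprocess.mask_source,
            min_contrast=config.preprocess.min_contrast,
        )
        manifest["stages"]["preprocess"]["n_patches"] = len(patches_ds)
        manifest["stages"]["preprocess"]["exclusions"] = [
            {"sample_id": e.sample_id, "reason": e.reason} for e in exclusions
        ]
        if exclusions:
            pd.DataFrame(manifest["stages"]["preprocess"]["exclusions"]).to_csv(
                out_dir / "exclusions.csv", index=False
            )

        reports: dict[str, EvalReport] = {}

        # 3. model comparison on the full band set
        for model_name in config.models:
            seed = _stage(f"loso-{model_name}")
            spec = {
                "mean": MeanPredictorSpec(),
                "lasso": LassoSpec(),
                "cnn": CnnSpec(train_config=config.train.to_config()),
            }[model_name]
            reports[f"{model_name}-full"] = run_loso(
                patches_ds, spec, seed=seed, n_val_subjects=config.n_val_subjects
            )

        # 4. band attribution + Top-k (only when a reduced subset is requested)
        subset_defs = {}
        if any(s != "full" for s in config.subsets):
            seed = _stage("importance")
            fitted, val_ds = fit_attribution_model(
                patches_ds,
                TrainConfig.attribution_preset(),
                seed,
                n_val_subjects=config.n_val_subjects,
            )
            sg, occ, consensus, topk_subset = compute_band_importance(
                fitted,
                val_ds,
                train_ds_for_fill=patches_ds,
                n_draws=config.smoothgrad_draws,
                max_samples=config.attribution_samples,
                seed=seed,
                k=config.k,
            )
            importance_table(sg, occ, consensus, topk_subset, patches_ds.axis).to_csv(
                out_dir / "band_importance.csv", index=False
            )
            manifest["stages"]["importance"]["topk_bands"] = topk_subset.indices.tolist()
            for name in config.subsets:
                if name == "full":
                    continue
                subset_defs[name] = (
                    topk_subset if name == "topk" else make_subset(name, patches_ds.axis)
                )

        # 5. CNN per reduced spectral configuration
        for name, subset in subset_defs.items():
            seed = _stage(f"loso-cnn-{name}")
            reduced = apply_subset(patches_ds, subset)
            reports[f"cnn-{name}"] = run_loso(
                reduced,
                CnnSpec(train_config=config.train.to_config()),
                seed=seed,
                n_val_subjects=config.n_val_subjects,
            )

        # 6. outputs
        table = comparison_table(reports)
        table.insert(1, "seed", config.seed)
        table.insert(2, "config_hash", config.hash())
        table.to_csv(out_dir / "comparison.csv", index=False)
        for name, report in reports.items():
            report.per_fold_table().to_csv(out_dir / f"per_fold_{name}.csv", index=False)
            report.stage_table().to_csv(out_dir / f"stage_mae_{name}.csv", index=False)
            report.per_day.to_csv(out_dir / f"per_day_{name}.csv", index=False)
    except Exception as err:
        _fail(err)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"reports": reports, "comparison": table, "manifest": manifest}
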