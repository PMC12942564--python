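"""Leave-one-subject-out evaluation, metrics, and stage-wise breakdowns.

All data partitioning is on a subject basis: each subject's acquisitions form
the held-out test set exactly once, which prevents leakage of a subject's
longitudinal trajectory between training and testing.  Metrics are reported
both as the unweighted mean over folds and pooled over all predictions (they
differ when subjects contribute different sample counts); the pooled R^2 is
the primary one, since per-fold R^2 on a handful of samples is unstable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import CohortDataset, assign_stage  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

ACCURACY_THRESHOLDS = (1, 2, 3)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricSet:
    """MAE/RMSE in days, R^2, and threshold accuracies in percent."""

    mae: float
    rmse: float
    r2: float  #: NaN when undefined (constant truth)
    acc1: float
    acc2: float
    acc3: float
    n: int

    @property
    def r2_defined(self) -> bool:
        return not np.isnan(self.r2)

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "acc1": self.acc1,
            "acc2": self.acc2,
            "acc3": self.acc3,
            "n": self.n,
        }


def compute_metrics(pred, truth) -> MetricSet:
    """MAE, RMSE, R^2 and Acc@{1,2,3}d for paired prediction/truth vectors.

    ``R^2 = 1 - SS_res / SS_tot`` with SS_tot about the truth mean; when the
    truth is constant (SS_tot = 0) R^2 is reported as NaN and flagged.
    Acc@Xd is the percentage of predictions within +-X days.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("pred and truth must be equal-length, non-empty 1-D vectors")
    err = pred - truth
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan")
    accs = [100.0 * float(np.mean(np.abs(err) <= x)) for x in ACCURACY_THRESHOLDS]
    return MetricSet(mae=mae, rmse=rmse, r2=r2, acc1=accs[0], acc2=accs[1], acc3=accs[2], n=pred.size)


# ---------------------------------------------------------------------------
# LOSO folds
# ---------------------------------------------------------------------------


@dataclass
class LosoFold:
    test_subject: str
    train_subjects: list[str]
    predictions: np.ndarray | None = None
    truths: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    metrics: MetricSet | None = None


def loso_split(dataset: CohortDataset) -> list[LosoFold]:
    """One fold per subject, in sorted subject order."""
    subjects = dataset.subjects
    if len(subjects) < 2:
        raise ValueError(f"LOSO needs >= 2 subjects, got {len(subjects)}")
    return [
        LosoFold(test_subject=s, train_subjects=[t for t in subjects if t != s])
        for s in subjects
    ]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-fold and aggregate results of one LOSO run."""

    model_name: str
    folds: list[LosoFold]
    pooled: MetricSet
    mean_over_folds: MetricSet
    stage_mae: dict  #: stage -> (mae, n)
    per_day: pd.DataFrame  #: per ground-truth day prediction summaries
    histories: list = field(default_factory=list)

    def per_fold_table(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            row = {"test_subject": f.test_subject}
            row.update(f.metrics.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def stage_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": k, "mae": v[0], "n": v[1]} for k, v in self.stage_mae.items()]
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "pooled": self.pooled.as_dict(),
            "mean_over_folds": self.mean_over_folds.as_dict(),
            "stage_mae": {k: {"mae": v[0], "n": v[1]} for k, v in self.stage_mae.items()},
            "per_fold": self.per_fold_table().to_dict(orient="records"),
        }


def _mean_over_folds(metric_sets: list[MetricSet]) -> MetricSet:
    def avg(key):
        values = [getattr(m, key) for m in metric_sets]
        finite = [v for v in values if not np.isnan(v)]
        return float(np.mean(finite)) if finite else float("nan")

    return MetricSet(
        mae=avg("mae"),
        rmse=avg("rmse"),
        r2=avg("r2"),
        acc1=avg("acc1"),
        acc2=avg("acc2"),
        acc3=avg("acc3"),
        n=int(sum(m.n for m in metric_sets)),
    )


def _per_day_table(truths: np.ndarray, preds: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"truth": truths, "pred": preds})
    rows = []
    for day, group in df.groupby("truth"):
        q1, q2, q3 = np.percentile(group["pred"], [25, 50, 75])
        rows.append(
            {
                "age_days": day,
                "n": len(group),
                "mean": group["pred"].mean(),
                "q1": q1,
                "median": q2,
                "q3": q3,
            }
        )
    return pd.DataFrame(rows)


def run_loso(
    dataset: CohortDataset,
    model_spec,
    seed: int = 0,
    n_val_subjects: int = 2,
) -> EvalReport:
    """Train one model per LOSO fold and aggregate its held-out predictions.

    For model specs that need a validation set (early stopping), the fold's
    training subjects are further split: ``n_val_subjects`` subjects, drawn
    deterministically from ``seed`` and the fold index, are held out for
    validation so that early stopping never sees the test subject.
    """
    folds = loso_split(dataset)
    all_preds, all_truths, all_stages = [], [], []
    histories = []
    kept_folds = []
    for k, fold in enumerate(folds):
        test_ds = dataset.subset_by_subjects([fold.test_subject])
        if len(test_ds) == 0:
            logger.warning("fold %s has no test samples; skipping", fold.test_subject)
            continue
        train_subjects = fold.train_subjects
        val_ds = None
        if getattr(model_spec, "needs_validation", False):
            rng = np.random.default_rng([seed, k])
            n_val = min(n_val_subjects, len(train_subjects) - 1)
            val_subjects = sorted(rng.choice(train_subjects, size=n_val, replace=False))
            train_subjects = [s for s in train_subjects if s not in val_subjects]
            val_ds = dataset.subset_by_subjects(val_subjects)
        train_ds = dataset.subset_by_subjects(train_subjects)

        fitted = model_spec.fit(train_ds, val_ds, seed=np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))
        preds = np.asarray(fitted.predict(test_ds), dtype=np.float64)
        truths = test_ds.ages()
        fold.predictions, fold.truths = preds, truths
        fold.sample_ids = [s.sample_id for s in test_ds]
        fold.metrics = compute_metrics(preds, truths)
        if getattr(fitted, "history", None) is not None:
            histories.append(fitted.history)
        all_preds.append(preds)
        all_truths.append(truths)
        all_stages.append(test_ds.stage_labels())
        kept_folds.append(fold)

    preds = np.concatenate(all_preds)
    truths = np.concatenate(all_truths)
    stages = np.concatenate(all_stages)
    pooled = compute_metrics(preds, truths)
    stage_mae = {}
    for stage in ("early", "middle", "late"):
        sel = stages == stage
        if sel.any():
            stage_mae[stage] = (float(np.mean(np.abs(preds[sel] - truths[sel]))), int(sel.sum()))
    return EvalReport(
        model_name=getattr(model_spec, "name", type(model_spec).__name__),
        folds=kept_folds,
        pooled=pooled,
        mean_over_folds=_mean_over_folds([f.metrics for f in kept_folds]),
        stage_mae=stage_mae,
        per_day=_per_day_table(truths, preds),
        histories=histories,
    )
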