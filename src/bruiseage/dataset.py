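"""Shared data containers: samples, cohorts, and healing-stage labels.

A *cohort* is the unit of leave-one-subject-out evaluation: a collection of
per-acquisition samples grouped by subject.  Both the raw phantom samples and
the preprocessed spectral-spatial patches live in the same container type;
every element only needs ``sample_id``, ``subject_id`` and ``age_days``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

# Healing stages by hematoma age: early (0-3 d, fresh hemoglobin, reddish),
# middle (4-9 d, highest spectral contrast), late (>= 10 d, bilirubin
# accumulation and fading).  Non-integer ages fall into the stage whose
# integer range contains their floor; ages beyond 20 d count as late.
STAGES = ("early", "middle", "late")
EARLY_MAX = 3
MIDDLE_MAX = 9


def assign_stage(age_days: float) -> str:
    """Map a hematoma age in days to its healing-stage label."""
    if age_days < 0:
        raise ValueError(f"age must be non-negative, got {age_days}")
    if age_days < EARLY_MAX + 1:
        return "early"
    if age_days < MIDDLE_MAX + 1:
        return "middle"
    return "late"


@dataclass
class Sample:
    """One preprocessed acquisition: a patch cube plus its labels."""

    sample_id: str
    subject_id: str
    age_days: float
    values: np.ndarray  #: (n_bands, P, P) reflectance patch, float32
    stage: str = ""
    mask_provenance: str | None = None

    def __post_init__(self) -> None:
        if not self.stage:
            self.stage = assign_stage(self.age_days)


@dataclass
class CohortDataset:
    """Collection of samples grouped by subject; the unit of LOSO splitting."""

    samples: list
    axis: object | None = None  #: WavelengthAxis of the shared spectral grid
    attrs: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator:
        return iter(self.samples)

    def __getitem__(self, i):
        return self.samples[i]

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.samples})

    def subset_by_subjects(self, subject_ids: Sequence[str]) -> "CohortDataset":
        keep = set(subject_ids)
        return CohortDataset(
            [s for s in self.samples if s.subject_id in keep], self.axis, dict(self.attrs)
        )

    def metadata(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "age_days": s.age_days,
                "stage": getattr(s, "stage", assign_stage(s.age_days)),
            }
            for s in self.samples
        ]
        return pd.DataFrame(rows)

    # Patch-cohort conveniences -------------------------------------------
    def patches(self) -> np.ndarray:
        """Stack sample values into an (n, bands, P, P) float32 array."""
        return np.stack([np.asarray(s.values, dtype=np.float32) for s in self.samples])

    def ages(self) -> np.ndarray:
        return np.array([s.age_days for s in self.samples], dtype=np.float64)

    def stage_labels(self) -> np.ndarray:
        return np.array([getattr(s, "stage", assign_stage(s.age_days)) for s in self.samples])

    def with_samples(self, samples: list) -> "CohortDataset":
        return replace(self, samples=samples)
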