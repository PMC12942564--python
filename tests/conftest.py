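import numpy as np
import pytest

from bruiseage.dataset import CohortDataset, Sample
from bruiseage.phantom import PhantomParams, generate_cohort
from bruiseage.preprocess import build_dataset_from_cohort


TINY_PARAMS = PhantomParams(
    n_subjects=4,
    acquisition_days=(0, 2, 5, 9, 14, 19),
    image_size=(24, 24),
    n_bands=16,
    radius_base=4.0,
    seed=7,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small phantom cohort shared by read-only tests."""
    return generate_cohort(TINY_PARAMS)


@pytest.fixture(scope="session")
def tiny_patches(tiny_cohort):
    """Preprocessed 16x16 patches from the tiny cohort."""
    dataset, exclusions = build_dataset_from_cohort(
        tiny_cohort, patch_size=16, mask_source="truth"
    )
    assert not exclusions
    return dataset


def make_patch_cohort(
    n_subjects=3,
    ages=(0.0, 5.0, 12.0),
    n_bands=6,
    patch=8,
    seed=0,
    age_in_band=0,
    noise=0.05,
):
    """Hand-rolled patch cohort whose ``age_in_band`` channel encodes age.

    Cheap stand-in for the full generator when a test only needs labeled
    patches with a known informative band.  The age signal is a centered
    blob (spatially structured, flip-symmetric) so it survives per-band
    ratio normalization.
    """
    rng = np.random.default_rng(seed)
    lo, hi = patch // 4, patch - patch // 4
    samples = []
    for s in range(n_subjects):
        for age in ages:
            values = rng.normal(0.5, noise, size=(n_bands, patch, patch)).astype(np.float32)
            values[age_in_band, lo:hi, lo:hi] += np.float32(age / 20.0)
            samples.append(
                Sample(
                    sample_id=f"S{s}_a{age}",
                    subject_id=f"S{s}",
                    age_days=float(age),
                    values=values,
                )
            )
    return CohortDataset(samples)
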