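"""Preprocessing: radiance -> reflectance, lesion localization, patch extraction.

Coordinate convention, used everywhere: 0-based ``(row, col)`` indices and
half-open windows.

The lesion localizer is a deterministic spectral-contrast method (spectral
angle to the surrounding-skin spectrum, Otsu threshold, largest connected
component).  Precomputed masks — e.g. from an external RGB segmentation
model — can be injected instead; the pipeline only needs the mask to find
the lesion center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu

from .dataset import CohortDataset, Sample
from .envi import read_envi
from .phantom import WavelengthAxis

logger = logging.getLogger(__name__)

DEFAULT_PATCH_SIZE = 64


class DegenerateReferenceError(ValueError):
    """White and dark references coincide somewhere they are divided."""


class LesionNotFoundError(RuntimeError):
    """No lesion with sufficient spectral contrast was found (sample excluded)."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class HyperCube:
    """A (bands, rows, cols) cube bound to a wavelength axis."""

    values: np.ndarray
    axis: WavelengthAxis | None = None
    kind: str = "radiance"  # "radiance" | "reflectance"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 3:
            raise ValueError(f"expected (bands, rows, cols), got shape {v.shape}")
        if self.axis is not None and self.axis.n_bands != v.shape[0]:
            raise ValueError(
                f"cube has {v.shape[0]} bands but axis has {self.axis.n_bands}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("cube contains non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class ReferencePair:
    """White/dark reference measurements: per-band spectra or full cubes."""

    white: np.ndarray
    dark: np.ndarray

    def broadcastable(self) -> tuple[np.ndarray, np.ndarray]:
        white, dark = np.asarray(self.white), np.asarray(self.dark)
        if white.shape != dark.shape:
            raise ValueError("white and dark references must share a shape")
        if white.ndim == 1:
            return white[:, None, None], dark[:, None, None]
        if white.ndim == 3:
            return white, dark
        raise ValueError("references must be (bands,) spectra or (bands, rows, cols) cubes")


@dataclass
class LesionMask:
    """Binary lesion mask plus a provenance tag."""

    mask: np.ndarray
    provenance: str  # "builtin-segmenter" | "external-file" | "ground-truth"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Patch:
    """A fixed-size spectral-spatial window with all source bands retained."""

    values: np.ndarray  #: (n_bands, P, P)
    center: tuple  #: requested (row, col) center in source coordinates
    origin: tuple  #: (row, col) of the window's top-left corner
    sample_id: str = ""


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def radiometric_normalize(raw: HyperCube, refs: ReferencePair) -> HyperCube:
    """Convert raw radiance to relative reflectance.

    ``reflectance = (raw - dark) / (white - dark)`` element-wise, computed in
    float64 and stored as float32 (full floating precision, no quantization).
    Values are *not* clipped, so mild excursions outside [0, 1] caused by
    sensor noise survive.
    """
    white, dark = refs.broadcastable()
    denom = white.astype(np.float64) - dark.astype(np.float64)
    bad = denom == 0
    if np.any(bad):
        band, row, col = (int(i[0]) for i in np.nonzero(bad))
        raise DegenerateReferenceError(
            f"white == dark at band {band}, pixel ({row}, {col})"
        )
    values = (raw.values.astype(np.float64) - dark) / denom
    return HyperCube(values=values.astype(np.float32), axis=raw.axis, kind="reflectance")


def _border_ring(mask_shape: tuple, box: tuple) -> tuple[np.ndarray, np.ndarray]:
    r0, r1, c0, c1 = box
    rows, cols = [], []
    for r in range(r0, r1):
        for c in range(c0, c1):
            if r in (r0, r1 - 1) or c in (c0, c1 - 1):
                rows.append(r)
                cols.append(c)
    return np.array(rows), np.array(cols)


def spectral_angle(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Angle (radians) between each pixel spectrum and a reference spectrum.

    ``spectra`` has bands on the first axis; the output drops that axis.
    """
    ref = reference / max(np.linalg.norm(reference), 1e-12)
    norms = np.sqrt(np.sum(spectra**2, axis=0))
    cos = np.tensordot(ref, spectra, axes=(0, 0)) / np.clip(norms, 1e-12, None)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def segment_lesion(
    cube: HyperCube,
    prompt_box: tuple | None = None,
    min_contrast: float = 0.01,
) -> LesionMask:
    """Localize the lesion by spectral contrast against surrounding skin.

    Within the prompt box (``(r0, r1, c0, c1)``, half-open; whole image when
    omitted) each pixel is scored by its spectral angle to the median
    spectrum of the box border, the score image is thresholded by Otsu's
    method, and the largest connected component is kept.  Raises
    :class:`LesionNotFoundError` when no sufficiently contrasted region
    exists (such samples are excluded downstream).
    """
    if cube.kind != "reflectance":
        raise ValueError("segment_lesion expects a reflectance cube")
    bands, rows, cols = cube.values.shape
    if prompt_box is None:
        box = (0, rows, 0, cols)
    else:
        r0, r1, c0, c1 = prompt_box
        box = (max(0, r0), min(rows, r1), max(0, c0), min(cols, c1))
        if box[1] - box[0] < 3 or box[3] - box[2] < 3:
            raise ValueError(f"prompt box {prompt_box} too small")
    r0, r1, c0, c1 = box

    ring_r, ring_c = _border_ring((rows, cols), box)
    reference = np.median(cube.values[:, ring_r, ring_c], axis=1)
    region = cube.values[:, r0:r1, c0:c1]
    angle = spectral_angle(region, reference)

    if float(angle.max()) < min_contrast:
        raise LesionNotFoundError("no spectral contrast inside the prompt box")
    threshold = threshold_otsu(angle)
    candidate = angle > max(threshold, min_contrast)
    if not candidate.any():
        raise LesionNotFoundError("thresholding left an empty mask")

    labels, n_components = ndimage.label(candidate, structure=np.ones((3, 3)))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_components + 1))
    keep = int(np.argmax(sizes)) + 1
    component = labels == keep
    if float(angle[component].mean()) < min_contrast:
        raise LesionNotFoundError("largest component is below the contrast threshold")

    mask = np.zeros((rows, cols), dtype=bool)
    mask[r0:r1, c0:c1] = component
    return LesionMask(mask=mask, provenance="builtin-segmenter")


def mask_center(mask: LesionMask | np.ndarray) -> tuple[int, int]:
    """Integer centroid (round half up) of the positive mask pixels."""
    m = mask.mask if isinstance(mask, LesionMask) else np.asarray(mask).astype(bool)
    rr, cc = np.nonzero(m)
    if rr.size == 0:
        raise ValueError("mask is empty")
    return int(np.floor(rr.mean() + 0.5)), int(np.floor(cc.mean() + 0.5))


def extract_patch(
    cube: HyperCube | np.ndarray,
    center: tuple[int, int],
    size: int = DEFAULT_PATCH_SIZE,
    sample_id: str = "",
) -> Patch:
    """Extract an exactly ``size x size`` window nominally centered at ``center``.

    All bands are retained.  Windows that would overrun the image are shifted
    (clamped) inside it, so the output is always full-size with no padding.
    """
    values = cube.values if isinstance(cube, HyperCube) else np.asarray(cube)
    _, rows, cols = values.shape
    if size > rows or size > cols:
        raise ValueError(f"patch size {size} exceeds image extent ({rows}, {cols})")
    r_start = int(np.clip(center[0] - size // 2, 0, rows - size))
    c_start = int(np.clip(center[1] - size // 2, 0, cols - size))
    window = values[:, r_start : r_start + size, c_start : c_start + size]
    return Patch(
        values=np.ascontiguousarray(window),
        center=(int(center[0]), int(center[1])),
        origin=(r_start, c_start),
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class Exclusion:
    sample_id: str
    reason: str


def _resolve_mask(
    source: str,
    reflectance: HyperCube,
    truth_mask: np.ndarray | None,
    external_mask: np.ndarray | None,
    min_contrast: float,
) -> LesionMask:
    if source == "truth":
        if truth_mask is None:
            raise ValueError("mask source 'truth' but no ground-truth mask available")
        if not truth_mask.any():
            raise LesionNotFoundError("ground-truth mask is empty")
        return LesionMask(mask=truth_mask, provenance="ground-truth")
    if source == "external":
        if external_mask is None:
            raise ValueError("mask source 'external' but no mask supplied")
        if not np.asarray(external_mask).any():
            raise LesionNotFoundError("external mask is empty")
        return LesionMask(mask=external_mask, provenance="external-file")
    if source == "builtin":
        return segment_lesion(reflectance, min_contrast=min_contrast)
    raise ValueError(f"unknown mask source {source!r}")


def build_dataset_from_cohort(
    cohort: CohortDataset,
    patch_size: int = DEFAULT_PATCH_SIZE,
    mask_source: str = "truth",
    min_contrast: float = 0.01,
) -> tuple[CohortDataset, list[Exclusion]]:
    """Run normalize -> localize -> center -> patch over an in-memory cohort.

    Samples whose lesion cannot be found are excluded and reported (with the
    reason) rather than failing the whole run.
    """
    out, exclusions = [], []
    for s in cohort:
        try:
            raw = HyperCube(values=s.cube, axis=cohort.axis, kind="radiance")
            reflectance = radiometric_normalize(raw, ReferencePair(s.white, s.dark))
            mask = _resolve_mask(
                mask_source, reflectance, getattr(s, "mask", None), None, min_contrast
            )
            center = mask_center(mask)
            patch = extract_patch(reflectance, center, size=patch_size, sample_id=s.sample_id)
        except LesionNotFoundError as err:
            logger.info("excluding %s: %s", s.sample_id, err)
            exclusions.append(Exclusion(s.sample_id, str(err)))
            continue
        out.append(
            Sample(
                sample_id=s.sample_id,
                subject_id=s.subject_id,
                age_days=s.age_days,
                values=patch.values.astype(np.float32),
                mask_provenance=mask.provenance,
            )
        )
    return CohortDataset(out, axis=cohort.axis, attrs=dict(cohort.attrs)), exclusions


def build_dataset(
    metadata_csv: str | Path,
    patch_size: int = DEFAULT_PATCH_SIZE,
    mask_source: str = "builtin",
    min_contrast: float = 0.01,
) -> tuple[CohortDataset, list[Exclusion]]:
    """File-based pipeline: read ENVI cubes listed in a metadata CSV.

    The CSV needs columns ``sample_id, subject_id, age_days, path_cube,
    path_white, path_dark`` and optionally ``path_mask`` (used for mask
    sources ``truth`` and ``external``).
    """
    meta = pd.read_csv(metadata_csv)
    out, exclusions = [], []
    axis = None
    for _, row in meta.iterrows():
        for key in ("path_cube", "path_white", "path_dark"):
            if not Path(row[key]).exists():
                raise FileNotFoundError(f"row {row['sample_id']}: missing file {row[key]}")
        cube_values, wl = read_envi(row["path_cube"])
        if axis is None and wl is not None:
            axis = WavelengthAxis(wl)
        white, _ = read_envi(row["path_white"])
        dark, _ = read_envi(row["path_dark"])
        mask_arr = None
        if "path_mask" in row and isinstance(row["path_mask"], str) and Path(row["path_mask"]).exists():
            mask_path = Path(row["path_mask"])
            if mask_path.suffix.lower() == ".png":
                import imageio.v3 as iio

                mask_arr = np.asarray(iio.imread(mask_path)) > 0
                if mask_arr.ndim == 3:  # collapse any color channels
                    mask_arr = mask_arr.any(axis=-1)
            else:
                mask_arr = read_envi(mask_path)[0][0] > 0
        try:
            raw = HyperCube(values=cube_values, axis=axis, kind="radiance")
            refs = ReferencePair(white.reshape(white.shape[0]), dark.reshape(dark.shape[0]))
            reflectance = radiometric_normalize(raw, refs)
            truth = mask_arr if mask_source == "truth" else None
            external = mask_arr if mask_source == "external" else None
            mask = _resolve_mask(mask_source, reflectance, truth, external, min_contrast)
            center = mask_center(mask)
            patch = extract_patch(reflectance, center, size=patch_size, sample_id=row["sample_id"])
        except LesionNotFoundError as err:
            logger.info("excluding %s: %s", row["sample_id"], err)
            exclusions.append(Exclusion(row["sample_id"], str(err)))
            continue
        out.append(
            Sample(
                sample_id=row["sample_id"],
                subject_id=row["subject_id"],
                age_days=float(row["age_days"]),
                values=patch.values.astype(np.float32),
                mask_provenance=mask.provenance,
            )
        )
    return CohortDataset(out, axis=axis, attrs={}), exclusions


# ---------------------------------------------------------------------------
# HDF5 patch container
# ---------------------------------------------------------------------------


def save_patches(dataset: CohortDataset, path: str | Path) -> None:
    """Write a patch cohort to an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("patches", data=dataset.patches(), compression="gzip")
        f.create_dataset("age_days", data=dataset.ages())
        ids = [s.sample_id for s in dataset]
        subjects = [s.subject_id for s in dataset]
        stages = [s.stage for s in dataset]
        str_dt = h5py.string_dtype()
        f.create_dataset("sample_id", data=ids, dtype=str_dt)
        f.create_dataset("subject_id", data=subjects, dtype=str_dt)
        f.create_dataset("stage", data=stages, dtype=str_dt)
        if dataset.axis is not None:
            f.create_dataset("wavelengths", data=dataset.axis.centers)


def load_patches(path: str | Path) -> CohortDataset:
    import h5py

    with h5py.File(path, "r") as f:
        patches = f["patches"][...]
        ages = f["age_days"][...]
        ids = [x.decode() for x in f["sample_id"][...]]
        subjects = [x.decode() for x in f["subject_id"][...]]
        axis = WavelengthAxis(f["wavelengths"][...]) if "wavelengths" in f else None
    samples = [
        Sample(sample_id=i, subject_id=s, age_days=float(a), values=p)
        for i, s, a, p in zip(ids, subjects, ages, patches)
    ]
    return CohortDataset(samples, axis=axis)
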