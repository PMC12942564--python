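"""Synthetic longitudinal hyperspectral hematoma phantoms.

The generator emulates the statistical structure of a forearm-hematoma HSI
study: a cohort of subjects imaged repeatedly over ~3 weeks with a visible /
near-infrared line-scan camera (default 400-1000 nm).  Each acquisition is a
radiance cube plus white/dark reference spectra.  The lesion's spectral
signature evolves from hemoglobin-dominated (reddish, strong Soret-band
absorption) to bilirubin-dominated (yellow-brown) and finally fades, while
its spatial extent grows and then shrinks.

Two design points matter downstream:

* Age information is deliberately split between the *spectral* composition
  (chromophore weights) and the *spatial* texture (a smooth heterogeneity
  field whose amplitude grows with age).  Spatial averaging destroys the
  texture channel, so a spectral-only baseline cannot use it.
* All randomness derives from one integer seed through per-subject
  ``SeedSequence`` spawn keys, so adding a subject never perturbs the data
  of existing subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .dataset import CohortDataset, assign_stage
from .envi import write_envi

# ---------------------------------------------------------------------------
# Wavelength axis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavelengthAxis:
    """A strictly increasing grid of band-center wavelengths in nm.

    ``make_wavelength_axis`` produces evenly spaced grids; axes obtained by
    band subsetting are merely strictly increasing.
    """

    centers: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=np.float64)
        object.__setattr__(self, "centers", centers)
        if centers.ndim != 1 or centers.size < 1:
            raise ValueError("wavelength axis needs a 1-D, non-empty center list")
        if centers.size > 1 and not np.all(np.diff(centers) > 0):
            raise ValueError("wavelength centers must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return int(self.centers.size)

    @property
    def range_min(self) -> float:
        return float(self.centers[0])

    @property
    def range_max(self) -> float:
        return float(self.centers[-1])

    @property
    def spacing(self) -> float:
        if self.n_bands < 2:
            return 0.0
        return float(np.mean(np.diff(self.centers)))

    def subset(self, indices: np.ndarray) -> "WavelengthAxis":
        return WavelengthAxis(self.centers[np.asarray(indices)])


def make_wavelength_axis(
    n_bands: int = 204, range_min: float = 400.0, range_max: float = 1000.0
) -> WavelengthAxis:
    """Evenly spaced band centers: ``range_min + i * (range_max - range_min) / (n - 1)``."""
    if n_bands < 2:
        raise ValueError(f"n_bands must be >= 2, got {n_bands}")
    if not range_min < range_max:
        raise ValueError(f"need range_min < range_max, got [{range_min}, {range_max}]")
    return WavelengthAxis(np.linspace(range_min, range_max, n_bands))


# ---------------------------------------------------------------------------
# Chromophore library
# ---------------------------------------------------------------------------

#: (center nm, FWHM nm, relative amplitude) Gaussian components per chromophore.
#: Peak positions follow the standard absorption maxima: the hemoglobin Soret
#: band near 415/430 nm, oxyhemoglobin Q-bands at 540/578 nm, a broad
#: deoxyhemoglobin band near 555 nm, and bilirubin near 460 nm.  The curves
#: are parametric approximations, not tabulated extinction coefficients.
GAUSSIAN_PEAKS: dict[str, list[tuple[float, float, float]]] = {
    "oxyhemoglobin": [(415.0, 20.0, 1.0), (540.0, 25.0, 0.35), (578.0, 25.0, 0.38)],
    "deoxyhemoglobin": [(430.0, 20.0, 1.0), (555.0, 45.0, 0.40)],
    "bilirubin": [(460.0, 25.0, 1.0)],
}

CHROMOPHORES = tuple(GAUSSIAN_PEAKS) + ("melanin",)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def chromophore_absorption(name: str, axis: WavelengthAxis) -> np.ndarray:
    """Non-negative absorption curve on ``axis``, unit-normalized to max 1.

    ``melanin`` is a monotone-decreasing power-law background; the other
    chromophores are sums of Gaussian peaks.
    """
    lam = axis.centers
    if name == "melanin":
        curve = (lam / lam[0]) ** -3.5
    elif name in GAUSSIAN_PEAKS:
        curve = np.zeros_like(lam)
        for center, fwhm, amp in GAUSSIAN_PEAKS[name]:
            sigma = fwhm * _FWHM_TO_SIGMA
            curve = curve + amp * np.exp(-0.5 * ((lam - center) / sigma) ** 2)
    else:
        raise KeyError(f"unknown chromophore {name!r}; known: {CHROMOPHORES}")
    peak = curve.max()
    if peak > 0:
        curve = curve / peak
    return curve


# ---------------------------------------------------------------------------
# Time course of chromophore weights
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeCourse:
    """Hematoma chromophore kinetics.

    Hemoglobin (oxy + deoxy) decays exponentially from its maximum at age 0;
    the oxygenated fraction relaxes from fresh, mostly oxygenated blood to a
    deoxygenated steady state; bilirubin rises from exactly zero, peaks in
    the middle stage and falls again; and a smooth fade factor drives the
    total lesion contrast toward zero as the resolution horizon approaches.
    All rates are per day.
    """

    hemoglobin_amp: float = 1.2
    hemoglobin_decay: float = 0.12
    oxy_fraction_base: float = 0.25
    oxy_fraction_amp: float = 0.55
    oxy_fraction_tau: float = 3.0
    bilirubin_amp: float = 0.9
    bilirubin_peak_day: float = 7.0
    bilirubin_shape: float = 1.5
    fade_horizon: float = 22.0
    fade_power: float = 3.0


@dataclass(frozen=True)
class ChromophoreWeights:
    oxyhemoglobin: float
    deoxyhemoglobin: float
    bilirubin: float

    @property
    def hemoglobin(self) -> float:
        return self.oxyhemoglobin + self.deoxyhemoglobin

    @property
    def total(self) -> float:
        return self.oxyhemoglobin + self.deoxyhemoglobin + self.bilirubin

    def as_dict(self) -> dict[str, float]:
        return {
            "oxyhemoglobin": self.oxyhemoglobin,
            "deoxyhemoglobin": self.deoxyhemoglobin,
            "bilirubin": self.bilirubin,
        }


def time_course_weights(age_days: float, params: TimeCourse | None = None) -> ChromophoreWeights:
    """Per-chromophore concentration weights at a given hematoma age."""
    if age_days < 0:
        raise ValueError(f"age must be non-negative, got {age_days}")
    p = params or TimeCourse()
    t = float(age_days)
    fade = np.exp(-((t / p.fade_horizon) ** p.fade_power))
    hemoglobin = p.hemoglobin_amp * np.exp(-p.hemoglobin_decay * t) * fade
    oxy_frac = p.oxy_fraction_base + p.oxy_fraction_amp * np.exp(-t / p.oxy_fraction_tau)
    # Gamma-shaped pulse normalized to 1 at its mode, exactly 0 at age 0.
    rel = t / p.bilirubin_peak_day
    pulse = rel**p.bilirubin_shape * np.exp(p.bilirubin_shape * (1.0 - rel))
    bilirubin = p.bilirubin_amp * pulse * fade
    return ChromophoreWeights(
        oxyhemoglobin=float(hemoglobin * oxy_frac),
        deoxyhemoglobin=float(hemoglobin * (1.0 - oxy_frac)),
        bilirubin=float(bilirubin),
    )


# ---------------------------------------------------------------------------
# Phantom parameters and rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomParams:
    """Full description of a synthetic cohort; ``seed`` determines everything."""

    n_subjects: int = 8
    acquisition_days: tuple = (0, 1, 2, 3, 4, 5, 6, 8, 10, 13, 16, 20)
    image_size: tuple = (64, 64)
    n_bands: int = 60
    range_min: float = 400.0
    range_max: float = 1000.0
    # Lesion radius trajectory: grow-then-shrink pulse on top of the base radius.
    radius_base: float = 10.0
    radius_growth: float = 1.0
    radius_peak_day: float = 6.0
    # Smooth multiplicative texture inside the lesion; amplitude ramps with age.
    heterogeneity_amp: float = 0.35
    heterogeneity_scale: float = 4.0
    # Sensor noise applied to radiance only.
    noise_mult_sd: float = 0.01
    noise_add_sd: float = 0.005
    # Minimum total chromophore weight for a lesion to count as visible;
    # 0 disables the exclusion rule.
    visibility_threshold: float = 0.0
    time_course: TimeCourse = field(default_factory=TimeCourse)
    white_level: float = 0.92
    dark_level: float = 0.04
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if len(self.acquisition_days) < 1:
            raise ValueError("need at least one acquisition day")
        if any(d < 0 for d in self.acquisition_days):
            raise ValueError("acquisition days must be non-negative")
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        rows, cols = self.image_size
        if rows < 4 or cols < 4:
            raise ValueError("image_size too small")
        if self.noise_mult_sd < 0 or self.noise_add_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        max_radius = _MAX_SUBJECT_RADIUS_MULT * self.radius_base * (1.0 + self.radius_growth)
        if max_radius > min(rows, cols) / 2.0:
            raise ValueError(
                f"lesion radius (up to {max_radius:.1f} px) exceeds image bounds {self.image_size}"
            )

    def axis(self) -> WavelengthAxis:
        return make_wavelength_axis(self.n_bands, self.range_min, self.range_max)


_MAX_SUBJECT_RADIUS_MULT = 1.15
_AGE_NORM = 20.0  # day at which the texture-amplitude ramp reaches its maximum


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject baseline drawn from the subject's private random stream."""

    subject_id: str
    melanin_coeff: float
    skin_level: float
    radius_mult: float
    center: tuple
    decay_mult: float
    bilirubin_peak_mult: float


@dataclass
class PhantomSample:
    """One rendered acquisition: radiance cube, references, and ground truth."""

    sample_id: str
    subject_id: str
    age_days: float
    cube: np.ndarray  #: (n_bands, rows, cols) radiance, float32
    white: np.ndarray  #: (n_bands,) white-reference spectrum
    dark: np.ndarray  #: (n_bands,) dark-reference spectrum
    mask: np.ndarray  #: (rows, cols) bool ground-truth lesion mask
    stage: str = ""
    visible: bool = True

    def __post_init__(self) -> None:
        if not self.stage:
            self.stage = assign_stage(self.age_days)


def _subject_profile(params: PhantomParams, index: int) -> SubjectProfile:
    rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(index,)))
    rows, cols = params.image_size
    jitter = rng.integers(-4, 5, size=2)
    return SubjectProfile(
        subject_id=f"S{index:02d}",
        melanin_coeff=float(rng.uniform(0.25, 0.6)),
        skin_level=float(rng.uniform(0.45, 0.6)),
        radius_mult=float(rng.uniform(0.85, _MAX_SUBJECT_RADIUS_MULT)),
        center=(rows // 2 + int(jitter[0]), cols // 2 + int(jitter[1])),
        decay_mult=float(rng.uniform(0.9, 1.1)),
        bilirubin_peak_mult=float(rng.uniform(0.9, 1.1)),
    )


def lesion_radius(age_days: float, params: PhantomParams, radius_mult: float = 1.0) -> float:
    """Grow-then-shrink radius trajectory (maximal at ``radius_peak_day``)."""
    rel = age_days / params.radius_peak_day
    pulse = rel * np.exp(1.0 - rel)
    return params.radius_base * radius_mult * (1.0 + params.radius_growth * pulse)


def informative_bands(params: PhantomParams, threshold: float = 0.25) -> np.ndarray:
    """Indices of bands whose generator weights vary with age.

    A band is informative when any age-varying chromophore (hemoglobin
    species or bilirubin) absorbs at least ``threshold`` of its own maximum
    there; melanin is an age-constant background and does not count.
    """
    axis = params.axis()
    curves = [chromophore_absorption(name, axis) for name in GAUSSIAN_PEAKS]
    mask = np.max(np.stack(curves), axis=0) >= threshold
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("no informative bands: wavelength range misses all chromophores")
    return idx


def render_sample(
    profile: SubjectProfile,
    age_days: float,
    params: PhantomParams,
    rng: np.random.Generator,
) -> PhantomSample:
    """Render one acquisition for a subject at a given hematoma age.

    Lesion reflectance follows a Beer-Lambert mixing model: the subject's
    skin baseline attenuated by ``exp(-sum_c w_c A_c(lambda))``, where the
    effective weights are modulated by a smooth radial falloff and by the
    age-ramped heterogeneity texture.  Noise is applied to radiance only.
    """
    params.validate()
    if age_days < 0:
        raise ValueError("age must be non-negative")
    axis = params.axis()
    rows, cols = params.image_size

    tc = replace(
        params.time_course,
        hemoglobin_decay=params.time_course.hemoglobin_decay * profile.decay_mult,
        bilirubin_peak_day=params.time_course.bilirubin_peak_day * profile.bilirubin_peak_mult,
    )
    weights = time_course_weights(age_days, tc)

    curves = {name: chromophore_absorption(name, axis) for name in GAUSSIAN_PEAKS}
    mix = sum(w * curves[name] for name, w in weights.as_dict().items())  # (bands,)

    skin = profile.skin_level * np.exp(
        -profile.melanin_coeff * chromophore_absorption("melanin", axis)
    )  # (bands,)

    radius = lesion_radius(age_days, params, profile.radius_mult)
    rr, cc = np.ogrid[:rows, :cols]
    dist = np.sqrt((rr - profile.center[0]) ** 2 + (cc - profile.center[1]) ** 2)
    falloff = np.exp(-((dist / radius) ** 2))  # (rows, cols)

    if params.heterogeneity_amp > 0:
        field2d = gaussian_filter(
            rng.standard_normal((rows, cols)), sigma=params.heterogeneity_scale
        )
        sd = field2d.std()
        if sd > 0:
            field2d = (field2d - field2d.mean()) / sd
        amp = params.heterogeneity_amp * min(age_days / _AGE_NORM, 1.0)
        texture = np.clip(1.0 + amp * field2d, 0.0, None)
    else:
        rng.standard_normal((rows, cols))  # keep the stream layout stable
        texture = np.ones((rows, cols))

    absorbance = mix[:, None, None] * (falloff * texture)[None, :, :]
    reflectance = skin[:, None, None] * np.exp(-absorbance)

    white = np.full(axis.n_bands, params.white_level)
    dark = np.full(axis.n_bands, params.dark_level)
    radiance = dark[:, None, None] + reflectance * (white - dark)[:, None, None]
    if params.noise_mult_sd > 0:
        radiance = radiance * (1.0 + params.noise_mult_sd * rng.standard_normal(radiance.shape))
    if params.noise_add_sd > 0:
        radiance = radiance + params.noise_add_sd * rng.standard_normal(radiance.shape)
    white_meas = white + 0.002 * rng.standard_normal(axis.n_bands)
    dark_meas = dark + 0.0005 * rng.standard_normal(axis.n_bands)

    mask = dist <= radius
    visible = weights.total > params.visibility_threshold
    return PhantomSample(
        sample_id=f"{profile.subject_id}_d{age_days:04.1f}",
        subject_id=profile.subject_id,
        age_days=float(age_days),
        cube=radiance.astype(np.float32),
        white=white_meas.astype(np.float64),
        dark=dark_meas.astype(np.float64),
        mask=mask,
        visible=visible,
    )


def generate_cohort(params: PhantomParams) -> CohortDataset:
    """Generate the full longitudinal cohort (a pure function of ``params``).

    Samples failing the visibility threshold emulate the exclusion of
    acquisitions without a visible hematoma and are dropped.  The returned
    dataset carries the generator's informative-band indices in
    ``attrs["informative_bands"]``.
    """
    params.validate()
    samples = []
    for s in range(params.n_subjects):
        profile = _subject_profile(params, s)
        for j, age in enumerate(params.acquisition_days):
            rng = np.random.default_rng(np.random.SeedSequence(params.seed, spawn_key=(s, j)))
            sample = render_sample(profile, float(age), params, rng)
            if sample.visible:
                samples.append(sample)
    return CohortDataset(
        samples,
        axis=params.axis(),
        attrs={"informative_bands": informative_bands(params), "params": params},
    )


# ---------------------------------------------------------------------------
# On-disk export (ENVI cubes + CSV metadata)
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write each sample as ENVI cubes plus a CSV metadata table.

    Per sample: the radiance cube, white/dark reference spectra stored as
    (bands, 1, 1) ENVI cubes, and the ground-truth mask as a single-band
    8-bit ENVI image (0 = background, 1 = lesion).  Returns the metadata path.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wl = cohort.axis.centers if cohort.axis is not None else None
    rows = []
    for s in cohort:
        stem = out_dir / s.sample_id
        path_cube = write_envi(stem.with_suffix(".img"), s.cube, wavelengths=wl)
        path_white = write_envi(
            Path(str(stem) + "_white.img"), s.white[:, None, None], wavelengths=wl
        )
        path_dark = write_envi(Path(str(stem) + "_dark.img"), s.dark[:, None, None], wavelengths=wl)
        path_mask = write_envi(Path(str(stem) + "_mask.img"), s.mask.astype(np.uint8))
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject_id": s.subject_id,
                "age_days": s.age_days,
                "stage": s.stage,
                "path_cube": str(path_cube),
                "path_white": str(path_white),
                "path_dark": str(path_dark),
                "path_mask": str(path_mask),
            }
        )
    meta_path = out_dir / "metadata.csv"
    pd.DataFrame(rows).to_csv(meta_path, index=False)
    return meta_path
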