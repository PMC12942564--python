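"""Spectral input configurations and consensus band importance.

Four input configurations are compared with the same architecture: an
RGB-like triplet (460/540/650 nm, matching typical Bayer-filter peak
sensitivities), a six-band physiological subset adding heme-degradation
wavelengths (504/569/578 nm), the full band set, and a data-driven Top-k
subset.  The Top-k bands come from a consensus of two attribution methods —
noise-averaged input-gradient saliency (SmoothGrad) and per-band occlusion
sensitivity — combined by averaging each band's importance rank across the
two methods (rank 1 = most important; lower consensus rank = better).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataset import CohortDataset, Sample
from .phantom import WavelengthAxis

RGB_WAVELENGTHS = (460.0, 540.0, 650.0)
PHYSIO_EXTRA_WAVELENGTHS = (504.0, 569.0, 578.0)

SUBSET_NAMES = ("rgb", "physio", "full", "topk")


@dataclass(frozen=True)
class BandScore:
    """Per-band importance values from one method (or the rank consensus)."""

    values: np.ndarray
    method: str  # "smoothgrad" | "occlusion" | "consensus-rank"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))

    @property
    def n_bands(self) -> int:
        return self.values.size

    def ranks(self) -> np.ndarray:
        """Descending-score ranks (1 = most important; ties get average rank)."""
        if self.method == "consensus-rank":
            return self.values
        return rankdata(-self.values, method="average")


@dataclass(frozen=True)
class BandSubset:
    name: str
    indices: np.ndarray  #: sorted, unique band indices
    wavelengths: np.ndarray  #: corresponding centers in nm

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0 or np.unique(idx).size != idx.size or not np.all(np.diff(idx) > 0):
            raise ValueError("subset indices must be non-empty, unique and sorted")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))

    def __len__(self) -> int:
        return self.indices.size


# ---------------------------------------------------------------------------
# Band lookup and named subsets
# ---------------------------------------------------------------------------


def nearest_band(axis: WavelengthAxis, target_nm: float) -> int:
    """Index of the band center closest to ``target_nm`` (ties -> lower index)."""
    margin = axis.spacing if axis.n_bands > 1 else 0.0
    if not (axis.range_min - margin <= target_nm <= axis.range_max + margin):
        raise ValueError(
            f"target {target_nm} nm outside axis range "
            f"[{axis.range_min}, {axis.range_max}] (+- one band spacing)"
        )
    return int(np.argmin(np.abs(axis.centers - target_nm)))


def make_subset(
    name: str,
    axis: WavelengthAxis,
    k: int | None = None,
    consensus: BandScore | None = None,
) -> BandSubset:
    """Build one of the named spectral configurations on ``axis``."""
    if name == "rgb":
        idx = sorted({nearest_band(axis, w) for w in RGB_WAVELENGTHS})
    elif name == "physio":
        idx = sorted(
            {nearest_band(axis, w) for w in RGB_WAVELENGTHS + PHYSIO_EXTRA_WAVELENGTHS}
        )
    elif name == "full":
        idx = list(range(axis.n_bands))
    elif name == "topk":
        if consensus is None:
            raise ValueError("topk subset requires a consensus BandScore")
        return top_k(consensus, k=20 if k is None else k, axis=axis)
    else:
        raise ValueError(f"unknown subset name {name!r}; expected one of {SUBSET_NAMES}")
    idx = np.asarray(idx, dtype=int)
    return BandSubset(name=name, indices=idx, wavelengths=axis.centers[idx])


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------


def smoothgrad_importance(
    model,
    patches: np.ndarray,
    noise_frac: float = 0.1,
    n_draws: int = 25,
    seed: int = 0,
) -> BandScore:
    """Noise-averaged input-gradient saliency, aggregated per band.

    For each of ``n_draws`` draws, Gaussian noise with standard deviation
    ``noise_frac`` x (input standard deviation) is added to every patch and
    the gradient of the model output with respect to the input is computed.
    Per band, the gradient is first averaged over the pixels of each sample
    (the per-channel sensitivity; random pixel-level fluctuations cancel
    here) and its magnitude then averaged over samples and draws.  ``model``
    must expose ``input_gradients(patches)``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    patches = np.asarray(patches, dtype=np.float32)
    rng = np.random.default_rng(seed)
    sd = float(noise_frac) * float(patches.std())
    scores = np.zeros(patches.shape[1], dtype=np.float64)
    for _ in range(n_draws):
        noisy = patches if sd == 0 else patches + rng.normal(0.0, sd, patches.shape).astype(np.float32)
        grads = model.input_gradients(noisy)
        scores += np.abs(grads.mean(axis=(2, 3))).mean(axis=0)
    return BandScore(values=scores / n_draws, method="smoothgrad")


REPLACEMENT_POLICIES = ("train-mean", "zero", "identity")


def occlusion_importance(
    model,
    patches: np.ndarray,
    truths: np.ndarray,
    replacement: str = "train-mean",
    replacement_values: np.ndarray | None = None,
) -> BandScore:
    """Per-band occlusion sensitivity: MAE degradation when a band is masked.

    Each band in turn is replaced — by the per-band training mean (default,
    so masking removes information without leaving the input manifold), by
    zero, or by itself (identity; a no-op control) — and the model's MAE on
    the given samples is recomputed.  ``score[b] = occluded MAE - baseline
    MAE`` (signed: a band whose removal helps scores negative).
    """
    if replacement not in REPLACEMENT_POLICIES:
        raise ValueError(f"unknown replacement policy {replacement!r}")
    patches = np.asarray(patches, dtype=np.float32)
    truths = np.asarray(truths, dtype=np.float64)
    if len(patches) < 1:
        raise ValueError("need at least one sample")
    baseline_mae = float(np.mean(np.abs(model.predict(patches) - truths)))
    if replacement == "train-mean":
        fill = (
            np.asarray(replacement_values, dtype=np.float32)
            if replacement_values is not None
            else patches.mean(axis=(0, 2, 3))
        )
    scores = np.empty(patches.shape[1], dtype=np.float64)
    for b in range(patches.shape[1]):
        occluded = patches.copy()
        if replacement == "train-mean":
            occluded[:, b] = fill[b]
        elif replacement == "zero":
            occluded[:, b] = 0.0
        # identity: leave the band as is
        mae = float(np.mean(np.abs(model.predict(occluded) - truths)))
        scores[b] = mae - baseline_mae
    return BandScore(values=scores, method="occlusion")


def rank_consensus(a: BandScore, b: BandScore) -> BandScore:
    """Average the two methods' importance ranks (lower = more important)."""
    if a.n_bands != b.n_bands:
        raise ValueError(f"length mismatch: {a.n_bands} vs {b.n_bands}")
    return BandScore(values=(a.ranks() + b.ranks()) / 2.0, method="consensus-rank")


def top_k(consensus: BandScore, k: int = 20, axis: WavelengthAxis | None = None) -> BandSubset:
    """The ``k`` bands with the best (smallest) consensus rank.

    Ties at the cut are broken toward the lower band index; the result is
    sorted by band index.
    """
    if consensus.method != "consensus-rank":
        raise ValueError("top_k expects a consensus-rank BandScore")
    n = consensus.n_bands
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.lexsort((np.arange(n), consensus.values))
    idx = np.sort(order[:k])
    wavelengths = axis.centers[idx] if axis is not None else np.full(k, np.nan)
    return BandSubset(name="topk", indices=idx, wavelengths=wavelengths)


def apply_subset(dataset: CohortDataset, subset: BandSubset) -> CohortDataset:
    """Restrict every patch (and the wavelength axis) to the subset's bands."""
    n_bands = dataset.patches().shape[1] if len(dataset) else subset.indices.max() + 1
    if subset.indices.max() >= n_bands:
        raise IndexError(
            f"subset index {subset.indices.max()} out of range for {n_bands} bands"
        )
    samples = [
        Sample(
            sample_id=s.sample_id,
            subject_id=s.subject_id,
            age_days=s.age_days,
            values=np.ascontiguousarray(s.values[subset.indices]),
            stage=s.stage,
            mask_provenance=s.mask_provenance,
        )
        for s in dataset
    ]
    axis = dataset.axis.subset(subset.indices) if dataset.axis is not None else None
    attrs = dict(dataset.attrs)
    attrs["band_subset"] = subset
    return CohortDataset(samples, axis=axis, attrs=attrs)


def load_topk_subset(csv_path) -> BandSubset:
    """Load the Top-k subset from an importance CSV (``selected_topk`` rows)."""
    table = pd.read_csv(csv_path)
    selected = table[table["selected_topk"]]
    if selected.empty:
        raise ValueError(f"{csv_path}: no selected_topk rows")
    return BandSubset(
        name="topk",
        indices=selected["band_index"].to_numpy(),
        wavelengths=selected["wavelength_nm"].to_numpy(),
    )


def importance_table(
    smoothgrad: BandScore,
    occlusion: BandScore,
    consensus: BandScore,
    subset: BandSubset,
    axis: WavelengthAxis,
) -> pd.DataFrame:
    """Tidy per-band table: scores, consensus rank, and Top-k membership."""
    selected = np.zeros(axis.n_bands, dtype=bool)
    selected[subset.indices] = True
    return pd.DataFrame(
        {
            "band_index": np.arange(axis.n_bands),
            "wavelength_nm": axis.centers,
            "score_smoothgrad": smoothgrad.values,
            "score_occlusion": occlusion.values,
            "consensus_rank": consensus.values,
            "selected_topk": selected,
        }
    )
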