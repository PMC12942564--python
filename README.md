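# bruiseage

Hematoma (bruise) age estimation from visible/near-infrared hyperspectral
images.  As a hematoma heals, its chromophore content evolves — hemoglobin
(Soret band ≈ 415–430 nm, Q-bands ≈ 540/578 nm) gives way to bilirubin
(≈ 460 nm) before the lesion fades — and that evolution is written into the
per-pixel reflectance spectra.  This package implements a full analysis
pipeline for regressing hematoma age in days from such data, for researchers
in forensic and biomedical optics:

* **Preprocessing** — radiometric normalization to reflectance,
  `(raw − dark) / (white − dark)`, lesion localization by spectral contrast
  (or injected masks), and fixed-size lesion-centered patch extraction.
* **Models** — a spectral-only baseline (Lasso on the spatially averaged
  spectrum, which doubles as a wavelength selector) versus a
  spectral–spatial CNN: a per-pixel 1-D convolutional spectral encoder
  (128/64/32 channels, kernels 7/5/3) followed by 2-D convolutions over the
  embedding map (64/128 channels) and a regression head.  The network and
  its exact backpropagation are implemented on numpy/numba, so everything
  runs on one CPU core with no deep-learning framework.
* **Evaluation** — leave-one-subject-out (LOSO) cross-validation with a
  subject-level leakage audit; MAE, RMSE, R², threshold accuracies
  Acc@±1/2/3 d, and healing-stage breakdowns (early 0–3 d, middle 4–9 d,
  late ≥ 10 d).
* **Band importance** — a consensus of SmoothGrad saliency and per-band
  occlusion sensitivity (rank averaging) selects a Top-20 band subset;
  RGB-like (460/540/650 nm) and physiological (＋504/569/578 nm)
  configurations are built in for comparison.
* **Synthetic phantoms** — a longitudinal hematoma phantom generator
  (age-dependent chromophore mixtures, grow-then-shrink lesions,
  age-ramped spatial texture, reference frames, sensor noise) so the whole
  pipeline is testable without any clinical data.  ENVI cube I/O and an
  HDF5 patch container connect the stages on disk.

See `docs/methods.md` for the models, the generator's assumptions, and all
numerical choices.

## Worked example

Run the full comparison grid on a synthetic cohort (8 subjects × 12
acquisitions, 60 bands, one seed) from the shell:

```bash
bruiseage run-experiment --out runs/demo --seed 1
```

or drive the library directly:

```python
from bruiseage import (PhantomParams, generate_cohort,
                       build_dataset_from_cohort, run_loso,
                       LassoSpec, CnnSpec)

cohort = generate_cohort(PhantomParams(seed=1, image_size=(64, 64)))
patches, _ = build_dataset_from_cohort(cohort, patch_size=48, mask_source="truth")
lasso = run_loso(patches, LassoSpec(), seed=1)
cnn = run_loso(patches, CnnSpec(), seed=1)
print(f"Lasso LOSO MAE {lasso.pooled.mae:.2f} d   CNN LOSO MAE {cnn.pooled.mae:.2f} d")
print("CNN stage MAE:", {k: round(v[0], 2) for k, v in cnn.stage_mae.items()})
```

which prints

```
Lasso LOSO MAE 2.43 d   CNN LOSO MAE 1.37 d
CNN stage MAE: {'early': 1.29, 'middle': 1.13, 'late': 1.69}
```

Read this as: averaged over all held-out subjects, the spectral-only Lasso
misses the true hematoma age by about two and a half days, the
spectral–spatial CNN by about 1.4 days — the CNN wins because part of the
age signal lives in spatial texture and in the surrounding-skin context
that spatial averaging destroys — and the faded late stage is harder than
the high-contrast middle stage.  (Numbers are for synthetic phantoms at
desk scale; they say nothing about clinical data.)

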