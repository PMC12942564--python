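"""The two age regressors: a spatially averaged Lasso baseline and a
spectral-spatial CNN.

The CNN has two stages.  A 1-D convolutional encoder runs along the spectral
axis of every pixel independently (weights shared across pixels; pixels are
folded into the batch dimension, which is mathematically identical), compresses
each spectrum to a short embedding, and averages it to one vector per pixel.
The resulting embedding map is then processed by 2-D convolutions that read
the spatial morphology of the lesion, and a small fully connected head
regresses the hematoma age in days.  Every convolution is followed by ReLU
then batch normalization; dropout is applied in the head.

The baseline collapses each patch to its per-band mean spectrum and fits an
L1-regularized linear model, which also acts as a wavelength selector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path
from sklearn.model_selection import GroupKFold, KFold
from sklearn.preprocessing import StandardScaler

from . import nn
from .dataset import CohortDataset

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CnnConfig:
    """Architecture hyperparameters; the defaults are the full-scale model."""

    n_bands: int = 204
    spectral_channels: tuple = (128, 64, 32)
    spectral_kernels: tuple = (7, 5, 3)
    spectral_paddings: tuple = (3, 2, 1)
    spectral_pool_len: int = 16
    #: "pool-then-mean": adaptive-pool the spectral feature sequence to
    #: ``spectral_pool_len`` and average those positions into one vector per
    #: pixel.  "direct": average over all positions without pooling (the two
    #: readings of an average following an adaptive pool; they differ only by
    #: bin weighting when the band count is not divisible by the pool length).
    spectral_average: str = "pool-then-mean"
    spatial_channels: tuple = (64, 128)
    head_hidden: int = 256
    adaptive_spatial: int = 4
    dropout: float = 0.3
    #: batch-norm running-statistics momentum.  Training runs with few
    #: updates per epoch need a larger value so that inference-mode
    #: normalization tracks the quickly moving batch statistics.
    bn_momentum: float = 0.1
    #: batch-norm variance floor.  With few channels a post-ReLU channel can
    #: go silent (variance ~ 0); a larger eps bounds the normalization gain
    #: so unseen subjects cannot excite a huge response through such channels.
    bn_eps: float = 1e-5

    @property
    def flatten_width(self) -> int:
        return self.spatial_channels[-1] * self.adaptive_spatial**2

    def validate(self) -> None:
        if self.n_bands < min(self.spectral_kernels):
            raise ValueError(
                f"n_bands={self.n_bands} smaller than the smallest spectral kernel"
            )
        if not (
            len(self.spectral_channels) == len(self.spectral_kernels) == len(self.spectral_paddings)
        ):
            raise ValueError("spectral channel/kernel/padding lists must align")
        if self.spectral_average not in ("pool-then-mean", "direct"):
            raise ValueError(f"unknown spectral_average mode {self.spectral_average!r}")

    @classmethod
    def phantom_preset(cls, n_bands: int) -> "CnnConfig":
        """Reduced-width configuration for desk-scale phantom experiments.

        Same architecture family and layer sequence as the full model, sized
        so that a leave-one-subject-out sweep trains in minutes on one CPU.
        """
        return cls(
            n_bands=n_bands,
            spectral_channels=(4, 4, 4),
            spatial_channels=(8, 16),
            head_hidden=32,
            bn_eps=1e-3,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol: Adam with flip augmentation and early stopping
    on validation MAE (minimum improvement ``min_delta`` within ``patience``
    epochs; the best-epoch parameters are restored)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    weight_decay: float = 1e-5
    max_epochs: int = 100
    patience: int = 25
    min_delta: float = 0.01
    augment_flips: bool = True
    grad_clip: float = 5.0  #: global gradient-norm ceiling (0 disables)
    cosine_decay: bool = False  #: cosine-anneal the learning rate over max_epochs
    #: samples used to reset batch-norm statistics before each validation
    #: pass (0 disables recalibration and relies on running averages)
    bn_recalibration_samples: int = 16
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("learning rate, batch size, epochs and patience must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")

    @classmethod
    def phantom_preset(cls, seed: int = 0) -> "TrainConfig":
        return cls(
            learning_rate=3e-3, batch_size=4, max_epochs=8, patience=3, grad_clip=2.0, seed=seed
        )

    @classmethod
    def attribution_preset(cls, seed: int = 0) -> "TrainConfig":
        """Longer schedule for the single tuning-split attribution model.

        Band attribution needs a well-converged model (an under-trained
        network stays sensitive to inputs it never learned to ignore), and
        one model can afford what a LOSO sweep cannot.
        """
        return cls(
            learning_rate=3e-3, batch_size=4, max_epochs=20, patience=6, grad_clip=2.0, seed=seed
        )


# ---------------------------------------------------------------------------
# Spectral signature + Lasso baseline
# ---------------------------------------------------------------------------


def spatial_average(patch) -> np.ndarray:
    """Per-band mean over all pixels of a patch (or a stack of patches)."""
    values = getattr(patch, "values", patch)
    values = np.asarray(values)
    if values.ndim == 3:
        return values.mean(axis=(1, 2))
    if values.ndim == 4:
        return values.mean(axis=(2, 3))
    raise ValueError(f"expected (bands, P, P) or (n, bands, P, P), got shape {values.shape}")


class LassoBaseline:
    """L1-regularized linear regression on mean spectra.

    The penalty strength is selected by internal cross-validation over a
    logarithmic grid anchored at the smallest penalty that zeroes every
    coefficient; folds are grouped by subject when group labels are given, so
    penalty selection never leaks subjects.
    """

    def __init__(self, n_alphas: int = 50, cv: int = 5, alpha_min_ratio: float = 1e-4):
        self.n_alphas = n_alphas
        self.cv = cv
        self.alpha_min_ratio = alpha_min_ratio

    def fit(self, X: np.ndarray, y: np.ndarray, groups: Sequence | None = None) -> "LassoBaseline":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if len(X) < 2:
            raise ValueError("need at least 2 training samples")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        n = len(y)
        alpha_max = float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)
        if alpha_max <= 0:  # constant targets: any penalty gives the constant model
            self.alpha_ = 1.0
            self.model_ = Lasso(alpha=self.alpha_).fit(Xs, y)
            return self
        alphas = np.logspace(
            np.log10(alpha_max * self.alpha_min_ratio), np.log10(alpha_max), self.n_alphas
        )
        self.alpha_ = self._select_alpha(Xs, y, alphas, groups)
        self.model_ = Lasso(alpha=self.alpha_, max_iter=10000).fit(Xs, y)
        return self

    def _select_alpha(self, Xs, y, alphas, groups) -> float:
        if groups is not None and len(set(groups)) >= 2:
            groups = np.asarray(groups)
            splitter = GroupKFold(n_splits=min(self.cv, len(set(groups))))
            splits = list(splitter.split(Xs, y, groups))
        else:
            splitter = KFold(n_splits=min(self.cv, len(y)))
            splits = list(splitter.split(Xs, y))
        alphas = np.sort(alphas)[::-1]  # lasso_path wants a decreasing grid
        errors = np.zeros(len(alphas))
        for train_idx, test_idx in splits:
            y_mean = y[train_idx].mean()
            with warnings.catch_warnings():
                # the smallest grid penalties routinely hit the iteration cap;
                # they are never selected and the path there is good enough
                warnings.simplefilter("ignore", ConvergenceWarning)
                _, coefs, _ = lasso_path(
                    Xs[train_idx], y[train_idx] - y_mean, alphas=alphas, max_iter=3000
                )
            preds = Xs[test_idx] @ coefs + y_mean  # (n_test, n_alphas)
            errors += np.mean((preds - y[test_idx, None]) ** 2, axis=0)
        return float(alphas[int(np.argmin(errors))])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model_.predict(self.scaler_.transform(np.asarray(X, dtype=np.float64)))

    @property
    def coef_(self) -> np.ndarray:
        return self.model_.coef_

    @property
    def intercept_(self) -> float:
        return float(self.model_.intercept_)

    @property
    def nonzero_bands_(self) -> np.ndarray:
        return np.flatnonzero(self.model_.coef_ != 0)


def fit_lasso(signatures: np.ndarray, ages: np.ndarray, groups=None, **kwargs) -> LassoBaseline:
    """Fit the spatially averaged Lasso baseline (see :class:`LassoBaseline`)."""
    return LassoBaseline(**kwargs).fit(signatures, ages, groups=groups)


# ---------------------------------------------------------------------------
# The spectral-spatial CNN
# ---------------------------------------------------------------------------


class HematomaCNN:
    """Spectral-spatial age regressor (see module docstring).

    Input is ``(n, n_bands, P, P)``; output is one age per sample.  The model
    is pure numpy: :meth:`forward` / :meth:`backward` provide exact gradients
    both for the parameters and for the input (used by saliency attribution).
    """

    def __init__(self, config: CnnConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.dropout_rng = np.random.default_rng(seed + 1)

        spectral: list[nn.Layer] = []
        c_prev = 1
        for c, k, p in zip(
            config.spectral_channels, config.spectral_kernels, config.spectral_paddings
        ):
            spectral += [
                nn.Conv1d(c_prev, c, k, p, rng),
                nn.ReLU(),
                nn.BatchNorm(c, momentum=config.bn_momentum, eps=config.bn_eps),
            ]
            c_prev = c
        self.spectral = nn.Sequential(spectral)
        self.spectral_pool = nn.AdaptiveAvgPool1d(config.spectral_pool_len)
        self.spectral_mean = nn.MeanOverAxis1()

        spatial: list[nn.Layer] = []
        s_prev = c_prev
        for s in config.spatial_channels:
            spatial += [
                nn.Conv2d(s_prev, s, 3, 1, rng),
                nn.ReLU(),
                nn.BatchNorm(s, momentum=config.bn_momentum, eps=config.bn_eps),
                nn.MaxPool2d(),
            ]
            s_prev = s
        self.spatial = nn.Sequential(spatial)
        self.spatial_pool = nn.AdaptiveAvgPool2d(config.adaptive_spatial)
        self.flatten = nn.Flatten()
        self.head = nn.Sequential(
            [
                nn.Linear(config.flatten_width, config.head_hidden, rng),
                nn.ReLU(),
                nn.Dropout(config.dropout, self.dropout_rng),
                nn.Linear(config.head_hidden, 1, rng),
            ]
        )

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[nn.Param]:
        return (
            self.spectral.params()
            + self.spatial.params()
            + self.head.params()
        )

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        self.dropout_rng = rng
        for layer in self.head.layers:
            if isinstance(layer, nn.Dropout):
                layer.rng = rng

    # -- forward / backward ---------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.F32)
        if x.ndim != 4 or x.shape[1] != self.config.n_bands:
            raise ValueError(
                f"expected (n, {self.config.n_bands}, P, P) input, got shape {x.shape}"
            )
        return x

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._check_input(x)
        n, bands, h, w = x.shape
        self._hw = (n, h, w)
        z = x.transpose(0, 2, 3, 1).reshape(n * h * w, bands, 1)
        z = self.spectral.forward(z, train)
        if self.config.spectral_average == "pool-then-mean":
            z = self.spectral_pool.forward(z, train)
        z = self.spectral_mean.forward(z, train)  # (n*h*w, C)
        emb = z.reshape(n, h, w, -1)
        s = self.spatial.forward(emb, train)
        s = self.spatial_pool.forward(s, train)
        s = self.flatten.forward(s, train)
        out = self.head.forward(s, train)
        return out[:, 0]

    def backward(self, g_out: np.ndarray, need_param_grads: bool = True) -> np.ndarray:
        n, h, w = self._hw
        g = self.head.backward(np.asarray(g_out, dtype=nn.F32)[:, None], need_param_grads)
        g = self.flatten.backward(g, need_param_grads)
        g = self.spatial_pool.backward(g, need_param_grads)
        g = self.spatial.backward(g, need_param_grads)
        g = g.reshape(n * h * w, -1)
        g = self.spectral_mean.backward(g, need_param_grads)
        if self.config.spectral_average == "pool-then-mean":
            g = self.spectral_pool.backward(g, need_param_grads)
        g = self.spectral.backward(g, need_param_grads)
        return g.reshape(n, h, w, self.config.n_bands).transpose(0, 3, 1, 2)

    def _bn_layers(self) -> list[nn.BatchNorm]:
        return [
            layer
            for stage in (self.spectral, self.spatial, self.head)
            for layer in stage.layers
            if isinstance(layer, nn.BatchNorm)
        ]

    def recalibrate_bn(self, x: np.ndarray) -> None:
        """Reset batch-norm running statistics to the statistics of ``x``.

        One dropout-free forward pass in training mode with momentum 1 makes
        inference-mode normalization match the current weights exactly,
        instead of an exponential average that lags them.  Called by the
        training loop before each validation pass.
        """
        bns = self._bn_layers()
        saved_momentum = [bn.momentum for bn in bns]
        dropouts = [l for l in self.head.layers if isinstance(l, nn.Dropout)]
        saved_rates = [d.rate for d in dropouts]
        for bn in bns:
            bn.momentum = 1.0
        for d in dropouts:
            d.rate = 0.0
        try:
            self.forward(x, train=True)
        finally:
            for bn, m in zip(bns, saved_momentum):
                bn.momentum = m
            for d, r in zip(dropouts, saved_rates):
                d.rate = r

    # -- full state (parameters + batch-norm running statistics) -------------
    def state_arrays(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.params()]
        for stage in (self.spectral, self.spatial, self.head):
            for layer in stage.layers:
                if isinstance(layer, nn.BatchNorm):
                    state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def load_state_arrays(self, state: list[np.ndarray]) -> None:
        params = self.params()
        for p, s in zip(params, state[: len(params)]):
            p.value[...] = s
        buffers = state[len(params) :]
        i = 0
        for stage in (self.spectral, self.spatial, self.head):
            for layer in stage.layers:
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean[...] = buffers[i]
                    layer.running_var[...] = buffers[i + 1]
                    i += 2

    # -- inference helpers ----------------------------------------------------
    def predict(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Deterministic inference (no augmentation, no dropout)."""
        x = self._check_input(x)
        out = np.empty(len(x), dtype=np.float64)
        for start in range(0, len(x), batch_size):
            out[start : start + batch_size] = self.forward(x[start : start + batch_size])
        return out

    def input_gradients(self, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """d(output)/d(input) per sample, evaluated in inference mode."""
        x = self._check_input(x)
        grads = np.empty_like(x)
        for start in range(0, len(x), batch_size):
            xb = x[start : start + batch_size]
            self.forward(xb, train=False)
            grads[start : start + batch_size] = self.backward(
                np.ones(len(xb)), need_param_grads=False
            )
        return grads


def build_cnn(config: CnnConfig, seed: int = 0) -> HematomaCNN:
    """Construct the spectral-spatial CNN for a given configuration."""
    return HematomaCNN(config, seed=seed)


def cnn_shape_trace(config: CnnConfig | None = None, image_size: int = 64) -> list[tuple[str, tuple]]:
    """Layer-by-layer output shapes, measured by running a real forward pass.

    Shapes are reported in channels-first convention: ``(C, L)`` per pixel for
    the spectral encoder, ``(C, H, W)`` for the spatial stage.  The spectral
    stage is traced on a small pixel block (its per-pixel shapes do not depend
    on the pixel count), which keeps the trace cheap even at full width.
    """
    config = config or CnnConfig()
    model = HematomaCNN(config, seed=0)
    bands = config.n_bands
    rows: list[tuple[str, tuple]] = [("input", (bands, image_size, image_size))]

    # Spectral encoder, per pixel: trace with a handful of pixel rows.
    z = np.zeros((4, bands, 1), dtype=nn.F32)
    rows.append(("pixel_spectral_reshape", (z.shape[2], z.shape[1])))
    for layer in model.spectral.layers:
        z = layer.forward(z)
        if isinstance(layer, nn.Conv1d):
            rows.append(("conv1d", (z.shape[2], z.shape[1])))
    if config.spectral_average == "pool-then-mean":
        z = model.spectral_pool.forward(z)
        rows.append(("adaptive_avg_pool1d", (z.shape[2], z.shape[1])))
    z = model.spectral_mean.forward(z)
    rows.append(("spectral_average", (z.shape[1],)))

    # Spatial stage on a full-size embedding map (cheap: few channels).
    emb = np.zeros(
        (1, image_size, image_size, config.spectral_channels[-1]), dtype=nn.F32
    )
    rows.append(
        ("spectral_embedding_map", (config.spectral_channels[-1], image_size, image_size))
    )
    s = emb
    for layer in model.spatial.layers:
        s = layer.forward(s)
        if isinstance(layer, nn.Conv2d):
            rows.append(("conv2d", (s.shape[3], s.shape[1], s.shape[2])))
        elif isinstance(layer, nn.MaxPool2d):
            rows.append(("maxpool2d", (s.shape[3], s.shape[1], s.shape[2])))
    s = model.spatial_pool.forward(s)
    rows.append(("adaptive_avg_pool2d", (s.shape[3], s.shape[1], s.shape[2])))
    s = model.flatten.forward(s)
    rows.append(("flatten", (s.shape[1],)))
    for layer in model.head.layers:
        s = layer.forward(s)
        if isinstance(layer, nn.Linear):
            rows.append(("linear", (s.shape[1],)))
    return rows


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _flip_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random horizontal/vertical flips, each with independent probability 0.5."""
    x = x.copy()
    flips = rng.random((len(x), 2)) < 0.5
    for i, (fv, fh) in enumerate(flips):
        if fv:
            x[i] = x[i, :, ::-1, :]
        if fh:
            x[i] = x[i, :, :, ::-1]
    return x


def train_model(
    model: HematomaCNN,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TrainConfig,
) -> dict:
    """Train with Adam on mean squared error, early-stopping on validation MAE.

    Returns a history dict (per-epoch train loss and validation MAE, and the
    best epoch); the model is left holding the best-epoch parameters.
    """
    cfg.validate()
    if len(x_val) == 0:
        raise ValueError("validation set must be non-empty (needed for early stopping)")
    x_train = np.asarray(x_train, dtype=nn.F32)
    y_train = np.asarray(y_train, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    model.set_dropout_rng(np.random.default_rng(cfg.seed + 10_007))
    params = model.params()
    opt = nn.Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)

    calib_idx = None
    if cfg.bn_recalibration_samples > 0:
        calib_idx = rng.choice(
            len(x_train), size=min(cfg.bn_recalibration_samples, len(x_train)), replace=False
        )
    best_mae = np.inf
    best_state = model.state_arrays()
    best_epoch = -1
    stale = 0
    history: dict = {"train_loss": [], "val_mae": []}

    for epoch in range(cfg.max_epochs):
        if cfg.cosine_decay:
            opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.max_epochs))
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = x_train[idx]
            if cfg.augment_flips:
                xb = _flip_batch(xb, rng)
            yb = y_train[idx]
            pred = model.forward(xb, train=True)
            err = pred - yb
            epoch_loss += float(np.sum(err**2))
            opt.zero_grad()
            model.backward(2.0 * err / len(idx))
            if cfg.grad_clip > 0:
                opt.clip_grad_norm(cfg.grad_clip)
            opt.step()
        history["train_loss"].append(epoch_loss / len(order))

        if calib_idx is not None:
            model.recalibrate_bn(x_train[calib_idx])
        val_mae = float(np.mean(np.abs(model.predict(x_val) - y_val)))
        history["val_mae"].append(val_mae)
        if best_mae - val_mae >= cfg.min_delta:
            best_mae, best_epoch, stale = val_mae, epoch, 0
            best_state = model.state_arrays()
        else:
            stale += 1
            if stale >= cfg.patience:
                break

    model.load_state_arrays(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_mae"] = best_mae
    return history


def predict(model: HematomaCNN, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """One finite, order-preserving prediction per sample (no augmentation)."""
    return model.predict(x, batch_size=batch_size)


# ---------------------------------------------------------------------------
# Model specs: a uniform fit/predict interface for LOSO evaluation
# ---------------------------------------------------------------------------


@dataclass
class FittedLasso:
    baseline: LassoBaseline

    def predict(self, dataset: CohortDataset) -> np.ndarray:
        return self.baseline.predict(spatial_average(dataset.patches()))


@dataclass
class LassoSpec:
    """Spatially averaged spectra + L1 linear model."""

    name: str = "lasso"
    needs_validation: bool = False

    def fit(self, train: CohortDataset, val: CohortDataset | None, seed: int) -> FittedLasso:
        X = spatial_average(train.patches())
        groups = [s.subject_id for s in train]
        return FittedLasso(fit_lasso(X, train.ages(), groups=groups))


@dataclass
class FittedCnn:
    model: HematomaCNN
    band_mean: np.ndarray
    band_sd: np.ndarray
    age_mean: float = 0.0
    age_sd: float = 1.0
    band_ratio: bool = True
    history: dict | None = None

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=nn.F32)
        if self.band_ratio:
            x = _band_ratio(x)
        return (x - self.band_mean) / self.band_sd

    def predict(self, dataset) -> np.ndarray:
        x = dataset.patches() if isinstance(dataset, CohortDataset) else np.asarray(dataset)
        return self.model.predict(self._standardize(x)) * self.age_sd + self.age_mean

    def input_gradients(self, patches: np.ndarray) -> np.ndarray:
        """Gradients of the predicted age (days) w.r.t. the raw reflectance.

        Chains exactly through the band standardization and, when enabled,
        the per-band ratio normalization (whose scale depends on the sample
        itself).
        """
        x = np.asarray(patches, dtype=nn.F32)
        g = self.model.input_gradients(self._standardize(x)) * self.age_sd
        g = g / self.band_sd  # gradient w.r.t. the normalized patch
        if not self.band_ratio:
            return g
        return _band_ratio_gradient(x, g)


def _band_ratio(x: np.ndarray) -> np.ndarray:
    """Per-band ratio normalization: each band divided by its own spatial
    mean within the patch, minus one.

    Under a multiplicative skin model (reflectance = baseline(lambda) x
    lesion attenuation), dividing every band by its patch mean cancels the
    subject's baseline — skin brightness, melanin level, illumination —
    exactly and *per band*, so no information is mixed across wavelengths.
    Bands without lesion absorption become flat (~0) rather than inheriting
    a sample-level scale, which keeps band attribution physically honest.
    The spatial pattern of each band (the carrier of lesion shape, depth and
    texture) is preserved.
    """
    mean = np.clip(x.mean(axis=(2, 3), keepdims=True), 1e-6, None)
    return x / mean - 1.0


def _band_ratio_gradient(x: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Exact chain rule through :func:`_band_ratio`.

    With y_i = x_i / m - 1 and m the spatial mean of the band,
    dL/dx_k = (g_k - mean_i(g_i * (y_i + 1))) / m.
    """
    mean = np.clip(x.mean(axis=(2, 3), keepdims=True), 1e-6, None)
    ratio = x / mean
    correction = (g * ratio).mean(axis=(2, 3), keepdims=True)
    return (g - correction) / mean


@dataclass
class CnnSpec:
    """Spectral-spatial CNN with ratio + per-band input standardization.

    ``cnn_config=None`` sizes the phantom preset to the dataset's band count
    at fit time.
    """

    cnn_config: CnnConfig | None = None
    train_config: TrainConfig = field(default_factory=TrainConfig.phantom_preset)
    band_ratio: bool = True
    #: "global": one shared scale for all bands, preserving the natural
    #: inter-band amplitude ordering (after ratio normalization, amplitude
    #: *is* information: bands without lesion absorption are nearly flat and
    #: should stay small).  "per-band": classical per-band unit variance,
    #: which amplifies pure-noise bands to the same scale as informative
    #: ones and blurs band attribution.
    scale_mode: str = "global"
    name: str = "cnn"
    needs_validation: bool = True

    def fit(self, train: CohortDataset, val: CohortDataset | None, seed: int) -> FittedCnn:
        if val is None or len(val) == 0:
            raise ValueError("CnnSpec needs a non-empty validation set for early stopping")
        x = np.asarray(train.patches(), dtype=nn.F32)
        xn = _band_ratio(x) if self.band_ratio else x
        config = self.cnn_config or CnnConfig.phantom_preset(n_bands=x.shape[1])
        band_mean = xn.mean(axis=(0, 2, 3), dtype=np.float64)[None, :, None, None].astype(nn.F32)
        if self.scale_mode == "global":
            band_sd = np.full(
                (1, x.shape[1], 1, 1), max(float(xn.std(dtype=np.float64)), 1e-6), dtype=nn.F32
            )
        elif self.scale_mode == "per-band":
            band_sd = xn.std(axis=(0, 2, 3), dtype=np.float64)[None, :, None, None].astype(nn.F32)
        else:
            raise ValueError(f"unknown scale_mode {self.scale_mode!r}")
        band_sd = np.clip(band_sd, 1e-6, None)
        ages = train.ages()
        # Targets are standardized for optimization (the network's zero-init
        # output then starts at the training mean age); predictions are mapped
        # back to days, and the early-stopping MAE is measured in days.
        age_mean = float(ages.mean())
        age_sd = float(max(ages.std(), 1e-6))
        fitted = FittedCnn(
            HematomaCNN(config, seed=seed),
            band_mean,
            band_sd,
            age_mean=age_mean,
            age_sd=age_sd,
            band_ratio=self.band_ratio,
        )
        cfg = replace(self.train_config, seed=seed, min_delta=self.train_config.min_delta / age_sd)
        fitted.history = train_model(
            fitted.model,
            fitted._standardize(x),
            (ages - age_mean) / age_sd,
            fitted._standardize(val.patches()),
            (val.ages() - age_mean) / age_sd,
            cfg,
        )
        fitted.history["val_mae"] = [v * age_sd for v in fitted.history["val_mae"]]
        fitted.history["best_val_mae"] = fitted.history["best_val_mae"] * age_sd
        return fitted


def save_checkpoint(
    fitted: FittedCnn,
    path,
    wavelengths: np.ndarray | None = None,
    seed: int | None = None,
) -> None:
    """Serialize a fitted CNN: architecture config, weights, normalization,
    and (when given) the wavelength subset and training seed."""
    import json
    from dataclasses import asdict

    arrays = {f"state_{i}": a for i, a in enumerate(fitted.model.state_arrays())}
    if wavelengths is not None:
        arrays["wavelengths"] = np.asarray(wavelengths, dtype=float)
    if seed is not None:
        arrays["train_seed"] = np.array(int(seed))
    np.savez(
        path,
        band_mean=fitted.band_mean,
        band_sd=fitted.band_sd,
        age_scale=np.array([fitted.age_mean, fitted.age_sd]),
        band_ratio=np.array(int(fitted.band_ratio)),
        config_json=np.array(json.dumps(asdict(fitted.model.config))),
        **arrays,
    )


def load_checkpoint(path) -> FittedCnn:
    import json

    with np.load(path, allow_pickle=False) as data:
        config = CnnConfig(
            **{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in json.loads(str(data["config_json"])).items()
            }
        )
        n_state = sum(1 for k in data.files if k.startswith("state_"))
        state = [data[f"state_{i}"] for i in range(n_state)]
        fitted = FittedCnn(
            HematomaCNN(config, seed=0),
            data["band_mean"],
            data["band_sd"],
            age_mean=float(data["age_scale"][0]),
            age_sd=float(data["age_scale"][1]),
            band_ratio=bool(int(data["band_ratio"])) if "band_ratio" in data.files else True,
        )
        fitted.model.load_state_arrays(state)
    return fitted


@dataclass
class FittedMean:
    value: float

    def predict(self, dataset: CohortDataset) -> np.ndarray:
        return np.full(len(dataset), self.value)


@dataclass
class MeanPredictorSpec:
    """Dummy reference: always predicts the training-set mean age."""

    name: str = "mean"
    needs_validation: bool = False

    def fit(self, train: CohortDataset, val: CohortDataset | None, seed: int) -> FittedMean:
        return FittedMean(float(train.ages().mean()))
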