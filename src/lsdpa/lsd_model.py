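"""The learned spectral decoloring regressor.

A fully connected feed-forward network maps a sum-normalized initial
pressure spectrum (one entry per wavelength) to a scalar sO2 estimate.  The
architecture is input(n) -> [dense(2n) -> leaky-ReLU -> dropout(0.2)] x 4
-> dense(1); the output head is linear and estimates are clamped to [0, 1]
only at reporting time.  Training minimizes a mean squared error loss with
minibatch Adam (default; plain SGD with momentum is available via config)
under a step learning-rate schedule lr = lr0 * base^(epoch // update_every)
(lr0 = 1e-2, base = 0.9, updates every two epochs; for Adam the schedule is
rescaled by ``adam_lr_factor`` to Adam's customary 1e-3 starting
magnitude).  Inputs are standardized per feature with statistics of the
training split, stored in the trained model.  All randomness
(initialization, splits, batch and dropout sampling) derives from the
config seed, so training is reproducible end to end.

The forward/backward pass is implemented directly in numpy; a trained
model is bound to the wavelength grid of its training data and refuses
spectra on any other grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigError, DataError, ValidationError, \
    WavelengthMismatchError
from .spectra import NORMALIZATION_ATOL, SpectraDataset

#: tolerance when verifying that prediction inputs are sum-normalized
_INPUT_SUM_ATOL = 1e-6


@dataclass(frozen=True)
class LSDConfig:
    """Hyperparameters of the LSD network and its training schedule."""

    n_inputs: int
    hidden_layers: int = 4
    hidden_width: Optional[int] = None   # None -> 2 * n_inputs
    dropout_rate: float = 0.2
    leaky_slope: float = 0.01
    epochs: int = 100
    batches_per_epoch: int = 500
    batch_size: int = 10_000
    lr_initial: float = 1e-2
    lr_decay_base: float = 0.9
    lr_update_every: int = 2
    split: Tuple[float, float, float] = (0.75, 0.05, 0.20)
    seed: int = 0
    loss: str = "mse"
    optimizer: str = "adam"
    momentum: float = 0.9        # SGD only
    adam_lr_factor: float = 0.1  # Adam effective lr = factor * schedule

    def __post_init__(self) -> None:
        if self.n_inputs < 2:
            raise ConfigError("n_inputs must be >= 2")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")
        for name in ("hidden_layers", "epochs", "batches_per_epoch",
                     "batch_size", "lr_update_every"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must lie in [0, 1)")
        if self.loss not in ("mse", "mae"):
            raise ConfigError("loss must be 'mse' or 'mae'")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigError("optimizer must be 'adam' or 'sgd'")

    @property
    def width(self) -> int:
        return self.hidden_width or 2 * self.n_inputs

    @classmethod
    def desk_scale(cls, n_inputs: int, seed: int = 0, **kw) -> "LSDConfig":
        """Reduced training schedule: 60 epochs of 500 batches of 256.

        3e4 parameter updates (the full schedule has 5e4) at a batch size
        matched to desk-scale dataset sizes (~2e4 spectra)."""
        return cls(n_inputs=n_inputs, epochs=60, batches_per_epoch=500,
                   batch_size=256, seed=seed, **kw)


def lr_schedule(epoch: int, cfg: LSDConfig) -> float:
    """Step schedule: lr0 * base^(epoch / update_every), held between steps."""
    if epoch < 0:
        raise ValidationError("epoch must be >= 0")
    return cfg.lr_initial * cfg.lr_decay_base ** (epoch // cfg.lr_update_every)


class LSDModel:
    """Weights plus forward/backward of the fully connected regressor."""

    def __init__(self, cfg: LSDConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        sizes = [cfg.n_inputs] + [cfg.width] * cfg.hidden_layers + [1]
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            # He initialization, suited to (leaky) ReLU hidden units
            self.weights.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def layer_widths(self) -> List[int]:
        return [self.weights[0].shape[0]] + [w.shape[1] for w in self.weights]

    def n_parameters(self) -> int:
        return sum(w.size for w in self.weights) + sum(
            b.size for b in self.biases)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None):
        """Forward pass; returns (output, cache for backward)."""
        cfg = self.cfg
        cache = []
        h = x
        n_hidden = len(self.weights) - 1
        for i in range(n_hidden):
            z = h @ self.weights[i] + self.biases[i]
            a = np.where(z > 0, z, cfg.leaky_slope * z)
            if train and cfg.dropout_rate > 0:
                keep = (rng.random(a.shape) >= cfg.dropout_rate)
                a = a * keep / (1.0 - cfg.dropout_rate)   # inverted dropout
            else:
                keep = None
            cache.append((h, z, keep))
            h = a
        out = (h @ self.weights[-1] + self.biases[-1])[:, 0]
        cache.append((h, None, None))
        return out, cache

    def backward(self, dout: np.ndarray, cache) -> List[Tuple[np.ndarray,
                                                              np.ndarray]]:
        """Gradient of the loss w.r.t. every weight/bias."""
        cfg = self.cfg
        grads: List[Tuple[np.ndarray, np.ndarray]] = [None] * len(self.weights)
        h_last = cache[-1][0]
        delta = dout[:, None]                      # (B, 1)
        grads[-1] = (h_last.T @ delta, delta.sum(axis=0))
        da = delta @ self.weights[-1].T
        for i in range(len(self.weights) - 2, -1, -1):
            h_in, z, keep = cache[i]
            if keep is not None:
                da = da * keep / (1.0 - cfg.dropout_rate)
            dz = da * np.where(z > 0, 1.0, cfg.leaky_slope)
            grads[i] = (h_in.T @ dz, dz.sum(axis=0))
            if i > 0:
                da = dz @ self.weights[i].T
        return grads


def build_model(cfg: LSDConfig) -> LSDModel:
    """Seeded construction of an untrained network."""
    return LSDModel(cfg)


@dataclass
class TrainedLSDModel:
    """A trained network bound to a specific wavelength grid."""

    model: LSDModel
    wavelength_grid: np.ndarray
    config: LSDConfig
    training_log: Dict[str, List[float]] = field(default_factory=dict)
    #: per-feature standardization constants fitted on the training split
    feature_mean: Optional[np.ndarray] = None
    feature_std: Optional[np.ndarray] = None

    def _standardize(self, x: np.ndarray) -> np.ndarray:
        if self.feature_mean is None:
            return x * self.config.n_inputs
        return (x - self.feature_mean) / self.feature_std

    def _check_inputs(self, spectra, wavelengths_nm=None) -> np.ndarray:
        x = np.atleast_2d(np.asarray(spectra, dtype=float))
        if x.shape[1] != self.config.n_inputs:
            raise WavelengthMismatchError(
                f"model expects {self.config.n_inputs} wavelengths, "
                f"got {x.shape[1]}")
        if wavelengths_nm is not None and not np.array_equal(
                np.asarray(wavelengths_nm, float), self.wavelength_grid):
            raise WavelengthMismatchError(
                f"model grid {self.wavelength_grid.tolist()} != "
                f"input grid {np.asarray(wavelengths_nm).tolist()}")
        sums = x.sum(axis=1)
        if np.max(np.abs(sums - 1.0)) > _INPUT_SUM_ATOL:
            raise ValidationError(
                "prediction inputs must be sum-to-one normalized")
        return x

    def predict(self, spectra, wavelengths_nm=None) -> np.ndarray:
        """sO2 estimates (clamped to [0, 1]) for normalized spectra."""
        x = self._check_inputs(spectra, wavelengths_nm)
        out, _ = self.model.forward(self._standardize(x), train=False)
        return np.clip(out, 0.0, 1.0)

    def predict_image(self, stack_values: np.ndarray,
                      wavelengths_nm, mask) -> np.ndarray:
        """Per-pixel sO2 map inside a mask (NaN elsewhere).

        Pixel spectra are normalized before prediction; all-zero pixels
        stay NaN."""
        mask = np.asarray(mask, dtype=bool)
        raw = stack_values[:, mask].T
        sums = raw.sum(axis=1)
        ok = sums > 0
        out = np.full(mask.shape, np.nan)
        if ok.any():
            est = self.predict(raw[ok] / sums[ok, None], wavelengths_nm)
            flat = np.flatnonzero(mask)
            vals = np.full(flat.size, np.nan)
            vals[ok] = est
            out.ravel()[flat] = vals
        return out

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, group) -> None:
        group.create_dataset("wavelengths_nm", data=self.wavelength_grid)
        cfg = self.config
        group.attrs["config"] = repr(cfg)
        for k in ("n_inputs", "hidden_layers", "dropout_rate", "leaky_slope",
                  "epochs", "batches_per_epoch", "batch_size", "lr_initial",
                  "lr_decay_base", "lr_update_every", "seed", "momentum",
                  "adam_lr_factor"):
            group.attrs[k] = getattr(cfg, k)
        group.attrs["loss"] = cfg.loss
        group.attrs["optimizer"] = cfg.optimizer
        group.attrs["split"] = list(cfg.split)
        if self.feature_mean is not None:
            group.create_dataset("feature_mean", data=self.feature_mean)
            group.create_dataset("feature_std", data=self.feature_std)
        for i, (w, b) in enumerate(zip(self.model.weights, self.model.biases)):
            group.create_dataset(f"w{i}", data=w)
            group.create_dataset(f"b{i}", data=b)
        for key, vals in self.training_log.items():
            group.create_dataset(f"log_{key}", data=np.asarray(vals))

    @classmethod
    def from_hdf5(cls, group) -> "TrainedLSDModel":
        cfg = LSDConfig(
            n_inputs=int(group.attrs["n_inputs"]),
            hidden_layers=int(group.attrs["hidden_layers"]),
            dropout_rate=float(group.attrs["dropout_rate"]),
            leaky_slope=float(group.attrs["leaky_slope"]),
            epochs=int(group.attrs["epochs"]),
            batches_per_epoch=int(group.attrs["batches_per_epoch"]),
            batch_size=int(group.attrs["batch_size"]),
            lr_initial=float(group.attrs["lr_initial"]),
            lr_decay_base=float(group.attrs["lr_decay_base"]),
            lr_update_every=int(group.attrs["lr_update_every"]),
            split=tuple(float(x) for x in group.attrs["split"]),
            seed=int(group.attrs["seed"]),
            loss=str(group.attrs["loss"]),
            optimizer=str(group.attrs.get("optimizer", "adam")),
            momentum=float(group.attrs["momentum"]),
            adam_lr_factor=float(group.attrs.get("adam_lr_factor", 0.1)),
        )
        model = LSDModel(cfg)
        i = 0
        while f"w{i}" in group:
            model.weights[i] = group[f"w{i}"][()]
            model.biases[i] = group[f"b{i}"][()]
            i += 1
        log = {k[4:]: list(group[k][()]) for k in group if k.startswith("log_")}
        fmean = group["feature_mean"][()] if "feature_mean" in group else None
        fstd = group["feature_std"][()] if "feature_std" in group else None
        return cls(model, group["wavelengths_nm"][()], cfg, log, fmean, fstd)


def split_dataset(dataset: SpectraDataset, cfg: LSDConfig
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded shuffled train/validation/test row indices."""
    n = len(dataset)
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(n)
    n_train = int(round(cfg.split[0] * n))
    n_val = int(round(cfg.split[1] * n))
    return (order[:n_train], order[n_train:n_train + n_val],
            order[n_train + n_val:])


def _loss_and_grad(pred, target, kind: str):
    err = pred - target
    if kind == "mse":
        return float(np.mean(err ** 2)), 2.0 * err / err.size
    return float(np.mean(np.abs(err))), np.sign(err) / err.size


def train(dataset: SpectraDataset, cfg: LSDConfig) -> TrainedLSDModel:
    """Train the regressor on a labeled spectra dataset.

    Batches are drawn with replacement from the training split (the
    schedule's sample demand normally exceeds the split size).  The test
    split is never touched here; validation loss is logged per epoch.
    """
    if np.max(np.abs(dataset.spectra.sum(axis=1) - 1.0)) > NORMALIZATION_ATOL:
        raise DataError("training spectra must be normalized")
    idx_train, idx_val, _ = split_dataset(dataset, cfg)
    if idx_train.size < 1:
        raise DataError("training split is empty")

    feature_mean = dataset.spectra[idx_train].mean(axis=0)
    feature_std = dataset.spectra[idx_train].std(axis=0)
    feature_std = np.where(feature_std < 1e-12, 1.0, feature_std)
    x_all = (dataset.spectra - feature_mean) / feature_std
    y_all = dataset.labels
    x_train, y_train = x_all[idx_train], y_all[idx_train]
    x_val, y_val = x_all[idx_val], y_all[idx_val]

    model = LSDModel(cfg)
    rng = np.random.default_rng(cfg.seed + 2)
    # first-moment (also SGD velocity) and second-moment accumulators
    m_w = [np.zeros_like(w) for w in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_w = [np.zeros_like(w) for w in model.weights]
    v_b = [np.zeros_like(b) for b in model.biases]
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8
    step = 0
    log: Dict[str, List[float]] = {"train_loss": [], "val_loss": [], "lr": []}

    for epoch in range(cfg.epochs):
        lr = lr_schedule(epoch, cfg)
        batch_losses = []
        for _ in range(cfg.batches_per_epoch):
            step += 1
            take = rng.integers(0, idx_train.size, cfg.batch_size)
            xb, yb = x_train[take], y_train[take]
            pred, cache = model.forward(xb, train=True, rng=rng)
            loss, dout = _loss_and_grad(pred, yb, cfg.loss)
            batch_losses.append(loss)
            grads = model.backward(dout, cache)
            for i, (gw, gb) in enumerate(grads):
                if cfg.optimizer == "adam":
                    lr_eff = lr * cfg.adam_lr_factor
                    m_w[i] = beta1 * m_w[i] + (1 - beta1) * gw
                    m_b[i] = beta1 * m_b[i] + (1 - beta1) * gb
                    v_w[i] = beta2 * v_w[i] + (1 - beta2) * gw ** 2
                    v_b[i] = beta2 * v_b[i] + (1 - beta2) * gb ** 2
                    c1, c2 = 1 - beta1 ** step, 1 - beta2 ** step
                    model.weights[i] -= lr_eff * (m_w[i] / c1) / (
                        np.sqrt(v_w[i] / c2) + adam_eps)
                    model.biases[i] -= lr_eff * (m_b[i] / c1) / (
                        np.sqrt(v_b[i] / c2) + adam_eps)
                else:
                    m_w[i] = cfg.momentum * m_w[i] - lr * gw
                    m_b[i] = cfg.momentum * m_b[i] - lr * gb
                    model.weights[i] += m_w[i]
                    model.biases[i] += m_b[i]
        log["train_loss"].append(float(np.mean(batch_losses)))
        if x_val.size:
            vpred, _ = model.forward(x_val, train=False)
            vloss, _ = _loss_and_grad(vpred, y_val, cfg.loss)
        else:
            vloss = float("nan")
        log["val_loss"].append(vloss)
        log["lr"].append(lr)

    return TrainedLSDModel(model, np.asarray(dataset.wavelengths_nm, float),
                           cfg, log, feature_mean, feature_std)
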