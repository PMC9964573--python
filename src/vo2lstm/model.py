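"""Sequence dataset construction and the windowed LSTM V̇O2 regressor.

The training unit is a window of ``window_length`` consecutive steps
(50 by default): inputs are the selected per-step features normalized to
[0, 1] with bounds fitted on the training split, the target is the V̇O2
attached to the window's last step, left in physical units (mL/min/kg).
Windows advance with stride 1 inside each contiguous recording and never
span recordings.

Two train/test split modes are provided: the shuffled 80/20 split (the
field-study protocol — note that adjacent windows share 49 of 50 steps, so
shuffling leaks heavily between train and test) and a blocked split that
holds out a contiguous tail per subject with a guard gap so no test window
overlaps any training window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .features import FEATURE_NAMES, StepRecord
from .lstm import LSTMRegressor, lstm_parameter_count
from .synthetic import ValidationError

__all__ = [
    "ModelConfig",
    "SequenceSample",
    "SequenceDataset",
    "ScalerBounds",
    "TrainedModel",
    "build_sequences",
    "fit_scaler",
    "apply_scaler",
    "split_dataset",
    "count_parameters",
    "train",
    "predict",
    "save_model",
    "load_model",
]

#: motion-only feature subset (no heart rate)
MOTION_FEATURES = ("mean_speed", "speed_p2p", "duration", "vertical_disp_p2p")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the sequence regressor.

    Defaults follow the field study: 50-step windows, one LSTM layer with
    150 hidden units, Adam with learning rate 0.005, 8000 epochs, shuffled
    80/20 split.  8000 epochs is sized for field datasets; a few hundred
    suffice for the synthetic benchmark and for tests.
    """

    window_length: int = 50
    hidden_units: int = 150
    lstm_layers: int = 1
    features: tuple[str, ...] = MOTION_FEATURES
    learning_rate: float = 0.005
    epochs: int = 8000
    batch_size: int = 64
    optimizer: str = "adam"
    split_ratio: float = 0.8
    split_mode: str = "shuffled"  # or "blocked"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_length < 1:
            raise ValidationError("window_length must be >= 1")
        if not self.features or not set(self.features) <= set(FEATURE_NAMES):
            raise ValidationError(
                f"features must be a non-empty subset of {FEATURE_NAMES}"
            )
        if not 0.0 < self.split_ratio < 1.0:
            raise ValidationError("split_ratio must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValidationError("only the adam optimizer is supported")
        if self.split_mode not in ("shuffled", "blocked"):
            raise ValidationError("split_mode must be 'shuffled' or 'blocked'")
        if self.epochs < 0 or self.hidden_units < 1 or self.lstm_layers < 1:
            raise ValidationError("invalid epochs / hidden_units / lstm_layers")


@dataclass(frozen=True)
class SequenceSample:
    """One normalized window of L steps x F features plus its scalar target."""

    inputs: np.ndarray  # (L, F)
    target: float  # mL/min/kg, unnormalized
    subject_id: int
    end_step_index: int


@dataclass
class SequenceDataset:
    """Windowed samples stored as arrays for efficient training."""

    inputs: np.ndarray  # (N, L, F) float32
    targets: np.ndarray  # (N,) float64
    subject_ids: np.ndarray  # (N,) int
    end_step_indices: np.ndarray  # (N,) int
    feature_names: tuple[str, ...]
    normalized: bool = False

    def __len__(self) -> int:
        return self.inputs.shape[0]

    def __getitem__(self, i: int) -> SequenceSample:
        return SequenceSample(
            inputs=self.inputs[i],
            target=float(self.targets[i]),
            subject_id=int(self.subject_ids[i]),
            end_step_index=int(self.end_step_indices[i]),
        )

    def subset(self, idx: np.ndarray) -> "SequenceDataset":
        return SequenceDataset(
            inputs=self.inputs[idx],
            targets=self.targets[idx],
            subject_ids=self.subject_ids[idx],
            end_step_indices=self.end_step_indices[idx],
            feature_names=self.feature_names,
            normalized=self.normalized,
        )


@dataclass(frozen=True)
class ScalerBounds:
    """Per-feature min/max fitted on the training split."""

    mins: np.ndarray
    maxs: np.ndarray
    feature_names: tuple[str, ...]

    def transform(self, values: np.ndarray, clip: bool = True) -> np.ndarray:
        out = (values - self.mins) / (self.maxs - self.mins)
        return np.clip(out, 0.0, 1.0) if clip else out

    def inverse_transform(self, values: np.ndarray) -> np.ndarray:
        return values * (self.maxs - self.mins) + self.mins


@dataclass
class TrainedModel:
    network: LSTMRegressor
    scaler: ScalerBounds
    config: ModelConfig
    parameter_count: int
    loss_history: list[float] = field(default_factory=list)


def build_sequences(
    steps: Sequence[StepRecord] | Sequence[Sequence[StepRecord]],
    config: ModelConfig,
) -> SequenceDataset:
    """Stride-1 windows of ``window_length`` steps per contiguous recording.

    ``steps`` is one recording or a list of recordings; each recording of N
    steps yields ``N − L + 1`` samples and windows never span recordings.
    The target is the V̇O2 attached to the window's last step.  Raises when
    any recording is shorter than the window or targets are missing.
    """
    if steps and isinstance(steps[0], StepRecord):
        recordings: Sequence[Sequence[StepRecord]] = [steps]  # type: ignore[list-item]
    else:
        recordings = steps  # type: ignore[assignment]
    L = config.window_length
    xs, ys, sids, ends = [], [], [], []
    for sid, rec in enumerate(recordings):
        n = len(rec)
        if n < L:
            raise ValidationError(
                f"recording {sid} has {n} steps; at least window_length={L} required"
            )
        feat = np.array(
            [[s.feature(f) for f in config.features] for s in rec], dtype=np.float64
        )
        targets = [s.vo2_target for s in rec]
        if any(t is None for t in targets[L - 1 :]):
            raise ValidationError(f"recording {sid}: V̇O2 targets missing")
        for j in range(n - L + 1):
            xs.append(feat[j : j + L])
            ys.append(targets[j + L - 1])
            sids.append(sid)
            ends.append(rec[j + L - 1].index)
    if not xs:
        raise ValidationError("no recordings given")
    return SequenceDataset(
        inputs=np.asarray(xs, dtype=np.float32),
        targets=np.asarray(ys, dtype=np.float64),
        subject_ids=np.asarray(sids, dtype=np.int64),
        end_step_indices=np.asarray(ends, dtype=np.int64),
        feature_names=tuple(config.features),
    )


def fit_scaler(dataset: SequenceDataset) -> ScalerBounds:
    """Per-feature min/max over all window entries of the training set."""
    flat = dataset.inputs.reshape(-1, dataset.inputs.shape[-1]).astype(np.float64)
    mins = flat.min(axis=0)
    maxs = flat.max(axis=0)
    degenerate = maxs <= mins
    if degenerate.any():
        bad = [n for n, d in zip(dataset.feature_names, degenerate) if d]
        raise ValidationError(f"constant feature(s) cannot be scaled: {bad}")
    return ScalerBounds(mins=mins, maxs=maxs, feature_names=dataset.feature_names)


def apply_scaler(dataset: SequenceDataset, bounds: ScalerBounds) -> SequenceDataset:
    """Map features to [0, 1] with the fitted bounds; out-of-range clipped."""
    if bounds.feature_names != dataset.feature_names:
        raise ValidationError(
            f"scaler features {bounds.feature_names} do not match dataset "
            f"features {dataset.feature_names}"
        )
    scaled = bounds.transform(dataset.inputs.astype(np.float64)).astype(np.float32)
    out = SequenceDataset(
        inputs=scaled,
        targets=dataset.targets.copy(),
        subject_ids=dataset.subject_ids.copy(),
        end_step_indices=dataset.end_step_indices.copy(),
        feature_names=dataset.feature_names,
        normalized=True,
    )
    return out


def split_dataset(
    dataset: SequenceDataset, config: ModelConfig
) -> tuple[SequenceDataset, SequenceDataset]:
    """Train/test split.

    ``shuffled``: uniform random permutation under the config seed, first
    ``split_ratio`` fraction to train (the field-study protocol).
    ``blocked``: per subject, the leading fraction of windows (by end-step
    order) goes to train and the tail to test, with a guard gap of
    ``window_length − 1`` windows dropped in between so no test window
    shares a step with any training window.
    """
    n = len(dataset)
    if n < 10:
        raise ValidationError("need at least 10 samples to split")
    if config.split_mode == "shuffled":
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(n)
        k = int(n * config.split_ratio)
        return dataset.subset(order[:k]), dataset.subset(order[k:])
    train_idx: list[int] = []
    test_idx: list[int] = []
    for sid in np.unique(dataset.subject_ids):
        idx = np.where(dataset.subject_ids == sid)[0]
        idx = idx[np.argsort(dataset.end_step_indices[idx])]
        k = int(idx.size * config.split_ratio)
        train_idx.extend(idx[:k])
        test_idx.extend(idx[k + config.window_length - 1 :])
    return dataset.subset(np.asarray(train_idx)), dataset.subset(np.asarray(test_idx))


def count_parameters(config: ModelConfig) -> int:
    """Closed-form trainable parameter count for the configured network."""
    return lstm_parameter_count(
        len(config.features), config.hidden_units, config.lstm_layers
    )


def train(train_set: SequenceDataset, config: ModelConfig) -> TrainedModel:
    """Fit the scaler on the training windows and train the LSTM.

    Accepts raw (unnormalized) windows; normalization bounds are fitted
    here, on the training split only, and stored with the model.  With
    ``epochs=0`` the initialized network is returned untrained.
    """
    if len(train_set) == 0:
        raise ValidationError("training set is empty")
    if train_set.feature_names != tuple(config.features):
        raise ValidationError("training set features do not match the config")
    if train_set.normalized:
        raise ValidationError("train() expects raw windows; scaling happens internally")
    bounds = fit_scaler(train_set)
    scaled = apply_scaler(train_set, bounds)
    net = LSTMRegressor(
        n_features=len(config.features),
        hidden_units=config.hidden_units,
        n_layers=config.lstm_layers,
        seed=config.seed,
    )
    history: list[float] = []
    if config.epochs > 0:
        history = net.fit(
            scaled.inputs,
            scaled.targets,
            epochs=config.epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=config.seed + 1,
        )
    model = TrainedModel(
        network=net,
        scaler=bounds,
        config=config,
        parameter_count=net.num_parameters(),
        loss_history=history,
    )
    assert model.parameter_count == count_parameters(config)
    return model


def predict(model: TrainedModel, dataset: SequenceDataset) -> np.ndarray:
    """Predicted V̇O2 (mL/min/kg), one scalar per sample."""
    if dataset.feature_names != model.scaler.feature_names:
        raise ValidationError(
            f"dataset features {dataset.feature_names} do not match the model's "
            f"{model.scaler.feature_names}"
        )
    if len(dataset) == 0:
        return np.empty(0)
    inputs = dataset.inputs
    if not dataset.normalized:
        inputs = model.scaler.transform(inputs.astype(np.float64)).astype(np.float32)
    return model.network.predict(inputs)


# ---------------------------------------------------------------------------
# persistence: weights as .npz-free plain text is wasteful; use NumPy's
# portable .npy-in-zip via savez plus a JSON sidecar for everything else
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    arrays = {name.replace(".", "_"): t for name, t in model.network.parameter_tensors()}
    np.savez(out / "weights.npz", **arrays)
    sidecar = {
        "config": {**model.config.__dict__, "features": list(model.config.features)},
        "scaler": {
            "mins": model.scaler.mins.tolist(),
            "maxs": model.scaler.maxs.tolist(),
            "feature_names": list(model.scaler.feature_names),
        },
        "parameter_count": model.parameter_count,
        "loss_history": model.loss_history,
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(model_dir: str | Path) -> TrainedModel:
    d = Path(model_dir)
    sidecar = json.loads((d / "model.json").read_text())
    cfg_dict = dict(sidecar["config"])
    cfg_dict["features"] = tuple(cfg_dict["features"])
    config = ModelConfig(**cfg_dict)
    net = LSTMRegressor(
        n_features=len(config.features),
        hidden_units=config.hidden_units,
        n_layers=config.lstm_layers,
        seed=config.seed,
    )
    with np.load(d / "weights.npz") as data:
        for name, tensor in net.parameter_tensors():
            arr = data[name.replace(".", "_")]
            if tensor.shape == ():
                if name == "dense.b":
                    net.b_out = np.asarray(arr, dtype=net.dtype).reshape(())
            else:
                tensor[...] = arr
    scaler = ScalerBounds(
        mins=np.asarray(sidecar["scaler"]["mins"]),
        maxs=np.asarray(sidecar["scaler"]["maxs"]),
        feature_names=tuple(sidecar["scaler"]["feature_names"]),
    )
    return TrainedModel(
        network=net,
        scaler=scaler,
        config=config,
        parameter_count=int(sidecar["parameter_count"]),
        loss_history=list(sidecar["loss_history"]),
    )
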