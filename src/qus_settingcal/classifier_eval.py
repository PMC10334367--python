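"""Patch classifiers and the repeated mismatch-experiment harness.

Training recipe: per-patch z-score normalization, cross-entropy loss with
uniform class weights, horizontal-flip augmentation (lateral-axis reversal)
with probability 0.5, Adam, batch size 128, and repeated trials with fresh
random frame selections reported as mean +- std of patch-wise accuracy (%)
and ROC-AUC.

Two trainable architectures are provided:

``small_cnn``
    A compact two-stage convolutional network on raw RF patches
    (conv 8@9x5 stride 4x2 -> ReLU -> conv 16@3x3 stride 2x2 -> ReLU ->
    global average pool -> linear softmax), implemented in numpy with an
    exact backward pass so training is deterministic given a seed.
``spectral_logreg``
    Logistic regression on per-patch averaged log power spectra — the
    classical spectral-QUS reference classifier.

``resnet50_mod`` and ``densenet201_mod`` are kept as architecture
specification presets (stage tables and a dry-run shape checker) for
full-scale runs on GPU frameworks; they are not trainable here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.fft import rfft
from scipy.signal.windows import hann
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .calibration import (
    SettingCalibrator,
    build_setting_calibrator,
    extract_calibrated_patches,
)
from .patching import Patch, PatchGridSpec, extract_patches
from .rf_io import FrameSet
from .simulator import SimConfig, make_calibration_stacks, preset_pair, simulate_dataset

__all__ = [
    "TrainConfig",
    "EvalResult",
    "ExperimentConfig",
    "zscore_normalize",
    "normalize_patch_array",
    "patches_to_arrays",
    "train_classifier",
    "fine_tune",
    "evaluate",
    "repeat_experiment",
    "run_mismatch_experiment",
    "architecture_summary",
    "dry_run_shapes",
    "EXPERIMENT_CONDITIONS",
]


# ---------------------------------------------------------------------------
# normalization


def zscore_normalize(patch: Patch | np.ndarray) -> Patch | np.ndarray:
    """Per-patch standardization to zero mean, unit standard deviation.

    A constant patch (zero std) maps to all zeros, with a warning; the
    transform is invariant to any affine rescaling of the input.
    """
    arr = patch.samples if isinstance(patch, Patch) else np.asarray(patch)
    x = arr.astype(float)
    std = x.std()
    if std == 0.0:
        warnings.warn("constant patch: z-score undefined, returning zeros")
        out = np.zeros_like(x)
    else:
        out = (x - x.mean()) / std
    if isinstance(patch, Patch):
        return Patch(out, patch.depth_line, patch.lateral_line,
                     patch.frame_index, patch.label)
    return out


def normalize_patch_array(X: np.ndarray, mode: str = "patch") -> np.ndarray:
    """Vectorized z-scoring of a stack of patches ``[n, h, w]``.

    ``mode="patch"`` standardizes each patch by its own statistics (the
    default; removes any global amplitude scale per patch);
    ``mode="dataset"`` uses one mean/std over the whole stack.
    """
    X = np.asarray(X)
    if X.dtype not in (np.float32, np.float64):
        X = X.astype(np.float32)
    if mode == "patch":
        mu = X.mean(axis=(1, 2), keepdims=True, dtype=np.float64)
        sd = X.std(axis=(1, 2), keepdims=True, dtype=np.float64)
        sd = np.where(sd == 0, 1.0, sd)
        return ((X - mu) / sd).astype(X.dtype)
    if mode == "dataset":
        sd = X.std(dtype=np.float64) or 1.0
        return ((X - X.mean(dtype=np.float64)) / sd).astype(X.dtype)
    raise ValueError("mode must be 'patch' or 'dataset'")


def patches_to_arrays(
    patches: Sequence[Patch],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack a patch list into (samples, labels, depth_lines)."""
    X = np.stack([p.samples for p in patches]).astype(np.float32)
    y = np.array([p.label for p in patches])
    d = np.array([p.depth_line for p in patches])
    return X, y, d


# ---------------------------------------------------------------------------
# configs and results


@dataclass
class TrainConfig:
    """Classifier training hyperparameters."""

    architecture: str = "small_cnn"
    learning_rate: float = 1e-3
    epochs: int = 4
    batch_size: int = 128
    flip_prob: float = 0.5
    seed: int = 0
    normalization: str = "patch"  # or "dataset"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")


@dataclass
class EvalResult:
    """Mean +- std of patch-wise accuracy (%) and ROC-AUC over repeats."""

    accuracy_mean: float
    accuracy_std: float
    auc_mean: float
    auc_std: float
    per_repeat: list[dict] = field(default_factory=list)

    @classmethod
    def from_runs(cls, runs: list[dict]) -> "EvalResult":
        acc = np.array([r["accuracy"] for r in runs], dtype=float)
        auc = np.array([r["auc"] for r in runs if r["auc"] is not None], dtype=float)
        return cls(
            accuracy_mean=float(acc.mean()),
            accuracy_std=float(acc.std(ddof=0)),
            auc_mean=float(auc.mean()) if auc.size else float("nan"),
            auc_std=float(auc.std(ddof=0)) if auc.size else float("nan"),
            per_repeat=list(runs),
        )


# ---------------------------------------------------------------------------
# architecture presets (specification tables)

_RESNET50_STAGES = [
    ("conv1", "7x7, 64, stride 2"),
    ("maxpool", "3x3 max pool, stride 2"),
    ("conv2", "[1x1,64; 3x3,64; 1x1,256] x3"),
    ("conv3", "[1x1,128; 3x3,128; 1x1,512] x4"),
    ("conv4", "[1x1,256; 3x3,256; 1x1,1024] x6"),
    ("conv5", "[1x1,512; 3x3,512; 1x1,2048] x3"),
    ("head", "global average pool, 2-d fc, softmax"),
]

_DENSENET201_TABLE = [
    ("conv1", (102, 15), "7x7, 64, stride 2"),
    ("maxpool", (51, 8), "3x3 max pool, stride 2"),
    ("dense1", (51, 8), "[1x1; 3x3] x6"),
    ("tr1", (25, 4), "1x1, 256 and 2x2 avgpool, stride 2"),
    ("dense2", (25, 4), "[1x1; 3x3] x12"),
    ("tr2", (12, 2), "1x1, 512 and 2x2 avgpool, stride 2"),
    ("dense3", (12, 2), "[1x1; 3x3] x48"),
    ("tr3", (6, 1), "1x1, 1024 and 2x2 avgpool, stride 2"),
    ("dense4", (6, 1), "[1x1; 3x3] x32"),
    ("head", (1, 1), "global average pool, 2-d fc, softmax"),
]


def architecture_summary(architecture: str) -> list[tuple]:
    """Stage table of a preset architecture."""
    if architecture == "resnet50_mod":
        return list(_RESNET50_STAGES)
    if architecture == "densenet201_mod":
        return [(n, k) for n, _, k in _DENSENET201_TABLE]
    raise ValueError(f"no stage table for {architecture!r}")


def dry_run_shapes(
    architecture: str, input_shape: tuple[int, int] = (200, 26), n_classes: int = 2
) -> list[tuple[str, tuple[int, ...]]]:
    """Per-stage output shapes for a preset on a given patch size.

    For ``resnet50_mod`` the shapes are propagated by standard stride-2
    'same'-padded downsampling (ceil division) through conv1, the max pool
    and the four bottleneck stages; ``densenet201_mod`` reports its declared
    table (valid only for 200x26 inputs).  The final entry is the softmax
    output ``(n_classes,)``.
    """
    if architecture == "resnet50_mod":
        h, w = input_shape
        shapes: list[tuple[str, tuple[int, ...]]] = []
        for name, _ in _RESNET50_STAGES[:-1]:
            if name != "conv2":  # conv2 keeps the max pool's resolution
                h, w = math.ceil(h / 2), math.ceil(w / 2)
            shapes.append((name, (h, w)))
        shapes.append(("output", (n_classes,)))
        return shapes
    if architecture == "densenet201_mod":
        if tuple(input_shape) != (200, 26):
            raise ValueError("densenet201_mod table is declared for 200x26 inputs")
        return [(n, s) for n, s, _ in _DENSENET201_TABLE[:-1]] + [
            ("output", (n_classes,))
        ]
    raise ValueError(f"no dry-run table for {architecture!r}")


# ---------------------------------------------------------------------------
# small_cnn: numpy convolutional network

_C1, _K1, _S1 = 8, (9, 5), (4, 2)
_C2, _K2, _S2 = 16, (3, 3), (2, 2)


def _conv_windows(x: np.ndarray, k: tuple[int, int], s: tuple[int, int]) -> np.ndarray:
    """Strided sliding windows of [n, h, w, c] -> [n, oh, ow, kh, kw, c]."""
    if x.ndim == 3:
        x = x[..., None]
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=(1, 2))
    # sliding_window_view yields [n, oh_full, ow_full, c, kh, kw]
    win = win[:, :: s[0], :: s[1]]
    return np.moveaxis(win, 3, 5)  # -> [n, oh, ow, kh, kw, c]


class SmallCNN:
    """Two-conv-stage softmax classifier on z-scored RF patches."""

    def __init__(self, input_shape: tuple[int, int], n_classes: int, rng: np.random.Generator):
        h, w = input_shape
        self.input_shape = (h, w)
        self.n_classes = n_classes
        o1 = ((h - _K1[0]) // _S1[0] + 1, (w - _K1[1]) // _S1[1] + 1)
        o2 = ((o1[0] - _K2[0]) // _S2[0] + 1, (o1[1] - _K2[1]) // _S2[1] + 1)
        self.o1, self.o2 = o1, o2
        f1 = _K1[0] * _K1[1]
        f2 = _K2[0] * _K2[1] * _C1
        self.params = {
            "W1": rng.normal(0, math.sqrt(2.0 / f1), (f1, _C1)).astype(np.float32),
            "b1": np.zeros(_C1, dtype=np.float32),
            "W2": rng.normal(0, math.sqrt(2.0 / f2), (f2, _C2)).astype(np.float32),
            "b2": np.zeros(_C2, dtype=np.float32),
            "W3": rng.normal(0, math.sqrt(2.0 / _C2), (_C2, n_classes)).astype(np.float32),
            "b3": np.zeros(n_classes, dtype=np.float32),
        }

    # forward ---------------------------------------------------------------

    def _forward(self, X: np.ndarray, keep: bool = False):
        n = X.shape[0]
        col1 = _conv_windows(X, _K1, _S1).reshape(n, -1, _K1[0] * _K1[1])
        z1 = col1 @ self.params["W1"] + self.params["b1"]
        a1 = np.maximum(z1, 0.0)  # [n, o1h*o1w, C1]
        a1_img = a1.reshape(n, *self.o1, _C1)
        col2 = _conv_windows(a1_img, _K2, _S2).reshape(
            n, -1, _K2[0] * _K2[1] * _C1
        )
        z2 = col2 @ self.params["W2"] + self.params["b2"]
        a2 = np.maximum(z2, 0.0)  # [n, o2h*o2w, C2]
        pooled = a2.mean(axis=1)
        logits = pooled @ self.params["W3"] + self.params["b3"]
        if keep:
            self._cache = (X, col1, z1, col2, z2, a2, pooled)
        return logits

    def predict_proba(self, X: np.ndarray, batch: int = 512) -> np.ndarray:
        out = []
        for i in range(0, X.shape[0], batch):
            logits = self._forward(X[i : i + batch])
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    # backward --------------------------------------------------------------

    def _backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        X, col1, z1, col2, z2, a2, pooled = self._cache
        n = X.shape[0]
        g: dict[str, np.ndarray] = {}
        g["W3"] = pooled.T @ dlogits
        g["b3"] = dlogits.sum(axis=0)
        dpooled = dlogits @ self.params["W3"].T
        da2 = np.repeat(dpooled[:, None, :], a2.shape[1], axis=1) / a2.shape[1]
        dz2 = da2 * (z2 > 0)
        g["W2"] = np.tensordot(col2, dz2, axes=([0, 1], [0, 1]))
        g["b2"] = dz2.sum(axis=(0, 1))
        dcol2 = dz2 @ self.params["W2"].T  # [n, o2 positions, k2 elems]
        dcol2 = dcol2.reshape(n, *self.o2, _K2[0], _K2[1], _C1)
        da1 = np.zeros((n, *self.o1, _C1), dtype=dcol2.dtype)
        for di in range(_K2[0]):
            for dj in range(_K2[1]):
                hi = di + _S2[0] * self.o2[0]
                wj = dj + _S2[1] * self.o2[1]
                da1[:, di:hi:_S2[0], dj:wj:_S2[1], :] += dcol2[:, :, :, di, dj, :]
        dz1 = da1.reshape(n, -1, _C1) * (z1 > 0)
        g["W1"] = np.tensordot(col1, dz1, axes=([0, 1], [0, 1]))
        g["b1"] = dz1.sum(axis=(0, 1))
        return g


@dataclass
class SmallCNNModel:
    """Trained small_cnn with its class ordering and loss history."""

    net: SmallCNN
    classes_: np.ndarray
    cfg: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(normalize_patch_array(X, self.cfg.normalization))

    def copy(self) -> "SmallCNNModel":
        import copy as _copy

        return _copy.deepcopy(self)


@dataclass
class SpectralLogRegModel:
    """Logistic regression on per-patch averaged log power spectra."""

    pipeline: object
    classes_: np.ndarray
    cfg: TrainConfig
    sampling_rate_hz: float = 40e6
    loss_history: list[float] = field(default_factory=list)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict_proba(
            _spectral_features(normalize_patch_array(X, self.cfg.normalization))
        )

    def copy(self) -> "SpectralLogRegModel":
        import copy as _copy

        return _copy.deepcopy(self)


_SPEC_NFFT = 256


def _spectral_features(X: np.ndarray) -> np.ndarray:
    """Per-patch log power spectrum, averaged over lateral lines."""
    w = hann(X.shape[1], sym=False)
    f = rfft(X * w[None, :, None], _SPEC_NFFT, axis=1)
    p = (np.abs(f) ** 2).mean(axis=2)
    return np.log10(p + 1e-20)


def _adam_step(params, grads, state, lr, t, b1=0.9, b2=0.999, eps=1e-8):
    for k in params:
        m, v = state[k]
        m = b1 * m + (1 - b1) * grads[k]
        v = b2 * v + (1 - b2) * grads[k] ** 2
        state[k] = (m, v)
        mhat = m / (1 - b1**t)
        vhat = v / (1 - b2**t)
        params[k] -= lr * mhat / (np.sqrt(vhat) + eps)


def _train_small_cnn_epochs(
    model: SmallCNNModel,
    Xn: np.ndarray,
    y_idx: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
    state=None,
    t0: int = 0,
) -> None:
    net = model.net
    n = Xn.shape[0]
    if state is None:
        state = {k: (np.zeros_like(v), np.zeros_like(v)) for k, v in net.params.items()}
    t = t0
    onehot = np.eye(net.n_classes, dtype=np.float32)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            Xb = Xn[idx]
            if cfg.flip_prob > 0:
                fm = rng.random(len(idx)) < cfg.flip_prob
                if fm.any():
                    Xb = Xb.copy()
                    Xb[fm] = Xb[fm, :, ::-1]
            logits = net._forward(Xb, keep=True)
            logits = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
            yb = onehot[y_idx[idx]]
            loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
            model.loss_history.append(float(loss))
            grads = net._backward((probs - yb) / len(idx))
            t += 1
            _adam_step(net.params, grads, state, cfg.learning_rate, t)


def train_classifier(
    X: np.ndarray | Sequence[Patch],
    y: np.ndarray | None = None,
    cfg: TrainConfig = TrainConfig(),
):
    """Train a patch classifier with the standard recipe.

    ``X`` may be a patch stack ``[n, h, w]`` with labels ``y``, or a list
    of labelled :class:`Patch` objects.  At least two classes must be
    present.  Returns a model exposing ``predict_proba`` and ``classes_``.
    """
    if y is None:
        X, y, _ = patches_to_arrays(X)  # type: ignore[arg-type]
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    y_idx = np.searchsorted(classes, y)
    Xn = normalize_patch_array(X, cfg.normalization)
    rng = np.random.default_rng(cfg.seed)

    if cfg.architecture == "small_cnn":
        net = SmallCNN(X.shape[1:], classes.size, rng)
        model = SmallCNNModel(net=net, classes_=classes, cfg=cfg)
        _train_small_cnn_epochs(model, Xn, y_idx, cfg, rng)
        return model
    if cfg.architecture == "spectral_logreg":
        pipe = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=1000, random_state=cfg.seed),
        )
        pipe.fit(_spectral_features(Xn), y)
        return SpectralLogRegModel(pipeline=pipe, classes_=classes, cfg=cfg)
    if cfg.architecture in ("resnet50_mod", "densenet201_mod"):
        raise NotImplementedError(
            f"{cfg.architecture} is an architecture specification preset "
            "(see architecture_summary/dry_run_shapes); train 'small_cnn' or "
            "'spectral_logreg' here"
        )
    raise ValueError(f"unknown architecture {cfg.architecture!r}")


def fine_tune(model, X: np.ndarray, y: np.ndarray, cfg: TrainConfig):
    """Warm-start continuation of training on a (small) labelled set.

    All weights are updated from the given model at ``cfg.learning_rate``;
    ``cfg.epochs == 0`` returns an unchanged copy.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    out = model.copy()
    out.cfg = replace(out.cfg, **{
        "learning_rate": cfg.learning_rate,
        "epochs": cfg.epochs,
        "flip_prob": cfg.flip_prob,
        "seed": cfg.seed,
    })
    if cfg.epochs == 0:
        return out
    if isinstance(out, SmallCNNModel):
        y_idx = np.searchsorted(out.classes_, y)
        Xn = normalize_patch_array(X, out.cfg.normalization)
        rng = np.random.default_rng(cfg.seed)
        _train_small_cnn_epochs(out, Xn, y_idx, out.cfg, rng)
        return out
    if isinstance(out, SpectralLogRegModel):
        lr = out.pipeline.named_steps["logisticregression"]
        lr.set_params(warm_start=True, max_iter=max(10, 50 * cfg.epochs))
        out.pipeline.fit(
            _spectral_features(normalize_patch_array(X, out.cfg.normalization)), y
        )
        return out
    raise TypeError(f"cannot fine-tune {type(model).__name__}")


def evaluate(model, X: np.ndarray, y: np.ndarray) -> dict:
    """Patch-wise accuracy (%) and ROC-AUC from class-1 scores.

    With a single class present the AUC is undefined and reported as None.
    """
    y = np.asarray(y)
    probs = model.predict_proba(np.asarray(X))
    pred = model.classes_[np.argmax(probs, axis=1)]
    acc = float(np.mean(pred == y) * 100.0)
    if np.unique(y).size < 2:
        return {"accuracy": acc, "auc": None}
    auc = float(roc_auc_score(y == model.classes_[1], probs[:, 1]))
    return {"accuracy": acc, "auc": auc}


# ---------------------------------------------------------------------------
# repeated mismatch experiments

EXPERIMENT_CONDITIONS = (
    "benchmark",
    "no_calibration",
    "train_time_50",
    "train_time_100",
    "test_time",
)


@dataclass
class ExperimentConfig:
    """One repeated setting-mismatch classification experiment.

    Frames are simulated per class at the training setting (training set)
    and at the testing setting (test set); a benchmark test set is drawn at
    the training setting.  A single stable-acquisition calibrator is built
    per experiment and shared by all repeats, as in a fixed calibration
    acquisition.
    """

    mismatch: str = "frequency"
    conditions: tuple[str, ...] = (
        "benchmark",
        "no_calibration",
        "train_time_100",
        "test_time",
    )
    n_train_frames_per_class: int = 100
    n_test_frames_per_class: int = 30
    n_cal_repeats: int = 10
    train_fraction: float = 0.5  # for train_time_50
    max_train_patches: int | None = 6000
    sim: SimConfig = field(default_factory=SimConfig)
    grid: PatchGridSpec = field(default_factory=PatchGridSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    seed: int = 0


def _frames_to_patch_arrays(fs: FrameSet, grid: PatchGridSpec):
    patches: list[Patch] = []
    for frame, label in fs:
        frame_patches = extract_patches(frame, grid)
        for p in frame_patches:
            p.label = label
        patches.extend(frame_patches)
    return patches_to_arrays(patches)


def _calibrated_patch_arrays(
    fs: FrameSet, cal: SettingCalibrator, direction: str, grid: PatchGridSpec
):
    patches: list[Patch] = []
    for frame, label in fs:
        frame_patches = extract_calibrated_patches(frame, cal, direction, grid)
        for p in frame_patches:
            p.label = label
        patches.extend(frame_patches)
    return patches_to_arrays(patches)


def _subsample(X, y, n_max, rng):
    if n_max is None or X.shape[0] <= n_max:
        return X, y
    idx = rng.choice(X.shape[0], size=n_max, replace=False)
    return X[idx], y[idx]


def run_mismatch_experiment(
    cfg: ExperimentConfig, n_repeats: int = 10
) -> dict[str, EvalResult]:
    """Run all requested conditions over repeated random data draws.

    Models are shared between conditions that define the same training: the
    uncalibrated model serves the benchmark, no-calibration and test-time
    conditions; train-time conditions retrain on calibrated training data.
    """
    setting_train, setting_test = preset_pair(cfg.mismatch)
    ss = np.random.SeedSequence(cfg.seed)
    cal_seed = int(ss.generate_state(1)[0] % 2**31)
    stack_tr, stack_te = make_calibration_stacks(
        cfg.sim, setting_train, setting_test, cfg.n_cal_repeats, cal_seed
    )
    cal = build_setting_calibrator(stack_tr, stack_te, cfg.grid)

    runs: dict[str, list[dict]] = {c: [] for c in cfg.conditions}
    for child in ss.spawn(n_repeats):
        seeds = [int(s % 2**31) for s in child.generate_state(6)]
        train_fs = simulate_dataset(
            cfg.sim, setting_train, cfg.n_train_frames_per_class, seeds[0]
        )
        test_fs = simulate_dataset(
            cfg.sim, setting_test, cfg.n_test_frames_per_class, seeds[1]
        )
        rng = np.random.default_rng(seeds[2])
        tc = replace(cfg.train, seed=seeds[3])

        X_tr, y_tr, _ = _frames_to_patch_arrays(train_fs, cfg.grid)
        X_te, y_te, _ = _frames_to_patch_arrays(test_fs, cfg.grid)

        model_uncal = None
        need_uncal = {"benchmark", "no_calibration", "test_time"} & set(cfg.conditions)
        if need_uncal:
            Xs, ys = _subsample(X_tr, y_tr, cfg.max_train_patches, rng)
            model_uncal = train_classifier(Xs, ys, tc)

        for cond in cfg.conditions:
            if cond == "benchmark":
                bench_fs = simulate_dataset(
                    cfg.sim, setting_train, cfg.n_test_frames_per_class, seeds[4]
                )
                Xb, yb, _ = _frames_to_patch_arrays(bench_fs, cfg.grid)
                runs[cond].append(evaluate(model_uncal, Xb, yb))
            elif cond == "no_calibration":
                runs[cond].append(evaluate(model_uncal, X_te, y_te))
            elif cond == "test_time":
                Xc, yc, _ = _calibrated_patch_arrays(
                    test_fs, cal, "test_time", cfg.grid
                )
                runs[cond].append(evaluate(model_uncal, Xc, yc))
            elif cond in ("train_time_100", "train_time_50"):
                Xc, yc, _ = _calibrated_patch_arrays(
                    train_fs, cal, "train_time", cfg.grid
                )
                if cond == "train_time_50":
                    # mix: calibrated patches for a random half of the
                    # frames, original patches for the rest (frame-level
                    # selection keeps a frame's patches consistent)
                    n_frames = len(train_fs)
                    ppf = cfg.grid.n_axial_lines * cfg.grid.n_lateral_lines
                    sel = np.zeros(n_frames, dtype=bool)
                    chosen = np.random.default_rng(seeds[5]).choice(
                        n_frames,
                        size=int(round(cfg.train_fraction * n_frames)),
                        replace=False,
                    )
                    sel[chosen] = True
                    mask = np.repeat(sel, ppf)
                    X_mix = np.where(mask[:, None, None], Xc, X_tr)
                    Xs, ys = _subsample(X_mix, y_tr, cfg.max_train_patches, rng)
                else:
                    Xs, ys = _subsample(Xc, yc, cfg.max_train_patches, rng)
                model_cal = train_classifier(Xs, ys, replace(tc, seed=seeds[3] + 1))
                runs[cond].append(evaluate(model_cal, X_te, y_te))
            else:
                raise ValueError(f"unknown condition {cond!r}")
    return {c: EvalResult.from_runs(r) for c, r in runs.items()}


def repeat_experiment(cfg: ExperimentConfig, n_repeats: int = 10) -> EvalResult:
    """Mean +- std over repeats for a single-condition experiment config."""
    if len(cfg.conditions) != 1:
        raise ValueError("repeat_experiment expects exactly one condition")
    return run_mismatch_experiment(cfg, n_repeats)[cfg.conditions[0]]
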