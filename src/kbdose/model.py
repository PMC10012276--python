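"""The fully-convolutional dose predictor and its training loop.

The network is a residual-bottleneck encoder with a 7x7/64-filter stem,
max pooling, and four stages of "deeper bottleneck" blocks (default counts
3, 4, 23, 5).  Spatial resolution is reduced to 1/8 of the input — stride 2
in the stem, the pool and the second stage, with the last two stages held
at stride 1 using dilation 2 and 4 (the standard dense-prediction
adaptation) — and restored to full resolution by a chain of
fractionally-strided deconvolutions.  Input is a 2-channel (CT, structure
map) stack in ANAT mode or 3-channel (CT, structure map, distance-to-PTV)
in COM mode; output is one dose channel per slice.

Training is slice-wise regression of dose normalized by the boost
prescription, with Adam; everything is seeded and runs deterministically
on a fixed platform.  A ``width_multiplier`` scales all channel widths for
desk-scale experiments without changing the topology.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import KFold

from . import nn
from .features import DEFAULT_CT_WINDOW, DEFAULT_DPTV_CAP_MM, assemble_inputs
from .grids import DoseMap
from .phantom import BOOST_PRESCRIPTION_GY, PhantomCase

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "ResNetFCN",
    "build_network",
    "DosePredictor",
    "train",
    "predict_volume",
    "kfold_split",
    "save_checkpoint",
    "load_checkpoint",
]

_STEM_WIDTH = 64
_STAGE_MID = (64, 128, 256, 512)
_EXPANSION = 4
_STAGE_STRIDE = (1, 2, 1, 1)
_STAGE_DILATION = (1, 1, 2, 4)
_OUTPUT_STRIDE = 8


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture knobs; defaults mirror the full-scale network."""

    in_channels: int = 3
    stem_filters: int = _STEM_WIDTH
    block_counts: tuple[int, int, int, int] = (3, 4, 23, 5)
    width_multiplier: float = 1.0
    out_channels: int = 1
    output_stride: int = _OUTPUT_STRIDE

    def validate(self) -> None:
        if self.in_channels not in (2, 3):
            raise ValueError(f"in_channels must be 2 (ANAT) or 3 (COM), got {self.in_channels}")
        if len(self.block_counts) != 4 or any(b < 1 for b in self.block_counts):
            raise ValueError(f"block_counts must be four positive counts, got {self.block_counts}")
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.output_stride != _OUTPUT_STRIDE:
            raise ValueError("only output stride 8 is supported")

    @staticmethod
    def tiny(in_channels: int = 3) -> "NetworkConfig":
        """Desk-scale preset: same topology, one block per stage, 1/4 width."""
        return NetworkConfig(in_channels=in_channels, block_counts=(1, 1, 1, 1), width_multiplier=0.25)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    loss: str = "mse"
    optimizer: str = "adam"
    lr: float = 1e-4
    lr_schedule: str = "cosine"
    batch_size: int = 8
    seed: int = 0
    device: str = "cpu"

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer != "adam":
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError(f"unknown lr schedule {self.lr_schedule!r}")
        if self.device != "cpu":
            raise ValueError("only CPU execution is supported")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def _width(base: int, mult: float) -> int:
    return max(2, int(round(base * mult)))


class ResNetFCN(nn.Module):
    """Encoder-decoder dose regressor; see the module docstring."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        wm = config.width_multiplier
        w = lambda c: _width(c, wm)

        stem_w = w(config.stem_filters)
        self.stem = nn.Sequential(
            nn.Conv2d(config.in_channels, stem_w, 7, stride=2, pad=3, bias=False, rng=rng),
            nn.BatchNorm2d(stem_w),
            nn.ReLU(),
            nn.MaxPool2d(3, stride=2, pad=1),
        )
        cin = stem_w
        self.stages = []
        for count, mid, stride, dil in zip(config.block_counts, _STAGE_MID, _STAGE_STRIDE, _STAGE_DILATION):
            cout = w(mid * _EXPANSION)
            blocks = [nn.Bottleneck(cin, w(mid), cout, stride=stride, dilation=dil, rng=rng)]
            for _ in range(count - 1):
                blocks.append(nn.Bottleneck(cout, w(mid), cout, stride=1, dilation=dil, rng=rng))
            self.stages.append(nn.Sequential(*blocks))
            cin = cout

        # decoder widths are floored: the deconvolution chain is cheap and
        # throttling it starves the upsampled dose pattern of channels
        d1, d2, d3 = max(32, w(64)), max(24, w(32)), max(16, w(16))
        self.head = nn.Sequential(
            nn.Conv2d(cin, d1, 1, bias=False, rng=rng), nn.BatchNorm2d(d1), nn.ReLU()
        )
        # each x2 deconvolution is followed by a 3x3 refinement convolution
        # to suppress the blocking artifacts of bare strided upsampling
        self.decoder = nn.Sequential(
            nn.ConvTranspose2x2(d1, d2, rng=rng), nn.BatchNorm2d(d2), nn.ReLU(),
            nn.Conv2d(d2, d2, 3, pad=1, bias=False, rng=rng), nn.BatchNorm2d(d2), nn.ReLU(),
            nn.ConvTranspose2x2(d2, d3, rng=rng), nn.BatchNorm2d(d3), nn.ReLU(),
            nn.Conv2d(d3, d3, 3, pad=1, bias=False, rng=rng), nn.BatchNorm2d(d3), nn.ReLU(),
            nn.ConvTranspose2x2(d3, d3, rng=rng), nn.BatchNorm2d(d3), nn.ReLU(),
            nn.Conv2d(d3, d3, 3, pad=1, bias=False, rng=rng), nn.BatchNorm2d(d3), nn.ReLU(),
            nn.Conv2d(d3, config.out_channels, 1, rng=rng),
        )
        self.encoder_shape_: tuple[int, int] | None = None
        self._pad = None

    def forward(self, x, train=True):
        n, c, h, w0 = x.shape
        if c != self.config.in_channels:
            raise ValueError(f"expected {self.config.in_channels} input channels, got {c}")
        s = self.config.output_stride
        ph = (-h) % s
        pw = (-w0) % s
        self._pad = (h, w0, ph, pw)
        if ph or pw:  # pad-and-crop contract for sizes not divisible by the stride
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        y = self.stem.forward(x, train)
        for stage in self.stages:
            y = stage.forward(y, train)
        self.encoder_shape_ = y.shape[2:]
        y = self.head.forward(y, train)
        y = self.decoder.forward(y, train)
        return y[:, :, :h, :w0]

    def backward(self, dy):
        h, w0, ph, pw = self._pad
        if ph or pw:
            dy = np.pad(dy, ((0, 0), (0, 0), (0, ph), (0, pw)))
        d = self.decoder.backward(dy)
        d = self.head.backward(d)
        for stage in reversed(self.stages):
            d = stage.backward(d)
        d = self.stem.backward(d)
        return d[:, :, :h, :w0]


def build_network(config: NetworkConfig, seed: int = 0) -> ResNetFCN:
    return ResNetFCN(config, seed=seed)


class DosePredictor(BaseEstimator):
    """Slice-wise dose-map regressor with a scikit-learn estimator surface.

    Parameters
    ----------
    mode : {"COM", "ANAT"}
        COM stacks (CT, structure map, distance-to-PTV); ANAT drops the
        distance channel.
    width_multiplier, block_counts, stem_filters
        Architecture scaling; see :class:`NetworkConfig`.
    epochs, loss, lr, batch_size, seed
        Training knobs; see :class:`TrainConfig`.
    dose_norm_gy : float
        Dose normalization denominator (default: the boost prescription,
        69.96 Gy, so normalized dose stays near [0, 1]).
    dptv_cap_mm, ct_window
        Input normalization constants, shared with feature assembly.

    Fitted attributes end in an underscore: ``network_``, ``history_``
    (per-epoch mean training loss), ``n_epochs_``, ``network_config_``.
    """

    def __init__(
        self,
        mode: str = "COM",
        width_multiplier: float = 0.25,
        block_counts: tuple[int, int, int, int] = (1, 1, 1, 1),
        stem_filters: int = _STEM_WIDTH,
        epochs: int = 100,
        loss: str = "mse",
        lr: float = 1e-4,
        lr_schedule: str = "cosine",
        batch_size: int = 8,
        seed: int = 0,
        dose_norm_gy: float = BOOST_PRESCRIPTION_GY,
        dptv_cap_mm: float = DEFAULT_DPTV_CAP_MM,
        ct_window: tuple[float, float] = DEFAULT_CT_WINDOW,
    ):
        self.mode = mode
        self.width_multiplier = width_multiplier
        self.block_counts = block_counts
        self.stem_filters = stem_filters
        self.epochs = epochs
        self.loss = loss
        self.lr = lr
        self.lr_schedule = lr_schedule
        self.batch_size = batch_size
        self.seed = seed
        self.dose_norm_gy = dose_norm_gy
        self.dptv_cap_mm = dptv_cap_mm
        self.ct_window = ct_window

    # -- internal -----------------------------------------------------------
    def _network_config(self) -> NetworkConfig:
        mode = self.mode.upper()
        if mode not in ("COM", "ANAT"):
            raise ValueError(f"unknown mode {self.mode!r}")
        return NetworkConfig(
            in_channels=3 if mode == "COM" else 2,
            stem_filters=self.stem_filters,
            block_counts=tuple(self.block_counts),
            width_multiplier=self.width_multiplier,
        )

    def _stack_case(self, case: PhantomCase) -> np.ndarray:
        stack = assemble_inputs(
            case, self.mode, ct_window=self.ct_window, dptv_cap_mm=self.dptv_cap_mm
        )
        return stack.channels

    # -- estimator surface --------------------------------------------------
    def fit(self, cases: list[PhantomCase], y=None) -> "DosePredictor":
        """Train on a list of phantom cases with ground-truth dose."""
        if not cases:
            raise ValueError("need at least one training case")
        tconf = TrainConfig(
            epochs=self.epochs, loss=self.loss, lr=self.lr,
            lr_schedule=self.lr_schedule, batch_size=self.batch_size, seed=self.seed,
        )
        tconf.validate()
        nconf = self._network_config()
        shape0 = cases[0].shape
        xs, ys = [], []
        for case in cases:
            if case.dose_gt is None:
                raise ValueError("training case lacks ground-truth dose")
            if case.shape != shape0:
                raise ValueError("training cases must share grid geometry")
            xs.append(self._stack_case(case))
            dose = np.moveaxis(case.dose_gt.values, 2, 0)[:, None, :, :]
            ys.append((dose / self.dose_norm_gy).astype(np.float32))
        x = np.concatenate(xs, axis=0)
        t = np.concatenate(ys, axis=0)
        if x.shape[1] != nconf.in_channels:
            raise ValueError(
                f"mode {self.mode} expects {nconf.in_channels} channels, stack has {x.shape[1]}"
            )

        net = build_network(nconf, seed=tconf.seed)
        opt = nn.Adam(net.parameters(), lr=tconf.lr)
        loss_fn = nn.mse_loss if tconf.loss == "mse" else nn.mae_loss
        rng = np.random.default_rng(tconf.seed + 1)
        n = x.shape[0]
        history = []
        for epoch in range(tconf.epochs):
            if tconf.lr_schedule == "cosine":
                opt.lr = tconf.lr * 0.5 * (1.0 + np.cos(np.pi * epoch / tconf.epochs))
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, tconf.batch_size):
                idx = order[start : start + tconf.batch_size]
                opt.zero_grad()
                pred = net.forward(x[idx], train=True)
                loss, dy = loss_fn(pred, t[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch + 1} "
                        f"(lr={tconf.lr}, batch={idx.tolist()})"
                    )
                net.backward(dy.astype(np.float32))
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))

        self.network_ = net
        self.network_config_ = nconf
        self.train_config_ = tconf
        self.history_ = history
        self.n_epochs_ = tconf.epochs
        return self

    def predict(self, case: PhantomCase) -> DoseMap:
        """Slice-wise inference stacked back into a 3D dose map in Gy."""
        if not hasattr(self, "network_"):
            raise RuntimeError("predictor is not fitted")
        x = self._stack_case(case)
        if x.shape[1] != self.network_config_.in_channels:
            raise ValueError("input channel count does not match the trained network")
        outs = []
        for start in range(0, x.shape[0], self.batch_size):
            outs.append(self.network_.forward(x[start : start + self.batch_size], train=False))
        pred = np.concatenate(outs, axis=0)[:, 0]  # (nz, H, W)
        dose = np.moveaxis(pred, 0, 2) * self.dose_norm_gy
        return DoseMap(np.clip(dose.astype(np.float64), 0.0, None), case.spacing)


def train(
    cases: list[PhantomCase],
    mode: str,
    network_config: NetworkConfig | None = None,
    train_config: TrainConfig | None = None,
) -> DosePredictor:
    """Functional wrapper over :class:`DosePredictor.fit`."""
    nconf = network_config if network_config is not None else NetworkConfig.tiny()
    tconf = train_config if train_config is not None else TrainConfig()
    expected = 3 if mode.upper() == "COM" else 2
    if nconf.in_channels != expected:
        raise ValueError(
            f"mode {mode} requires {expected} input channels, config has {nconf.in_channels}"
        )
    est = DosePredictor(
        mode=mode,
        width_multiplier=nconf.width_multiplier,
        block_counts=nconf.block_counts,
        stem_filters=nconf.stem_filters,
        epochs=tconf.epochs,
        loss=tconf.loss,
        lr=tconf.lr,
        lr_schedule=tconf.lr_schedule,
        batch_size=tconf.batch_size,
        seed=tconf.seed,
    )
    return est.fit(cases)


def predict_volume(model: DosePredictor, case: PhantomCase) -> DoseMap:
    """Functional wrapper over :class:`DosePredictor.predict`."""
    return model.predict(case)


def kfold_split(cohort, k: int, seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled k-fold partition of a cohort (or its size) into train/test
    index pairs; folds are disjoint, cover everything and differ in size by
    at most one.  Deterministic for a given seed."""
    n = cohort if isinstance(cohort, int) else len(cohort)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"cannot split {n} cases into {k} folds")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in kf.split(np.arange(n))]


def save_checkpoint(est: DosePredictor, path: str | Path) -> None:
    """Weights + embedded JSON config in one npz archive."""
    if not hasattr(est, "network_"):
        raise RuntimeError("cannot checkpoint an unfitted predictor")
    path = Path(path)
    params = est.network_.parameters()
    arrays = {f"p{i}": p.value for i, p in enumerate(params)}
    bn_state = {}
    i = 0
    for layer in _iter_modules(est.network_):
        if isinstance(layer, nn.BatchNorm2d):
            arrays[f"bn{i}_mean"] = layer.running_mean
            arrays[f"bn{i}_var"] = layer.running_var
            i += 1
    meta = {
        "params": est.get_params(),
        "network_config": asdict(est.network_config_),
        "history": est.history_,
    }
    np.savez_compressed(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> DosePredictor:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        est = DosePredictor(**{k: tuple(v) if isinstance(v, list) else v for k, v in meta["params"].items()})
        nconf = meta["network_config"]
        nconf["block_counts"] = tuple(nconf["block_counts"])
        est.network_config_ = NetworkConfig(**nconf)
        est.network_ = build_network(est.network_config_, seed=0)
        for i, p in enumerate(est.network_.parameters()):
            p.value = data[f"p{i}"].copy()
            p.grad = np.zeros_like(p.value)
        i = 0
        for layer in _iter_modules(est.network_):
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = data[f"bn{i}_mean"].copy()
                layer.running_var = data[f"bn{i}_var"].copy()
                i += 1
        est.history_ = list(meta["history"])
        est.n_epochs_ = len(est.history_)
        est.train_config_ = TrainConfig(epochs=est.n_epochs_, loss=est.loss, lr=est.lr,
                                        batch_size=est.batch_size, seed=est.seed)
    return est


def _iter_modules(module: nn.Module):
    """Depth-first iteration over submodules, deterministic order."""
    yield module
    for v in module.__dict__.values():
        if isinstance(v, nn.Module):
            yield from _iter_modules(v)
        elif isinstance(v, (list, tuple)):
            for item in v:
                if isinstance(item, nn.Module):
                    yield from _iter_modules(item)
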