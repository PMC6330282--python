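"""CNN pseudo-CT synthesis from UTE echoes.

A U-net-style encoder-decoder regresses Hounsfield units from 16-slice
windows of three channels (echo 1, echo 2, R2* map).  Downsampling uses
stride-2 convolutions instead of max pooling; every convolution is followed
by batch normalization, ReLU and dropout, with the dropout fraction rising
linearly from 0.1 to 0.3 through the encoder and falling back through the
decoder.  Whole-volume inference slides the 16-slice window over every start
position and averages all predictions covering each voxel.

Training/evaluation is subject-level k-fold cross-validated so no network
predicts a subject it was trained on.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .folds import FoldSplit, kfold_split  # noqa: F401  (re-exported surface)
from .mrac import MuMap, compute_r2star, hu_to_mu
from .nn import (Adam, BatchNorm3d, Conv3d, ConvTranspose3d, Dropout, ReLU,
                 mse_loss)
from .phantom import TE1_MS, TE2_MS, PhantomCase, substream
from .volume import Volume

__all__ = [
    "NetworkSpec", "TrainConfig", "WindowSet", "UNet3D",
    "build_network", "count_parameters", "extract_windows",
    "train", "predict_volume", "kfold_split", "FoldSplit", "deepute_crossval",
]

WINDOW_DEPTH = 16
HU_SCALE = 1000.0  # targets are regressed as HU / HU_SCALE


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the pseudo-CT network."""

    depth: int = 4               # number of resolution levels (downsamplings)
    base_channels: int = 16
    in_channels: int = 3
    out_channels: int = 1
    window_depth: int = WINDOW_DEPTH
    dropout_min: float = 0.1
    dropout_max: float = 0.3

    def __post_init__(self):
        if self.window_depth != WINDOW_DEPTH:
            raise ValueError(f"window depth is fixed at {WINDOW_DEPTH} slices")
        if (self.in_channels, self.out_channels) != (3, 1):
            raise ValueError("network takes 3 channels in, 1 out")
        if not 1 <= self.depth <= 4:
            raise ValueError("depth must be 1..4 (16 slices allow 4 halvings)")
        sched = self.dropout_schedule
        if np.any(np.diff(sched) < 0) or sched[0] < 0.1 - 1e-9 or sched[-1] > 0.3 + 1e-9:
            raise ValueError("encoder dropout must rise within [0.1, 0.3]")

    @property
    def dropout_schedule(self) -> np.ndarray:
        """Per-encoder-level dropout fractions, linear dropout_min..dropout_max."""
        if self.depth == 1:
            return np.array([self.dropout_min])
        return np.linspace(self.dropout_min, self.dropout_max, self.depth)

    @classmethod
    def micro(cls, **overrides) -> "NetworkSpec":
        kw = dict(depth=2, base_channels=4)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 2
    epochs: int = 100
    seed: int = 0
    window_subsample: int = 1   # train on every n-th window start
    lr_decay: float = 1.0       # multiplier applied at each decay epoch
    lr_decay_at: Tuple[float, ...] = ()  # fractions of total epochs
    init_output_bias: bool = True  # start the output head at the target mean
    ema_decay: float = 0.0      # Polyak averaging of weights; 0 disables

    def __post_init__(self):
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.window_subsample < 1:
            raise ValueError("window_subsample must be >= 1")

    @classmethod
    def micro(cls, epochs: int = 10, seed: int = 0, **overrides) -> "TrainConfig":
        """Scaled-down training defaults for the 32^3 battery."""
        kw = dict(learning_rate=3e-3, batch_size=2, epochs=epochs, seed=seed,
                  window_subsample=2, lr_decay=0.3, lr_decay_at=(0.6, 0.85),
                  ema_decay=0.99)
        kw.update(overrides)
        return cls(**kw)


class _Seq:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class UNet3D:
    """Encoder-decoder with stride-2 downsampling and skip connections."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        init = substream(seed, "he-init")
        self._drop_rng = substream(seed, "dropout")
        d = spec.depth
        ch = [spec.base_channels * 2 ** i for i in range(d + 1)]
        p_enc = spec.dropout_schedule

        def block(cin, cout, p, k=3, stride=1):
            return [Conv3d(cin, cout, k=k, stride=stride, rng=init),
                    BatchNorm3d(cout), ReLU(), Dropout(p, self._drop_rng)]

        self.enc, self.down, self.up, self.dec = [], [], [], []
        cin = spec.in_channels
        for i in range(d):
            self.enc.append(_Seq(block(cin, ch[i], p_enc[i]) +
                                 block(ch[i], ch[i], p_enc[i])))
            self.down.append(_Seq(block(ch[i], ch[i], p_enc[i], stride=2)))
            cin = ch[i]
        self.bottleneck = _Seq(block(ch[d - 1], ch[d], p_enc[-1]) +
                               block(ch[d], ch[d], p_enc[-1]))
        for i in reversed(range(d)):
            above = ch[i + 1]
            self.up.append(ConvTranspose3d(above, ch[i], rng=init))
            self.dec.append(_Seq(block(2 * ch[i], ch[i], p_enc[i]) +
                                 block(ch[i], ch[i], p_enc[i])))
        # self.up/dec[j] handles level i = d-1-j
        self.final = Conv3d(ch[0], spec.out_channels, k=1, rng=init)
        self._ch = ch

    def layers(self):
        out = []
        for seq in self.enc + self.down + [self.bottleneck] + self.dec:
            out.extend(seq.layers)
        out.extend(self.up)
        out.append(self.final)
        return out

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        d = self.spec.depth
        if any(s % 2 ** d for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be divisible by {2 ** d}")
        self._skips = []
        h = x.astype(np.float32)
        for i in range(d):
            h = self.enc[i].forward(h, train)
            self._skips.append(h)
            h = self.down[i].forward(h, train)
        h = self.bottleneck.forward(h, train)
        for j, i in enumerate(reversed(range(d))):
            h = self.up[j].forward(h, train)
            h = np.concatenate([self._skips[i], h], axis=1)
            h = self.dec[j].forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dy: np.ndarray) -> None:
        d = self.spec.depth
        dskips = [None] * d
        dh = self.final.backward(dy)
        for j, i in zip(reversed(range(d)), range(d)):
            dh = self.dec[j].backward(dh)
            c = self._ch[i]
            dskips[i] = dh[:, :c]
            dh = self.up[j].backward(dh[:, c:])
        dh = self.bottleneck.backward(dh)
        for i in reversed(range(d)):
            dh = self.down[i].backward(dh)
            dh = dh + dskips[i]
            dh = self.enc[i].backward(dh)


def build_network(spec: NetworkSpec, seed: int = 0) -> UNet3D:
    """He-initialized network under the given seed."""
    return UNet3D(spec, seed=seed)


def count_parameters(model: UNet3D) -> int:
    return sum(int(np.prod(p.shape)) for l in model.layers()
               for p in l.params.values())


@dataclass
class WindowSet:
    """Dense 16-slice training windows of one case, with normalization."""

    windows: np.ndarray          # (n, 3, 16, H, W) float32, normalized
    targets: np.ndarray          # (n, 1, 16, H, W) float32, HU / HU_SCALE
    norm: Dict[str, Tuple[float, float]]  # channel -> (center, scale)

    def __len__(self):
        return self.windows.shape[0]

    def __getitem__(self, i):
        return self.windows[i], self.targets[i]


def _robust_norm(x: np.ndarray) -> Tuple[float, float]:
    """Median/IQR center and scale; scale falls back to std then 1."""
    med = float(np.median(x))
    q25, q75 = np.percentile(x, [25, 75])
    scale = float(q75 - q25)
    if scale <= 0:
        scale = float(x.std()) or 1.0
    return med, scale


def case_channels(case: PhantomCase) -> np.ndarray:
    """(3, D, H, W) stack of echo1, echo2 and the derived R2* map."""
    r2 = compute_r2star(case.ute1, case.ute2, TE1_MS, TE2_MS).volume.data
    return np.stack([case.ute1.data, case.ute2.data, r2])


def extract_windows(case: PhantomCase, channels: np.ndarray | None = None) -> WindowSet:
    """One (window, target) pair per valid 16-slice start index, stride 1.

    A volume with S slices yields S - 15 windows; window at start s covers
    source slices s..s+15.  Channels are normalized per case by median/IQR;
    targets are the matching CT slices in HU / 1000.
    """
    if channels is None:
        channels = case_channels(case)
    n_slices = channels.shape[1]
    if n_slices < WINDOW_DEPTH:
        raise ValueError(f"need >= {WINDOW_DEPTH} slices, got {n_slices}")
    norm = {}
    normed = np.empty_like(channels, dtype=np.float32)
    for c, name in enumerate(("echo1", "echo2", "r2star")):
        center, scale = _robust_norm(channels[c])
        norm[name] = (center, scale)
        normed[c] = (channels[c] - center) / scale
    ct = (case.ct_hu.data / HU_SCALE).astype(np.float32)

    n_win = n_slices - WINDOW_DEPTH + 1
    wins = np.empty((n_win, 3, WINDOW_DEPTH) + channels.shape[2:], dtype=np.float32)
    tgts = np.empty((n_win, 1, WINDOW_DEPTH) + channels.shape[2:], dtype=np.float32)
    for s in range(n_win):
        wins[s] = normed[:, s:s + WINDOW_DEPTH]
        tgts[s, 0] = ct[s:s + WINDOW_DEPTH]
    return WindowSet(wins, tgts, norm)


def train(model: UNet3D, cases: Sequence[PhantomCase], cfg: TrainConfig) -> List[float]:
    """Minimize MSE over shuffled windows; returns per-epoch mean loss.

    Loss is reported on the internal HU/1000 scale.  A NaN loss aborts with
    diagnostics rather than silently diverging.
    """
    if not cases:
        raise ValueError("need at least one training case")
    sets = [extract_windows(c) for c in cases]
    x = np.concatenate([s.windows[::cfg.window_subsample] for s in sets])
    y = np.concatenate([s.targets[::cfg.window_subsample] for s in sets])
    rng = substream(cfg.seed, "shuffle")
    if cfg.init_output_bias and not model.final.params["b"].any():
        # regression head starts at the mean target, so early epochs refine
        # structure instead of chasing the global offset
        model.final.params["b"][:] = y.mean()
    opt = Adam(model.layers(), lr=cfg.learning_rate)
    history: List[float] = []
    layers = model.layers()
    ema = None
    if cfg.ema_decay > 0:
        # Polyak averaging: evaluate with a running average of the weights,
        # which damps the optimizer noise of short schedules
        ema = [{k: p.copy() for k, p in l.params.items()} for l in layers]
    n = x.shape[0]
    decay_epochs = {int(f * cfg.epochs) for f in cfg.lr_decay_at}
    for epoch in range(cfg.epochs):
        if epoch in decay_epochs:
            opt.lr *= cfg.lr_decay
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            pred = model.forward(x[idx], train=True)
            loss, grad = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, step {start // cfg.batch_size}; "
                    f"lr={cfg.learning_rate}, batch={cfg.batch_size}")
            model.backward(grad)
            opt.step()
            if ema is not None:
                d = cfg.ema_decay
                for l, e in zip(layers, ema):
                    for k, p in l.params.items():
                        e[k] += (1.0 - d) * (p - e[k])
            total += loss * len(idx)
            seen += len(idx)
        history.append(total / seen)
    if ema is not None:
        for l, e in zip(layers, ema):
            for k in l.params:
                l.params[k][...] = e[k]
    return history


def predict_volume(model: UNet3D, case: PhantomCase,
                   batch_size: int = 4) -> Volume:
    """Overlap-averaged whole-volume pseudo-CT in HU.

    Every 16-slice window is predicted (evaluation mode: batch-norm running
    statistics, no dropout) and each voxel's value is the mean over all
    windows covering it.
    """
    ws = extract_windows(case)
    n = len(ws)
    d = case.ct_hu.shape[0]
    acc = np.zeros(case.ct_hu.shape, dtype=np.float64)
    cover = np.zeros(d, dtype=np.int64)
    for start in range(0, n, batch_size):
        batch = ws.windows[start:start + batch_size]
        pred = model.forward(batch, train=False)
        for j in range(batch.shape[0]):
            s = start + j
            acc[s:s + WINDOW_DEPTH] += pred[j, 0].astype(np.float64)
            cover[s:s + WINDOW_DEPTH] += 1
    out = acc / cover[:, None, None] * HU_SCALE
    return case.ct_hu.like(out, units="HU")


def coverage_counts(n_slices: int) -> np.ndarray:
    """How many sliding windows cover each slice (closed form)."""
    s = np.arange(n_slices)
    n_win = n_slices - WINDOW_DEPTH + 1
    return np.minimum.reduce([s + 1, np.full(n_slices, n_win),
                              n_slices - s, np.full(n_slices, WINDOW_DEPTH)])


def deepute_crossval(cases: Sequence[PhantomCase], k: int,
                     net_spec: NetworkSpec, cfg: TrainConfig,
                     seed: int = 0):
    """k-fold train/predict: each case is predicted by a network that never
    saw its subject.  Returns (results, histories) where results maps
    (subject_id, exam_index) -> (MuMap, pseudo_ct Volume)."""
    folds = kfold_split(cases, k=k, seed=seed)
    results, histories = {}, {}
    for fold in range(k):
        train_ids = set(folds.train_subjects(fold))
        train_cases = [c for c in cases if c.subject_id in train_ids]
        model = build_network(net_spec, seed=seed + fold)
        histories[fold] = train(model, train_cases, cfg)
        for case in cases:
            if case.subject_id in train_ids:
                continue
            pct = predict_volume(model, case)
            pct_clipped = pct.like(np.clip(pct.data, -1000.0, 3000.0), units="HU")
            mu = hu_to_mu(pct_clipped)
            results[(case.subject_id, case.exam_index)] = (
                MuMap(mu.volume, provenance="DEEPUTE"), pct_clipped)
    return results, histories
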