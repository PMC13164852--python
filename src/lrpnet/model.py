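"""LRPNet: a lightweight residual PoolFormer network for electrome windows.

The input is one preprocessed 1 x 30 x 30 window matrix.  The network is

    pointwise (1x1) embedding to 16 channels
    -> one PoolFormer block (pooling token mixer + channel MLP)
    -> five ECA-gated depthwise-separable residual blocks
       (16 -> 32 -> 64 -> 96 -> 128 -> 128, all stride 1, spatial size
       preserved)
    -> global average pooling to 128 features
    -> linear map + softmax over the treatment classes.

The PoolFormer block and the ECA gates can each be toggled off, giving
the four-variant ablation grid under a single code path.
``LRPNetClassifier`` wraps the network as a scikit-learn estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn

__all__ = [
    "LRPNetConfig",
    "PoolFormerBlock",
    "ResidualBlock",
    "LRPNet",
    "LRPNetClassifier",
    "count_parameters",
]

INPUT_SIDE = 30


@dataclass
class LRPNetConfig:
    """Architecture hyperparameters (the defaults are the full model)."""

    num_classes: int = 5
    in_channels: int = 1
    input_size: int = INPUT_SIDE
    embed_channels: int = 16
    residual_channels: tuple[int, ...] = (32, 64, 96, 128, 128)
    kernel_size: int = 3
    use_poolformer: bool = True
    use_eca: bool = True
    pool_size: int = 3
    mlp_ratio: float = 4.0
    eca_kernel: int | None = None  # None = adaptive per channel count

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if len(self.residual_channels) != 5:
            raise ValueError("residual channel schedule must have length 5")
        if self.kernel_size % 2 == 0 or self.pool_size % 2 == 0:
            raise ValueError("kernel and pool sizes must be odd")
        if self.eca_kernel is not None and self.eca_kernel % 2 == 0:
            raise ValueError("eca_kernel must be odd")
        if self.mlp_ratio <= 0:
            raise ValueError("mlp_ratio must be positive")


class PoolFormerBlock(nn.Module):
    """MetaFormer block with a pooling token mixer.

    Pre-norm layout with batch normalization:
    ``x + (avgpool(BN(x)) - BN(x))`` followed by
    ``y + Conv1x1(ReLU(Conv1x1(BN(y))))`` with channel expansion
    ``mlp_ratio``.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 pool_size: int = 3, mlp_ratio: float = 4.0, dtype=np.float32):
        hidden = int(round(channels * mlp_ratio))
        self.norm1 = nn.BatchNorm2d(channels, dtype=dtype)
        self.pool = nn.AvgPoolSame(pool_size)
        self.norm2 = nn.BatchNorm2d(channels, dtype=dtype)
        self.fc1 = nn.Conv1x1(channels, hidden, rng, dtype=dtype)
        self.act = nn.ReLU()
        self.fc2 = nn.Conv1x1(hidden, channels, rng, dtype=dtype)

    def params(self):
        return (self.norm1.params() + self.norm2.params()
                + self.fc1.params() + self.fc2.params())

    def set_training(self, mode: bool) -> None:
        for m in (self.norm1, self.norm2):
            m.set_training(mode)
        self.training = mode

    def mix_tokens(self, x: np.ndarray) -> np.ndarray:
        """The token-mixing stage alone: avgpool(x) - x (no norm, no MLP)."""
        return self.pool.forward(x) - x

    def forward(self, x):
        u = self.norm1.forward(x)
        self._u = u
        y = x + (self.pool.forward(u) - u)
        v = self.norm2.forward(y)
        z = y + self.fc2.forward(self.act.forward(self.fc1.forward(v)))
        return z

    def backward(self, dz):
        dmlp = self.fc1.backward(self.act.backward(self.fc2.backward(dz)))
        dy = dz + self.norm2.backward(dmlp)
        du = self.pool.backward(dy) - dy
        return dy + self.norm1.backward(du)


class ResidualBlock(nn.Module):
    """Depthwise-separable residual block with an optional ECA gate.

    Main path: depthwise 3x3 -> pointwise 1x1 to ``c_out`` -> BN ->
    ECA (if enabled).  Shortcut: identity when channels match, else a
    1x1 projection + BN.  Output: ReLU(main + shortcut).
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 use_eca: bool = True, eca_kernel: int | None = None,
                 dtype=np.float32):
        self.dw = nn.DepthwiseConv3x3(c_in, rng, dtype=dtype)
        self.pw = nn.Conv1x1(c_in, c_out, rng, bias=False, dtype=dtype)
        self.bn = nn.BatchNorm2d(c_out, dtype=dtype)
        self.eca = (
            nn.ECAGate(c_out, rng, kernel=eca_kernel, dtype=dtype)
            if use_eca else None
        )
        if c_in == c_out:
            self.proj = None
            self.proj_bn = None
        else:
            self.proj = nn.Conv1x1(c_in, c_out, rng, bias=False, dtype=dtype)
            self.proj_bn = nn.BatchNorm2d(c_out, dtype=dtype)
        self.relu = nn.ReLU()
        self.c_in, self.c_out = c_in, c_out

    def params(self):
        out = self.dw.params() + self.pw.params() + self.bn.params()
        if self.eca is not None:
            out += self.eca.params()
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out

    def set_training(self, mode: bool) -> None:
        self.bn.set_training(mode)
        if self.proj_bn is not None:
            self.proj_bn.set_training(mode)
        self.training = mode

    def forward(self, x):
        main = self.bn.forward(self.pw.forward(self.dw.forward(x)))
        if self.eca is not None:
            main = self.eca.forward(main)
        short = x if self.proj is None else self.proj_bn.forward(self.proj.forward(x))
        return self.relu.forward(main + short)

    def backward(self, dy):
        dr = self.relu.backward(dy)
        dmain = dr
        if self.eca is not None:
            dmain = self.eca.backward(dmain)
        dx = self.dw.backward(self.pw.backward(self.bn.backward(dmain)))
        if self.proj is None:
            dx = dx + dr
        else:
            dx = dx + self.proj.backward(self.proj_bn.backward(dr))
        return dx


class LRPNet:
    """The full network: embedding, PoolFormer, residual stack, GAP head."""

    def __init__(self, config: LRPNetConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        c = config.embed_channels
        self.embed = nn.Conv1x1(config.in_channels, c, rng, bias=True, dtype=dtype)
        self.poolformer = (
            PoolFormerBlock(c, rng, config.pool_size, config.mlp_ratio, dtype=dtype)
            if config.use_poolformer else None
        )
        self.blocks: list[ResidualBlock] = []
        for c_out in config.residual_channels:
            self.blocks.append(
                ResidualBlock(c, c_out, rng, use_eca=config.use_eca,
                              eca_kernel=config.eca_kernel, dtype=dtype)
            )
            c = c_out
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(c, config.num_classes, rng, dtype=dtype)
        self.training = True

    # -- plumbing ---------------------------------------------------------
    def _modules(self):
        mods = [self.embed]
        if self.poolformer is not None:
            mods.append(self.poolformer)
        mods.extend(self.blocks)
        mods.extend([self.gap, self.head])
        return mods

    def params(self) -> list[nn.Parameter]:
        out: list[nn.Parameter] = []
        for m in self._modules():
            out.extend(m.params())
        return out

    def set_training(self, mode: bool) -> None:
        self.training = mode
        for m in self._modules():
            m.set_training(mode)

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        side = self.config.input_size
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1:] != (self.config.in_channels, side, side):
            raise ValueError(
                f"expected input (N, {self.config.in_channels}, {side}, {side}), "
                f"got {x.shape}"
            )
        return x

    # -- computation ------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Raw class logits for a batch."""
        h = self.embed.forward(self._check_input(x))
        if self.poolformer is not None:
            h = self.poolformer.forward(h)
        for block in self.blocks:
            h = block.forward(h)
        return self.head.forward(self.gap.forward(h))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.gap.backward(self.head.backward(dlogits))
        for block in reversed(self.blocks):
            d = block.backward(d)
        if self.poolformer is not None:
            d = self.poolformer.backward(d)
        return self.embed.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x))

    def forward_trace(self, x: np.ndarray) -> list[tuple[str, tuple[int, ...]]]:
        """Named feature shapes at every layer boundary (shape probe)."""
        x = self._check_input(x)
        trace = [("input", x.shape[1:])]
        h = self.embed.forward(x)
        trace.append(("pointwise_embed", h.shape[1:]))
        if self.poolformer is not None:
            h = self.poolformer.forward(h)
            trace.append(("poolformer", h.shape[1:]))
        for i, block in enumerate(self.blocks):
            h = block.forward(h)
            trace.append((f"residual_{i + 1}", h.shape[1:]))
        g = self.gap.forward(h)
        trace.append(("gap", (g.shape[1], 1, 1)))
        logits = self.head.forward(g)
        trace.append(("softmax", (logits.shape[1],)))
        return trace

    def count_parameters(self) -> int:
        return sum(p.size for p in self.params())

    def _batchnorms(self):
        out = []
        if self.poolformer is not None:
            out += [self.poolformer.norm1, self.poolformer.norm2]
        for b in self.blocks:
            out.append(b.bn)
            if b.proj_bn is not None:
                out.append(b.proj_bn)
        return out

    def refresh_batchnorm_stats(self, x: np.ndarray, batch_size: int = 64) -> None:
        """Recalibrate BN running statistics with one sweep over ``x``.

        Short training runs leave the exponential running averages far
        from the activation statistics, which breaks eval-mode
        prediction; a cumulative-average sweep fixes them exactly.
        """
        x = self._check_input(x)
        for bn in self._batchnorms():
            bn.start_stats_refresh()
        was_training = self.training
        self.set_training(True)
        for start in range(0, len(x), batch_size):
            self.forward(x[start : start + batch_size])
        for bn in self._batchnorms():
            bn.end_stats_refresh()
        self.set_training(was_training)

    def describe(self) -> str:
        """A printable layer table (shapes and parameter counts)."""
        probe = np.zeros(
            (1, self.config.in_channels, self.config.input_size,
             self.config.input_size), dtype=self.dtype,
        )
        was_training = self.training
        self.set_training(False)
        trace = self.forward_trace(probe)
        self.set_training(was_training)
        lines = [f"{'layer':<18}{'output shape':<18}"]
        for name, shape in trace:
            lines.append(f"{name:<18}{'x'.join(str(s) for s in shape):<18}")
        lines.append(f"trainable parameters: {self.count_parameters()}")
        return "\n".join(lines)


def count_parameters(config: LRPNetConfig) -> int:
    """Exact trainable-parameter count for a configuration."""
    return LRPNet(config, seed=0).count_parameters()


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite loss at epoch {epoch}")
        self.epoch = epoch


class LRPNetClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator around :class:`LRPNet`.

    ``X`` may be (N, 900) flat windows, (N, 30, 30) or (N, 1, 30, 30)
    matrices.  Training minimizes softmax cross-entropy with Adam
    (defaults: learning rate 1e-4, batch size 30, 200 epochs); the
    random state seeds initialization and batch shuffling, so identical
    seeds and data give identical fits.

    Attributes set by :meth:`fit`: ``classes_``, ``model_``,
    ``loss_curve_``, ``train_accuracy_curve_``, ``n_features_in_``.
    """

    def __init__(
        self,
        embed_channels: int = 16,
        residual_channels: tuple[int, ...] = (32, 64, 96, 128, 128),
        use_poolformer: bool = True,
        use_eca: bool = True,
        pool_size: int = 3,
        mlp_ratio: float = 4.0,
        eca_kernel: int | None = None,
        learning_rate: float = 1e-4,
        batch_size: int = 30,
        epochs: int = 200,
        random_state: int | None = None,
    ):
        self.embed_channels = embed_channels
        self.residual_channels = residual_channels
        self.use_poolformer = use_poolformer
        self.use_eca = use_eca
        self.pool_size = pool_size
        self.mlp_ratio = mlp_ratio
        self.eca_kernel = eca_kernel
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _as_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2 and X.shape[1] == INPUT_SIDE * INPUT_SIDE:
            X = X.reshape(-1, 1, INPUT_SIDE, INPUT_SIDE)
        elif X.ndim == 3 and X.shape[1:] == (INPUT_SIDE, INPUT_SIDE):
            X = X[:, None, :, :]
        elif X.ndim != 4:
            raise ValueError(f"cannot interpret input of shape {X.shape}")
        return X

    def _network_config(self, num_classes: int) -> LRPNetConfig:
        return LRPNetConfig(
            num_classes=num_classes,
            embed_channels=self.embed_channels,
            residual_channels=tuple(self.residual_channels),
            use_poolformer=self.use_poolformer,
            use_eca=self.use_eca,
            pool_size=self.pool_size,
            mlp_ratio=self.mlp_ratio,
            eca_kernel=self.eca_kernel,
        )

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y):
        Xb = self._as_batch(X)
        y = np.asarray(y)
        if len(Xb) != len(y):
            raise ValueError("X and y length mismatch")
        if len(Xb) == 0:
            raise ValueError("empty training set")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.n_features_in_ = int(np.prod(Xb.shape[1:]))

        seed = 0 if self.random_state is None else int(self.random_state)
        self.model_ = LRPNet(self._network_config(len(self.classes_)), seed=seed)
        rng = np.random.default_rng(seed + 1)
        opt = nn.Adam(self.model_.params(), lr=self.learning_rate)
        loss_fn = nn.SoftmaxCrossEntropy()

        n = len(Xb)
        self.loss_curve_ = []
        self.train_accuracy_curve_ = []
        self.model_.set_training(True)
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xb[idx], y_idx[idx]
                logits = self.model_.forward(xb)
                loss = loss_fn.forward(logits, yb)
                if not np.isfinite(loss):
                    raise TrainingDivergedError(epoch)
                opt.zero_grad()
                self.model_.backward(loss_fn.backward())
                opt.step()
                losses.append(loss)
                correct += int(np.sum(logits.argmax(axis=1) == yb))
            self.loss_curve_.append(float(np.mean(losses)))
            self.train_accuracy_curve_.append(correct / n)
        if self.epochs > 0:
            self.model_.refresh_batchnorm_stats(Xb)
        self.model_.set_training(False)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        Xb = self._as_batch(X)
        self.model_.set_training(False)
        out = []
        for start in range(0, len(Xb), 512):
            out.append(self.model_.predict_proba(Xb[start : start + 512]))
        return np.concatenate(out, axis=0)

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]
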