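"""Residual CNN for square 1-channel pseudo-images of arbitrary side length.

The network is a standard pre-classifier residual stack: a 3x3 stem, stages
of residual blocks (the first block of each later stage downsamples by
stride 2), adaptive global average pooling, and a linear head.  Global
pooling makes one set of weights valid for any input side length.

Pseudo-images have no translation invariance to exploit — each feature lives
at one fixed pixel — so by default two fixed coordinate channels (row and
column position scaled to [-1, 1]) are concatenated to the input before the
stem.  This gives the convolutional features direct access to absolute pixel
position, which is exactly the cue needed to single out individual planted
features; without it the stack could only sense position indirectly through
boundary padding.

Two registered architectures:

- ``"resnet18"``: the classic 18-layer configuration (widths 64/128/256/512,
  two blocks per stage, stride-2 stem).
- ``"small"``: a light 8-layer variant (widths 16/32/64, one block per
  stage) for desk-scale runs.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    AvgPool2d,
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool,
    Linear,
    Param,
    ReLU,
)

__all__ = ["ResidualBlock", "ResidualCNN", "ARCHITECTURES", "make_network"]


class ResidualBlock:
    """conv-bn-relu-conv-bn with an identity (or projected) skip, then relu."""

    def __init__(self, cin: int, cout: int, stride: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.conv1 = Conv2d(cin, cout, 3, stride, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm2d(cout, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm2d(cout, dtype=dtype)
        self.relu_out = ReLU()
        self.projection = stride != 1 or cin != cout
        if self.projection:
            self.conv_s = Conv2d(cin, cout, 1, stride, pad=0, rng=rng, dtype=dtype)
            self.bn_s = BatchNorm2d(cout, dtype=dtype)

    def sublayers(self) -> list[tuple[str, object]]:
        out = [("conv1", self.conv1), ("bn1", self.bn1), ("conv2", self.conv2),
               ("bn2", self.bn2)]
        if self.projection:
            out += [("conv_s", self.conv_s), ("bn_s", self.bn_s)]
        return out

    def params(self) -> list[Param]:
        return [p for _, l in self.sublayers() for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        main = self.bn2.forward(
            self.conv2.forward(
                self.relu1.forward(
                    self.bn1.forward(self.conv1.forward(x, train), train), train
                ),
                train,
            ),
            train,
        )
        skip = (
            self.bn_s.forward(self.conv_s.forward(x, train), train)
            if self.projection
            else x
        )
        return self.relu_out.forward(main + skip, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        dmain = self.conv1.backward(
            self.bn1.backward(
                self.relu1.backward(
                    self.conv2.backward(self.bn2.backward(dsum))
                )
            )
        )
        dskip = (
            self.conv_s.backward(self.bn_s.backward(dsum))
            if self.projection
            else dsum
        )
        return dmain + dskip


ARCHITECTURES: dict[str, dict] = {
    "resnet18": {"widths": (64, 128, 256, 512), "blocks": (2, 2, 2, 2),
                 "stem_stride": 2, "downsample": "stride"},
    "small": {"widths": (16, 32, 64), "blocks": (1, 1, 1), "stem_stride": 1,
              "downsample": "stride"},
}


class ResidualCNN:
    def __init__(
        self,
        n_classes: int,
        widths: tuple[int, ...] = (16, 32, 64),
        blocks: tuple[int, ...] = (1, 1, 1),
        in_channels: int = 1,
        coord_channels: bool = True,
        stem_stride: int = 1,
        downsample: str = "stride",
        seed: int = 0,
        dtype=np.float32,
    ):
        if downsample not in ("stride", "pool"):
            raise ValueError("downsample must be 'stride' or 'pool'")
        rng = np.random.default_rng(seed)
        self.in_channels = in_channels
        self.coord_channels = coord_channels
        self.dtype = dtype
        cin = in_channels + (2 if coord_channels else 0)
        self.stem = Conv2d(cin, widths[0], 3, stem_stride, rng=rng, dtype=dtype)
        self.stem_bn = BatchNorm2d(widths[0], dtype=dtype)
        self.stem_relu = ReLU()
        # stages hold blocks and, between stages, the chosen downsampler:
        # strided first block (classic) or a 2x2 average pool before stride-1
        # blocks (gradient-antialiased)
        self.stages: list[object] = []
        prev = widths[0]
        for i, (w, nb) in enumerate(zip(widths, blocks)):
            for j in range(nb):
                if i > 0 and j == 0:
                    if downsample == "pool":
                        self.stages.append(AvgPool2d(2))
                        stride = 1
                    else:
                        stride = 2
                else:
                    stride = 1
                self.stages.append(ResidualBlock(prev, w, stride, rng, dtype))
                prev = w
        self.pool = GlobalAvgPool()
        self.fc = Linear(prev, n_classes, rng=rng, dtype=dtype)

    # -- plumbing ---------------------------------------------------------
    def named_layers(self) -> list[tuple[str, object]]:
        out = [("stem", self.stem), ("stem_bn", self.stem_bn)]
        for i, b in enumerate(self.stages):
            if isinstance(b, ResidualBlock):
                out += [(f"stage{i}.{n}", l) for n, l in b.sublayers()]
        out.append(("fc", self.fc))
        return out

    def params(self) -> list[Param]:
        ps = self.stem.params() + self.stem_bn.params()
        for b in self.stages:
            ps += b.params()
        return ps + self.fc.params()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- forward / backward ----------------------------------------------
    def _with_coords(self, x: np.ndarray) -> np.ndarray:
        if not self.coord_channels:
            return x
        n, _, h, w = x.shape
        rows = np.linspace(-1.0, 1.0, h, dtype=x.dtype)[:, None]
        cols = np.linspace(-1.0, 1.0, w, dtype=x.dtype)[None, :]
        rr = np.broadcast_to(rows, (h, w))
        cc = np.broadcast_to(cols, (h, w))
        coords = np.broadcast_to(
            np.stack([rr, cc])[None], (n, 2, h, w)
        )
        return np.concatenate([x, coords], axis=1)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = self._with_coords(np.asarray(x, dtype=self.dtype))
        h = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, train), train), train
        )
        for b in self.stages:
            h = b.forward(h, train)
        return self.fc.forward(self.pool.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """Backpropagate to the input; returns gradient for the data channels."""
        d = self.pool.backward(self.fc.backward(dlogits))
        for b in reversed(self.stages):
            d = b.backward(d)
        d = self.stem.backward(
            self.stem_bn.backward(self.stem_relu.backward(d))
        )
        return d[:, : self.in_channels]

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class predictions in eval mode (frozen batch-norm statistics)."""
        preds = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            preds.append(logits.argmax(axis=1))
        return np.concatenate(preds)

    def input_gradient(
        self, x: np.ndarray, target_classes: np.ndarray,
        contrast: bool = False,
    ) -> np.ndarray:
        """Per-sample input gradient of the target logit, in eval mode.

        With ``contrast`` the gradient is taken of the target logit minus the
        mean of the other logits — the quantity that actually drives a
        softmax decision — so evidence shared by all classes cancels.
        """
        logits = self.forward(x, train=False)
        onehot = np.zeros_like(logits)
        onehot[np.arange(len(target_classes)), target_classes] = 1.0
        if contrast:
            onehot -= (1.0 - onehot) / (logits.shape[1] - 1)
        return self.backward(onehot)

    # -- checkpointing ----------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.named_layers():
            if isinstance(layer, (Conv2d, Linear)):
                out[f"{name}.w"] = layer.w.data
                out[f"{name}.b"] = layer.b.data
            elif isinstance(layer, BatchNorm2d):
                out[f"{name}.gamma"] = layer.gamma.data
                out[f"{name}.beta"] = layer.beta.data
                out[f"{name}.running_mean"] = layer.running_mean
                out[f"{name}.running_var"] = layer.running_var
        return out

    def save(self, path) -> None:
        np.savez(path, **self.state_arrays())

    def load(self, path) -> None:
        with np.load(path) as data:
            for name, layer in self.named_layers():
                if isinstance(layer, (Conv2d, Linear)):
                    layer.w.data = data[f"{name}.w"]
                    layer.b.data = data[f"{name}.b"]
                elif isinstance(layer, BatchNorm2d):
                    layer.gamma.data = data[f"{name}.gamma"]
                    layer.beta.data = data[f"{name}.beta"]
                    layer.running_mean = data[f"{name}.running_mean"]
                    layer.running_var = data[f"{name}.running_var"]


def make_network(arch: str, n_classes: int, seed: int = 0,
                 coord_channels: bool = True) -> ResidualCNN:
    """Instantiate a registered architecture; unknown names list the options."""
    if arch not in ARCHITECTURES:
        raise ValueError(
            f"unknown architecture {arch!r}; supported: "
            + ", ".join(sorted(ARCHITECTURES))
        )
    cfg = ARCHITECTURES[arch]
    return ResidualCNN(
        n_classes=n_classes,
        widths=cfg["widths"],
        blocks=cfg["blocks"],
        stem_stride=cfg["stem_stride"],
        downsample=cfg.get("downsample", "stride"),
        coord_channels=coord_channels,
        seed=seed,
    )
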