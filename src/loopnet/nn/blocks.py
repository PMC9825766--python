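"""Composite units: the conv->BN->PReLU->dropout layer and the dense block.

A "convolution layer" here is the four-operation sequence convolution,
batch normalization, PReLU and dropout. A dense block stacks four such
layers with DenseNet-style connectivity: the first layer consumes the block
input (and may downsample it); each subsequent layer consumes the channel
concatenation of all previous layers' outputs, and the block emits the
concatenation of all four layers' outputs.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm2d, Conv2D, Dropout, Layer, PReLU


class ConvUnit(Layer):
    """convolution -> batch normalization -> PReLU -> dropout."""

    def __init__(self, in_channels, out_channels, kernel, stride=(1, 1), dilation=(1, 1),
                 padding="valid", dropout=0.2, prelu_init=0.25, rng=None):
        rng = rng or np.random.default_rng()
        self.conv = Conv2D(in_channels, out_channels, kernel, stride, dilation, padding, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.act = PReLU(out_channels, init=prelu_init)
        self.drop = Dropout(dropout, rng=rng)
        self._order = [self.conv, self.bn, self.act, self.drop]

    def params(self):
        return [p for layer in self._order for p in layer.params()]

    def state_dict(self, prefix=""):
        out = {}
        for name, layer in zip(("conv", "bn", "act"), self._order):
            out.update(layer.state_dict(prefix=f"{prefix}{name}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for name, layer in zip(("conv", "bn", "act"), self._order):
            layer.load_state_dict(state, prefix=f"{prefix}{name}.")

    def out_shape(self, in_shape):
        return self.conv.out_shape(in_shape)

    def forward(self, x, train=False):
        for layer in self._order:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self._order):
            dy = layer.backward(dy)
        return dy

    def spec(self) -> dict:
        return {
            "filters": self.conv.out_channels,
            "in_channels": self.conv.in_channels,
            "kernel": self.conv.kernel,
            "stride": self.conv.stride,
            "dilation": self.conv.dilation[0],
            "padding": self.conv.padding,
            "operations": ("convolution", "batch_normalization", "prelu", "dropout"),
        }


class DenseBlock(Layer):
    """Four convolution layers with concatenation skip connections.

    Layer 1 may change the spatial geometry (e.g. kernel 20x4 stride 10x4 on
    one-hot sequence input); because of that, the raw input cannot join the
    later concatenations, so connectivity runs over layer outputs: layer k
    (k >= 2) receives concat(y_1, ..., y_{k-1}) along channels, and the block
    output is concat(y_1, ..., y_4) with sum(filters) channels.
    """

    def __init__(self, in_channels, in_shape, filters=(64, 32, 16, 16),
                 dilations=(1, 2, 3, 4), first_kernel=(20, 4), first_stride=(10, 4),
                 inner_kernel=(3, 1), dropout=0.2, prelu_init=0.25, rng=None):
        if len(filters) != len(dilations):
            raise ValueError("filters and dilations must have equal length")
        rng = rng or np.random.default_rng()
        self.filters = tuple(filters)
        self.layers: list[ConvUnit] = []
        self.layers.append(
            ConvUnit(in_channels, filters[0], first_kernel, first_stride,
                     dilation=(dilations[0], 1), padding="valid",
                     dropout=dropout, prelu_init=prelu_init, rng=rng)
        )
        self.inner_shape = self.layers[0].out_shape(in_shape)
        for k in range(1, len(filters)):
            self.layers.append(
                ConvUnit(sum(filters[:k]), filters[k], inner_kernel, (1, 1),
                         dilation=(dilations[k], 1), padding="same",
                         dropout=dropout, prelu_init=prelu_init, rng=rng)
            )
        self.out_channels = sum(filters)
        self.out_shape = self.inner_shape
        self._ys_shapes = None

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def state_dict(self, prefix=""):
        out = {}
        for k, layer in enumerate(self.layers):
            out.update(layer.state_dict(prefix=f"{prefix}layer{k}."))
        return out

    def load_state_dict(self, state, prefix=""):
        for k, layer in enumerate(self.layers):
            layer.load_state_dict(state, prefix=f"{prefix}layer{k}.")

    def forward(self, x, train=False):
        ys = [self.layers[0].forward(x, train=train)]
        for layer in self.layers[1:]:
            ys.append(layer.forward(np.concatenate(ys, axis=1), train=train))
        return np.concatenate(ys, axis=1)

    def backward(self, dout):
        # Split the block-output gradient into per-layer-output slices, then
        # walk layers in reverse, adding each layer's input gradient back onto
        # the slices of the earlier outputs it consumed.
        splits = np.cumsum(self.filters)[:-1]
        dys = list(np.split(dout, splits, axis=1))
        for k in range(len(self.layers) - 1, 0, -1):
            dx = self.layers[k].backward(dys[k])
            for j, piece in enumerate(np.split(dx, splits[:k - 1], axis=1) if k > 1 else [dx]):
                dys[j] = dys[j] + piece
        return self.layers[0].backward(dys[0])

    def describe(self) -> dict:
        return {
            "n_layers": len(self.layers),
            "out_channels": self.out_channels,
            "out_shape": tuple(self.out_shape),
            "layers": [layer.spec() for layer in self.layers],
        }
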