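"""Convolutional trunks for the image encoder.

``ResNet34Trunk`` is the 34-layer residual network with its global pooling
and classification layers removed, so a 224x224x3 patch maps to a 7x7x512
feature grid.  ``SmallConvTrunk`` is a compact strided-conv stack for
desk-scale experiments (64x64 patches -> 4x4 x d_att).  Both are initialised
from the model seed; externally trained backbone weights can be loaded into
a checkpoint when available.
"""

from __future__ import annotations

import numpy as np

from ..nn import Module, Conv2d, BatchNorm2d, Tensor


class BasicBlock(Module):
    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, rng, stride=1, padding=1)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.down_conv = Conv2d(c_in, c_out, 1, rng, stride=stride)
            self.down_bn = BatchNorm2d(c_out)
        else:
            self.down_conv = None
            self.down_bn = None

    def __call__(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        identity = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return (out + identity).relu()


class ResNet34Trunk(Module):
    """Residual trunk truncated before pooling/classification: out 7x7x512."""

    LAYERS = (3, 4, 6, 3)
    CHANNELS = (64, 128, 256, 512)

    def __init__(self, rng: np.random.Generator):
        self.stem = Conv2d(3, 64, 7, rng, stride=2, padding=3)
        self.stem_bn = BatchNorm2d(64)
        self.blocks: list[BasicBlock] = []
        c_in = 64
        for n_blocks, c_out, stride in zip(self.LAYERS, self.CHANNELS,
                                           (1, 2, 2, 2)):
            for b in range(n_blocks):
                self.blocks.append(
                    BasicBlock(c_in, c_out, stride if b == 0 else 1, rng))
                c_in = c_out
        self.out_channels = c_in

    def __call__(self, x: Tensor) -> Tensor:
        x = self.stem_bn(self.stem(x)).relu()
        x = x.maxpool2d(kernel=3, stride=2, padding=1)
        for blk in self.blocks:
            x = blk(x)
        return x


class SmallConvTrunk(Module):
    """Stride-4 5x5 stem plus stride-2 3x3 stages; output channels = d_att.

    Total downsampling is 16x, so a 64x64 patch yields a 4x4 feature grid.
    """

    def __init__(self, d_att: int, channels: tuple[int, ...],
                 rng: np.random.Generator):
        widths = tuple(channels) + (d_att,)
        self.stem = Conv2d(3, widths[0], 5, rng, stride=4, padding=2)
        self.stem_bn = BatchNorm2d(widths[0])
        self.convs = [Conv2d(widths[i], widths[i + 1], 3, rng, stride=2,
                             padding=1) for i in range(len(widths) - 1)]
        self.bns = [BatchNorm2d(w) for w in widths[1:]]
        self.out_channels = d_att

    def __call__(self, x: Tensor) -> Tensor:
        x = self.stem_bn(self.stem(x)).relu()
        for conv, bn in zip(self.convs, self.bns):
            x = bn(conv(x)).relu()
        return x
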