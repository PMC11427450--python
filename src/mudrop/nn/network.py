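"""The droplet-state encoder-decoder network.

A U-Net-style encoder-decoder tuned for droplet scenes: shallow encoder
blocks use two 3x3 convolutions (fast capture of edges and shapes), deep
blocks use three (richer state/position semantics); every convolution is
3x3, stride 1, ReLU, with a 2x2 max pool between blocks.  The decoder uses
direct twofold upsampling followed by convolutions — eight in total, two per
resolution level to mirror the encoder — with skip connections concatenating
the encoder feature map at equal resolution.  A final 1x1 convolution
projects to the 5 class channels (background + four droplet states).
"""
from __future__ import annotations

import numpy as np

from .layers import Conv2d, GroupNorm, MaxPool2, ReLU, Upsample2

ENCODER_DEPTHS = (2, 2, 3, 3)        # convs per encoder block
WIDTH_MULTIPLIERS = (1, 2, 4, 8)     # channel growth per block


class DropletNet:
    """Maps ``(N, H, W, 3)`` images to ``(N, H, W, 5)`` class logits.

    ``H`` and ``W`` must be divisible by ``2**4`` (four pooling stages).
    ``norm="group"`` inserts group normalization between each convolution
    and its ReLU — a trainability aid for short desk-scale schedules that
    leaves the convolutional structure (layer counts, kernels, widths,
    skips, head) untouched; ``norm="none"`` gives the plain conv + ReLU
    stacks.
    """

    def __init__(self, base_width: int = 64, width_scale: float = 1.0,
                 num_classes: int = 5, upsample_mode: str = "nearest",
                 norm: str = "group",
                 rng: np.random.Generator | None = None) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        if norm not in ("group", "none"):
            raise ValueError("norm must be 'group' or 'none'")
        widths = [max(2, int(round(base_width * width_scale * m)))
                  for m in WIDTH_MULTIPLIERS]
        self.widths = widths
        self.num_classes = num_classes

        def conv_unit(cin, cout):
            unit = [Conv2d(cin, cout, 3, rng)]
            if norm == "group":
                unit.append(GroupNorm(cout))
            unit.append(ReLU())
            return unit

        self.enc_blocks: list[list] = []
        cin = 3
        for depth, w in zip(ENCODER_DEPTHS, widths):
            block = []
            for _ in range(depth):
                block += conv_unit(cin, w)
                cin = w
            self.enc_blocks.append(block)
        self.pools = [MaxPool2() for _ in widths]

        # decoder: one (upsample, conv, conv) stage per encoder block,
        # deepest first; the first conv consumes the concatenated skip.
        self.dec_stages: list[tuple] = []
        up_ch = widths[-1]
        for skip_ch in reversed(widths):
            stage = [Upsample2(upsample_mode)]
            stage += conv_unit(up_ch + skip_ch, skip_ch)
            stage += conv_unit(skip_ch, skip_ch)
            self.dec_stages.append(tuple(stage))
            up_ch = skip_ch
        self.head = Conv2d(widths[0], num_classes, 1, rng)

    # -- introspection ------------------------------------------------------
    def layers(self):
        for block in self.enc_blocks:
            yield from block
        yield from self.pools
        for stage in self.dec_stages:
            yield from stage
        yield self.head

    def params(self):
        out = []
        for layer in self.layers():
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(getattr(obj, name).size for obj, name, _ in self.params())

    def conv_layer_counts(self) -> dict[str, int]:
        enc = sum(1 for b in self.enc_blocks for l in b if isinstance(l, Conv2d))
        dec = sum(1 for s in self.dec_stages for l in s if isinstance(l, Conv2d))
        return {"encoder": enc, "decoder": dec, "head": 1}

    # -- passes -------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError("expected (N, H, W, 3) input")
        if x.shape[1] % 16 or x.shape[2] % 16:
            raise ValueError("input height/width must be divisible by 16")
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            for layer in block:
                x = layer.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        self._skip_channels = [s.shape[3] for s in skips] if train else None
        for stage, skip in zip(self.dec_stages, reversed(skips)):
            x = stage[0].forward(x, train)
            x = np.concatenate([x, skip], axis=3)
            for layer in stage[1:]:
                x = layer.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, g: np.ndarray) -> None:
        g = self.head.backward(g)
        skip_grads = []
        for stage in reversed(self.dec_stages):
            up = stage[0]
            for layer in reversed(stage[1:]):
                g = layer.backward(g)
            up_ch = g.shape[3] - self._skip_channels[len(skip_grads)]
            skip_grads.append(g[..., up_ch:])
            g = up.backward(np.ascontiguousarray(g[..., :up_ch]))
        # skip_grads[j] is the gradient of the j-th (shallow-to-deep) skip
        for block, pool, sg in zip(reversed(self.enc_blocks),
                                   reversed(self.pools), reversed(skip_grads)):
            g = pool.backward(g) + sg
            for layer in reversed(block):
                g = layer.backward(g)

    # -- weights ------------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, (obj, name, _) in enumerate(self.params()):
            out[f"p{i}_{name}"] = getattr(obj, name)
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, (obj, name, _) in enumerate(self.params()):
            val = arrays[f"p{i}_{name}"]
            if val.shape != getattr(obj, name).shape:
                raise ValueError("checkpoint does not match this architecture")
            setattr(obj, name, val.astype(np.float32))
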