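"""The multi-output 3D U-net.

One CT channel in; three parallel single-channel heads out (segmentation
logits, longitude, diameter), attached to the last intermediate layer and
not to each other.  Each level is two 3^3 convolutions with batch
normalization, ReLU and dropout; levels are joined by 2x max pooling on the
way down and nearest-neighbor 2x upsampling on the way up, with skip
concatenations between encoder and decoder layers of the same spatial
shape.  With the default configuration (channel ladder 16 -> 512 over 7
levels) the trainable parameter count is 36.6 M.

The deepest skip (encoder level preceding the bottleneck into the first
decoder layer) is disabled by default: with it the default ladder counts
40.1 M parameters, without it 36.6 M, matching the published total of the
architecture this reproduces; it can be re-enabled per config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Adam, Conv3d, ConvBlock, MaxPool2, Param, Upsample2

__all__ = ["UNetConfig", "UNet3D", "build_unet", "count_parameters"]


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts levels including the bottleneck: the default of 7 with
    ``base_channels`` 16 and ``max_channels`` 512 yields the ladder
    16, 32, 64, 128, 256, 512 with a 512-channel bottleneck, i.e. a
    256 x 256 x 192 input reaches a 4 x 4 x 3 bottleneck.  Spatial input
    dims must be divisible by ``2**(depth - 1)``.
    """

    base_channels: int = 16
    depth: int = 7
    max_channels: int = 512
    convs_per_level: int = 2
    kernel: int = 3
    dropout: float = 0.1
    bottleneck_skip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be at least 2 (one level plus bottleneck)")
        if self.base_channels < 1 or self.convs_per_level < 1:
            raise ValueError("base_channels and convs_per_level must be positive")

    def encoder_channels(self) -> list[int]:
        return [
            min(self.base_channels * 2**i, self.max_channels)
            for i in range(self.depth - 1)
        ]

    def bottleneck_channels(self) -> int:
        return min(self.base_channels * 2 ** (self.depth - 1), self.max_channels)

    def decoder_channels(self) -> list[int]:
        # decoder layer at a given resolution carries half the channels the
        # encoder had there (256, 128, ..., base for the default ladder);
        # the last decoder layer sits at half resolution and a final
        # upsampling feeds the heads, so there are depth - 2 decoder levels
        return self.encoder_channels()[-2::-1]

    def validate_shape(self, shape: tuple[int, int, int]) -> None:
        div = 2 ** (self.depth - 1)
        for ax, n in zip("xyz", shape):
            if n % div:
                raise ValueError(
                    f"axis {ax} has {n} voxels, not divisible by {div} "
                    f"(depth {self.depth})"
                )


class UNet3D:
    """Encoder-decoder with three parallel regression/segmentation heads."""

    def __init__(self, config: UNetConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._dropout_rng = np.random.default_rng(config.seed + 1)
        c = config
        enc_ch = c.encoder_channels()
        dec_ch = c.decoder_channels()

        self.enc_blocks: list[ConvBlock] = []
        cin = 1
        for ch in enc_ch:
            self.enc_blocks.append(
                ConvBlock(cin, ch, c.convs_per_level, c.kernel, c.dropout, self._mkrng())
            )
            cin = ch
        self.pools = [MaxPool2() for _ in enc_ch]
        self.bottleneck = ConvBlock(
            cin, c.bottleneck_channels(), c.convs_per_level, c.kernel, c.dropout, self._mkrng()
        )
        cin = c.bottleneck_channels()

        self.ups = [Upsample2() for _ in dec_ch]
        self.dec_blocks: list[ConvBlock] = []
        self.dec_skip: list[bool] = []
        for j, ch in enumerate(dec_ch):
            use_skip = j > 0 or c.bottleneck_skip
            skip_ch = enc_ch[-(j + 1)] if use_skip else 0
            self.dec_blocks.append(
                ConvBlock(
                    cin + skip_ch, ch, c.convs_per_level, c.kernel, c.dropout, self._mkrng()
                )
            )
            self.dec_skip.append(use_skip)
            cin = ch
        self.final_up = Upsample2()
        self.heads = {
            name: Conv3d(cin, 1, 1, self._mkrng())
            for name in ("segmentation", "longitude", "diameter")
        }
        self._tape: dict | None = None

    def _mkrng(self) -> np.random.Generator:
        # weight init and dropout share the config seed but separate streams
        return np.random.default_rng(self.rng.integers(0, 2**31))

    # -- parameters ------------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.enc_blocks:
            out += blk.params()
        out += self.bottleneck.params()
        for blk in self.dec_blocks:
            out += blk.params()
        for head in self.heads.values():
            out += head.params()
        return out

    # -- forward / backward ---------------------------------------------

    def forward(self, ct: np.ndarray, train: bool = False) -> dict[str, np.ndarray]:
        """Run the network on a (D, H, W) normalized CT volume.

        Returns raw head outputs (``segmentation`` is a logit volume) with
        the channel axis dropped.
        """
        self.config.validate_shape(ct.shape)
        h = np.ascontiguousarray(ct[None], dtype=np.float32)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        concat_sizes = []
        for j, (up, blk) in enumerate(zip(self.ups, self.dec_blocks)):
            h = up.forward(h, train)
            if self.dec_skip[j]:
                skip = skips[-(j + 1)]
                concat_sizes.append((h.shape[0], skip.shape[0]))
                h = np.concatenate([h, skip], axis=0)
            else:
                concat_sizes.append(None)
            h = blk.forward(h, train)
        h = self.final_up.forward(h, train)
        outputs = {k: head.forward(h, train)[0] for k, head in self.heads.items()}
        if train:
            self._tape = {"concat_sizes": concat_sizes}
        return outputs

    def backward(self, grads: dict[str, np.ndarray]) -> None:
        """Backpropagate per-head loss gradients; accumulates into params."""
        assert self._tape is not None, "call forward(train=True) first"
        concat_sizes = self._tape["concat_sizes"]
        dh = None
        for k, head in self.heads.items():
            d = head.backward(grads[k][None])
            dh = d if dh is None else dh + d
        dh = self.final_up.backward(dh)
        skip_grads: dict[int, np.ndarray] = {}
        for j in range(len(self.dec_blocks) - 1, -1, -1):
            dh = self.dec_blocks[j].backward(dh)
            if concat_sizes[j] is not None:
                n_up, _ = concat_sizes[j]
                skip_idx = len(self.enc_blocks) - 1 - j
                skip_grads[skip_idx] = dh[n_up:]
                dh = dh[:n_up]
            dh = self.ups[j].backward(dh)
        dh = self.bottleneck.backward(dh)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            dh = self.pools[i].backward(dh)
            if i in skip_grads:
                dh = dh + skip_grads[i]
            dh = self.enc_blocks[i].backward(dh)
        self._tape = None

    # -- persistence -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All weights and batch-norm running stats, keyed for np.savez."""
        out = {}
        for i, p in enumerate(self.params()):
            out[f"param_{i}"] = p.value
        bn_idx = 0
        for blk in self._all_blocks():
            for lay in blk.layers:
                if hasattr(lay, "running_mean"):
                    out[f"bn_mean_{bn_idx}"] = lay.running_mean
                    out[f"bn_var_{bn_idx}"] = lay.running_var
                    bn_idx += 1
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = np.ascontiguousarray(arrays[f"param_{i}"], dtype=np.float32)
            p.grad = np.zeros_like(p.value)
        bn_idx = 0
        for blk in self._all_blocks():
            for lay in blk.layers:
                if hasattr(lay, "running_mean"):
                    lay.running_mean = np.asarray(arrays[f"bn_mean_{bn_idx}"], dtype=np.float32)
                    lay.running_var = np.asarray(arrays[f"bn_var_{bn_idx}"], dtype=np.float32)
                    bn_idx += 1

    def _all_blocks(self) -> list[ConvBlock]:
        return [*self.enc_blocks, self.bottleneck, *self.dec_blocks]


def build_unet(config: UNetConfig, input_shape: tuple[int, int, int] | None = None) -> UNet3D:
    """Build the U-net; validates *input_shape* divisibility if given.

    The network is fully convolutional, so the parameter count does not
    depend on the input spatial shape.
    """
    if input_shape is not None:
        config.validate_shape(tuple(input_shape))
    return UNet3D(config)


def count_parameters(model: UNet3D) -> int:
    """Total trainable parameters (conv weights/biases, BN scale/shift)."""
    return sum(p.size for p in model.params())
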