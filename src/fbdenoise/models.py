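"""Network architectures for the joint denoising pipeline.

Three builders with explicit shape contracts:

* :class:`NNet` -- the noise-level-map estimator: a plain fully
  convolutional stack (default 20 layers of 64 3x3 kernels, zero padding,
  no pooling, no batch normalisation) that maps a noisy image y to a
  per-pixel noise standard-deviation estimate sigma_y of the same shape.
  The last layer has no activation; an absolute-value transform enforces
  sigma_y >= 0.
* :class:`DNet` -- the denoiser: a U-shaped encoder/decoder (default
  depth 3, 64 first-layer channels) whose encoder downsamples with 2x2
  max pooling and whose decoder upsamples with bilinear interpolation.
  All convolutions are padded ``same``, so skip connections concatenate
  without cropping.  The noisy image and the noise map enter as a
  2-channel input (``use_noise_map=False`` gives the 1-channel variant).
* :class:`QNet` -- the no-reference quality scorer: a lightweight
  convolutional backbone extracts a semantic feature vector; a
  hypernetwork branch maps that vector to the *weights* of a 4-layer
  fully connected quality head, which then scores the same features.
  The quality head therefore has no free parameters of its own.

All builders are deterministic given an integer ``seed`` for weight
initialisation (He-style normal init).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad

__all__ = [
    "NNetConfig",
    "DNetConfig",
    "QNetConfig",
    "NNet",
    "DNet",
    "QNet",
    "build_nnet",
    "build_dnet",
    "build_qnet",
]


# ---------------------------------------------------------------------------
# configs


@dataclass
class NNetConfig:
    """Fully convolutional noise estimator: no pooling, no batch norm."""

    n_layers: int = 20
    kernel: int = 3
    channels: int = 64
    activation: str = "relu"

    def validate(self):
        if self.n_layers < 2:
            raise ValueError("NNet needs at least input and output layers")
        if self.kernel < 1 or self.kernel % 2 == 0:
            raise ValueError("kernel must be odd and positive")
        if self.channels < 1:
            raise ValueError("channels must be positive")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class DNetConfig:
    """U-shaped denoiser configuration."""

    depth: int = 3
    first_channels: int = 64
    in_channels: int = 2          # image + noise map
    upsample: str = "bilinear"
    downsample: str = "max_pool"
    use_noise_map: bool = True
    # leaky slope keeps narrow single-image nets from dying wholesale
    activation: str = "leaky_relu"

    def validate(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.first_channels < 1:
            raise ValueError("first_channels must be positive")
        if self.activation not in ("relu", "leaky_relu"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.upsample != "bilinear":
            raise ValueError("only bilinear upsampling is supported")
        if self.downsample != "max_pool":
            raise ValueError("only max-pool downsampling is supported")
        expected = 2 if self.use_noise_map else 1
        if self.in_channels != expected:
            raise ValueError("in_channels inconsistent with use_noise_map")


@dataclass
class QNetConfig:
    """Quality scorer configuration.

    The default backbone is a lightweight 6-conv CNN trained from
    scratch; ``resnet50`` is accepted as a config value but requires
    externally supplied weights and is not buildable here.
    """

    backbone: str = "lightweight_cnn"
    n_quality_fc: int = 4
    hyper_weights: bool = True
    feature_dim: int = 112          # 2 moments x (8+16+32) stage channels
    head_dims: tuple = (16, 8, 4)   # hidden widths of the 4-FC quality head
    hyper_hidden: int = 32

    def validate(self):
        if self.backbone not in ("lightweight_cnn", "resnet50"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.n_quality_fc != 4:
            raise ValueError("the quality head has exactly four FC layers")
        if len(self.head_dims) != self.n_quality_fc - 1:
            raise ValueError("head_dims must list the three hidden widths")
        if not self.hyper_weights:
            raise ValueError("the quality head weights are hypernetwork outputs")


# ---------------------------------------------------------------------------
# helpers


def _he_conv(rng, cout, cin, k, gain=2.0):
    std = np.sqrt(gain / (cin * k * k))
    w = ad.parameter(rng.normal(0.0, std, size=(cout, cin, k, k)))
    b = ad.parameter(np.zeros(cout))
    return w, b


def _he_linear(rng, mout, nin, std=None):
    if std is None:
        std = np.sqrt(2.0 / nin)
    w = ad.parameter(rng.normal(0.0, std, size=(mout, nin)))
    b = ad.parameter(np.zeros(mout))
    return w, b


def _as_tensor(x):
    if isinstance(x, ad.Tensor):
        return x
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    return ad.constant(x)


# ---------------------------------------------------------------------------
# N-Net


class NNet:
    """Noise-level-map estimator: ImageGrid -> NoiseLevelMap (same shape)."""

    def __init__(self, config: NNetConfig | None = None, seed: int = 0):
        self.config = config or NNetConfig()
        self.config.validate()
        c = self.config
        rng = np.random.default_rng(seed)
        self.layers = []
        widths = [1] + [c.channels] * (c.n_layers - 1) + [1]
        for i in range(c.n_layers):
            self.layers.append(_he_conv(rng, widths[i + 1], widths[i], c.kernel))

    @property
    def n_conv_layers(self):
        return len(self.layers)

    def params(self):
        return [t for wb in self.layers for t in wb]

    def n_params(self):
        return sum(p.data.size for p in self.params())

    def __call__(self, x):
        """Forward pass; accepts (H,W) array or (1,H,W) tensor."""
        act = ad.relu if self.config.activation == "relu" else ad.leaky_relu
        h = _as_tensor(x)
        last = len(self.layers) - 1
        for i, (w, b) in enumerate(self.layers):
            h = ad.conv2d(h, w, b)
            if i != last:            # output layer has no activation
                h = act(h)
        return ad.abs_(h)            # sigma >= 0


# ---------------------------------------------------------------------------
# D-Net


class DNet:
    """U-shaped denoiser: (ImageGrid, NoiseLevelMap) -> ImageGrid."""

    def __init__(self, config: DNetConfig | None = None, seed: int = 0):
        self.config = config or DNetConfig()
        self.config.validate()
        c = self.config
        rng = np.random.default_rng(seed)
        ch = [c.first_channels * 2 ** i for i in range(c.depth + 1)]
        self.enc = []
        cin = c.in_channels
        for i in range(c.depth):
            self.enc.append((_he_conv(rng, ch[i], cin, 3), _he_conv(rng, ch[i], ch[i], 3)))
            cin = ch[i]
        self.bottleneck = (_he_conv(rng, ch[c.depth], cin, 3),
                           _he_conv(rng, ch[c.depth], ch[c.depth], 3))
        self.dec = []
        up_cin = ch[c.depth]
        for i in reversed(range(c.depth)):
            self.dec.append((_he_conv(rng, ch[i], up_cin + ch[i], 3),
                             _he_conv(rng, ch[i], ch[i], 3)))
            up_cin = ch[i]
        self.out = _he_conv(rng, 1, ch[0], 3)

    def params(self):
        out = []
        for pair in self.enc + [self.bottleneck] + self.dec:
            for w, b in pair:
                out += [w, b]
        out += list(self.out)
        return out

    def n_params(self):
        return sum(p.data.size for p in self.params())

    @property
    def first_layer_out_channels(self):
        return self.enc[0][0][0].shape[0] if self.enc else self.bottleneck[0][0].shape[0]

    def __call__(self, image, noise_map=None):
        """Denoise; inputs may be arrays or tensors of matching (H,W)."""
        img = _as_tensor(image)
        parts = [img]
        if self.config.use_noise_map:
            if noise_map is None:
                raise ValueError("this D-Net expects a noise map input")
            nm = _as_tensor(noise_map)
            if nm.shape != img.shape:
                raise ValueError("image and noise map shapes differ")
            parts.append(nm)
        h0, w0 = img.shape[1:]
        act = ad.relu if self.config.activation == "relu" else ad.leaky_relu
        x = ad.concat_channels(parts) if len(parts) > 1 else parts[0]

        # reflect-pad odd sizes up to a multiple of 2^depth, crop at the end
        mult = 2 ** self.config.depth
        ph = (-h0) % mult
        pw = (-w0) % mult
        if ph or pw:
            x = ad.pad_reflect(x, (0, ph), (0, pw))

        skips = []
        for c1, c2 in self.enc:
            x = act(ad.conv2d(x, *c1))
            x = act(ad.conv2d(x, *c2))
            skips.append(x)
            x = ad.max_pool2(x)
        x = act(ad.conv2d(x, *self.bottleneck[0]))
        x = act(ad.conv2d(x, *self.bottleneck[1]))
        for (c1, c2), skip in zip(self.dec, reversed(skips)):
            x = ad.upsample_bilinear2(x)
            x = ad.concat_channels([x, skip])
            x = act(ad.conv2d(x, *c1))
            x = act(ad.conv2d(x, *c2))
        x = ad.conv2d(x, *self.out)
        if ph or pw:
            x = ad.crop(x, h0, w0)
        return x


# ---------------------------------------------------------------------------
# Q-Net


class QNet:
    """No-reference quality scorer with a hypernetwork-weighted head.

    The backbone is six padded 3x3 convolutions in three stages
    (8, 16, 32 channels), each stage followed by 2x2 max pooling.  Each
    stage contributes its globally pooled first and second activation
    moments, giving a multi-scale semantic vector ``s`` of length
    ``feature_dim`` (second moments carry the noise-energy statistics
    that distinguish residual noise from image texture).  The hyper
    branch maps ``s`` through one hidden layer to the flattened weights
    and biases of the quality head, four FC layers
    ``feature_dim -> 16 -> 8 -> 4 -> 1`` that score ``s`` itself.
    """

    _STAGE_CH = (8, 16, 32)

    def __init__(self, config: QNetConfig | None = None, seed: int = 0):
        self.config = config or QNetConfig()
        self.config.validate()
        c = self.config
        if c.backbone == "resnet50":
            raise NotImplementedError(
                "resnet50 backbone requires externally supplied weights")
        if c.feature_dim != 2 * sum(self._STAGE_CH):
            raise ValueError("feature_dim must equal twice the total stage width")
        rng = np.random.default_rng(seed)
        s1, s2, s3 = self._STAGE_CH
        self.convs = [
            _he_conv(rng, s1, 1, 3), _he_conv(rng, s1, s1, 3),
            _he_conv(rng, s2, s1, 3), _he_conv(rng, s2, s2, 3),
            _he_conv(rng, s3, s2, 3), _he_conv(rng, s3, s3, 3),
        ]
        # layout of the generated quality-head parameter vector
        dims = [c.feature_dim, *c.head_dims, 1]
        self._head_shapes = [(dims[i + 1], dims[i]) for i in range(4)]
        n_out = sum(m * n + m for m, n in self._head_shapes)
        self.hyper1 = _he_linear(rng, c.hyper_hidden, c.feature_dim)
        # small init keeps the generated weights near zero at start
        self.hyper2 = _he_linear(rng, n_out, c.hyper_hidden, std=0.01)
        # output scale applied by __call__; training sets this so scores
        # come out on the pseudo-label scale
        self.score_scale = 1.0

    def params(self):
        out = []
        for w, b in self.convs:
            out += [w, b]
        out += [*self.hyper1, *self.hyper2]
        return out

    @property
    def n_quality_fc_layers(self):
        return len(self._head_shapes)

    def _features(self, x):
        h = _as_tensor(x)
        _, hh, ww = h.shape
        ph = (-hh) % 8
        pw = (-ww) % 8
        if ph or pw:
            h = ad.pad_reflect(h, (0, ph), (0, pw))
        moments = []
        for i, conv in enumerate(self.convs):
            h = ad.relu(ad.conv2d(h, *conv))
            if i % 2 == 1:
                moments.append(ad.global_avg_pool(h))
                moments.append(ad.global_avg_pool(ad.square(h)))
                h = ad.max_pool2(h)
        return ad.concat_channels(moments)

    def _head(self, s):
        theta = ad.linear(ad.relu(ad.linear(s, *self.hyper1)), *self.hyper2)
        h = s
        off = 0
        for li, (m, n) in enumerate(self._head_shapes):
            w = ad.reshape(ad.narrow(theta, off, m * n), (m, n))
            off += m * n
            b = ad.narrow(theta, off, m)
            off += m
            h = ad.linear(h, w, b)
            if li < len(self._head_shapes) - 1:
                h = ad.relu(h)
        return h  # (1,)

    def score_tensor(self, x):
        """Differentiable score of one image tensor (used in training)."""
        return self._head(self._features(x))

    def __call__(self, image):
        """Score a single image (2-D array in [0,1]) -> float.

        Images larger than 224 pixels on a side are scored as the mean
        over five 224x224 crops (four corners + centre).
        """
        img = np.asarray(image, dtype=np.float32)
        if img.ndim != 2:
            raise ValueError("QNet scores single-channel 2-D images")
        h, w = img.shape
        lim = 224
        if h <= lim and w <= lim:
            crops = [img]
        else:
            ch, cw = min(h, lim), min(w, lim)
            rs = [0, h - ch, (h - ch) // 2]
            cs = [0, w - cw, (w - cw) // 2]
            crops = [img[:ch, :cw], img[:ch, w - cw:], img[h - ch:, :cw],
                     img[h - ch:, w - cw:],
                     img[rs[2]:rs[2] + ch, cs[2]:cs[2] + cw]]
        return self.score_scale * float(
            np.mean([self.score_tensor(c).item() for c in crops]))


def build_nnet(config: NNetConfig | None = None, seed: int = 0) -> NNet:
    return NNet(config, seed)


def build_dnet(config: DNetConfig | None = None, seed: int = 0) -> DNet:
    return DNet(config, seed)


def build_qnet(config: QNetConfig | None = None, seed: int = 0) -> QNet:
    return QNet(config, seed)
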