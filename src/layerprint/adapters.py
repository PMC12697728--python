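"""Model adapters: the contract between networks and the RSA machinery.

An adapter exposes (i) named layers, (ii) flattened unit-activation patterns
per layer for a batch of images, and (iii) a vector-Jacobian product that
pulls cotangents on those activations back to input pixels.  Everything
downstream (RSM construction, image synthesis) talks only to this contract,
so any convolutional network can be plugged in.

The built-in :class:`SmallCNNAdapter` is a seeded random convolutional stack
implemented directly in NumPy with hand-written forward and backward passes;
it runs everywhere, is bit-reproducible from its seed, and is the network
used throughout the test-suite and the demo pipeline.  An Inception-V1
(GoogLeNet) adapter matching the twelve layers used for full-scale synthesis
(the first three convolutional layers and every subsequent inception-block
output) is available when PyTorch/torchvision are installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusSet",
    "ModelAdapter",
    "SmallCNNAdapter",
    "InceptionV1Adapter",
    "register_adapter",
    "create_adapter",
    "available_adapters",
]


# ---------------------------------------------------------------------------
# Stimulus container
# ---------------------------------------------------------------------------

@dataclass
class StimulusSet:
    """An ordered set of RGB images stored as float pixels.

    Parameters
    ----------
    pixels
        Array of shape ``(n_images, height, width, 3)``.
    image_ids
        One label per image, in presentation order.
    value_range
        Declared inclusive pixel range; optimizers clamp to it after every
        step.
    """

    pixels: np.ndarray
    image_ids: Sequence[str] = None  # type: ignore[assignment]
    value_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4 or self.pixels.shape[-1] != 3:
            raise ValueError(
                f"pixels must have shape (n_images, H, W, 3); got {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 2:
            raise ValueError("a stimulus set needs at least 2 images")
        if self.image_ids is None:
            self.image_ids = [f"img{i:02d}" for i in range(self.pixels.shape[0])]
        self.image_ids = list(self.image_ids)
        if len(self.image_ids) != self.pixels.shape[0]:
            raise ValueError("image_ids length must match n_images")
        lo, hi = self.value_range
        if self.pixels.min() < lo - 1e-12 or self.pixels.max() > hi + 1e-12:
            raise ValueError("pixel values outside the declared value range")

    @property
    def n_images(self) -> int:
        return self.pixels.shape[0]

    def copy(self) -> "StimulusSet":
        return StimulusSet(self.pixels.copy(), list(self.image_ids), self.value_range)


# ---------------------------------------------------------------------------
# Adapter contract
# ---------------------------------------------------------------------------

class ModelAdapter:
    """Abstract contract for a convolutional network.

    Subclasses must define ``layer_ids`` (unique, ordered), ``input_shape``
    ``(H, W, 3)``, ``layer_shapes`` mapping each layer to its activation
    tensor shape ``(channels, height, width)``, and the two methods below.
    Activation patterns are flattened channel-major, i.e. the units of
    channel ``c`` occupy the contiguous slice
    ``[c * h * w, (c + 1) * h * w)`` of the pattern vector.
    """

    layer_ids: tuple[str, ...]
    input_shape: tuple[int, int, int]
    layer_shapes: Mapping[str, tuple[int, int, int]]

    def activations(self, pixels: np.ndarray) -> dict[str, np.ndarray]:
        """Per-layer flattened activation patterns, ``layer -> (n, n_units)``."""
        raise NotImplementedError

    def pixel_gradient(
        self, pixels: np.ndarray, cotangents: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        """Gradient w.r.t. pixels of ``sum_l <cotangents[l], activations[l]>``.

        ``cotangents`` maps a subset of ``layer_ids`` to arrays shaped like
        the corresponding activation patterns.  Returns an array shaped like
        ``pixels``.
        """
        raise NotImplementedError

    # -- shared helpers ----------------------------------------------------

    def check_layer(self, layer_id: str) -> None:
        if layer_id not in self.layer_ids:
            raise KeyError(
                f"unknown layer {layer_id!r}; known layers: {list(self.layer_ids)}"
            )

    def check_input(self, pixels: np.ndarray) -> np.ndarray:
        pixels = np.asarray(pixels, dtype=np.float64)
        if pixels.ndim != 4 or pixels.shape[1:] != self.input_shape:
            raise ValueError(
                f"expected input of shape (n, {self.input_shape[0]}, "
                f"{self.input_shape[1]}, {self.input_shape[2]}); got {pixels.shape}"
            )
        return pixels

    def n_units(self, layer_id: str) -> int:
        c, h, w = self.layer_shapes[layer_id]
        return c * h * w

    def channel_slice(self, layer_id: str, channel: int) -> slice:
        """Flat-index slice of one channel's units (channel-major layout)."""
        c, h, w = self.layer_shapes[layer_id]
        if not 0 <= channel < c:
            raise IndexError(f"channel {channel} out of range for {layer_id} ({c})")
        return slice(channel * h * w, (channel + 1) * h * w)


# ---------------------------------------------------------------------------
# NumPy convolution primitives (stride + same-padding, with exact VJPs)
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int) -> np.ndarray:
    # x: (n, H, W, Cin), w: (kh, kw, Cin, Cout), b: (Cout,)
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (n, Ho, Wo, Cin, kh, kw)
    return np.einsum("nhwcij,ijcd->nhwd", win, w, optimize=True) + b


def _conv_backward_input(
    gy: np.ndarray, w: np.ndarray, x_shape: tuple[int, ...], stride: int
) -> np.ndarray:
    # gy: (n, Ho, Wo, Cout) -> gx: x_shape
    n, H, W, _ = x_shape
    kh, kw = w.shape[:2]
    ph, pw = kh // 2, kw // 2
    ho, wo = gy.shape[1], gy.shape[2]
    gxp = np.zeros((n, H + 2 * ph, W + 2 * pw, w.shape[2]))
    for i in range(kh):
        for j in range(kw):
            contrib = np.einsum("nhwd,cd->nhwc", gy, w[i, j], optimize=True)
            gxp[:, i : i + stride * ho : stride, j : j + stride * wo : stride] += contrib
    return gxp[:, ph : ph + H, pw : pw + W, :]


# ---------------------------------------------------------------------------
# Small random CNN adapter
# ---------------------------------------------------------------------------

@dataclass
class _ConvLayer:
    weight: np.ndarray  # (kh, kw, Cin, Cout)
    bias: np.ndarray    # (Cout,)
    stride: int
    nonlinearity: str   # "tanh" or "linear"


class SmallCNNAdapter(ModelAdapter):
    """A fixed (untrained) convolutional stack with analytic gradients.

    Weights are drawn once from a seeded He-scaled normal; the network is
    then frozen, so activation patterns and pixel gradients are
    deterministic functions of the input.  tanh nonlinearities keep
    gradients alive on arbitrary noise images, and inputs are centered by
    ``input_offset`` before the first convolution so that units have no
    shared baseline across statistically exchangeable images (a shared
    baseline would pin all pattern correlations near a common constant).
    """

    def __init__(
        self,
        layers: Sequence[_ConvLayer],
        input_shape: tuple[int, int, int],
        layer_ids: Sequence[str] | None = None,
        input_offset: float = 0.0,
    ) -> None:
        self._layers = list(layers)
        self.input_offset = float(input_offset)
        self.input_shape = tuple(input_shape)  # type: ignore[assignment]
        ids = list(layer_ids) if layer_ids is not None else [
            f"conv{i + 1}" for i in range(len(self._layers))
        ]
        if len(set(ids)) != len(ids):
            raise ValueError("layer_ids must be unique")
        if len(ids) != len(self._layers):
            raise ValueError("one layer_id per conv layer required")
        self.layer_ids = tuple(ids)
        # Derive activation shapes by tracing a dummy forward pass.
        shapes: dict[str, tuple[int, int, int]] = {}
        h, w = self.input_shape[:2]
        for lid, layer in zip(self.layer_ids, self._layers):
            h = -(-h // layer.stride)
            w = -(-w // layer.stride)
            shapes[lid] = (layer.weight.shape[-1], h, w)
        self.layer_shapes = shapes

    # -- construction ------------------------------------------------------

    @classmethod
    def seeded(
        cls,
        seed: int,
        input_size: int = 64,
        channels: Sequence[int] = (8, 12, 16),
        kernel_size: int = 3,
        stride: int = 2,
    ) -> "SmallCNNAdapter":
        rng = np.random.default_rng(seed)
        layers = []
        c_in = 3
        for c_out in channels:
            fan_in = kernel_size * kernel_size * c_in
            w = rng.standard_normal((kernel_size, kernel_size, c_in, c_out))
            w *= np.sqrt(2.0 / fan_in)
            layers.append(_ConvLayer(w, np.zeros(c_out), stride, "tanh"))
            c_in = c_out
        return cls(layers, (input_size, input_size, 3), input_offset=0.5)

    # -- forward / backward ------------------------------------------------

    def _forward(self, pixels: np.ndarray) -> list[np.ndarray]:
        """Post-nonlinearity activation tensors per layer, (n, H, W, C)."""
        x = pixels - self.input_offset
        acts = []
        for layer in self._layers:
            z = _conv_forward(x, layer.weight, layer.bias, layer.stride)
            x = np.tanh(z) if layer.nonlinearity == "tanh" else z
            acts.append(x)
        return acts

    @staticmethod
    def _flatten(a: np.ndarray) -> np.ndarray:
        # (n, H, W, C) -> (n, C*H*W) channel-major
        return np.transpose(a, (0, 3, 1, 2)).reshape(a.shape[0], -1)

    @staticmethod
    def _unflatten(g: np.ndarray, shape_chw: tuple[int, int, int]) -> np.ndarray:
        c, h, w = shape_chw
        return np.transpose(g.reshape(g.shape[0], c, h, w), (0, 2, 3, 1))

    def activations(self, pixels: np.ndarray) -> dict[str, np.ndarray]:
        pixels = self.check_input(pixels)
        acts = self._forward(pixels)
        return {lid: self._flatten(a) for lid, a in zip(self.layer_ids, acts)}

    def pixel_gradient(
        self, pixels: np.ndarray, cotangents: Mapping[str, np.ndarray]
    ) -> np.ndarray:
        pixels = self.check_input(pixels)
        for lid in cotangents:
            self.check_layer(lid)
        acts = self._forward(pixels)
        inputs = [pixels] + acts[:-1]
        g = np.zeros_like(acts[-1])
        for idx in range(len(self._layers) - 1, -1, -1):
            lid = self._layers[idx], self.layer_ids[idx]
            layer, name = lid[0], lid[1]
            if name in cotangents:
                ct = np.asarray(cotangents[name], dtype=np.float64)
                if ct.shape != (pixels.shape[0], self.n_units(name)):
                    raise ValueError(
                        f"cotangent for {name} must have shape "
                        f"({pixels.shape[0]}, {self.n_units(name)}); got {ct.shape}"
                    )
                g = g + self._unflatten(ct, self.layer_shapes[name])
            if layer.nonlinearity == "tanh":
                g = g * (1.0 - acts[idx] ** 2)
            g = _conv_backward_input(g, layer.weight, inputs[idx].shape, layer.stride)
        return g


# ---------------------------------------------------------------------------
# Inception-V1 adapter (requires torch + torchvision)
# ---------------------------------------------------------------------------

class InceptionV1Adapter(ModelAdapter):
    """Pretrained GoogLeNet exposing 12 layers: conv1-3 and all nine
    inception-block (mixed-pooling) concatenated outputs.

    The tensor tapped inside each inception block is the block's
    concatenated output (the default documented here); pass
    ``layer_overrides`` mapping layer_id to a module name to tap a
    different tensor.  CPU-only; requires torch and torchvision.
    """

    DEFAULT_LAYERS = (
        "conv1", "conv2", "conv3",
        "inception3a", "inception3b",
        "inception4a", "inception4b", "inception4c", "inception4d", "inception4e",
        "inception5a", "inception5b",
    )

    def __init__(self, layer_overrides: Mapping[str, str] | None = None) -> None:
        try:
            import torch  # noqa: F401
            import torchvision  # noqa: F401
        except ImportError as exc:  # pragma: no cover - torch not in test env
            raise ImportError(
                "InceptionV1Adapter requires torch and torchvision; install them "
                "or use the 'small_cnn' adapter"
            ) from exc
        self._torch = __import__("torch")
        tv = __import__("torchvision")
        self._model = tv.models.googlenet(weights="DEFAULT").eval()
        self.input_shape = (224, 224, 3)
        overrides = dict(layer_overrides or {})
        self._module_names = {
            lid: overrides.get(lid, lid) for lid in self.DEFAULT_LAYERS
        }
        self.layer_ids = tuple(self.DEFAULT_LAYERS)
        self.layer_shapes = self._trace_shapes()

    # pragma: no cover - exercised only when torch is available
    def _capture(self, x):
        torch = self._torch
        captured: dict[str, object] = {}
        hooks = []
        modules = dict(self._model.named_modules())
        for lid, mname in self._module_names.items():
            def make_hook(key):
                def hook(_m, _i, out):
                    captured[key] = out
                return hook
            hooks.append(modules[mname].register_forward_hook(make_hook(lid)))
        try:
            self._model(x)
        finally:
            for h in hooks:
                h.remove()
        return captured

    def _trace_shapes(self):  # pragma: no cover
        torch = self._torch
        with torch.no_grad():
            cap = self._capture(torch.zeros(1, 3, 224, 224))
        return {
            lid: tuple(int(s) for s in cap[lid].shape[1:]) for lid in self.layer_ids
        }

    def _to_torch(self, pixels):  # pragma: no cover
        torch = self._torch
        return torch.as_tensor(
            np.transpose(pixels, (0, 3, 1, 2)), dtype=torch.float32
        )

    def activations(self, pixels):  # pragma: no cover
        torch = self._torch
        pixels = self.check_input(pixels)
        with torch.no_grad():
            cap = self._capture(self._to_torch(pixels))
        return {
            lid: cap[lid].reshape(pixels.shape[0], -1).numpy().astype(np.float64)
            for lid in self.layer_ids
        }

    def pixel_gradient(self, pixels, cotangents):  # pragma: no cover
        torch = self._torch
        pixels = self.check_input(pixels)
        x = self._to_torch(pixels).requires_grad_(True)
        cap = self._capture(x)
        loss = None
        for lid, ct in cotangents.items():
            self.check_layer(lid)
            t = torch.as_tensor(ct, dtype=torch.float32)
            term = (cap[lid].reshape(pixels.shape[0], -1) * t).sum()
            loss = term if loss is None else loss + term
        loss.backward()
        return np.transpose(x.grad.numpy(), (0, 2, 3, 1)).astype(np.float64)


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., ModelAdapter]] = {}


def register_adapter(name: str, factory: Callable[..., ModelAdapter]) -> None:
    _REGISTRY[name] = factory


def create_adapter(name: str, **kwargs) -> ModelAdapter:
    if name not in _REGISTRY:
        raise KeyError(f"unknown adapter {name!r}; available: {sorted(_REGISTRY)}")
    return _REGISTRY[name](**kwargs)


def available_adapters() -> list[str]:
    return sorted(_REGISTRY)


register_adapter("small_cnn", lambda seed=0, **kw: SmallCNNAdapter.seeded(seed, **kw))
register_adapter("inception_v1", lambda **kw: InceptionV1Adapter(**kw))
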