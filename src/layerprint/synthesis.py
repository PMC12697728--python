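"""Two-phase pixel-space synthesis of layer-orthogonalized image sets.

Phase 1 ("diversify") turns seeded uniform noise into visually rich images
by gradient ascent on one learned feature channel per image, plus a penalty
encouraging a broad RGB distribution.  Phase 2 ("orthogonalize") jointly
updates all images by gradient descent on the sum of squared off-diagonal
second-order correlations, driving the layer RSMs apart.

The gradient of the orthogonality cost with respect to pixels is computed
analytically: the chain pixels -> activations -> first-order RSMs ->
triangle vectors -> second-order correlations -> cost is differentiated by
hand (the Pearson-correlation gradient appears twice), and the activation
cotangents are pulled back through the network by the adapter's
vector-Jacobian product.  Tests validate the whole chain against central
finite differences.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .adapters import ModelAdapter, StimulusSet
from .cnn_rsm import (
    DegenerateInputError,
    mean_adjacent,
    mean_offdiagonal,
    orthogonality_cost,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SynthesisConfig",
    "SynthesisTrace",
    "init_noise",
    "diversify_phase",
    "orthogonalize_phase",
    "synthesize",
    "natural_baseline",
    "som_from_pixels",
    "save_stimuli",
    "load_stimuli",
]


@dataclass
class SynthesisConfig:
    """Knobs of the two-phase synthesis.

    Defaults are the full-scale protocol (16 images at 224 x 224, 28,800
    diversification and 1,800 orthogonalization iterations); tests and the
    demo pipeline pass a desk-scale configuration instead.
    """

    n_images: int = 16
    image_size: tuple[int, int] = (224, 224)
    phase1_iters: int = 28_800
    phase2_iters: int = 1_800
    step_size: float = 0.05
    rgb_breadth_weight: float = 0.1
    seed: int = 0
    target_layer: str | None = None      # default: deepest adapter layer
    target_channels: Sequence[int] | None = None  # default: seeded distinct draw
    value_range: tuple[float, float] = (0.0, 1.0)
    max_restarts: int = 3                # fresh-noise restarts on degenerate RSMs

    def __post_init__(self) -> None:
        if self.phase1_iters < 0 or self.phase2_iters < 0:
            raise ValueError("iteration counts must be >= 0")
        if self.n_images < 2:
            raise ValueError("n_images must be >= 2")
        if self.target_channels is not None and len(self.target_channels) != self.n_images:
            raise ValueError("need one target channel per image")


@dataclass
class SynthesisTrace:
    cost_per_iteration: np.ndarray
    initial_som: np.ndarray
    final_som: np.ndarray
    final_images: StimulusSet


def init_noise(config: SynthesisConfig) -> StimulusSet:
    """I.i.d. uniform pixel noise in the declared range, reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.value_range
    h, w = config.image_size
    pixels = rng.uniform(lo, hi, size=(config.n_images, h, w, 3))
    return StimulusSet(pixels, value_range=config.value_range)


# ---------------------------------------------------------------------------
# Differentiable pieces (forward values + hand-derived gradients)
# ---------------------------------------------------------------------------

def _standardize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows centered and scaled to unit L2 norm; returns (z, norms)."""
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    if np.any(norms == 0):
        raise DegenerateInputError("zero-variance row encountered")
    return xc / norms[:, None], norms


def _som_forward(acts: dict[str, np.ndarray], layer_ids: Sequence[str]):
    """Forward pass from activations to the second-order matrix.

    Returns everything the backward pass needs: per-layer standardized
    patterns Z_l with norms, RSMs C_l, standardized triangle vectors u_l
    with norms, and the second-order matrix R.
    """
    n = next(iter(acts.values())).shape[0]
    iu = np.triu_indices(n, k=1)
    Zs, s_pat, Cs, us, s_tri = [], [], [], [], []
    for lid in layer_ids:
        z, norms = _standardize_rows(acts[lid])
        c = np.clip(z @ z.T, -1.0, 1.0)
        v = c[iu]
        vc = v - v.mean()
        nv = np.linalg.norm(vc)
        if nv == 0:
            raise DegenerateInputError(f"constant RSM triangle in layer {lid}")
        Zs.append(z)
        s_pat.append(norms)
        Cs.append(c)
        us.append(vc / nv)
        s_tri.append(nv)
    U = np.stack(us)                      # (L, m)
    R = np.clip(U @ U.T, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return Zs, s_pat, Cs, us, s_tri, R, iu


def _som_backward(Zs, s_pat, Cs, us, s_tri, R, iu) -> list[np.ndarray]:
    """Gradient of the off-diagonal sum of squares w.r.t. each layer's
    activation patterns.

    d cost / d R_ij = 4 R_ij for each unordered pair (both triangles are
    summed); the Pearson gradient d corr(u, v)/du = (v_hat - r u_hat)/||u_c||
    is applied first across layers (second order) and then across images
    (first order).
    """
    L = len(us)
    grads = []
    U = np.stack(us)
    # d cost / d u_l's raw triangle vector v_l
    W = 4.0 * R * (~np.eye(L, dtype=bool))           # (L, L) pair weights
    for l in range(L):
        # sum_j W[l, j] * (u_j - R[l, j] u_l) / s_tri[l]
        gv = (W[l] @ U - (W[l] @ R[l]) * us[l]) / s_tri[l]    # (m,)
        # scatter onto the symmetric RSM gradient
        n = Cs[l].shape[0]
        G = np.zeros((n, n))
        G[iu] = gv
        G = G + G.T
        # first-order Pearson gradient onto pattern rows
        z = Zs[l]
        row_scale = (G * Cs[l]).sum(axis=1)
        gA = (G @ z - row_scale[:, None] * z) / s_pat[l][:, None]
        grads.append(gA)
    return grads


def som_from_pixels(
    adapter: ModelAdapter, pixels: np.ndarray, layer_ids: Sequence[str] | None = None
) -> np.ndarray:
    """Second-order matrix of a pixel array under an adapter (no gradient)."""
    layer_ids = list(layer_ids or adapter.layer_ids)
    acts = adapter.activations(pixels)
    *_, R, _ = _som_forward(acts, layer_ids)
    return R


def _cost_and_pixel_grad(adapter: ModelAdapter, pixels: np.ndarray,
                         layer_ids: Sequence[str]):
    acts = adapter.activations(pixels)
    Zs, s_pat, Cs, us, s_tri, R, iu = _som_forward(acts, layer_ids)
    cost = orthogonality_cost(R)
    gA = _som_backward(Zs, s_pat, Cs, us, s_tri, R, iu)
    cotangents = {lid: g for lid, g in zip(layer_ids, gA)}
    gx = adapter.pixel_gradient(pixels, cotangents)
    return cost, gx, R


# ---------------------------------------------------------------------------
# Phase 1: per-image channel maximization with RGB-breadth penalty
# ---------------------------------------------------------------------------

def _pick_target_channels(adapter: ModelAdapter, layer: str, n: int,
                          seed: int) -> np.ndarray:
    n_channels = adapter.layer_shapes[layer][0]
    rng = np.random.default_rng(seed)
    if n <= n_channels:
        return rng.choice(n_channels, size=n, replace=False)
    return rng.choice(n_channels, size=n, replace=True)


def _breadth_penalty_grad(pixels: np.ndarray) -> tuple[float, np.ndarray]:
    """Penalty = -(mean over channels of the per-channel pixel SD) per image.

    Minimizing it broadens each color channel's distribution.  Returns the
    batch-summed penalty and its pixel gradient.
    """
    eps = 1e-8
    n = pixels.shape[0]
    flat = pixels.reshape(n, -1, 3)                   # (n, HW, 3)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1) + eps                       # (n, 3)
    penalty = float(-(sd - eps).mean(axis=1).sum())
    npix = flat.shape[1]
    g = -(flat - mu) / (npix * sd[:, None, :]) / 3.0
    return penalty, g.reshape(pixels.shape)


def diversify_phase(
    stimuli: StimulusSet, adapter: ModelAdapter, config: SynthesisConfig
) -> StimulusSet:
    """Gradient ascent on one target channel per image (phase 1)."""
    layer = config.target_layer or adapter.layer_ids[-1]
    adapter.check_layer(layer)
    if config.target_channels is not None:
        channels = np.asarray(config.target_channels, dtype=int)
    else:
        channels = _pick_target_channels(adapter, layer, stimuli.n_images,
                                         config.seed)
    pixels = stimuli.pixels.copy()
    lo, hi = stimuli.value_range
    n = stimuli.n_images
    n_units = adapter.layer_shapes[layer]
    ch_size = n_units[1] * n_units[2]
    for _ in range(config.phase1_iters):
        ct = np.zeros((n, adapter.n_units(layer)))
        for k in range(n):
            sl = adapter.channel_slice(layer, int(channels[k]))
            ct[k, sl] = -1.0 / ch_size          # loss = -mean(channel activation)
        g_act = adapter.pixel_gradient(pixels, {layer: ct})
        _, g_pen = _breadth_penalty_grad(pixels)
        g = g_act + config.rgb_breadth_weight * g_pen
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite loss gradient in diversify phase")
        pixels = np.clip(pixels - config.step_size * g, lo, hi)
    return StimulusSet(pixels, list(stimuli.image_ids), stimuli.value_range)


# ---------------------------------------------------------------------------
# Phase 2: joint orthogonalization of the layer RSMs
# ---------------------------------------------------------------------------

def orthogonalize_phase(
    stimuli: StimulusSet, adapter: ModelAdapter, config: SynthesisConfig
) -> SynthesisTrace:
    """Joint gradient descent of all images against the orthogonality cost."""
    if len(adapter.layer_ids) < 2:
        raise ValueError("adapter must expose at least 2 layers")
    layer_ids = list(adapter.layer_ids)
    lo, hi = stimuli.value_range

    for attempt in range(config.max_restarts + 1):
        pixels = (stimuli.pixels.copy() if attempt == 0
                  else init_noise(SynthesisConfig(
                      n_images=config.n_images, image_size=stimuli.pixels.shape[1:3],
                      seed=config.seed + 1000 + attempt,
                      value_range=stimuli.value_range)).pixels)
        try:
            initial_som = som_from_pixels(adapter, pixels, layer_ids)
            # costs[i] is the cost after update i, so the trace ends at the
            # final image set's cost
            costs: list[float] = []
            for it in range(config.phase2_iters):
                cost, gx, _ = _cost_and_pixel_grad(adapter, pixels, layer_ids)
                if it > 0:
                    costs.append(cost)
                pixels = np.clip(pixels - config.step_size * gx, lo, hi)
            final_som = som_from_pixels(adapter, pixels, layer_ids)
            if config.phase2_iters > 0:
                costs.append(orthogonality_cost(final_som))
            final = StimulusSet(pixels, list(stimuli.image_ids), stimuli.value_range)
            return SynthesisTrace(np.asarray(costs), initial_som, final_som, final)
        except DegenerateInputError:
            logger.warning(
                "degenerate RSM during orthogonalization (attempt %d); "
                "restarting from fresh noise", attempt + 1,
            )
    raise DegenerateInputError(
        f"orthogonalization failed after {config.max_restarts} fresh-noise restarts"
    )


def synthesize(adapter: ModelAdapter, config: SynthesisConfig) -> SynthesisTrace:
    """Full protocol: noise init, diversify, then orthogonalize."""
    stimuli = init_noise(config)
    stimuli = diversify_phase(stimuli, adapter, config)
    return orthogonalize_phase(stimuli, adapter, config)


# ---------------------------------------------------------------------------
# Baseline: random image sets drawn from a library
# ---------------------------------------------------------------------------

def natural_baseline(
    adapter: ModelAdapter,
    image_library: StimulusSet,
    set_size: int,
    n_sets: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Distribution of mean off-diagonal second-order correlations over
    random subsets of an image library (the comparison distribution for the
    synthesized set), plus the adjacent-layer-only variant."""
    n_lib = image_library.n_images
    if n_lib < set_size:
        raise ValueError(f"library has {n_lib} images; need at least {set_size}")
    rng = np.random.default_rng(seed)
    mean_off = np.empty(n_sets)
    mean_adj = np.empty(n_sets)
    for s in range(n_sets):
        idx = rng.choice(n_lib, size=set_size, replace=False)
        som = som_from_pixels(adapter, image_library.pixels[idx])
        mean_off[s] = mean_offdiagonal(som)
        mean_adj[s] = mean_adjacent(som)
    return {"mean_offdiag": mean_off, "mean_adjacent": mean_adj}


# ---------------------------------------------------------------------------
# I/O: 8-bit PNG for viewing + lossless float sidecar for exact state
# ---------------------------------------------------------------------------

def save_stimuli(stimuli: StimulusSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lo, hi = stimuli.value_range
    for i, iid in enumerate(stimuli.image_ids):
        arr8 = np.round((stimuli.pixels[i] - lo) / (hi - lo) * 255).astype(np.uint8)
        Image.fromarray(arr8, mode="RGB").save(out / f"{iid}.png")
    np.savez_compressed(out / "stimuli.npz", pixels=stimuli.pixels)
    (out / "stimuli.json").write_text(json.dumps({
        "image_ids": list(stimuli.image_ids),
        "value_range": list(stimuli.value_range),
    }))


def load_stimuli(in_dir: str | Path) -> StimulusSet:
    src = Path(in_dir)
    meta = json.loads((src / "stimuli.json").read_text())
    pixels = np.load(src / "stimuli.npz")["pixels"]
    return StimulusSet(pixels, meta["image_ids"], tuple(meta["value_range"]))
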