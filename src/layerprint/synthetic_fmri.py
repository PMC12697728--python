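"""Synthetic beta maps (and BOLD) with known representational ground truth.

Designated cubic regions of a voxel grid carry the representational
geometry of designated model layers: region voxels are drawn column-wise
from a zero-mean multivariate normal across images whose covariance equals
the target layer RSM, so the expected image-by-image correlation matrix of
the region is exactly that RSM.  Patterns are shared across runs within a
participant, jittered additively across participants, and perturbed by
i.i.d. run noise; everything else is pure noise.  This gives every
searchlight/mapping analysis a testable ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cnn_rsm import LayerRSM
from .design_glm import BetaMaps, DesignMatrix, TrialSequence, build_design

__all__ = [
    "Region",
    "GroundTruthSpec",
    "embed_rsm",
    "simulate_betamaps",
    "simulate_bold",
    "cube_region",
]


@dataclass
class Region:
    """A set of grid voxels carrying one layer's geometry."""

    voxels: np.ndarray        # (k, 3) integer grid coordinates
    layer_id: str
    signal_scale: float = 1.0

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        if self.voxels.ndim != 2 or self.voxels.shape[1] != 3:
            raise ValueError("voxels must be a (k, 3) coordinate array")


@dataclass
class GroundTruthSpec:
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    regions: Sequence[Region] = field(default_factory=list)
    noise_sd: float = 1.0
    n_participants: int = 8
    n_runs: int = 8
    participant_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        grid = np.asarray(self.grid_shape)
        seen: set[tuple[int, ...]] = set()
        for reg in self.regions:
            if np.any(reg.voxels < 0) or np.any(reg.voxels >= grid):
                raise ValueError(f"region voxels outside grid for {reg.layer_id}")
            coords = {tuple(v) for v in reg.voxels}
            if seen & coords:
                raise ValueError("regions must be disjoint")
            seen |= coords


def cube_region(center: Sequence[int], half_width: int, layer_id: str,
                signal_scale: float = 1.0) -> Region:
    """Convenience: a cubic region of side ``2*half_width + 1``."""
    c = np.asarray(center, dtype=int)
    rng = np.arange(-half_width, half_width + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    return Region(grid + c, layer_id, signal_scale)


# ---------------------------------------------------------------------------
# Geometry embedding
# ---------------------------------------------------------------------------

def embed_rsm(target: LayerRSM | np.ndarray, n_voxels: int,
              seed: int | np.random.Generator = 0) -> np.ndarray:
    """(n_images, n_voxels) patterns whose expected image-correlation matrix
    equals ``target``.

    Voxel columns are i.i.d. draws from N(0, target).  The target is
    symmetrized and eigenvalues within numerical noise of zero are floored;
    a genuinely non-PSD input is rejected.  With ``n_voxels == 1`` the
    patterns are returned without validation (no correlation is computable).
    """
    values = target.values if isinstance(target, LayerRSM) else np.asarray(target)
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    sym = (values + values.T) / 2.0
    w, V = np.linalg.eigh(sym)
    if w.min() < -1e-8:
        raise ValueError(f"target matrix is not positive semidefinite "
                         f"(min eigenvalue {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    L = V * np.sqrt(w)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return L @ rng.standard_normal((values.shape[0], n_voxels))


# ---------------------------------------------------------------------------
# Beta-map simulation
# ---------------------------------------------------------------------------

def _region_flat_indices(mask: np.ndarray, region: Region) -> np.ndarray:
    """Indices of region voxels in the masked-vector (C-order) layout."""
    lin = np.full(mask.shape, -1, dtype=int)
    lin[mask] = np.arange(int(mask.sum()))
    idx = lin[tuple(region.voxels.T)]
    if np.any(idx < 0):
        raise ValueError("region voxel outside the mask")
    return idx


def simulate_betamaps(
    spec: GroundTruthSpec,
    layer_rsms: Mapping[str, LayerRSM | np.ndarray],
) -> tuple[dict[tuple[int, int], BetaMaps], dict]:
    """Per-(participant, run) beta maps plus a ground-truth record.

    Returns ``(betamaps, truth)`` where ``betamaps[(p, r)]`` is a
    :class:`BetaMaps` over the full-grid mask and ``truth`` records the
    regions, source layers, scales and seed.
    """
    for reg in spec.regions:
        if reg.layer_id not in layer_rsms:
            raise KeyError(f"no RSM supplied for layer {reg.layer_id!r}")
    first = next(iter(layer_rsms.values())) if layer_rsms else None
    n_images = (first.n if isinstance(first, LayerRSM)
                else np.asarray(first).shape[0]) if first is not None else 16
    image_ids = [f"img{i:02d}" for i in range(n_images)]
    mask = np.ones(spec.grid_shape, dtype=bool)
    n_mask = int(mask.sum())

    ss = np.random.SeedSequence(spec.seed)
    base_ss, jitter_ss, noise_ss = ss.spawn(3)

    # group-level region patterns
    base_rng = np.random.default_rng(base_ss)
    base_patterns = []
    for reg in spec.regions:
        base_patterns.append(embed_rsm(layer_rsms[reg.layer_id],
                                       len(reg.voxels), base_rng))

    jitter_rng = np.random.default_rng(jitter_ss)
    noise_rng = np.random.default_rng(noise_ss)
    out: dict[tuple[int, int], BetaMaps] = {}
    for p in range(spec.n_participants):
        participant_patterns = []
        for reg, base in zip(spec.regions, base_patterns):
            jit = jitter_rng.standard_normal(base.shape) * spec.participant_sd
            participant_patterns.append(base + jit)
        for r in range(spec.n_runs):
            values = noise_rng.standard_normal((n_images, n_mask)) * spec.noise_sd
            for reg, pat in zip(spec.regions, participant_patterns):
                idx = _region_flat_indices(mask, reg)
                values[:, idx] += reg.signal_scale * pat
            out[(p, r)] = BetaMaps(values, mask, image_ids,
                                   run_id=f"sub{p:02d}_run{r:02d}")
    truth = {
        "grid_shape": list(spec.grid_shape),
        "regions": [
            {"layer_id": reg.layer_id, "signal_scale": reg.signal_scale,
             "n_voxels": int(len(reg.voxels)),
             "voxels": reg.voxels.tolist()}
            for reg in spec.regions
        ],
        "noise_sd": spec.noise_sd,
        "participant_sd": spec.participant_sd,
        "n_participants": spec.n_participants,
        "n_runs": spec.n_runs,
        "seed": spec.seed,
    }
    return out, truth


def save_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


# ---------------------------------------------------------------------------
# BOLD simulation
# ---------------------------------------------------------------------------

def simulate_bold(
    spec: GroundTruthSpec,
    seq: TrialSequence,
    layer_rsms: Mapping[str, LayerRSM | np.ndarray],
    tr_s: float = 1.5,
    n_volumes: int = 250,
    bold_noise_sd: float = 0.0,
    ar1_coef: float = 0.0,
) -> tuple[dict[tuple[int, int], np.ndarray], dict[tuple[int, int], BetaMaps], DesignMatrix]:
    """Time series ``design @ betas + noise`` per (participant, run).

    Optional AR(1) noise (coefficient ``ar1_coef``) supports robustness
    tests; the default is white noise.  Feeding the output through
    :func:`layerprint.design_glm.fit_glm` recovers the simulated betas.
    """
    betamaps, _truth = simulate_betamaps(spec, layer_rsms)
    any_bm = next(iter(betamaps.values()))
    design = build_design(seq, tr_s=tr_s, n_volumes=n_volumes,
                          image_ids=any_bm.image_ids)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7_654_321]))
    bold: dict[tuple[int, int], np.ndarray] = {}
    for key, bm in betamaps.items():
        series = design.values @ bm.values
        if bold_noise_sd > 0:
            eps = rng.standard_normal(series.shape) * bold_noise_sd
            if ar1_coef != 0.0:
                for t in range(1, eps.shape[0]):
                    eps[t] += ar1_coef * eps[t - 1]
            series = series + eps
        bold[key] = series
    return bold, betamaps, design
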