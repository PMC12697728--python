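"""Cubic searchlights and the representational-stability analysis.

Around every in-mask voxel a 7 x 7 x 7 cube (clipped at volume borders and
intersected with the mask) defines a local pattern.  Stability contrasts the
mean correlation of same-image patterns across runs (with 16 images and 8
runs: C(8,2) x 16 = 448 pairings) against a null distribution built by
repeatedly subsampling that many values from all between-image cross-run
correlations (C(8,2) x 16 x 15 = 6,720 ordered-image pairings) and
averaging; the statistic is the z-score of the within-image mean under that
null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .cnn_rsm import DegenerateInputError, LayerRSM, compute_rsm
from .design_glm import BetaMaps

__all__ = [
    "SearchlightIndex",
    "StatMap",
    "enumerate_searchlights",
    "searchlight_rsm",
    "count_pairings",
    "stability_z",
    "stability_map",
    "save_statmap",
    "load_statmap",
]


@dataclass
class SearchlightIndex:
    center: tuple[int, int, int]
    voxel_ids: np.ndarray     # flat indices into the masked-vector layout

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        if self.voxel_ids.size > 343:
            raise ValueError("a 7x7x7 searchlight cannot exceed 343 voxels")


@dataclass
class StatMap:
    """One statistic per in-mask voxel; undefined centers are NaN-flagged."""

    values: np.ndarray        # 3-D grid, NaN outside mask / where undefined
    mask: np.ndarray
    statistic_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a grid")


def enumerate_searchlights(
    mask: np.ndarray, half_width: int = 3
) -> list[SearchlightIndex]:
    """One clipped, mask-intersected cube per in-mask voxel."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    lin = np.full(mask.shape, -1, dtype=int)
    lin[mask] = np.arange(int(mask.sum()))
    out = []
    for center in np.argwhere(mask):
        lo = np.maximum(center - half_width, 0)
        hi = np.minimum(center + half_width + 1, mask.shape)
        sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        ids = lin[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][sub]
        out.append(SearchlightIndex(tuple(int(c) for c in center), ids))
    return out


def searchlight_rsm(betas: BetaMaps, sl: SearchlightIndex) -> LayerRSM:
    """Image-by-image RSM of the beta patterns inside one searchlight."""
    if sl.voxel_ids.size < 2:
        raise ValueError("searchlight needs at least 2 voxels")
    return compute_rsm(betas.values[:, sl.voxel_ids])


def count_pairings(n_images: int, n_runs: int) -> tuple[int, int]:
    """(within, between) comparison counts across runs.

    Within: every unordered run pair for each image, C(R,2) x n.  Between:
    ordered image pairs across unordered run pairs, C(R,2) x n x (n-1) —
    image A in run 1 vs. B in run 2 and B in run 1 vs. A in run 2 are both
    counted, which is what yields 6,720 for 16 images and 8 runs.
    """
    if n_runs < 2 or n_images < 2:
        raise ValueError("need n_runs >= 2 and n_images >= 2")
    pairs = comb(n_runs, 2)
    return pairs * n_images, pairs * n_images * (n_images - 1)


# ---------------------------------------------------------------------------
# Stability statistic
# ---------------------------------------------------------------------------

def _cross_run_correlations(patterns: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within/between correlation values from (n_runs, n_images, k) patterns."""
    R, n, k = patterns.shape
    if k < 2:
        raise ValueError("searchlight needs at least 2 voxels")
    centered = patterns - patterns.mean(axis=2, keepdims=True)
    norms = np.linalg.norm(centered, axis=2)
    if np.any(norms == 0):
        raise DegenerateInputError("constant pattern in searchlight")
    z = centered / norms[:, :, None]
    within, between = [], []
    for r in range(R):
        for s in range(r + 1, R):
            cc = z[r] @ z[s].T            # (n, n): image_r x image_s
            within.append(np.diag(cc))
            off = cc[~np.eye(n, dtype=bool)]
            between.append(off)
    # canonical (sorted) order makes the seeded subsampling — and hence the
    # z — exactly invariant to image relabeling and run order
    return np.concatenate(within), np.sort(np.concatenate(between))


def _subsample_means(values: np.ndarray, m: int, n_resamples: int,
                     rng: np.random.Generator, chunk: int = 250) -> np.ndarray:
    """Means of ``n_resamples`` size-``m`` subsamples drawn without
    replacement, vectorized in chunks (random-key argpartition)."""
    N = values.size
    if m > N:
        raise ValueError("subsample larger than population")
    out = np.empty(n_resamples)
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
        out[done:done + b] = values[idx].mean(axis=1)
        done += b
    return out


def stability_z(
    run_betas: Sequence[BetaMaps] | np.ndarray,
    sl: SearchlightIndex | None = None,
    n_resamples: int = 5000,
    seed: int = 0,
) -> float:
    """Representational-stability z for one searchlight.

    ``run_betas`` is either a sequence of per-run :class:`BetaMaps` (with
    ``sl`` selecting the voxels) or a pre-extracted
    ``(n_runs, n_images, k)`` pattern array.  The subsample size equals this
    data set's own within count, matching the number of values averaged into
    the within-image estimate.
    """
    if isinstance(run_betas, np.ndarray):
        patterns = run_betas
    else:
        if sl is None:
            raise ValueError("sl is required with BetaMaps input")
        patterns = np.stack([bm.values[:, sl.voxel_ids] for bm in run_betas])
    if patterns.shape[0] < 2:
        raise ValueError("need at least 2 runs")
    within, between = _cross_run_correlations(patterns)
    rng = np.random.default_rng(seed)
    null = _subsample_means(between, within.size, n_resamples, rng)
    sd = null.std()
    if sd == 0:
        raise DegenerateInputError("null distribution has zero SD")
    return float((within.mean() - null.mean()) / sd)


def stability_map(
    run_betas: Sequence[BetaMaps],
    mask: np.ndarray | None = None,
    half_width: int = 3,
    n_resamples: int = 5000,
    master_seed: int = 0,
) -> StatMap:
    """Stability z at every searchlight center.

    Per-center seeds derive from ``(master_seed, center_flat_index)`` so the
    map does not depend on evaluation order; undefined centers (degenerate
    patterns or < 2 voxels) are recorded as NaN.
    """
    mask = run_betas[0].mask if mask is None else np.asarray(mask, dtype=bool)
    values = np.full(mask.shape, np.nan)
    stacked = np.stack([bm.values for bm in run_betas])  # (R, n, V)
    for sl in enumerate_searchlights(mask, half_width):
        flat = int(np.ravel_multi_index(sl.center, mask.shape))
        seed = np.random.SeedSequence([master_seed, flat])
        if sl.voxel_ids.size < 2:
            continue
        patterns = stacked[:, :, sl.voxel_ids]
        try:
            z = stability_z(patterns, n_resamples=n_resamples,
                            seed=np.random.default_rng(seed).integers(2**31))
        except DegenerateInputError:
            continue
        values[sl.center] = z
    return StatMap(values, mask, statistic_name="stability_z")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_statmap(stat: StatMap, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(stat.values, affine=np.eye(4)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "statistic_name": stat.statistic_name, "params": params or {},
    }))


def load_statmap(path: str | Path) -> StatMap:
    path = Path(path)
    values = np.asarray(nib.load(str(path)).get_fdata())
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    return StatMap(values, ~np.isnan(values), statistic_name=meta["statistic_name"])
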