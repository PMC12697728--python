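"""Overlap of thresholded layer maps and bootstrap comparison across regimes.

The overlap of base map M with map N is |M ∩ N| / |M| — the fraction of M's
significant voxels shared with N — giving a generally asymmetric L x L
matrix (if M ⊂ N with |N| = 2|M|, then M:N = 1.0 but N:M = 0.5).  Layers
with no significant voxels have undefined rows and are excluded from
summary means.  Mean overlap for one image regime is compared against a
bootstrap distribution built by resampling per-image-set means with
replacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OverlapMatrix",
    "overlap_ratio",
    "overlap_matrix",
    "mean_overlap",
    "bootstrap_compare",
    "save_overlap_csv",
    "load_overlap_csv",
]


@dataclass
class OverlapMatrix:
    values: np.ndarray        # (L, L); NaN where the base row is undefined
    layer_ids: list[str]
    defined: np.ndarray       # (L,) bool; False for layers with empty maps

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.defined = np.asarray(self.defined, dtype=bool)
        L = len(self.layer_ids)
        if self.values.shape != (L, L):
            raise ValueError("values must be (L, L)")


def _as_set(voxels) -> frozenset:
    if isinstance(voxels, np.ndarray):
        if voxels.dtype == bool:
            return frozenset(map(tuple, np.argwhere(voxels)))
        return frozenset(map(tuple, np.atleast_2d(voxels)))
    return frozenset(voxels)


def overlap_ratio(map_m, map_n) -> float:
    """|M ∩ N| / |M|; NaN (undefined) when the base map M is empty."""
    M, N = _as_set(map_m), _as_set(map_n)
    if not M:
        return float("nan")
    return len(M & N) / len(M)


def overlap_matrix(sig_maps: Mapping[str, object]) -> OverlapMatrix:
    """All ordered layer pairs; empty base layers give undefined (NaN) rows."""
    layer_ids = list(sig_maps)
    if len(layer_ids) < 2:
        raise ValueError("need at least 2 layers")
    sets = {lid: _as_set(sig_maps[lid]) for lid in layer_ids}
    L = len(layer_ids)
    values = np.full((L, L), np.nan)
    defined = np.array([len(sets[lid]) > 0 for lid in layer_ids])
    for i, mi in enumerate(layer_ids):
        if not defined[i]:
            continue
        for j, mj in enumerate(layer_ids):
            values[i, j] = overlap_ratio(sets[mi], sets[mj])
    return OverlapMatrix(values, layer_ids, defined)


def mean_overlap(matrix: OverlapMatrix, mode: str = "all_offdiag") -> float:
    """Mean over the defined entries of the selected band.

    ``all_offdiag``: every off-diagonal entry.  ``adjacent``: the first
    off-diagonals only (one step above and below the diagonal).  Layers with
    no significant voxels are excluded entirely — as base and as comparison —
    so an empty map neither contributes undefined rows nor drags the mean
    down with zero ratios.
    """
    L = len(matrix.layer_ids)
    if mode == "all_offdiag":
        band = ~np.eye(L, dtype=bool)
    elif mode == "adjacent":
        band = np.zeros((L, L), dtype=bool)
        idx = np.arange(L - 1)
        band[idx, idx + 1] = True
        band[idx + 1, idx] = True
    else:
        raise ValueError("mode must be 'all_offdiag' or 'adjacent'")
    band &= np.outer(matrix.defined, matrix.defined)
    vals = matrix.values[band]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no defined off-diagonal entries")
    return float(vals.mean())


def bootstrap_compare(
    observed_mean: float,
    per_set_means: Sequence[float],
    n_boot: int = 5000,
    seed: int = 0,
    alternative: str = "less",
) -> tuple[float, np.ndarray]:
    """Bootstrap test of the observed mean against per-image-set means.

    Resamples the per-set means with replacement ``n_boot`` times, takes the
    grand mean of each resample, and returns the add-one p-value with the
    bootstrap distribution.  ``alternative='less'`` (default) asks whether
    the observed mean is lower than the distribution — the direction in
    which synthesis is expected to reduce overlap; ``'two-sided'`` doubles
    the smaller tail.
    """
    per_set_means = np.asarray(per_set_means, dtype=np.float64)
    if per_set_means.size == 0:
        raise ValueError("per_set_means must be nonempty")
    rng = np.random.default_rng(seed)
    k = per_set_means.size
    idx = rng.integers(0, k, size=(n_boot, k))
    dist = per_set_means[idx].mean(axis=1)
    p_less = (1 + np.sum(dist <= observed_mean)) / (1 + n_boot)
    if alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p_greater = (1 + np.sum(dist >= observed_mean)) / (1 + n_boot)
        p = min(1.0, 2 * min(p_less, p_greater))
    else:
        raise ValueError("alternative must be 'less' or 'two-sided'")
    return float(p), dist


def save_overlap_csv(matrix: OverlapMatrix, path: str | Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.layer_ids,
                 columns=matrix.layer_ids).to_csv(path, float_format="%.17g")


def load_overlap_csv(path: str | Path) -> OverlapMatrix:
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=np.float64)
    defined = ~np.all(np.isnan(values), axis=1)
    return OverlapMatrix(values, [str(c) for c in df.columns], defined)
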