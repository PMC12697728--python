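"""Representational similarity matrices and the second-order layer geometry.

A first-order RSM correlates the unit-activation patterns evoked by every
pair of images within one layer.  Vectorizing each layer's RSM (strict upper
triangle, row-major) and correlating the vectors across layers yields the
L x L second-order matrix; its off-diagonal sum of squares is the
orthogonalization cost that image synthesis minimizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .adapters import ModelAdapter, StimulusSet

__all__ = [
    "LayerRSM",
    "DegenerateInputError",
    "extract_activations",
    "compute_rsm",
    "upper_triangle",
    "from_upper_triangle",
    "second_order_matrix",
    "orthogonality_cost",
    "mean_offdiagonal",
    "mean_adjacent",
    "save_matrix_csv",
    "load_matrix_csv",
]


class DegenerateInputError(ValueError):
    """A pattern or RSM triangle has zero variance, so a Pearson correlation
    is undefined.  Raised eagerly instead of propagating NaN."""


@dataclass
class LayerRSM:
    """An n_images x n_images Pearson-correlation matrix for one layer."""

    values: np.ndarray
    layer_id: str = ""
    image_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape != (n, n):
            raise ValueError("RSM must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("RSM must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("RSM must have a unit diagonal")
        if self.values.min() < -1 - 1e-10 or self.values.max() > 1 + 1e-10:
            raise ValueError("RSM entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def extract_activations(
    adapter: ModelAdapter, stimuli: StimulusSet
) -> dict[str, np.ndarray]:
    """Flattened per-layer activation patterns, ``layer -> (n_images, n_units)``."""
    return adapter.activations(stimuli.pixels)


def compute_rsm(patterns: np.ndarray, layer_id: str = "") -> LayerRSM:
    """Pearson-correlate every pair of rows of an (n_images, n_units) table.

    Raises
    ------
    DegenerateInputError
        If any row is constant (zero variance), or n_units < 2.
    """
    patterns = np.asarray(patterns, dtype=np.float64)
    if patterns.ndim != 2:
        raise ValueError("patterns must be 2-D (n_images, n_units)")
    if patterns.shape[1] < 2:
        raise ValueError("need at least 2 units per pattern")
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0).tolist()
        raise DegenerateInputError(f"zero-variance activation pattern(s) at rows {bad}")
    values = np.corrcoef(patterns)
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    # corrcoef can break exact symmetry in the last ulp
    values = (values + values.T) / 2.0
    return LayerRSM(values, layer_id=layer_id)


def upper_triangle(rsm: LayerRSM | np.ndarray) -> np.ndarray:
    """Strict upper triangle in fixed row-major order, length n(n-1)/2.

    This ordering is a format guarantee: every downstream regression consumes
    vectors produced here, and :func:`from_upper_triangle` inverts it.
    """
    values = rsm.values if isinstance(rsm, LayerRSM) else np.asarray(rsm)
    n = values.shape[0]
    if n < 3:
        raise ValueError(
            f"RSM must be at least 3 x 3 to vectorize (got {n}); a shorter "
            "triangle cannot be correlated downstream"
        )
    iu = np.triu_indices(n, k=1)
    return values[iu].copy()


def from_upper_triangle(vec: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric unit-diagonal matrix from its strict upper triangle."""
    vec = np.asarray(vec, dtype=np.float64)
    m = vec.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    out = np.eye(n)
    iu = np.triu_indices(n, k=1)
    out[iu] = vec
    out[(iu[1], iu[0])] = vec
    return out


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    uc = u - u.mean()
    vc = v - v.mean()
    nu, nv = np.linalg.norm(uc), np.linalg.norm(vc)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("constant RSM upper triangle")
    return float(np.clip(uc @ vc / (nu * nv), -1.0, 1.0))


def second_order_matrix(rsms: Sequence[LayerRSM]) -> np.ndarray:
    """L x L Pearson correlations between the layers' vectorized RSMs."""
    if len(rsms) < 2:
        raise ValueError("need at least 2 layer RSMs")
    n = rsms[0].n
    if any(r.n != n for r in rsms):
        raise ValueError("all RSMs must have the same number of images")
    vecs = [upper_triangle(r) for r in rsms]
    L = len(vecs)
    out = np.eye(L)
    for i in range(L):
        for j in range(i + 1, L):
            out[i, j] = out[j, i] = _pearson(vecs[i], vecs[j])
    return out


def orthogonality_cost(som: np.ndarray) -> float:
    """Sum of squared off-diagonal second-order correlations (both triangles).

    Zero iff all layer pairs are perfectly decorrelated.  The unit diagonal
    is excluded: it would add a constant with zero gradient.
    """
    som = np.asarray(som, dtype=np.float64)
    off = som - np.diag(np.diag(som))
    return float(np.sum(off**2))


def _offdiag_mask(L: int) -> np.ndarray:
    return ~np.eye(L, dtype=bool)


def mean_offdiagonal(som: np.ndarray) -> float:
    """Mean of all off-diagonal second-order correlations (signed)."""
    som = np.asarray(som)
    return float(som[_offdiag_mask(som.shape[0])].mean())


def mean_adjacent(som: np.ndarray) -> float:
    """Mean over the first off-diagonals (adjacent layers, above and below)."""
    som = np.asarray(som)
    L = som.shape[0]
    band = np.concatenate([np.diagonal(som, 1), np.diagonal(som, -1)])
    if L < 2:
        raise ValueError("need at least 2 layers")
    return float(band.mean())


# ---------------------------------------------------------------------------
# CSV serialization (ids as headers; round-trip exact to 15 significant digits)
# ---------------------------------------------------------------------------

def save_matrix_csv(path: str | Path, values: np.ndarray, ids: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=np.float64), index=list(ids),
                      columns=list(ids))
    df.to_csv(path, float_format="%.17g")


def load_matrix_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0)
    return df.to_numpy(dtype=np.float64), [str(c) for c in df.columns]
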