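"""Mapping model layers to the brain.

For each searchlight and layer, a leave-one-participant-out (LOPO)
regression predicts the held-out participant's searchlight RSM triangle
from the layer RSM triangle: the remaining participants' triangles are
averaged, a slope+intercept regression of that average on the layer vector
is fit, and the prediction is scored on the held-out triangle with
out-of-sample R-squared (1 - SS_res/SS_tot, not clipped at zero).  R-squared
is normalized to a z-score against a permutation null that shuffles every
participant's triangle entries independently and reruns the whole LOPO
procedure (500 permutations by default).

The residual method isolates a layer's unique contribution: all vectors are
z-scored, the searchlight triangle is residualized on the other layers'
triangles (coefficients estimated on the training-fold average and applied
to the held-out vector, preventing leakage), and the held-out layer is fit
to the residuals with a simple regression.

Group-level significance uses a one-sample t-test per center with
family-wise correction by sign-flip max-statistic permutation — a
self-contained substitute for cluster-enhanced randomization tools, trading
cluster sensitivity for portability.  Per-participant z maps can be
exported as a 4-D NIfTI for external cluster-based correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cnn_rsm import DegenerateInputError, LayerRSM, upper_triangle
from .design_glm import BetaMaps
from .searchlight import SearchlightIndex, StatMap, enumerate_searchlights

__all__ = [
    "LayerFitResult",
    "SignificanceMap",
    "lopo_fit",
    "permutation_null",
    "fit_layer",
    "searchlight_vectors",
    "zmap_for_layer",
    "residual_fit",
    "residualize",
    "group_inference",
    "max_layer_labels",
]


@dataclass
class LayerFitResult:
    layer_id: str
    r_squared: np.ndarray     # one per held-out participant
    null_mean: float          # of the across-fold-mean R^2 under permutation
    null_sd: float

    @property
    def z(self) -> np.ndarray:
        """Per-participant z against the across-fold-mean null."""
        return (self.r_squared - self.null_mean) / self.null_sd

    @property
    def z_mean(self) -> float:
        """Center-level z: the across-fold mean R^2 against its own null.

        Under a true null this is one more draw from the permutation
        distribution, so it is approximately standard normal; it equals the
        average of the per-participant z values.
        """
        return float((self.r_squared.mean() - self.null_mean) / self.null_sd)


@dataclass
class SignificanceMap:
    significant: np.ndarray   # boolean grid (or flat boolean over centers)
    alpha: float
    correction_name: str


# ---------------------------------------------------------------------------
# LOPO regression
# ---------------------------------------------------------------------------

def _lopo_r2(Y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized LOPO R-squared.

    Y has shape (..., P, m): per-participant vectors (leading axes may index
    permutations).  For each fold h, the training average over the other
    participants is regressed on x (slope+intercept), the fitted line
    evaluated at x is the prediction, and R^2 is scored against Y[..., h, :].
    """
    P, m = Y.shape[-2], Y.shape[-1]
    xc = x - x.mean()
    xvar = xc @ xc
    if xvar == 0:
        raise DegenerateInputError("layer vector is constant")
    total = Y.sum(axis=-2, keepdims=True)
    train_mean = (total - Y) / (P - 1)                 # (..., P, m)
    slope = (train_mean @ xc) / xvar                   # (..., P)
    intercept = train_mean.mean(axis=-1) - slope * x.mean()
    pred = slope[..., None] * x + intercept[..., None]
    ss_res = ((Y - pred) ** 2).sum(axis=-1)
    y_mean = Y.mean(axis=-1, keepdims=True)
    ss_tot = ((Y - y_mean) ** 2).sum(axis=-1)
    if np.any(ss_tot == 0):
        raise DegenerateInputError("zero-variance held-out vector")
    return 1.0 - ss_res / ss_tot


def lopo_fit(vectors: np.ndarray, layer_vector: np.ndarray) -> np.ndarray:
    """Out-of-sample R-squared per held-out participant.

    ``vectors`` is (n_participants, m) of searchlight RSM triangles;
    ``layer_vector`` is the layer RSM triangle (length m).
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    layer_vector = np.asarray(layer_vector, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[1] != layer_vector.shape[0]:
        raise ValueError("vectors must be (P, m) matching the layer vector")
    if vectors.shape[0] < 2:
        raise ValueError("LOPO needs at least 2 participants")
    return _lopo_r2(vectors, layer_vector)


def permutation_null(
    vectors: np.ndarray,
    layer_vector: np.ndarray,
    n_perm: int = 500,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the across-fold mean R-squared.

    Each permutation shuffles every participant's triangle entries with an
    independent fresh shuffle, then reruns the full LOPO procedure.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    P, m = vectors.shape
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, P, m))
    order = np.argsort(keys, axis=-1)
    shuffled = np.take_along_axis(np.broadcast_to(vectors, (n_perm, P, m)),
                                  order, axis=-1)
    r2 = _lopo_r2(shuffled, np.asarray(layer_vector, dtype=np.float64))
    return r2.mean(axis=-1)


def fit_layer(
    vectors: np.ndarray,
    layer_vector: np.ndarray,
    layer_id: str = "",
    n_perm: int = 500,
    seed: int = 0,
) -> LayerFitResult:
    """True LOPO R-squared plus permutation-null z normalization."""
    r2 = lopo_fit(vectors, layer_vector)
    null = permutation_null(vectors, layer_vector, n_perm=n_perm, seed=seed)
    sd = null.std()
    if sd == 0:
        raise DegenerateInputError("permutation null has zero SD")
    return LayerFitResult(layer_id, r2, float(null.mean()), float(sd))


# ---------------------------------------------------------------------------
# Whole-brain z maps
# ---------------------------------------------------------------------------

def searchlight_vectors(
    betamaps: Mapping[int, Sequence[BetaMaps]],
    sl: SearchlightIndex,
) -> np.ndarray:
    """(P, m) run-averaged searchlight RSM triangles, one row per participant."""
    from .searchlight import searchlight_rsm

    rows = []
    for p in sorted(betamaps):
        rsms = [searchlight_rsm(bm, sl).values for bm in betamaps[p]]
        rows.append(upper_triangle(np.mean(rsms, axis=0)))
    return np.stack(rows)


def zmap_for_layer(
    betamaps: Mapping[int, Sequence[BetaMaps]],
    layer_rsm: LayerRSM | np.ndarray,
    stability_mask: np.ndarray,
    half_width: int = 3,
    n_perm: int = 500,
    seed: int = 0,
    layer_id: str = "",
) -> dict[int, StatMap]:
    """Per-participant searchlight z maps for one layer, restricted to the
    representationally stable voxels."""
    import warnings

    stability_mask = np.asarray(stability_mask, dtype=bool)
    participants = sorted(betamaps)
    grids = {p: np.full(stability_mask.shape, np.nan) for p in participants}
    if not stability_mask.any():
        warnings.warn("stability mask is empty; returning empty maps")
        return {p: StatMap(grids[p], stability_mask, f"z_{layer_id}")
                for p in participants}
    layer_vec = upper_triangle(layer_rsm)
    full_mask = next(iter(betamaps.values()))[0].mask
    # searchlights are defined on the acquisition mask but only evaluated
    # at stable centers
    lin = np.full(full_mask.shape, -1, dtype=int)
    lin[full_mask] = np.arange(int(full_mask.sum()))
    for sl in enumerate_searchlights(full_mask, half_width):
        if not stability_mask[sl.center]:
            continue
        if sl.voxel_ids.size < 2:
            continue
        flat = int(np.ravel_multi_index(sl.center, full_mask.shape))
        center_seed = int(np.random.default_rng(
            np.random.SeedSequence([seed, flat])).integers(2**31))
        try:
            vecs = searchlight_vectors(betamaps, sl)
            fit = fit_layer(vecs, layer_vec, layer_id=layer_id,
                            n_perm=n_perm, seed=center_seed)
        except DegenerateInputError:
            continue
        for p, zval in zip(participants, fit.z):
            grids[p][sl.center] = zval
    return {p: StatMap(grids[p], stability_mask, f"z_{layer_id}")
            for p in participants}


# ---------------------------------------------------------------------------
# Residual method
# ---------------------------------------------------------------------------

def _zscore(v: np.ndarray, axis: int = -1) -> np.ndarray:
    sd = v.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError("cannot z-score a constant vector")
    return (v - v.mean(axis=axis, keepdims=True)) / sd


def residualize(vector: np.ndarray, others: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS residual of ``vector`` on ``others`` (rows are predictors), with
    intercept; returns ``(residual, coefficients)``.  The residual is
    orthogonal to every predictor and to the intercept."""
    vector = np.asarray(vector, dtype=np.float64)
    others = np.atleast_2d(np.asarray(others, dtype=np.float64))
    if others.size == 0:
        X = np.ones((vector.shape[0], 1))
    else:
        X = np.column_stack([others.T, np.ones(vector.shape[0])])
    coef, *_ = np.linalg.lstsq(X, vector, rcond=None)
    return vector - X @ coef, coef


def residual_fit(
    vectors: np.ndarray,
    target_layer_vector: np.ndarray,
    other_layer_vectors: np.ndarray,
) -> np.ndarray:
    """LOPO R-squared of the target layer against residualized searchlight
    triangles.

    All vectors are z-scored first.  Within each training fold the averaged
    searchlight triangle is regressed on the other layers' triangles (with
    intercept); the training residuals define the fit of the target layer
    (slope+intercept), and the held-out participant's triangle is
    residualized with the training-fold coefficients before scoring.
    """
    vectors = _zscore(np.asarray(vectors, dtype=np.float64))
    target = _zscore(np.asarray(target_layer_vector, dtype=np.float64))
    others = np.asarray(other_layer_vectors, dtype=np.float64)
    if others.ndim == 1:
        others = others[None, :]
    if others.size:
        others = _zscore(others)
    P, m = vectors.shape
    if P < 3:
        raise ValueError("LOPO needs at least 3 participants")
    if others.size:
        X = np.column_stack([others.T, np.ones(m)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            bad = _name_collinear(others)
            raise np.linalg.LinAlgError(
                f"other-layer predictors are collinear after z-scoring: {bad}"
            )
    else:
        X = np.ones((m, 1))

    r2 = np.empty(P)
    for h in range(P):
        train = vectors[np.arange(P) != h].mean(axis=0)
        coef, *_ = np.linalg.lstsq(X, train, rcond=None)
        resid_train = train - X @ coef
        resid_test = vectors[h] - X @ coef
        tc = target - target.mean()
        tvar = tc @ tc
        slope = (resid_train @ tc) / tvar
        intercept = resid_train.mean() - slope * target.mean()
        pred = slope * target + intercept
        ss_res = ((resid_test - pred) ** 2).sum()
        ss_tot = ((resid_test - resid_test.mean()) ** 2).sum()
        if ss_tot == 0:
            raise DegenerateInputError("zero-variance residualized held-out vector")
        r2[h] = 1.0 - ss_res / ss_tot
    return r2


def _name_collinear(others: np.ndarray) -> list[str]:
    """Identify (by index) predictor pairs with |correlation| ~ 1."""
    cc = np.corrcoef(others)
    bad = []
    K = others.shape[0]
    for i in range(K):
        for j in range(i + 1, K):
            if abs(cc[i, j]) > 1 - 1e-10:
                bad.append(f"predictors {i} and {j}")
    return bad or [f"predictor {i}" for i in range(K)]


# ---------------------------------------------------------------------------
# Group inference (sign-flip max-statistic FWE)
# ---------------------------------------------------------------------------

def group_inference(
    z_maps: Sequence[StatMap] | np.ndarray,
    alpha: float = 0.05,
    n_sign_flips: int = 1000,
    seed: int = 0,
) -> SignificanceMap:
    """One-sample t per center with family-wise sign-flip correction.

    The null assumes participant maps are sign-symmetric about zero; each of
    ``n_sign_flips`` flips negates whole participant maps, the maximum t
    across centers is recorded, and a center is significant when its
    observed t exceeds the (1 - alpha) quantile of that max distribution
    (one-tailed, positive effects).  Centers where all participants agree on
    a nonzero value with zero variance are treated as significant (t is
    unbounded there).
    """
    if isinstance(z_maps, np.ndarray):
        data = np.asarray(z_maps, dtype=np.float64)
        grid_shape = data.shape[1:]
    else:
        data = np.stack([m.values for m in z_maps])
        grid_shape = z_maps[0].values.shape
    P = data.shape[0]
    if P < 5:
        raise ValueError("group inference needs at least 5 participants")
    flat = data.reshape(P, -1)
    defined = np.all(np.isfinite(flat), axis=0)
    sig_flat = np.zeros(flat.shape[1], dtype=bool)
    if defined.any():
        Y = flat[:, defined]
        t_obs = _one_sample_t(Y)
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_sign_flips, P))
        max_t = np.empty(n_sign_flips)
        for b in range(n_sign_flips):
            tb = _one_sample_t(flips[b][:, None] * Y)
            max_t[b] = np.max(tb)
        # corrected p with the add-one estimator
        p_corr = (1 + (max_t[:, None] >= t_obs[None, :]).sum(axis=0)) / (
            1 + n_sign_flips)
        sig_flat[defined] = p_corr < alpha
    return SignificanceMap(sig_flat.reshape(grid_shape), alpha,
                           "sign-flip max-statistic FWE")


def _one_sample_t(Y: np.ndarray) -> np.ndarray:
    P = Y.shape[0]
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(P))
    # zero variance: certainty; signed infinity keeps the max-stat ordering
    zerovar = sd == 0
    t[zerovar] = np.where(mean[zerovar] > 0, np.inf,
                          np.where(mean[zerovar] < 0, -np.inf, 0.0))
    return t


def max_layer_labels(
    group_t: Mapping[str, np.ndarray],
    significant: Mapping[str, np.ndarray],
    layer_order: Sequence[str],
) -> np.ndarray:
    """Consolidated map: each significant center labeled by the layer with
    the largest group t (ties -> lowest layer index); -1 where nothing is
    significant."""
    shape = next(iter(group_t.values())).shape
    labels = np.full(shape, -1, dtype=int)
    best = np.full(shape, -np.inf)
    for idx, lid in enumerate(layer_order):
        t = np.asarray(group_t[lid], dtype=np.float64)
        sig = np.asarray(significant[lid], dtype=bool)
        with np.errstate(invalid="ignore"):
            better = sig & (t > best)   # strict: ties keep the earlier layer
        labels[better] = idx
        best[better] = t[better]
    return labels
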