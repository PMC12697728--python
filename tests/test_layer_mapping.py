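"""LOPO layer regression, permutation nulls, the residual method, and
sign-flip group inference."""

import numpy as np
import pytest

from layerprint.cnn_rsm import DegenerateInputError
from layerprint.design_glm import BetaMaps
from layerprint.layer_mapping import (
    fit_layer,
    group_inference,
    lopo_fit,
    max_layer_labels,
    permutation_null,
    residual_fit,
    residualize,
    zmap_for_layer,
)
from layerprint.searchlight import StatMap
from layerprint.synthetic_fmri import GroundTruthSpec, cube_region, simulate_betamaps


# ---------------------------------------------------------------------------
# LOPO regression
# ---------------------------------------------------------------------------

def test_lopo_perfect_fit_gives_unit_r2(rng):
    x = rng.standard_normal(120)
    vectors = np.tile(x, (6, 1))
    np.testing.assert_allclose(lopo_fit(vectors, x), 1.0, atol=1e-12)


def test_lopo_matches_hand_solved_least_squares():
    # two participants, length-3 vectors: fold 0 trains on participant 1 alone
    x = np.array([0.0, 1.0, 2.0])
    vectors = np.array([[1.0, 2.0, 2.0],
                        [0.5, 1.5, 3.1]])
    r2 = lopo_fit(vectors, x)
    for hold in (0, 1):
        train = vectors[1 - hold]
        slope, intercept = np.polyfit(x, train, 1)
        pred = slope * x + intercept
        held = vectors[hold]
        expected = 1 - np.sum((held - pred) ** 2) / np.sum(
            (held - held.mean()) ** 2)
        assert r2[hold] == pytest.approx(expected, abs=1e-12)


def test_lopo_unrelated_predictor_has_nonpositive_mean_r2():
    r2s = []
    for s in range(500):
        rng = np.random.default_rng(s)
        vectors = rng.standard_normal((5, 120))
        x = rng.standard_normal(120)
        r2s.append(lopo_fit(vectors, x).mean())
    assert np.mean(r2s) <= 0


def test_lopo_rejects_degenerate_inputs(rng):
    vectors = rng.standard_normal((4, 10))
    with pytest.raises(DegenerateInputError, match="constant"):
        lopo_fit(vectors, np.ones(10))
    vectors[2] = 5.0
    with pytest.raises(DegenerateInputError, match="zero-variance"):
        lopo_fit(vectors, rng.standard_normal(10))


# ---------------------------------------------------------------------------
# Permutation null
# ---------------------------------------------------------------------------

def test_permutation_null_seeded_and_nonpositive_under_independence(rng):
    vectors = rng.standard_normal((6, 120))
    x = rng.standard_normal(120)
    a = permutation_null(vectors, x, n_perm=200, seed=3)
    b = permutation_null(vectors, x, n_perm=200, seed=3)
    np.testing.assert_array_equal(a, b)
    assert a.mean() <= 0


def test_matched_data_yields_large_z(rng):
    x = rng.standard_normal(120)
    vectors = x[None] + 0.2 * rng.standard_normal((6, 120))
    fit = fit_layer(vectors, x, n_perm=500, seed=0)
    assert fit.z_mean > 3
    assert np.all(fit.z > 3)


def test_null_z_is_approximately_standard_normal():
    """Under a true null the across-fold-mean z is ~N(0, 1)."""
    zs = []
    for s in range(200):
        rng = np.random.default_rng(10_000 + s)
        vectors = rng.standard_normal((6, 120))
        x = rng.standard_normal(120)
        zs.append(fit_layer(vectors, x, n_perm=500, seed=s).z_mean)
    zs = np.asarray(zs)
    assert abs(zs.mean()) < 0.1
    assert 0.8 < zs.std() < 1.2


# ---------------------------------------------------------------------------
# Residual method
# ---------------------------------------------------------------------------

def test_residuals_orthogonal_to_all_predictors(rng):
    others = rng.standard_normal((11, 120))
    vector = rng.standard_normal(120)
    resid, _ = residualize(vector, others)
    for row in others:
        assert abs(resid @ row) < 1e-8
    assert abs(resid.sum()) < 1e-8  # intercept orthogonality


def test_residual_fit_zero_when_fully_explained(rng):
    others = rng.standard_normal((11, 120))
    w = rng.standard_normal(11)
    combo = w @ others
    vectors = np.tile(combo, (6, 1)) + 1e-3 * rng.standard_normal((6, 120))
    target = rng.standard_normal(120)
    r2 = residual_fit(vectors, target, others)
    assert np.all(np.abs(r2) < 0.05)


def test_residual_fit_recovers_unique_contribution(rng):
    target = rng.standard_normal(120)
    others = rng.standard_normal((11, 120))
    vectors = target[None] + 0.3 * rng.standard_normal((6, 120))
    r2_resid = residual_fit(vectors, target, others)
    r2_plain = lopo_fit(vectors, target)
    assert r2_resid.mean() > 0.5
    assert r2_resid.mean() == pytest.approx(r2_plain.mean(), abs=0.2)


def test_residual_fit_with_no_other_layers_matches_lopo(rng):
    target = rng.standard_normal(60)
    vectors = target[None] + 0.5 * rng.standard_normal((5, 60))
    zv = (vectors - vectors.mean(1, keepdims=True)) / vectors.std(1, keepdims=True)
    zt = (target - target.mean()) / target.std()
    r2_resid = residual_fit(vectors, target, np.empty((0, 60)))
    r2_plain = lopo_fit(zv, zt)
    np.testing.assert_allclose(r2_resid, r2_plain, atol=1e-10)


def test_residual_fit_rejects_collinear_predictors(rng):
    base = rng.standard_normal(60)
    others = np.stack([base, 2 * base + 3])  # collinear after z-scoring
    vectors = rng.standard_normal((5, 60))
    with pytest.raises(np.linalg.LinAlgError, match="collinear"):
        residual_fit(vectors, rng.standard_normal(60), others)


# ---------------------------------------------------------------------------
# Group inference
# ---------------------------------------------------------------------------

def _maps(arrs):
    mask = np.ones(arrs[0].shape, dtype=bool)
    return [StatMap(a, mask, "z") for a in arrs]


def test_group_inference_null_and_certain_cases():
    zeros = [np.zeros((4, 4, 4)) for _ in range(8)]
    sig = group_inference(_maps(zeros), seed=0)
    assert not sig.significant.any()

    fives = [np.full((4, 4, 4), 5.0) for _ in range(10)]
    sig = group_inference(_maps(fives), seed=0)
    assert sig.significant.all()
    assert sig.correction_name == "sign-flip max-statistic FWE"


def test_group_inference_requires_enough_participants():
    with pytest.raises(ValueError, match="at least 5"):
        group_inference(_maps([np.zeros((3, 3, 3))] * 4), seed=0)


def test_group_inference_is_specific_to_signal_region():
    hits, containments = 0, 0
    region = np.zeros((8, 8, 8), dtype=bool)
    region[2:5, 2:5, 2:5] = True
    dilated = np.zeros_like(region)
    dilated[1:6, 1:6, 1:6] = True
    for s in range(20):
        rng = np.random.default_rng(s)
        maps = [np.where(region, 3.0, 0.0) + 0.8 * rng.standard_normal(region.shape)
                for _ in range(8)]
        sig = group_inference(_maps(maps), n_sign_flips=300, seed=s)
        if sig.significant[region].any():
            hits += 1
        if not sig.significant[~dilated].any():
            containments += 1
    assert hits >= 18       # detects the region
    assert containments >= 18  # and stays inside its dilation


# ---------------------------------------------------------------------------
# z maps and consolidated labels
# ---------------------------------------------------------------------------

def test_zmap_peaks_in_ground_truth_region(rng, ortho_rsms, adapter):
    layer_ids = list(ortho_rsms)
    spec = GroundTruthSpec(grid_shape=(12, 12, 12),
                           regions=[cube_region((5, 5, 5), 3, layer_ids[2], 2.0)],
                           noise_sd=1.0, n_participants=5, n_runs=2,
                           participant_sd=0.2, seed=21)
    bms, truth = simulate_betamaps(spec, ortho_rsms)
    grouped = {}
    for (p, r), bm in sorted(bms.items()):
        grouped.setdefault(p, []).append(bm)
    stability_mask = np.zeros((12, 12, 12), dtype=bool)
    stability_mask[4:7, 4:7, 4:7] = True  # around the region center
    stability_mask[9:12, 9:12, 9:12] = True  # noise-only comparison corner
    zmaps = zmap_for_layer(grouped, ortho_rsms[layer_ids[2]], stability_mask,
                           n_perm=150, seed=1, layer_id=layer_ids[2])
    group_z = np.nanmean(np.stack([zmaps[p].values for p in grouped]), axis=0)
    assert np.nanmax(group_z[4:7, 4:7, 4:7]) > 3
    assert np.nanmax(group_z[9:12, 9:12, 9:12]) < np.nanmax(group_z[4:7, 4:7, 4:7])


def test_zmap_empty_stability_mask_warns(rng, ortho_rsms):
    mask = np.ones((4, 4, 4), dtype=bool)
    bm = BetaMaps(rng.standard_normal((8, 64)), mask,
                  [f"img{i:02d}" for i in range(8)])
    grouped = {0: [bm], 1: [bm], 2: [bm]}
    with pytest.warns(UserWarning, match="empty"):
        zmaps = zmap_for_layer(grouped, list(ortho_rsms.values())[0],
                               np.zeros((4, 4, 4), dtype=bool), n_perm=10, seed=0)
    assert all(np.isnan(m.values).all() for m in zmaps.values())


def test_max_layer_labels_tie_breaks_to_earlier_layer():
    t = {"a": np.array([[2.0, 1.0]]), "b": np.array([[2.0, 3.0]])}
    sig = {"a": np.array([[True, True]]), "b": np.array([[True, True]])}
    labels = max_layer_labels(t, sig, ["a", "b"])
    assert labels[0, 0] == 0  # tie -> lowest layer index
    assert labels[0, 1] == 1
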