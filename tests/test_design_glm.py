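"""Trial sequences, the double-gamma HRF, design matrices and the GLM."""

import math

import numpy as np
import pandas as pd
import pytest

from layerprint.design_glm import (
    BetaMaps,
    TrialSequence,
    build_design,
    double_gamma_hrf,
    fit_glm,
    generate_sequence,
    load_betamaps,
    read_fsl_evs,
    save_betamaps,
    write_fsl_evs,
)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def test_default_sequence_contract():
    seq = generate_sequence(seed=0)
    assert seq.n_trials == 80
    counts = seq.trials["image_id"].value_counts()
    assert (counts == 5).all() and len(counts) == 16
    ids = seq.trials["image_id"].to_numpy()
    assert (ids[1:] != ids[:-1]).all()
    assert seq.trials["is_target"].sum() == math.ceil(0.1 * 80)


def test_sequence_constraints_hold_across_seeds():
    for seed in range(200):
        seq = generate_sequence(seed=seed)
        ids = seq.trials["image_id"].to_numpy()
        assert (ids[1:] != ids[:-1]).all()
        assert (seq.trials["image_id"].value_counts() == 5).all()
        gaps = np.diff(seq.trials["onset_s"].to_numpy()) - 1.5
        assert set(np.round(gaps, 9)) <= {1.5, 3.0, 4.5}


def test_sequence_reproducible_and_isi_uniform():
    a = generate_sequence(seed=42)
    b = generate_sequence(seed=42)
    pd.testing.assert_frame_equal(a.trials, b.trials)
    # ISI frequencies uniform within a generous binomial band
    gaps = []
    for seed in range(300):
        seq = generate_sequence(seed=seed)
        gaps.extend(np.round(np.diff(seq.trials["onset_s"]) - 1.5, 9))
    gaps = np.asarray(gaps)
    for isi in (1.5, 3.0, 4.5):
        frac = np.mean(gaps == isi)
        assert abs(frac - 1 / 3) < 0.02


def test_sequence_infeasible_constraints_fail_constructively():
    with pytest.raises(ValueError, match="could not build|at least 2"):
        generate_sequence(n_images=1, n_reps=2, seed=0)


# ---------------------------------------------------------------------------
# HRF
# ---------------------------------------------------------------------------

def _hand_double_gamma(t, a1=6.0, a2=16.0, ratio=1 / 6):
    """Independent evaluation of the difference-of-gammas (scale 1)."""
    def gpdf(t, a):
        return np.where(t > 0,
                        t ** (a - 1) * np.exp(-t) / math.gamma(a), 0.0)
    return gpdf(t, a1) - ratio * gpdf(t, a2)


def test_hrf_origin_peak_and_argmax():
    assert double_gamma_hrf(np.array([0.0]))[0] == 0.0
    dense = np.arange(0, 40, 0.001)
    vals = double_gamma_hrf(dense)
    assert vals.max() == pytest.approx(1.0, abs=1e-6)
    # argmax matches a brute-force grid search of the raw two-gamma formula
    hand = _hand_double_gamma(dense)
    assert abs(dense[np.argmax(vals)] - dense[np.argmax(hand)]) < 0.01
    assert 4.5 < dense[np.argmax(vals)] < 6.5  # gamma(6) mode is 5 s
    # undershoot present around 16 s
    assert vals[np.searchsorted(dense, 16.0)] < 0


def test_hrf_proportional_to_hand_formula():
    t = np.linspace(0, 30, 121)
    ours = double_gamma_hrf(t)
    hand = _hand_double_gamma(t)
    np.testing.assert_allclose(ours, hand / hand.max(), atol=1e-9)


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _single_event_sequence(image_id="img00", onset=10.0, ids=("img00", "img01")):
    trials = pd.DataFrame({
        "image_id": [image_id], "onset_s": [onset],
        "duration_s": [1.5], "is_target": [False],
    })
    return TrialSequence(trials, run_length_s=onset + 1.5)


def test_design_single_event_is_local():
    seq = _single_event_sequence()
    d = build_design(seq, n_volumes=40, image_ids=["img00", "img01"])
    assert d.values.shape == (40, 2)
    assert np.abs(d.values[:, 0]).max() > 0
    np.testing.assert_array_equal(d.values[:, 1], 0.0)
    # response is causal: nothing before the onset volume
    assert np.all(d.values[: int(10.0 / 1.5), 0] == 0)


def test_design_deterministic_and_rejects_overrun():
    seq = _single_event_sequence()
    a = build_design(seq, n_volumes=40, image_ids=["img00"])
    b = build_design(seq, n_volumes=40, image_ids=["img00"])
    np.testing.assert_array_equal(a.values, b.values)
    with pytest.raises(ValueError, match="past the end"):
        build_design(_single_event_sequence(onset=100.0), n_volumes=40,
                     image_ids=["img00"])


def test_design_empty_sequence_is_all_zero():
    trials = pd.DataFrame({"image_id": [], "onset_s": [], "duration_s": [],
                           "is_target": []})
    seq = TrialSequence(trials, run_length_s=0.0)
    d = build_design(seq, n_volumes=20, image_ids=["img00", "img01"])
    np.testing.assert_array_equal(d.values, 0.0)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def test_glm_exact_recovery_and_shift_invariance(rng):
    seq = generate_sequence(n_images=4, n_reps=3, seed=1)
    design = build_design(seq, n_volumes=60)
    true_betas = rng.standard_normal((4, 30))
    bold = design.values @ true_betas
    fit = fit_glm(bold, design)
    np.testing.assert_allclose(fit.values, true_betas, atol=1e-8)
    # adding a constant offset only moves the intercept
    fit2 = fit_glm(bold + 7.5, design)
    np.testing.assert_allclose(fit2.values, true_betas, atol=1e-8)


def test_glm_matches_normal_equations(rng):
    seq = generate_sequence(n_images=3, n_reps=2, seed=2)
    design = build_design(seq, n_volumes=40)
    bold = rng.standard_normal((40, 11))
    fit = fit_glm(bold, design)
    X = np.column_stack([design.values, np.ones(40)])
    expected = np.linalg.solve(X.T @ X, X.T @ bold)[:-1]
    np.testing.assert_allclose(fit.values, expected, atol=1e-8)


def test_glm_pure_noise_betas_center_on_zero(rng):
    seq = generate_sequence(n_images=4, n_reps=3, seed=3)
    design = build_design(seq, n_volumes=60)
    bold = rng.standard_normal((60, 4000))
    fit = fit_glm(bold, design)
    mean = fit.values.mean()
    se = fit.values.std() / np.sqrt(fit.values.size)
    assert abs(mean) < 3 * se + 1e-12


def test_glm_names_collinear_regressors():
    seq = generate_sequence(n_images=3, n_reps=2, seed=4)
    design = build_design(seq, n_volumes=40)
    design.values[:, 2] = design.values[:, 0]  # duplicate a regressor
    with pytest.raises(np.linalg.LinAlgError, match="img00|img02"):
        fit_glm(np.zeros((40, 3)), design)


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_fsl_ev_round_trip(tmp_path):
    seq = generate_sequence(seed=7)
    write_fsl_evs(seq, tmp_path)
    loaded = read_fsl_evs(tmp_path)
    a = seq.trials.sort_values("onset_s").reset_index(drop=True)
    b = loaded.trials.sort_values("onset_s").reset_index(drop=True)
    np.testing.assert_allclose(a["onset_s"], b["onset_s"], atol=1e-6)
    assert (a["image_id"].to_numpy() == b["image_id"].to_numpy()).all()
    assert (a["is_target"].to_numpy() == b["is_target"].to_numpy()).all()


def test_betamaps_nifti_round_trip(tmp_path, rng):
    mask = rng.uniform(size=(5, 6, 4)) > 0.3
    values = rng.standard_normal((3, int(mask.sum())))
    bm = BetaMaps(values, mask, ["img00", "img01", "img02"], run_id="run01")
    save_betamaps(bm, tmp_path / "betas.nii")
    loaded = load_betamaps(tmp_path / "betas.nii")
    np.testing.assert_allclose(loaded.values, values, atol=1e-12)
    np.testing.assert_array_equal(loaded.mask, mask)
    assert loaded.image_ids == bm.image_ids and loaded.run_id == "run01"
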