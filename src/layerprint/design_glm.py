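"""Trial sequences, HRF-convolved design matrices, and mass-univariate GLM.

The event-related design mirrors a rapid fMRI protocol: each of 16 images is
shown exactly 5 times per run (80 presentations), 1.5 s on screen, never
back-to-back, with inter-stimulus intervals jittered uniformly over
{1.5, 3, 4.5} s; 10% of trials carry a behavioral target flag.  Onsets are
convolved with a canonical double-gamma hemodynamic response function and
sampled at the TR grid (1.5 s, 250 volumes per run); per-image beta maps
come from an ordinary-least-squares fit per voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import ceil
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

__all__ = [
    "TrialSequence",
    "DesignMatrix",
    "BetaMaps",
    "generate_sequence",
    "double_gamma_hrf",
    "build_design",
    "fit_glm",
    "write_fsl_evs",
    "read_fsl_evs",
    "save_betamaps",
    "load_betamaps",
]


@dataclass
class TrialSequence:
    """Ordered trial records with onsets in seconds."""

    trials: pd.DataFrame  # columns: image_id, onset_s, duration_s, is_target
    run_length_s: float

    def __post_init__(self) -> None:
        required = {"image_id", "onset_s", "duration_s", "is_target"}
        if not required.issubset(self.trials.columns):
            raise ValueError(f"trials must have columns {sorted(required)}")
        onsets = self.trials["onset_s"].to_numpy()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.trials["image_id"].unique())


@dataclass
class DesignMatrix:
    values: np.ndarray        # (n_volumes, n_regressors)
    tr_s: float
    regressor_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape[1] != len(self.regressor_ids):
            raise ValueError("one regressor id per column required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design matrix must be finite")


@dataclass
class BetaMaps:
    """Per-image voxelwise GLM coefficients over a masked 3-D grid."""

    values: np.ndarray        # (n_images, n_mask_voxels)
    mask: np.ndarray          # 3-D boolean grid
    image_ids: list[str]
    run_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        n_mask = int(self.mask.sum())
        if self.values.shape != (len(self.image_ids), n_mask):
            raise ValueError(
                f"values must be (n_images={len(self.image_ids)}, "
                f"n_mask_voxels={n_mask}); got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("beta values must be finite")

    def volume(self) -> np.ndarray:
        """4-D (n_images, X, Y, Z) array; NaN outside the mask."""
        out = np.full((len(self.image_ids),) + self.mask.shape, np.nan)
        out[:, self.mask] = self.values
        return out


# ---------------------------------------------------------------------------
# Trial-sequence generation
# ---------------------------------------------------------------------------

def generate_sequence(
    n_images: int = 16,
    n_reps: int = 5,
    stim_dur_s: float = 1.5,
    isi_choices_s: Sequence[float] = (1.5, 3.0, 4.5),
    target_rate: float = 0.1,
    seed: int = 0,
    max_restarts: int = 200,
) -> TrialSequence:
    """Pseudo-random trial order: each image exactly ``n_reps`` times, no
    back-to-back repeats, ISIs uniform over the jitter set.

    The order is built sequentially, drawing each trial among the images
    with presentations remaining (excluding the previous image) with
    probability proportional to the remaining count; dead ends restart the
    draw, and a constructively infeasible constraint set fails after
    ``max_restarts`` attempts.
    """
    n_trials = n_images * n_reps
    if n_trials < 2:
        raise ValueError("need at least 2 trials")
    rng = np.random.default_rng(seed)
    image_ids = [f"img{i:02d}" for i in range(n_images)]

    order = None
    for _ in range(max_restarts):
        remaining = np.full(n_images, n_reps)
        seq = np.empty(n_trials, dtype=int)
        prev = -1
        ok = True
        for t in range(n_trials):
            weights = remaining.astype(float)
            if prev >= 0:
                weights[prev] = 0.0
            total = weights.sum()
            if total == 0:
                ok = False
                break
            seq[t] = rng.choice(n_images, p=weights / total)
            remaining[seq[t]] -= 1
            prev = seq[t]
        if ok:
            order = seq
            break
    if order is None:
        raise ValueError(
            f"could not build a no-repeat sequence for n_images={n_images}, "
            f"n_reps={n_reps} after {max_restarts} restarts"
        )

    isis = rng.choice(np.asarray(isi_choices_s, dtype=float), size=n_trials)
    onsets = np.empty(n_trials)
    t = 0.0
    for i in range(n_trials):
        onsets[i] = t
        t += stim_dur_s + isis[i]
    run_length = onsets[-1] + stim_dur_s

    n_targets = ceil(target_rate * n_trials)
    target_idx = rng.choice(n_trials, size=n_targets, replace=False)
    is_target = np.zeros(n_trials, dtype=bool)
    is_target[target_idx] = True

    trials = pd.DataFrame({
        "image_id": [image_ids[k] for k in order],
        "onset_s": onsets,
        "duration_s": stim_dur_s,
        "is_target": is_target,
    })
    return TrialSequence(trials, run_length_s=float(run_length))


# ---------------------------------------------------------------------------
# Double-gamma HRF
# ---------------------------------------------------------------------------

def double_gamma_hrf(
    t_s: np.ndarray,
    peak_delay_s: float = 6.0,
    undershoot_delay_s: float = 16.0,
    peak_dispersion_s: float = 1.0,
    undershoot_dispersion_s: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical difference-of-gammas HRF, peak-normalized to 1.

    ``h(t) = g(t; 6, 1) - (1/6) g(t; 16, 1)`` with gamma densities
    parameterized by delay/dispersion; peaks near 6 s with an undershoot
    near 16 s.  All five parameters are overridable.
    """
    t_s = np.asarray(t_s, dtype=np.float64)
    if np.any(t_s < 0):
        raise ValueError("time grid must be nonnegative")

    def raw(t):
        peak = gamma_dist.pdf(t, peak_delay_s / peak_dispersion_s,
                              scale=peak_dispersion_s)
        under = gamma_dist.pdf(t, undershoot_delay_s / undershoot_dispersion_s,
                               scale=undershoot_dispersion_s)
        return peak - undershoot_ratio * under

    dense = np.arange(0.0, 50.0, 0.01)
    norm = raw(dense).max()
    return raw(t_s) / norm


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def build_design(
    seq: TrialSequence,
    tr_s: float = 1.5,
    n_volumes: int = 250,
    oversample_dt_s: float = 0.05,
    hrf_kwargs: dict | None = None,
    image_ids: Sequence[str] | None = None,
) -> DesignMatrix:
    """Boxcar events per image convolved with the HRF, sampled at volume times."""
    run_dur = n_volumes * tr_s
    ends = seq.trials["onset_s"] + seq.trials["duration_s"]
    if (ends > run_dur + 1e-9).any():
        raise ValueError("a trial extends past the end of the run")
    ids = list(image_ids) if image_ids is not None else seq.image_ids
    n_hi = int(np.ceil(run_dur / oversample_dt_s)) + 1
    t_hi = np.arange(n_hi) * oversample_dt_s
    hrf = double_gamma_hrf(np.arange(0.0, 32.0, oversample_dt_s),
                           **(hrf_kwargs or {}))
    cols = np.zeros((n_volumes, len(ids)))
    vol_idx = np.round(np.arange(n_volumes) * tr_s / oversample_dt_s).astype(int)
    for j, iid in enumerate(ids):
        boxcar = np.zeros(n_hi)
        sel = seq.trials[seq.trials["image_id"] == iid]
        for _, tr in sel.iterrows():
            a = int(np.round(tr["onset_s"] / oversample_dt_s))
            b = int(np.round((tr["onset_s"] + tr["duration_s"]) / oversample_dt_s))
            boxcar[a:b] = 1.0
        conv = np.convolve(boxcar, hrf)[:n_hi] * oversample_dt_s
        cols[:, j] = conv[vol_idx]
    return DesignMatrix(cols, tr_s=tr_s, regressor_ids=ids)


# ---------------------------------------------------------------------------
# Mass-univariate GLM
# ---------------------------------------------------------------------------

def fit_glm(
    bold: np.ndarray,
    design: DesignMatrix,
    mask: np.ndarray | None = None,
    run_id: str = "",
) -> BetaMaps:
    """Per-voxel OLS of ``bold`` (n_volumes x n_voxels) on the design plus an
    intercept nuisance column; returns one coefficient per (image, voxel).

    Raises a rank-deficiency error naming the collinear regressors.
    """
    bold = np.asarray(bold, dtype=np.float64)
    X = np.column_stack([design.values, np.ones(design.values.shape[0])])
    if bold.shape[0] != X.shape[0]:
        raise ValueError("bold and design must have the same number of volumes")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X[:, :-1], design.regressor_ids)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear regressors: {bad}"
        )
    betas, *_ = np.linalg.lstsq(X, bold, rcond=None)
    betas = betas[:-1]  # drop the intercept
    if mask is None:
        mask = np.ones((bold.shape[1], 1, 1), dtype=bool)
    return BetaMaps(betas, mask, list(design.regressor_ids), run_id=run_id)


def _collinear_columns(X: np.ndarray, ids: Sequence[str]) -> list[str]:
    """Name regressors involved in exact linear dependence (diagnostic only)."""
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(others) == np.linalg.matrix_rank(X):
            bad.append(ids[j])
    return bad or list(ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fsl_evs(seq: TrialSequence, out_dir: str | Path) -> None:
    """One 3-column text file (onset, duration, weight) per image."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for iid in seq.image_ids:
        sel = seq.trials[seq.trials["image_id"] == iid]
        rows = np.column_stack([
            sel["onset_s"].to_numpy(), sel["duration_s"].to_numpy(),
            np.ones(len(sel)),
        ])
        np.savetxt(out / f"{iid}.txt", rows, fmt="%.6f")
    meta = {
        "run_length_s": seq.run_length_s,
        "target_onsets_s": seq.trials.loc[seq.trials["is_target"],
                                          "onset_s"].tolist(),
    }
    (out / "sequence.json").write_text(json.dumps(meta))


def read_fsl_evs(in_dir: str | Path) -> TrialSequence:
    src = Path(in_dir)
    meta = json.loads((src / "sequence.json").read_text())
    records = []
    for f in sorted(src.glob("img*.txt")):
        rows = np.atleast_2d(np.loadtxt(f))
        for onset, dur, _w in rows:
            records.append((f.stem, onset, dur))
    records.sort(key=lambda r: r[1])
    target_onsets = set(np.round(meta["target_onsets_s"], 6))
    trials = pd.DataFrame(records, columns=["image_id", "onset_s", "duration_s"])
    trials["is_target"] = [round(o, 6) in target_onsets
                           for o in trials["onset_s"]]
    return TrialSequence(trials, run_length_s=meta["run_length_s"])


def save_betamaps(betas: BetaMaps, path: str | Path) -> None:
    """4-D NIfTI stack (X, Y, Z, n_images) plus a JSON sidecar of image ids."""
    path = Path(path)
    vol = np.moveaxis(betas.volume(), 0, -1)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "image_ids": betas.image_ids, "run_id": betas.run_id,
    }))


def load_betamaps(path: str | Path) -> BetaMaps:
    path = Path(path)
    vol = np.asarray(nib.load(str(path)).get_fdata())
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    vol = np.moveaxis(vol, -1, 0)
    mask = ~np.isnan(vol[0])
    values = vol[:, mask]
    return BetaMaps(values, mask, meta["image_ids"], run_id=meta["run_id"])
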