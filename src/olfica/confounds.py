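"""Nuisance regressors for the task-modulated connectivity GLM.

Covers the full nuisance block: the 24-parameter motion expansion (6 rigid-body
parameters, temporal derivatives, and quadratics of both), five aCompCor
components from a noise-region mask, per-frame spike regressors where motion
exceeds 1 mm framewise displacement or a standardized DVARS of 2, and a
discrete-cosine high-pass basis at 0.01 Hz.  High-pass filtering is expressed
as regressors inside the GLM rather than as a separate temporal filter so the
projection and its degrees of freedom stay in one model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Bold4D

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


def framewise_displacement(motion: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power's framewise displacement in mm.

    FD_t = sum |Δ translation| + head_radius * sum |Δ rotation| with rotations
    in radians projected onto a sphere of the given head radius; FD_0 = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must have 6 columns; got shape {motion.shape}")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + head_radius_mm * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def dvars(bold: Bold4D, standardize: bool = True) -> np.ndarray:
    """Spatial RMS of the frame-to-frame signal difference over the mask.

    With ``standardize`` the series is divided by its own median over t >= 1,
    making the conventional spike threshold of 2 scale-free; DVARS_0 = 0.
    """
    if not bold.mask.any():
        raise ValueError("empty mask")
    sig = bold.data[bold.mask]  # voxels x t
    d = np.diff(sig, axis=1)
    series = np.concatenate([[0.0], np.sqrt((d**2).mean(axis=0))])
    if standardize:
        med = np.median(series[1:])
        if med > 0:
            series = series / med
    return series


def motion_expansion(motion: np.ndarray) -> pd.DataFrame:
    """24-parameter Volterra expansion: [m, Δm, m², (Δm)²].

    Derivatives are backward differences with a leading 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must have 6 columns; got shape {motion.shape}")
    deriv = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    cols: dict[str, np.ndarray] = {}
    for j, name in enumerate(MOTION_COLUMNS):
        cols[name] = motion[:, j]
    for j, name in enumerate(MOTION_COLUMNS):
        cols[f"{name}_derivative1"] = deriv[:, j]
    for j, name in enumerate(MOTION_COLUMNS):
        cols[f"{name}_power2"] = motion[:, j] ** 2
    for j, name in enumerate(MOTION_COLUMNS):
        cols[f"{name}_derivative1_power2"] = deriv[:, j] ** 2
    return pd.DataFrame(cols)


def acompcor(bold: Bold4D, noise_mask: np.ndarray, n_components: int = 5) -> pd.DataFrame:
    """Anatomical CompCor: top principal-component timeseries of a noise region.

    Each noise voxel's series is detrended (mean + linear) before the PCA; the
    returned component timeseries are unit-normalized and ordered by
    decreasing explained variance.
    """
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if noise_mask.shape != bold.shape3d:
        raise ValueError("noise mask grid does not match data grid")
    if np.logical_and(noise_mask, bold.mask).any():
        raise ValueError("noise mask must be disjoint from the analysis mask")
    n_vox = int(noise_mask.sum())
    if n_vox < n_components:
        raise ValueError(f"noise mask has {n_vox} voxels; need >= {n_components}")
    series = bold.data[noise_mask].T.astype(float)  # t x voxels
    t = np.arange(series.shape[0], dtype=float)
    trend = np.column_stack([np.ones_like(t), t - t.mean()])
    series = series - trend @ np.linalg.lstsq(trend, series, rcond=None)[0]
    u, s, _ = np.linalg.svd(series, full_matrices=False)
    comps = u[:, :n_components]
    # sign convention: each component positively correlated with its own peak loading
    flip = np.sign(comps[np.abs(comps).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    comps = comps * flip
    return pd.DataFrame(comps, columns=[f"a_comp_cor_{i:02d}" for i in range(n_components)])


def spike_regressors(
    fd: np.ndarray,
    dvars_series: np.ndarray,
    fd_thresh: float = 1.0,
    dvars_thresh: float = 2.0,
) -> pd.DataFrame:
    """One indicator column per frame exceeding either motion threshold."""
    fd = np.asarray(fd, dtype=float)
    dvars_series = np.asarray(dvars_series, dtype=float)
    if fd.shape != dvars_series.shape:
        raise ValueError("fd and dvars series must have equal length")
    flagged = np.flatnonzero((fd > fd_thresh) | (dvars_series > dvars_thresh))
    if flagged.size == len(fd):
        raise ValueError("every frame is flagged; spike regressors would saturate the design")
    cols = {}
    for i, frame in enumerate(flagged):
        col = np.zeros(len(fd))
        col[frame] = 1.0
        cols[f"motion_outlier_{i:02d}"] = col
    return pd.DataFrame(cols, index=range(len(fd)))


def dct_highpass_basis(n_frames: int, tr_s: float, cutoff_hz: float = 0.01) -> pd.DataFrame:
    """Discrete-cosine basis spanning frequencies below ``cutoff_hz``.

    K = floor(2 * n_frames * tr_s * cutoff_hz) columns (constant excluded — it
    belongs to the intercept); columns are orthonormal.
    """
    if n_frames < 4:
        raise ValueError("need at least 4 frames for a DCT basis")
    k_max = int(np.floor(2.0 * n_frames * tr_s * cutoff_hz))
    if k_max >= n_frames // 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz yields {k_max} DCT columns, too many for {n_frames} frames"
        )
    t = np.arange(n_frames)
    cols = {}
    for k in range(1, k_max + 1):
        c = np.cos(np.pi * (2 * t + 1) * k / (2 * n_frames))
        cols[f"cosine_{k:02d}"] = c * np.sqrt(2.0 / n_frames)
    return pd.DataFrame(cols, index=range(n_frames))


@dataclass
class ConfoundMatrix:
    """Full nuisance block for one run plus the diagnostic FD/DVARS series."""

    frame: pd.DataFrame
    fd_mm: np.ndarray
    dvars: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)


def build_confound_matrix(
    bold: Bold4D,
    motion: np.ndarray,
    noise_mask: np.ndarray,
    n_acompcor: int = 5,
    fd_thresh: float = 1.0,
    dvars_thresh: float = 2.0,
    highpass_hz: float = 0.01,
    dvars_standardized: bool = True,
) -> ConfoundMatrix:
    """Assemble motion24 + aCompCor + spikes + DCT for one run."""
    fd = framewise_displacement(motion)
    dv = dvars(bold, standardize=dvars_standardized)
    parts = [
        motion_expansion(motion),
        acompcor(bold, noise_mask, n_components=n_acompcor),
        spike_regressors(fd, dv, fd_thresh=fd_thresh, dvars_thresh=dvars_thresh),
        dct_highpass_basis(bold.n_frames, bold.tr_s, cutoff_hz=highpass_hz),
    ]
    frame = pd.concat([p.reset_index(drop=True) for p in parts], axis=1)
    return ConfoundMatrix(frame=frame, fd_mm=fd, dvars=dv)


def export_confounds(cm: ConfoundMatrix, dvars_standardized: bool = True) -> pd.DataFrame:
    """Confound table with fMRIPrep-style column names, diagnostics included."""
    out = cm.frame.copy()
    out["framewise_displacement"] = cm.fd_mm
    out["std_dvars" if dvars_standardized else "dvars"] = cm.dvars
    return out
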