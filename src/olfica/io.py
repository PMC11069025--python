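"""Readers and writers for BOLD volumes and tabular sidecars.

The on-disk dataset layout is BIDS-like: per subject, one 4D NIfTI per run
(``sub-XX_run-R_bold.nii.gz``) plus tab-separated events and confounds files,
and a cohort-level ``participants.tsv``.  The only image-level preprocessing
step in scope is spatial Gaussian smoothing; registration, distortion
correction and normalisation are assumed to have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))

EVENT_COLUMNS = ("onset", "duration", "trial_type")
CONFOUND_MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")
PARTICIPANT_COLUMNS = ("subject", "apoe4", "sdoit", "familiarity", "age", "sex")


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


@dataclass
class Bold4D:
    """A 4D BOLD image: data on an (x, y, z, t) grid with affine, TR and mask.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Signal in arbitrary units.
    affine : ndarray, shape (4, 4)
        Voxel-to-world map (NIfTI convention, 0-based voxel indices).
    tr_s : float
        Repetition time in seconds.
    mask : ndarray of bool, shape (x, y, z), optional
        Analysis mask; defaults to all-true.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValidationError(
                f"BOLD data must be 4D (x, y, z, t); got {self.data.ndim} dimensions"
            )
        if self.data.shape[3] < 2:
            raise ValidationError("BOLD data must have at least 2 frames")
        if not self.tr_s or self.tr_s <= 0:
            raise ValidationError(
                "TR must be positive; pass an explicit tr_s override if the "
                "header time step is missing or zero"
            )
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValidationError(
                f"mask grid {self.mask.shape} does not match data grid {self.data.shape[:3]}"
            )
        if not np.isfinite(self.data[self.mask]).all():
            raise ValidationError("non-finite values inside mask")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def voxel_sizes_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


def load_bold(path: str | Path, tr_s: float | None = None, mask: np.ndarray | None = None) -> Bold4D:
    """Load a 4D NIfTI-1 file.

    TR is taken from the header time-step field unless ``tr_s`` overrides it.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a 4D image, got {data.ndim}D")
    if tr_s is None:
        header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        if header_tr <= 0:
            raise ValidationError(
                f"{path}: header TR is missing or zero; pass tr_s explicitly"
            )
        tr_s = header_tr
    return Bold4D(data=data, affine=img.affine, tr_s=tr_s, mask=mask)


def save_bold(bold: Bold4D, path: str | Path) -> Path:
    """Write a :class:`Bold4D` as float32 NIfTI-1, recording TR in the header."""
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms(tuple(img.header.get_zooms()[:3]) + (float(bold.tr_s),))
    img.header.set_xyzt_units("mm", "sec")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def save_volume(vol: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3D (or 4D stack-of-maps) volume as float32 NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), str(path))
    return path


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column '{col}'")


def load_events(path: str | Path) -> pd.DataFrame:
    """Load an events TSV and validate the event-table invariants.

    Columns: onset, duration, trial_type (stim/baseline), odorant, outcome.
    Outcome strings are case-folded; stim rows must carry hit/miss.  Unknown
    columns are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, EVENT_COLUMNS, path)
    if not df["onset"].is_monotonic_increasing:
        raise ValidationError(f"{path}: onsets must be nondecreasing")
    if (df["duration"] <= 0).any():
        raise ValidationError(f"{path}: durations must be positive")
    if "outcome" in df.columns:
        df["outcome"] = df["outcome"].astype(str).str.strip().str.lower()
        stim = df[df["trial_type"] == "stim"]
        bad = ~stim["outcome"].isin(["hit", "miss"])
        if bad.any():
            raise ValidationError(
                f"{path}: stim rows must have outcome hit/miss; got "
                f"{sorted(stim['outcome'][bad].unique())}"
            )
    elif (df["trial_type"] == "stim").any():
        raise ValidationError(f"{path}: missing required column 'outcome'")
    return df


def load_confounds(path: str | Path) -> pd.DataFrame:
    """Load a confounds TSV; requires the six rigid-body motion columns."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, CONFOUND_MOTION_COLUMNS, path)
    return df


def load_participants(path: str | Path) -> pd.DataFrame:
    """Load the cohort covariate table (ApoE ε4, SDOIT, familiarity, age, sex)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, PARTICIPANT_COLUMNS, path)
    if not df["sdoit"].between(0, 8).all():
        raise ValidationError(f"{path}: sdoit scores must lie in [0, 8]")
    if not df["familiarity"].between(1, 10).all():
        raise ValidationError(f"{path}: familiarity ratings must lie in [1, 10]")
    return df


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def smooth_gaussian(bold: Bold4D, fwhm_mm: float) -> Bold4D:
    """Per-frame 3D Gaussian smoothing with the given FWHM in millimetres.

    sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to voxel units via
    the affine's voxel sizes.  A FWHM of 0 is the identity.  Boundaries use
    nearest-neighbour extension so constants are preserved on small grids.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return bold
    rot = bold.affine[:3, :3]
    vox = np.sqrt((rot**2).sum(axis=0))
    # shear check: columns of the rotation block must be orthogonal
    gram = rot.T @ rot
    off = gram - np.diag(np.diag(gram))
    if np.abs(off).max() > 1e-6 * vox.max() ** 2:
        raise ValueError("affine has shear; smoothing on sheared grids is unsupported")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vox
    out = np.empty_like(bold.data, dtype=np.float64)
    for t in range(bold.n_frames):
        out[..., t] = ndimage.gaussian_filter(
            bold.data[..., t].astype(np.float64), sigma=sigma_vox, mode="nearest"
        )
    return Bold4D(data=out, affine=bold.affine, tr_s=bold.tr_s, mask=bold.mask)
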