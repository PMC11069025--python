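"""Synthetic odor-identification task-fMRI cohort generator.

Emulates the acquisition the analysis assumes: two runs per subject, eight
odorants presented four times each per run in 16-s stimulation+choice events,
a 16-s baseline block after each set of eight, TR = 2 s, with hit/miss
outcomes, per-run rigid-body motion traces, a per-subject covariate table
(ApoE ε4 carrier status, SDOIT odor-identification score, mean odor
familiarity, age, sex), and 4D BOLD volumes built from planted spatial
networks.

The BOLD model is linear: each planted network contributes its spatial map
times a timecourse made of (a) HRF-convolved hit/miss responses scaled by
per-subject amplitudes and (b) an intrinsic low-frequency fluctuation.  The
intrinsic term is what makes the networks separable by ICA (pure task-locked
timecourses all live in the 2-dimensional span of the hit/miss regressors)
and keeps the gPPI design full rank.  One designated network's hit amplitude
is a linear function of the centered covariates, including a three-way
ApoE x SDOIT x familiarity moderation; one network acts as gPPI seed whose
(centered) timecourse couples into a target voxel set during hit events only.
Noise is AR(1) + linear drift + thermal Gaussian, and frames where the motion
trace carries a planted spike receive a global intensity offset so FD/DVARS
flagging has something to find.

Everything is driven by one integer seed through spawned RNG streams, so any
volume is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hemodynamics import HrfKernel, build_condition_regressor, canonical_hrf
from .io import Bold4D, save_bold, save_table, save_volume


@dataclass
class CohortSpec:
    """Acquisition, schedule, covariate and noise parameters for one cohort."""

    n_subjects: int = 10
    grid: tuple[int, int, int] = (15, 15, 12)
    n_runs: int = 2
    tr_s: float = 2.0
    event_s: float = 16.0
    odorants: int = 8
    reps_per_run: int = 4
    baseline_s: float = 16.0
    n_frames: int | None = None  # default: exactly the schedule length

    n_components: int = 6
    n_task_components: int = 5

    # covariate model (single-ε4-carrier design; SDOIT 0-8, familiarity 1-10)
    apoe_fraction: float = 16 / 36
    sdoit_mean: float = 4.4
    sdoit_sd: float = 2.0
    familiarity_mean: float = 4.7
    familiarity_sd: float = 1.9
    age_mean: float = 76.6
    age_sd: float = 4.2
    female_fraction: float = 20 / 36

    # hit probability: logistic in SDOIT so ability and accuracy correlate
    hit_logit_intercept: float = 0.4
    hit_logit_slope: float = 0.35

    # signal model
    intrinsic_sd: float = 1.0
    intrinsic_smooth_frames: float = 3.0
    base_hit_amplitudes: tuple = (1.0, 0.9, 0.9, 0.8, 0.8)
    miss_ratio: float = 0.6
    moderated_component: int = 4
    tmfc_seed_component: int = 0
    tmfc_gain: float = 0.5
    tmfc_n_targets: int = 30

    # noise model
    ar1_phi: float = 0.3
    drift_amplitude: float = 0.5
    thermal_sd: float = 0.5
    spike_prob: float = 0.0
    spike_artifact: float = 3.0

    # noise-region (CSF-like) box for aCompCor, at the grid corner
    noise_box: tuple[int, int, int] = (4, 4, 3)

    def __post_init__(self) -> None:
        if self.n_frames is None:
            self.n_frames = self.schedule_frames()
        if self.n_frames * self.tr_s < self.schedule_length_s():
            raise ValueError(
                f"run of {self.n_frames} frames ({self.n_frames * self.tr_s:.0f}s) "
                f"cannot hold the schedule ({self.schedule_length_s():.0f}s); "
                f"need at least {self.schedule_frames()} frames"
            )
        if not 0 <= self.apoe_fraction <= 1:
            raise ValueError("apoe_fraction must lie in [0, 1]")

    def schedule_length_s(self) -> float:
        block = self.odorants * self.event_s + self.baseline_s
        return self.reps_per_run * block

    def schedule_frames(self) -> int:
        return int(np.ceil(self.schedule_length_s() / self.tr_s))


@dataclass
class ActivationModeration:
    """Linear moderation of the designated network's hit amplitude."""

    apoe: float = -0.25
    sdoit: float = 0.05
    fam: float = 0.05
    apoe_x_sdoit: float = 0.03
    apoe_x_fam: float = 0.03
    sdoit_x_fam: float = 0.02
    three_way: float = 0.078


@dataclass
class GroundTruth:
    planted_maps: np.ndarray  # C x (x,y,z), unit peak
    planted_maps_z: np.ndarray  # C x (x,y,z), z-scored over analysis mask
    planted_task_amplitudes: np.ndarray  # subjects x C x 2 (hit, miss)
    activation_moderation: ActivationModeration
    tmfc_seed_component: int
    tmfc_targets: np.ndarray  # boolean volume
    tmfc_gains: np.ndarray  # per subject (hit-specific coupling gain)
    noise_model: dict
    seeds: dict[str, int]
    analysis_mask: np.ndarray
    noise_mask: np.ndarray


# ---------------------------------------------------------------------------
# spatial maps
# ---------------------------------------------------------------------------

def _blob(grid, center, sigma) -> np.ndarray:
    axes = [np.arange(n, dtype=float) for n in grid]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    d2 = ((xx - center[0]) ** 2 + (yy - center[1]) ** 2 + (zz - center[2]) ** 2)
    return np.exp(-d2 / (2.0 * sigma**2))


def plant_spatial_maps(
    grid: tuple[int, int, int],
    n_components: int,
    seed: int,
    max_abs_r: float = 0.2,
    exclude: np.ndarray | None = None,
    max_tries: int = 500,
) -> np.ndarray:
    """Plant ``n_components`` unit-peak blob maps, pairwise |spatial r| < 0.2.

    Each map is a sum of 1-3 Gaussian blobs normalised to unit peak.  Blob
    centers avoid ``exclude`` (e.g. the noise-region box).  Deterministic for
    a fixed seed; a grid below 12 voxels on any axis cannot hold enough
    non-overlapping blobs and raises, naming the axis.
    """
    if n_components < 2:
        raise ValueError("need at least 2 components")
    for ax, n in enumerate(grid):
        if n < 12:
            raise ValueError(
                f"grid axis {'xyz'[ax]} has {n} voxels; need >= 12 to place "
                "non-overlapping blobs"
            )
    rng = np.random.default_rng(seed)
    maps: list[np.ndarray] = []
    flat: list[np.ndarray] = []
    for c in range(n_components):
        for _ in range(max_tries):
            n_blobs = rng.integers(1, 4)
            vol = np.zeros(grid)
            for _ in range(n_blobs):
                center = [rng.uniform(2.5, g - 3.5) for g in grid]
                if exclude is not None and exclude[
                    int(round(center[0])), int(round(center[1])), int(round(center[2]))
                ]:
                    center = [g - 1 - c_ for g, c_ in zip(grid, center)]
                sigma = rng.uniform(1.4, 2.2)
                vol += _blob(grid, center, sigma)
            vol /= vol.max()
            v = vol.ravel() - vol.mean()
            ok = all(
                abs(v @ u / np.sqrt((v @ v) * (u @ u))) < max_abs_r for u in flat
            )
            if ok:
                maps.append(vol)
                flat.append(v)
                break
        else:
            raise RuntimeError(
                f"could not place component {c} with pairwise |r| < {max_abs_r} "
                f"on grid {grid} after {max_tries} tries"
            )
    return np.stack(maps)


# ---------------------------------------------------------------------------
# events and motion
# ---------------------------------------------------------------------------

def schedule_events(spec: CohortSpec, subject_accuracy: float, seed: int) -> pd.DataFrame:
    """One run's event table: blocks of 8 odorant events plus a 16-s baseline.

    Each stimulation+choice event lasts ``event_s`` seconds; every odorant
    appears once per block in a seeded random order; each stim event is a hit
    with probability ``subject_accuracy`` (independent Bernoulli draws).
    """
    if not 0.0 <= subject_accuracy <= 1.0:
        raise ValueError("subject_accuracy must lie in [0, 1]")
    if spec.n_frames * spec.tr_s < spec.schedule_length_s():
        raise ValueError(
            f"run length {spec.n_frames} frames is insufficient; "
            f"need {spec.schedule_frames()}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    t = 0.0
    for _ in range(spec.reps_per_run):
        order = rng.permutation(spec.odorants)
        for od in order:
            outcome = "hit" if rng.random() < subject_accuracy else "miss"
            rows.append(
                {"onset": t, "duration": spec.event_s, "trial_type": "stim",
                 "odorant": int(od), "outcome": outcome}
            )
            t += spec.event_s
        rows.append(
            {"onset": t, "duration": spec.baseline_s, "trial_type": "baseline",
             "odorant": -1, "outcome": ""}
        )
        t += spec.baseline_s
    return pd.DataFrame(rows)


def simulate_motion(n_frames: int, spike_prob: float, seed: int) -> np.ndarray:
    """Six-column rigid-body motion trace as bounded random walks.

    Translations in mm, rotations in radians.  With probability
    ``spike_prob`` a frame receives a >1 mm translation jump, so framewise
    displacement spikes exist in fixtures when requested.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    steps = np.clip(rng.normal(0.0, 0.03, size=(n_frames, 6)), -0.12, 0.12)
    steps[:, 3:] *= 0.01  # rotations stay small (rad)
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)
    motion[:, :3] = np.clip(motion[:, :3], -0.5, 0.5)
    motion[:, 3:] = np.clip(motion[:, 3:], -0.01, 0.01)
    if spike_prob > 0:
        spikes = rng.random(n_frames) < spike_prob
        spikes[0] = False
        if spike_prob >= 1.0:
            spikes[1:] = True
        for f in np.flatnonzero(spikes):
            motion[f:, 0] += 1.5 * rng.choice([-1.0, 1.0])
    return motion


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def draw_covariates(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Per-subject covariate table mirroring the study population.

    ApoE ε4 carrier status Bernoulli, SDOIT an integer score on 0-8,
    familiarity continuous on 1-10, age Gaussian, sex Bernoulli.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_subjects
    apoe = (rng.random(n) < spec.apoe_fraction).astype(int)
    sdoit = np.clip(np.round(rng.normal(spec.sdoit_mean, spec.sdoit_sd, n)), 0, 8)
    fam = np.clip(rng.normal(spec.familiarity_mean, spec.familiarity_sd, n), 1.0, 10.0)
    age = rng.normal(spec.age_mean, spec.age_sd, n)
    sex = (rng.random(n) < spec.female_fraction).astype(int)
    return pd.DataFrame(
        {
            "subject": [f"sub-{i + 1:02d}" for i in range(n)],
            "apoe4": apoe,
            "sdoit": sdoit.astype(int),
            "familiarity": fam,
            "age": age,
            "sex": sex,
        }
    )


def simulate_activation_outcome(
    covariates: pd.DataFrame,
    moderation: ActivationModeration | None = None,
    base: float = 0.8,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Per-subject activation betas under the covariate-moderation model.

    Outcome = base + moderation terms in the centered covariates + Gaussian
    noise — the scalar analogue of the moderated network activation the group
    regression is meant to recover.
    """
    moderation = moderation or ActivationModeration()
    rng = np.random.default_rng(seed)
    sdoit_c = covariates["sdoit"] - covariates["sdoit"].mean()
    fam_c = covariates["familiarity"] - covariates["familiarity"].mean()
    apoe = covariates["apoe4"].astype(float)
    mu = (
        base
        + moderation.apoe * apoe
        + moderation.sdoit * sdoit_c
        + moderation.fam * fam_c
        + moderation.apoe_x_sdoit * apoe * sdoit_c
        + moderation.apoe_x_fam * apoe * fam_c
        + moderation.sdoit_x_fam * sdoit_c * fam_c
        + moderation.three_way * apoe * sdoit_c * fam_c
    )
    return mu.to_numpy() + rng.normal(0.0, noise_sd, len(covariates))


def hit_probability(spec: CohortSpec, sdoit: np.ndarray) -> np.ndarray:
    """Logistic accuracy model linking identification ability to in-scanner hits."""
    z = spec.hit_logit_intercept + spec.hit_logit_slope * (
        np.asarray(sdoit, dtype=float) - 4.0
    )
    return 1.0 / (1.0 + np.exp(-z))


# ---------------------------------------------------------------------------
# ground truth assembly
# ---------------------------------------------------------------------------

def _masks_for(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    noise = np.zeros(spec.grid, dtype=bool)
    bx, by, bz = spec.noise_box
    noise[:bx, :by, :bz] = True
    analysis = ~noise
    return analysis, noise


def build_ground_truth(
    spec: CohortSpec,
    covariates: pd.DataFrame,
    seed: int,
    moderation: ActivationModeration | None = None,
) -> GroundTruth:
    """Plant maps, per-subject amplitudes, the moderation and the gPPI effect."""
    moderation = moderation or ActivationModeration()
    ss = np.random.SeedSequence(seed)
    map_seed, amp_seed, target_seed = (int(s) for s in ss.generate_state(3) % (2**31))
    analysis_mask, noise_mask = _masks_for(spec)
    maps = plant_spatial_maps(spec.grid, spec.n_components, map_seed, exclude=noise_mask)

    flatmask = analysis_mask.ravel()
    maps_z = np.empty_like(maps)
    for c in range(spec.n_components):
        v = maps[c].ravel()[flatmask]
        maps_z[c] = (maps[c] - v.mean()) / v.std()

    n = spec.n_subjects
    amps = np.zeros((n, spec.n_components, 2))  # (hit, miss)
    base = np.asarray(spec.base_hit_amplitudes, dtype=float)
    n_task = min(spec.n_task_components, spec.n_components, len(base))
    for c in range(n_task):
        amps[:, c, 0] = base[c]
        amps[:, c, 1] = base[c] * spec.miss_ratio

    sdoit_c = covariates["sdoit"] - covariates["sdoit"].mean()
    fam_c = covariates["familiarity"] - covariates["familiarity"].mean()
    apoe = covariates["apoe4"].astype(float)
    mod = moderation
    dc = spec.moderated_component
    amps[:, dc, 0] += (
        mod.apoe * apoe
        + mod.sdoit * sdoit_c
        + mod.fam * fam_c
        + mod.apoe_x_sdoit * apoe * sdoit_c
        + mod.apoe_x_fam * apoe * fam_c
        + mod.sdoit_x_fam * sdoit_c * fam_c
        + mod.three_way * apoe * sdoit_c * fam_c
    )

    # gPPI targets: a compact in-mask ball centered where every planted map is
    # weak (a connected cluster, as real coupling effects are)
    rng = np.random.default_rng(target_seed)
    peak_load = np.abs(maps).max(axis=0)
    grid_idx = np.indices(spec.grid)
    interior = analysis_mask.copy()
    for ax, g in enumerate(spec.grid):
        interior &= (grid_idx[ax] >= 2) & (grid_idx[ax] <= g - 3)
    cand = np.flatnonzero(interior.ravel())
    center_flat = cand[np.argmin(peak_load.ravel()[cand])]
    center = np.unravel_index(center_flat, spec.grid)
    d2 = sum((grid_idx[ax] - center[ax]) ** 2 for ax in range(3)).astype(float)
    d2[~analysis_mask] = np.inf
    order = np.argsort(d2.ravel(), kind="stable")[: spec.tmfc_n_targets]
    targets = np.zeros(spec.grid, dtype=bool)
    targets.ravel()[order] = True

    gains = np.full(n, spec.tmfc_gain)

    subj_seeds = {
        f"sub-{i + 1:02d}": int(s)
        for i, s in enumerate(ss.generate_state(n + 3)[3:] % (2**31))
    }
    return GroundTruth(
        planted_maps=maps,
        planted_maps_z=maps_z,
        planted_task_amplitudes=amps,
        activation_moderation=moderation,
        tmfc_seed_component=spec.tmfc_seed_component,
        tmfc_targets=targets,
        tmfc_gains=gains,
        noise_model={
            "ar1_phi": spec.ar1_phi,
            "drift_amplitude": spec.drift_amplitude,
            "thermal_sd": spec.thermal_sd,
        },
        seeds={"maps": map_seed, "amplitudes": amp_seed, **subj_seeds},
        analysis_mask=analysis_mask,
        noise_mask=noise_mask,
    )


# ---------------------------------------------------------------------------
# BOLD synthesis
# ---------------------------------------------------------------------------

def _smooth_series(x: np.ndarray, width: float) -> np.ndarray:
    if width <= 0:
        return x
    from scipy.ndimage import gaussian_filter1d

    return gaussian_filter1d(x, sigma=width, axis=0, mode="nearest")


def component_timecourses(
    spec: CohortSpec,
    events: pd.DataFrame,
    amplitudes: np.ndarray,
    hrf: HrfKernel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frames x C timecourses: task responses plus intrinsic fluctuations."""
    n_frames = spec.n_frames
    hit_reg = build_condition_regressor(events, "hit", n_frames, spec.tr_s, hrf)
    miss_reg = build_condition_regressor(events, "miss", n_frames, spec.tr_s, hrf)
    tcs = np.empty((n_frames, spec.n_components))
    for c in range(spec.n_components):
        intrinsic = _smooth_series(
            rng.standard_normal(n_frames), spec.intrinsic_smooth_frames
        )
        sd = intrinsic.std()
        if sd > 0:
            intrinsic = intrinsic / sd * spec.intrinsic_sd
        tcs[:, c] = amplitudes[c, 0] * hit_reg + amplitudes[c, 1] * miss_reg + intrinsic
    return tcs


def simulate_subject_bold(
    spec: CohortSpec,
    ground_truth: GroundTruth,
    events: pd.DataFrame,
    motion: np.ndarray,
    subject_index: int,
    seed: int,
    hrf: HrfKernel | None = None,
) -> tuple[Bold4D, np.ndarray]:
    """One run's 4D BOLD for one subject; returns (bold, timecourses).

    BOLD = sum_c map_c x timecourse_c + hit-gated seed coupling into the
    target voxels + drift + AR(1)-filtered thermal noise + spike artifacts.
    With thermal/drift amplitudes at 0 the volume equals the deterministic
    mean field exactly (the intrinsic fluctuation is part of the signal and is
    reproduced from the seeded stream).
    """
    if ground_truth.planted_maps.shape[1:] != tuple(spec.grid):
        raise ValueError(
            f"planted map grid {ground_truth.planted_maps.shape[1:]} does not "
            f"match spec grid {spec.grid}"
        )
    hrf = hrf or canonical_hrf(10.0, spec.tr_s)
    ss = np.random.SeedSequence(seed)
    rng_sig, rng_noise = (np.random.default_rng(s) for s in ss.spawn(2))
    n_frames = spec.n_frames
    amps = ground_truth.planted_task_amplitudes[subject_index]
    tcs = component_timecourses(spec, events, amps, hrf, rng_sig)

    maps_flat = ground_truth.planted_maps_z.reshape(spec.n_components, -1)
    vol = tcs @ maps_flat  # frames x voxels

    # condition-specific seed->target coupling (gPPI ground truth, hits only)
    seed_tc = tcs[:, ground_truth.tmfc_seed_component]
    hit_reg = build_condition_regressor(events, "hit", n_frames, spec.tr_s, hrf)
    inter = (seed_tc - seed_tc.mean()) * (hit_reg - hit_reg.mean())
    gain = ground_truth.tmfc_gains[subject_index]
    tvox = np.flatnonzero(ground_truth.tmfc_targets.ravel())
    vol[:, tvox] += gain * inter[:, None]

    # noise: linear drift with a random spatial field + AR(1) thermal noise
    n_vox = vol.shape[1]
    if spec.drift_amplitude > 0:
        slope = rng_noise.normal(0.0, spec.drift_amplitude, n_vox)
        ramp = np.linspace(-1.0, 1.0, n_frames)
        vol += ramp[:, None] * slope[None, :]
    if spec.thermal_sd > 0:
        white = rng_noise.normal(0.0, spec.thermal_sd, (n_frames, n_vox))
        noise = np.empty_like(white)
        noise[0] = white[0]
        for t in range(1, n_frames):
            noise[t] = spec.ar1_phi * noise[t - 1] + white[t]
        vol += noise

    # motion spike artifacts: global offset at frames with planted FD spikes
    from .confounds import framewise_displacement

    fd = framewise_displacement(motion)
    for f in np.flatnonzero(fd > 1.0):
        vol[f] += spec.spike_artifact * rng_noise.standard_normal(n_vox)

    # CSF-like noise region: shared physiological factor + thermal noise
    nvox_noise = np.flatnonzero(ground_truth.noise_mask.ravel())
    t_axis = np.arange(n_frames) * spec.tr_s
    physio = np.sin(2 * np.pi * 0.08 * t_axis + rng_noise.uniform(0, 2 * np.pi))
    weights = rng_noise.normal(1.0, 0.3, nvox_noise.size)
    vol[:, nvox_noise] = physio[:, None] * weights[None, :]
    if spec.thermal_sd > 0:
        vol[:, nvox_noise] += rng_noise.normal(
            0.0, 0.3 * spec.thermal_sd, (n_frames, nvox_noise.size)
        )

    data = vol.T.reshape(*spec.grid, n_frames)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    bold = Bold4D(
        data=data, affine=affine, tr_s=spec.tr_s, mask=ground_truth.analysis_mask
    )
    return bold, tcs


# ---------------------------------------------------------------------------
# cohort bundle
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    spec: CohortSpec
    participants: pd.DataFrame
    ground_truth: GroundTruth
    bold: list[list[Bold4D]]  # subject x run
    events: list[list[pd.DataFrame]]
    motion: list[list[np.ndarray]]
    timecourses: list[list[np.ndarray]]  # planted, subject x run, frames x C


def generate_cohort(
    spec: CohortSpec,
    seed: int,
    moderation: ActivationModeration | None = None,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate (and optionally write) a full cohort; idempotent per seed."""
    ss = np.random.SeedSequence(seed)
    cov_seed, gt_seed = (int(s) for s in ss.generate_state(2) % (2**31))
    covariates = draw_covariates(spec, cov_seed)
    gt = build_ground_truth(spec, covariates, gt_seed, moderation=moderation)
    hrf = canonical_hrf(10.0, spec.tr_s)
    p_hit = hit_probability(spec, covariates["sdoit"].to_numpy())

    bolds, events_all, motions, tcs_all = [], [], [], []
    for i in range(spec.n_subjects):
        sub_id = f"sub-{i + 1:02d}"
        sub_ss = np.random.SeedSequence(gt.seeds[sub_id])
        run_seeds = sub_ss.generate_state(3 * spec.n_runs) % (2**31)
        b_runs, e_runs, m_runs, t_runs = [], [], [], []
        for r in range(spec.n_runs):
            ev_seed, mo_seed, bo_seed = (int(s) for s in run_seeds[3 * r : 3 * r + 3])
            ev = schedule_events(spec, float(p_hit[i]), ev_seed)
            mo = simulate_motion(spec.n_frames, spec.spike_prob, mo_seed)
            bold, tcs = simulate_subject_bold(spec, gt, ev, mo, i, bo_seed, hrf=hrf)
            b_runs.append(bold)
            e_runs.append(ev)
            m_runs.append(mo)
            t_runs.append(tcs)
        bolds.append(b_runs)
        events_all.append(e_runs)
        motions.append(m_runs)
        tcs_all.append(t_runs)

    cohort = Cohort(
        spec=spec,
        participants=covariates,
        ground_truth=gt,
        bold=bolds,
        events=events_all,
        motion=motions,
        timecourses=tcs_all,
    )
    if out_dir is not None:
        write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    """Write the BIDS-like dataset plus a ground-truth manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    gt = cohort.ground_truth
    for i in range(spec.n_subjects):
        sub = f"sub-{i + 1:02d}"
        func = out / sub / "func"
        for r in range(spec.n_runs):
            save_bold(cohort.bold[i][r], func / f"{sub}_run-{r + 1}_bold.nii.gz")
            save_table(cohort.events[i][r], func / f"{sub}_run-{r + 1}_events.tsv")
            mo = pd.DataFrame(
                cohort.motion[i][r],
                columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
            )
            save_table(mo, func / f"{sub}_run-{r + 1}_confounds.tsv")
    save_table(cohort.participants, out / "participants.tsv")
    affine = np.diag([3.0, 3.0, 3.0, 1.0])
    save_volume(gt.analysis_mask.astype(np.float32), affine, out / "brain_mask.nii.gz")
    save_volume(gt.noise_mask.astype(np.float32), affine, out / "noise_mask.nii.gz")
    save_volume(np.moveaxis(gt.planted_maps, 0, -1), affine, out / "planted_maps.nii.gz")
    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in asdict(spec).items()},
        "activation_moderation": asdict(gt.activation_moderation),
        "tmfc": {
            "seed_component": gt.tmfc_seed_component,
            "gains": gt.tmfc_gains.tolist(),
            "n_targets": int(gt.tmfc_targets.sum()),
        },
        "noise_model": gt.noise_model,
        "seeds": gt.seeds,
        "planted_task_amplitudes": gt.planted_task_amplitudes.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))
    return out
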