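"""End-to-end orchestration: smooth → group ICA → temporal sorting →
condition betas → TMFC → group statistics, over a BIDS-like dataset directory.

Every stage is driven by a :class:`PipelineConfig`; a JSON manifest ties each
run's outputs to the inputs, seeds and thresholds that produced them, so a
rerun with the same configuration reproduces every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import confounds as cf
from . import groupstats as gs
from . import ica as ica_mod
from . import sorting as sort_mod
from . import tmfc as tmfc_mod
from .hemodynamics import build_condition_regressor, build_task_design, canonical_hrf
from .io import Bold4D, load_bold, load_confounds, load_events, load_participants, smooth_gaussian

log = logging.getLogger("olfica")


@dataclass
class PipelineConfig:
    """All tunable parameters of the pipeline with their default thresholds."""

    dataset_dir: str = "."
    output_dir: str = "derivatives"
    smoothing_fwhm_mm: float = 8.0
    ica_order: int | str = "mdl"  # integer, or "mdl" for automatic selection
    icasso_runs: int = 10
    subject_pca_factor: float = 1.5  # l1 = round(factor * order)
    retention_threshold: float = 0.2
    hrf_duration_s: float = 10.0
    fd_thresh_mm: float = 1.0
    dvars_thresh: float = 2.0
    dvars_standardized: bool = True
    highpass_hz: float = 0.01
    tmap_voxel_p: float = 0.0001
    tmap_cluster_k: int = 100
    regression_voxel_p: float = 0.001
    regression_cluster_k: int = 75
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("smoothing_fwhm_mm", "retention_threshold", "hrf_duration_s",
                     "fd_thresh_mm", "dvars_thresh", "highpass_hz", "tmap_voxel_p",
                     "regression_voxel_p"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


class StageError(RuntimeError):
    """Wraps a stage failure with the stage name and subject context."""

    def __init__(self, stage: str, context: str, cause: Exception):
        super().__init__(f"[{stage}] {context}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class Dataset:
    subjects: list[str]
    participants: pd.DataFrame
    bold: list[list[Bold4D]]
    events: list[list[pd.DataFrame]]
    motion: list[list[np.ndarray]]
    mask: np.ndarray
    noise_mask: np.ndarray
    tr_s: float


def load_dataset(dataset_dir: str | Path) -> Dataset:
    """Load the on-disk cohort layout written by the synthetic generator."""
    root = Path(dataset_dir)
    import nibabel as nib

    participants = load_participants(root / "participants.tsv")
    mask = np.asanyarray(nib.load(str(root / "brain_mask.nii.gz")).dataobj) > 0.5
    noise_mask = np.asanyarray(nib.load(str(root / "noise_mask.nii.gz")).dataobj) > 0.5
    subjects = list(participants["subject"])
    bolds, events, motions = [], [], []
    tr_s = None
    for sub in subjects:
        func = root / sub / "func"
        runs = sorted(func.glob(f"{sub}_run-*_bold.nii.gz"))
        if not runs:
            raise StageError("load", sub, FileNotFoundError(f"no BOLD runs in {func}"))
        b_runs, e_runs, m_runs = [], [], []
        for bold_path in runs:
            run_tag = bold_path.name.split("_run-")[1].split("_")[0]
            try:
                bold = load_bold(bold_path, mask=mask)
                ev = load_events(func / f"{sub}_run-{run_tag}_events.tsv")
                mo = load_confounds(func / f"{sub}_run-{run_tag}_confounds.tsv")
            except Exception as exc:  # noqa: BLE001
                raise StageError("load", f"{sub} run-{run_tag}", exc) from exc
            b_runs.append(bold)
            e_runs.append(ev)
            m_runs.append(mo[list(cf.MOTION_COLUMNS)].to_numpy())
            tr_s = bold.tr_s
        bolds.append(b_runs)
        events.append(e_runs)
        motions.append(m_runs)
    return Dataset(
        subjects=subjects,
        participants=participants,
        bold=bolds,
        events=events,
        motion=motions,
        mask=mask,
        noise_mask=noise_mask,
        tr_s=float(tr_s),
    )


@dataclass
class PipelineResult:
    config: PipelineConfig
    component_set: ica_mod.ComponentSet
    subject_components: ica_mod.SubjectComponents
    relevance: sort_mod.TaskRelevance
    retained: np.ndarray
    betas: sort_mod.ConditionBetas
    tmfc_maps: dict  # (subject_idx, component) -> TmfcMaps
    activation_fits: dict  # (component, condition) -> GroupFit
    tmfc_fits: dict  # (component, condition) -> (GroupFit, StatMap thresholded 3-way)
    tmaps: dict  # component -> StatMap
    manifest: dict
    mask: np.ndarray = field(default=None)  # type: ignore


def run_pipeline(config: PipelineConfig, dataset: Dataset | None = None) -> PipelineResult:
    """Execute every stage and return the bundled results + manifest."""
    if dataset is None:
        dataset = load_dataset(config.dataset_dir)
    mask = dataset.mask
    tr = dataset.tr_s
    hrf = canonical_hrf(config.hrf_duration_s, tr)

    # --- smoothing -------------------------------------------------------
    log.info("smoothing %d subjects at %.1f mm FWHM", len(dataset.subjects),
             config.smoothing_fwhm_mm)
    smoothed: list[list[Bold4D]] = []
    for sub, runs in zip(dataset.subjects, dataset.bold):
        try:
            smoothed.append([smooth_gaussian(b, config.smoothing_fwhm_mm) for b in runs])
        except Exception as exc:  # noqa: BLE001
            raise StageError("smooth", sub, exc) from exc

    # --- group ICA -------------------------------------------------------
    subject_matrices = [
        np.vstack([b.data[mask].T for b in runs]) for runs in smoothed
    ]
    if config.ica_order == "mdl":
        order = ica_mod.estimate_order_mdl(np.vstack(subject_matrices))
    else:
        order = int(config.ica_order)
    log.info("group ICA at order %d (ICASSO x%d)", order, config.icasso_runs)
    try:
        cset = ica_mod.run_group_ica(
            subject_matrices,
            c=order,
            l1=int(round(config.subject_pca_factor * order)),
            n_runs=config.icasso_runs,
            base_seed=config.seed,
        )
        subj_comps = ica_mod.gica3_backreconstruct(cset)
    except Exception as exc:  # noqa: BLE001
        raise StageError("ica", "group", exc) from exc

    run_frames = [b.n_frames for b in smoothed[0]]

    def split_runs(tc: np.ndarray) -> list[np.ndarray]:
        out, start = [], 0
        for n in run_frames:
            out.append(tc[start : start + n])
            start += n
        return out

    subject_run_tcs = [split_runs(tc) for tc in subj_comps.timecourses]

    # --- temporal sorting ------------------------------------------------
    generic = [
        build_condition_regressor(dataset.events[0][r], "all_stim", run_frames[r], tr, hrf)
        for r in range(len(run_frames))
    ]
    relevance = sort_mod.sort_by_task_correlation(subject_run_tcs, generic)
    retained = sort_mod.retain_task_components(relevance, config.retention_threshold)
    log.info("retained %d/%d components: %s", len(retained), order, list(retained))

    # --- condition betas -------------------------------------------------
    designs = [
        [
            build_task_design(dataset.events[i][r], tr, run_frames[r], hrf).frame
            for r in range(len(run_frames))
        ]
        for i in range(len(dataset.subjects))
    ]
    betas = sort_mod.condition_betas(subject_run_tcs, designs, components=retained)

    # --- TMFC ------------------------------------------------------------
    tmfc_maps: dict = {}
    confound_cache = []
    for i, sub in enumerate(dataset.subjects):
        try:
            cms = [
                cf.build_confound_matrix(
                    smoothed[i][r],
                    dataset.motion[i][r],
                    dataset.noise_mask,
                    fd_thresh=config.fd_thresh_mm,
                    dvars_thresh=config.dvars_thresh,
                    highpass_hz=config.highpass_hz,
                    dvars_standardized=config.dvars_standardized,
                )
                for r in range(len(run_frames))
            ]
        except Exception as exc:  # noqa: BLE001
            raise StageError("confounds", sub, exc) from exc
        confound_cache.append(cms)
        concat = Bold4D(
            data=np.concatenate([b.data for b in smoothed[i]], axis=3),
            affine=smoothed[i][0].affine,
            tr_s=tr,
            mask=mask,
        )
        for c_idx, comp in enumerate(retained):
            try:
                design = tmfc_mod.build_ppi_design(
                    subj_comps.timecourses[i][:, comp], designs[i], cms
                )
                fit = tmfc_mod.fit_voxelwise_glm(concat, design)
                tmfc_maps[(i, int(comp))] = tmfc_mod.extract_tmfc(fit)
            except Exception as exc:  # noqa: BLE001
                raise StageError("tmfc", f"{sub} component {comp}", exc) from exc

    # --- group statistics ------------------------------------------------
    gdesign = gs.build_group_design(dataset.participants)
    regression_ok = gdesign.n > gdesign.frame.shape[1]
    if not regression_ok:
        log.warning(
            "n=%d subjects cannot identify the %d-column moderation design; "
            "group regressions skipped", gdesign.n, gdesign.frame.shape[1],
        )
    tmaps, activation_fits, tmfc_fits = {}, {}, {}
    for j, comp in enumerate(retained):
        comp = int(comp)
        subj_maps = subj_comps.maps[:, comp, :]
        raw_t = gs.one_sample_tmap(subj_maps)
        vol_t = _unflatten(raw_t, mask)
        tmaps[comp] = gs.cluster_threshold(
            vol_t, p_voxel=config.tmap_voxel_p, k_min=config.tmap_cluster_k,
            connectivity=config.connectivity, mask=mask,
        )
        if not regression_ok:
            continue
        for cond, vals in (("hit", betas.hit[:, j]), ("miss", betas.miss[:, j])):
            activation_fits[(comp, cond)] = gs.fit_group_regression(vals, gdesign)
        for cond in ("hit", "miss"):
            stack = []
            for i in range(len(dataset.subjects)):
                m = getattr(tmfc_maps[(i, comp)], cond)
                stack.append(m if m is not None else np.full(int(mask.sum()), np.nan))
            outcome = np.asarray(stack)
            ok = np.isfinite(outcome).all(axis=1)
            fit = gs.fit_group_regression(outcome[ok], _subset_design(gdesign, ok))
            smap = fit.stat_map("apoe_x_sdoit_x_fam")
            vol = _unflatten(smap, mask)
            thresh = gs.cluster_threshold(
                vol, p_voxel=config.regression_voxel_p,
                k_min=config.regression_cluster_k,
                connectivity=config.connectivity, mask=mask,
            )
            tmfc_fits[(comp, cond)] = (fit, thresh)

    manifest = _build_manifest(config, dataset, order, cset, relevance, retained)
    return PipelineResult(
        config=config,
        component_set=cset,
        subject_components=subj_comps,
        relevance=relevance,
        retained=retained,
        betas=betas,
        tmfc_maps=tmfc_maps,
        activation_fits=activation_fits,
        tmfc_fits=tmfc_fits,
        tmaps=tmaps,
        manifest=manifest,
        mask=mask,
    )


def _unflatten(stat_map: gs.StatMap, mask: np.ndarray) -> gs.StatMap:
    stat = np.zeros(mask.shape)
    p = np.ones(mask.shape)
    stat[mask] = stat_map.stat
    p[mask] = stat_map.p
    return gs.StatMap(stat=stat, p=p, df=stat_map.df, flags=dict(stat_map.flags))


def _subset_design(design: gs.GroupDesign, keep: np.ndarray) -> gs.GroupDesign:
    return gs.GroupDesign(
        frame=design.frame.loc[keep].reset_index(drop=True),
        centers=design.centers,
        subjects=design.subjects[keep],
    )


def _build_manifest(config, dataset, order, cset, relevance, retained) -> dict:
    payload = {
        "config": asdict(config),
        "n_subjects": len(dataset.subjects),
        "ica_order": int(order),
        "stability_iq": [float(x) for x in cset.stability_iq],
        "retained_components": [int(c) for c in retained],
        "mean_abs_corr": {
            int(r.component): round(float(r.mean_abs_corr), 6)
            for r in relevance.table.itertuples()
        },
    }
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
    payload["manifest_sha256"] = digest
    return payload


def save_results(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write manifest, relevance/beta tables, and cluster tables as text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
    result.relevance.table.to_csv(out / "task_relevance.tsv", sep="\t", index=False)
    beta_rows = []
    for j, comp in enumerate(result.betas.components):
        for i in range(result.betas.hit.shape[0]):
            beta_rows.append(
                {"subject_index": i, "component": int(comp),
                 "hit_beta": result.betas.hit[i, j], "miss_beta": result.betas.miss[i, j]}
            )
    pd.DataFrame(beta_rows).to_csv(out / "condition_betas.tsv", sep="\t", index=False)
    for comp, smap in result.tmaps.items():
        if smap.cluster_table is not None:
            smap.cluster_table.to_csv(
                out / f"component-{comp:02d}_tmap_clusters.tsv", sep="\t", index=False
            )
    for (comp, cond), (fit, thresh) in result.tmfc_fits.items():
        if thresh.cluster_table is not None:
            thresh.cluster_table.to_csv(
                out / f"component-{comp:02d}_cond-{cond}_tmfc_clusters.tsv",
                sep="\t", index=False,
            )
    return out
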