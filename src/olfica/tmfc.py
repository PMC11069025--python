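"""Hybrid ICA-gPPI: task-modulated functional connectivity maps.

For each subject and each retained component, a generalized
psychophysiological-interaction GLM is fitted at every voxel.  The design
carries the main effects of hits, misses and the (mean-centered) component
timecourse, the two interaction regressors — centered seed x centered
condition regressor — and the full nuisance block (24-parameter motion,
5 aCompCor, spike indicators, DCT high-pass), with per-run intercepts and
per-run DCT bases when runs are concatenated.  The interaction betas are the
TMFC maps: the change in seed-voxel coupling specific to each condition.

No hemodynamic deconvolution of the seed is applied: interactions are formed
directly on the observed seed timecourse against HRF-convolved psychological
regressors (a boxcar option is available), which is well-posed at TR 2 s with
16-s events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confounds import ConfoundMatrix
from .io import Bold4D


@dataclass
class PpiDesign:
    frame: pd.DataFrame
    roles: dict[str, str]
    empty_conditions: list[str] = field(default_factory=list)
    dropped_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rank = int(np.linalg.matrix_rank(self.frame.to_numpy()))

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


def build_ppi_design(
    seed_timecourse: np.ndarray,
    task_designs: list[pd.DataFrame],
    confound_matrices: list[ConfoundMatrix],
    convolved_psych: bool = True,
    boxcar_designs: list[pd.DataFrame] | None = None,
) -> PpiDesign:
    """Assemble the gPPI design for concatenated runs.

    ``task_designs[r]`` holds the per-run HRF-convolved hit/miss columns;
    ``seed_timecourse`` is the concatenated component timecourse.  The seed
    and the psychological regressors are centered per run before the products
    are formed, so TMFC betas are invariant to constant offsets of either
    parent.  All-zero columns (e.g. a condition absent from a run pair) are
    dropped and recorded; rank deficiency among the task + interaction block
    raises, naming the collinear pair.
    """
    run_lengths = [len(d) for d in task_designs]
    if len(seed_timecourse) != sum(run_lengths):
        raise ValueError("seed timecourse length does not match concatenated runs")
    psych_src = task_designs if convolved_psych else boxcar_designs
    if psych_src is None:
        raise ValueError("boxcar_designs required when convolved_psych=False")

    n_total = sum(run_lengths)
    cols: dict[str, np.ndarray] = {}
    roles: dict[str, str] = {}

    def add(name: str, values: np.ndarray, role: str) -> None:
        cols[name] = values
        roles[name] = role

    offsets = np.concatenate([[0], np.cumsum(run_lengths)])
    for r, n in enumerate(run_lengths):
        block = np.zeros(n_total)
        block[offsets[r] : offsets[r + 1]] = 1.0
        add(f"intercept_run{r + 1}", block, "nuisance")

    seed_c = np.zeros(n_total)
    psych_c = {"hit": np.zeros(n_total), "miss": np.zeros(n_total)}
    psych_raw = {"hit": np.zeros(n_total), "miss": np.zeros(n_total)}
    for r in range(len(run_lengths)):
        sl = slice(offsets[r], offsets[r + 1])
        seg = np.asarray(seed_timecourse[sl], dtype=float)
        seed_c[sl] = seg - seg.mean()
        for cond in ("hit", "miss"):
            raw = np.asarray(psych_src[r][cond], dtype=float)
            psych_raw[cond][sl] = np.asarray(task_designs[r][cond], dtype=float)
            psych_c[cond][sl] = raw - raw.mean() if np.any(raw) else raw

    empty = [cond for cond in ("hit", "miss") if not np.any(psych_raw[cond])]
    for cond in ("hit", "miss"):
        add(cond, psych_c[cond], "task")
    add("seed", seed_c, "task")
    for cond in ("hit", "miss"):
        add(f"{cond}_x_seed", psych_c[cond] * seed_c, "interaction")

    for r, cm in enumerate(confound_matrices):
        sl = slice(offsets[r], offsets[r + 1])
        for name in cm.frame.columns:
            vals = cm.frame[name].to_numpy(dtype=float)
            if name.startswith(("a_comp_cor", "trans", "rot")):
                # shared columns across runs (subject-level nuisances)
                key = name
            else:
                key = f"{name}_run{r + 1}"
            if key not in cols:
                cols[key] = np.zeros(n_total)
                roles[key] = "nuisance"
            cols[key][sl] = vals

    dropped = [k for k, v in cols.items() if not np.any(v)]
    for k in dropped:
        del cols[k]
        del roles[k]

    frame = pd.DataFrame(cols)
    design = PpiDesign(frame=frame, roles=roles, empty_conditions=empty, dropped_columns=dropped)

    task_like = [k for k, v in roles.items() if v in ("task", "interaction")]
    sub = frame[task_like].to_numpy()
    if np.linalg.matrix_rank(sub) < len(task_like):
        corr = np.corrcoef(sub.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(
            f"task/interaction block is rank deficient; most collinear pair: "
            f"'{task_like[i]}' and '{task_like[j]}'"
        )
    return design


@dataclass
class GlmFit:
    betas: dict[str, np.ndarray]  # column name -> volume (masked vector)
    residual_variance: np.ndarray
    df: int
    mask: np.ndarray


def fit_voxelwise_glm(bold: Bold4D, design: PpiDesign | pd.DataFrame) -> GlmFit:
    """Mass-univariate OLS: one pseudo-inverse applied to every voxel series.

    Voxels with non-finite series are excluded from the mask with a warning.
    """
    import warnings

    x = design.matrix if isinstance(design, PpiDesign) else design.to_numpy(dtype=float)
    names = design.columns if isinstance(design, PpiDesign) else list(design.columns)
    mask = bold.mask.copy()
    y = bold.data[mask].T.astype(float)  # t x voxels
    finite = np.isfinite(y).all(axis=0)
    if not finite.all():
        warnings.warn(f"excluding {int((~finite).sum())} voxels with non-finite series")
        idx = np.flatnonzero(mask.ravel())[~finite]
        mask.ravel()[idx] = False
        y = y[:, finite]
    rank = np.linalg.matrix_rank(x)
    df = x.shape[0] - rank
    if df <= 0:
        raise ValueError(f"no residual degrees of freedom: frames={x.shape[0]}, rank={rank}")
    beta = np.linalg.pinv(x) @ y
    resid = y - x @ beta
    resvar = (resid**2).sum(axis=0) / df
    return GlmFit(
        betas={name: beta[j] for j, name in enumerate(names)},
        residual_variance=resvar,
        df=df,
        mask=mask,
    )


@dataclass
class TmfcMaps:
    """Interaction-beta volumes per condition for one subject x component."""

    hit: np.ndarray | None  # masked vector, None when the condition was empty
    miss: np.ndarray | None
    residual_variance: np.ndarray
    df: int
    mask: np.ndarray


def extract_tmfc(fit: GlmFit) -> TmfcMaps:
    """Pick the hit x seed and miss x seed interaction betas out of a GLM fit.

    A missing interaction column (condition empty for this subject) yields a
    ``None`` map — flagged missing rather than zero.
    """
    return TmfcMaps(
        hit=fit.betas.get("hit_x_seed"),
        miss=fit.betas.get("miss_x_seed"),
        residual_variance=fit.residual_variance,
        df=fit.df,
        mask=fit.mask,
    )
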