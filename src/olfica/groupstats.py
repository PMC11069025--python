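"""Group-level inference: one-sample t maps, moderated multiple regression
with ApoE x odor-identification x odor-familiarity interactions, cluster-extent
thresholding, and marginal-means tables.

The moderation model regresses a per-subject outcome (a network-activation
beta, or a TMFC map voxel) on ApoE ε4 carrier status, SDOIT score, mean odor
familiarity, sex and age, plus the ApoE x SDOIT, ApoE x familiarity,
SDOIT x familiarity and three-way interaction terms.  Continuous predictors
are mean-centered before products are formed; the highest-order coefficient
is invariant to that centering.  Inference is two-tailed throughout, with
voxel-p plus cluster-extent thresholding and no further multiplicity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

DESIGN_COLUMNS = (
    "intercept",
    "apoe4",
    "sdoit_c",
    "fam_c",
    "sex",
    "age_c",
    "apoe_x_sdoit",
    "apoe_x_fam",
    "sdoit_x_fam",
    "apoe_x_sdoit_x_fam",
)


@dataclass
class GroupDesign:
    """Covariate design with centered continuous predictors and interactions.

    Binary predictors (ApoE carrier status, sex) are coded 0/1 and left
    uncentered; SDOIT, familiarity and age are centered to their sample mean.
    """

    frame: pd.DataFrame
    centers: dict[str, float]
    subjects: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.frame)


def build_group_design(participants: pd.DataFrame, center: bool = True) -> GroupDesign:
    """Build the 10-column moderation design from a participants table.

    Rows with any missing covariate are dropped (subjects with missing
    olfactory testing data leave the regression).
    """
    needed = ["apoe4", "sdoit", "familiarity", "age", "sex"]
    pt = participants.dropna(subset=needed).reset_index(drop=True)
    n_dropped = len(participants) - len(pt)
    if n_dropped:
        import logging

        logging.getLogger(__name__).info(
            "dropped %d subjects with missing covariates", n_dropped
        )
    centers = {
        "sdoit": float(pt["sdoit"].mean()) if center else 0.0,
        "familiarity": float(pt["familiarity"].mean()) if center else 0.0,
        "age": float(pt["age"].mean()) if center else 0.0,
    }
    sdoit_c = pt["sdoit"] - centers["sdoit"]
    fam_c = pt["familiarity"] - centers["familiarity"]
    frame = pd.DataFrame(
        {
            "intercept": np.ones(len(pt)),
            "apoe4": pt["apoe4"].astype(float),
            "sdoit_c": sdoit_c,
            "fam_c": fam_c,
            "sex": pt["sex"].astype(float),
            "age_c": pt["age"] - centers["age"],
            "apoe_x_sdoit": pt["apoe4"] * sdoit_c,
            "apoe_x_fam": pt["apoe4"] * fam_c,
            "sdoit_x_fam": sdoit_c * fam_c,
            "apoe_x_sdoit_x_fam": pt["apoe4"] * sdoit_c * fam_c,
        }
    )
    subjects = (
        pt["subject"].to_numpy() if "subject" in pt.columns else np.arange(len(pt))
    )
    return GroupDesign(frame=frame, centers=centers, subjects=subjects)


@dataclass
class StatMap:
    """Voxelwise statistic/p volumes with threshold metadata and clusters."""

    stat: np.ndarray
    p: np.ndarray
    df: int
    voxel_p: float | None = None
    k_min: int | None = None
    connectivity: int | None = None
    labels: np.ndarray | None = None
    cluster_table: pd.DataFrame | None = None
    flags: dict = field(default_factory=dict)


def one_sample_tmap(subject_maps: np.ndarray) -> StatMap:
    """Voxelwise one-sample t-test across subjects (two-tailed).

    ``subject_maps`` is subjects x (volume shape).  Zero-variance voxels get
    p = 1 with a flag instead of a division error.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for a one-sample t-test")
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    zero_var = sd == 0
    sd_safe = np.where(zero_var, 1.0, sd)
    t = mean / (sd_safe / np.sqrt(n))
    t[zero_var] = 0.0
    df = n - 1
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[zero_var] = 1.0
    return StatMap(stat=t, p=p, df=df, flags={"zero_variance_voxels": int(zero_var.sum())})


@dataclass
class GroupFit:
    """OLS estimates for the moderation design; vectorised over outcomes."""

    coef: pd.DataFrame | np.ndarray  # columns x outcomes (DataFrame when scalar)
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    columns: list[str]
    design: GroupDesign

    def coef_named(self, name: str):
        row = np.asarray(self.coef)[self.columns.index(name)]
        return float(row.item()) if row.size == 1 else row

    def stat_map(self, name: str, shape=None) -> StatMap:
        j = self.columns.index(name)
        t = np.asarray(self.t)[j]
        p = np.asarray(self.p)[j]
        if shape is not None:
            t = t.reshape(shape)
            p = p.reshape(shape)
        return StatMap(stat=t, p=p, df=self.df)


def fit_group_regression(outcome: np.ndarray, design: GroupDesign) -> GroupFit:
    """OLS of a per-subject outcome (scalar or voxel vector) on the design.

    Subjects with a missing (NaN) scalar outcome are dropped.  Rank-deficient
    designs raise, naming the aliased columns.
    """
    x = design.matrix
    y = np.asarray(outcome, dtype=float)
    scalar = y.ndim == 1
    if scalar:
        keep = np.isfinite(y)
        y = y[keep][:, None]
        x = x[keep]
    if x.shape[0] <= x.shape[1]:
        raise ValueError(
            f"n={x.shape[0]} subjects cannot identify {x.shape[1]} design columns"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _, r = np.linalg.qr(x)
        names = list(design.frame.columns)
        aliased = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"group design is rank deficient; aliased columns: {aliased}")
    xtx_inv = np.linalg.inv(x.T @ x)
    beta = xtx_inv @ x.T @ y
    resid = y - x @ beta
    df = x.shape[0] - x.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    cols = list(design.frame.columns)
    if scalar:
        coef = pd.DataFrame({"coef": beta[:, 0]}, index=cols)
        return GroupFit(coef=coef, se=se[:, 0], t=t[:, 0], p=p[:, 0], df=df,
                        columns=cols, design=design)
    return GroupFit(coef=beta, se=se, t=t, p=p, df=df, columns=cols, design=design)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def cluster_threshold(
    stat_map: StatMap,
    p_voxel: float = 0.001,
    k_min: int = 75,
    connectivity: int = 26,
    mask: np.ndarray | None = None,
) -> StatMap:
    """Voxel-p + cluster-extent thresholding with sign-split clustering.

    Positive- and negative-statistic voxels below the two-tailed voxel p are
    clustered separately by connected-components labeling at the stated
    connectivity (6/18/26); clusters smaller than ``k_min`` are discarded.
    The cluster table is sorted by size descending.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of 6/18/26, got {connectivity}")
    structure = _STRUCTURES[connectivity]
    stat = stat_map.stat
    supra = stat_map.p < p_voxel
    if mask is not None:
        supra = supra & np.asarray(mask, bool)
    labels = np.zeros(stat.shape, dtype=int)
    rows = []
    next_label = 1
    for sign, name in ((1, "positive"), (-1, "negative")):
        binary = supra & (np.sign(stat) == sign)
        lab, n_found = ndimage.label(binary, structure=structure)
        for region in range(1, n_found + 1):
            voxels = lab == region
            size = int(voxels.sum())
            if size < k_min:
                continue
            peak_flat = np.flatnonzero(voxels.ravel())[
                np.abs(stat.ravel()[voxels.ravel()]).argmax()
            ]
            peak = np.unravel_index(peak_flat, stat.shape)
            labels[voxels] = next_label
            rows.append(
                {
                    "label": next_label,
                    "direction": name,
                    "size": size,
                    "peak_x": peak[0],
                    "peak_y": peak[1],
                    "peak_z": peak[2],
                    "peak_stat": float(stat[peak]),
                }
            )
            next_label += 1
    table = pd.DataFrame(rows, columns=["label", "direction", "size", "peak_x",
                                        "peak_y", "peak_z", "peak_stat"])
    if len(table):
        table = table.sort_values("size", ascending=False).reset_index(drop=True)
    return StatMap(
        stat=stat,
        p=stat_map.p,
        df=stat_map.df,
        voxel_p=p_voxel,
        k_min=k_min,
        connectivity=connectivity,
        labels=labels,
        cluster_table=table,
        flags=dict(stat_map.flags),
    )


def marginal_means(
    fit: GroupFit,
    sdoit_grid: np.ndarray | None = None,
    familiarity_sd: float | None = None,
) -> pd.DataFrame:
    """Predicted outcomes over SDOIT for low/high familiarity x ApoE status.

    Familiarity is evaluated one sample SD below and above its mean; sex is
    weighted 0.5 and age held at its mean (centered 0).  Grid points outside
    the observed covariate range are flagged as extrapolation.
    """
    design = fit.design
    obs_sdoit = design.frame["sdoit_c"].to_numpy()
    if sdoit_grid is None:
        sdoit_grid = np.linspace(obs_sdoit.min(), obs_sdoit.max(), 9)
    else:
        sdoit_grid = np.asarray(sdoit_grid, dtype=float) - design.centers["sdoit"]
    obs_fam = design.frame["fam_c"].to_numpy()
    fam_sd = familiarity_sd if familiarity_sd is not None else float(obs_fam.std(ddof=1))
    coef = np.asarray(fit.coef).ravel()
    rows = []
    for apoe in (0, 1):
        for fam_label, fam_c in (("low", -fam_sd), ("high", fam_sd)):
            for s_c in sdoit_grid:
                x = np.array(
                    [1.0, apoe, s_c, fam_c, 0.5, 0.0,
                     apoe * s_c, apoe * fam_c, s_c * fam_c, apoe * s_c * fam_c]
                )
                rows.append(
                    {
                        "apoe4": apoe,
                        "familiarity_group": fam_label,
                        "sdoit": s_c + design.centers["sdoit"],
                        "predicted": float(x @ coef),
                        "extrapolated": bool(
                            s_c < obs_sdoit.min() - 1e-9 or s_c > obs_sdoit.max() + 1e-9
                        ),
                    }
                )
    return pd.DataFrame(rows)
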