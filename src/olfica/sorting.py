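"""Temporal sorting of components against the expected hemodynamic response.

Components are ranked by the mean over subjects and runs of the absolute
Pearson correlation between their back-reconstructed timecourses and the
generic (all-stimulus) HRF regressor; components exceeding |r| > 0.2 are
retained as task-relevant.  For retained components, hit- and miss-specific
beta coefficients are estimated per subject by multiple regression of the
component timecourse on subject-specific hit/miss regressors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RETENTION_THRESHOLD = 0.2


@dataclass
class TaskRelevance:
    """Per-component task-correlation summary, sorted descending."""

    table: pd.DataFrame  # columns: component, mean_abs_corr, retained

    @property
    def retained(self) -> np.ndarray:
        return self.table.loc[self.table["retained"], "component"].to_numpy()


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    return float(a @ b / denom) if denom > 0 else 0.0


def sort_by_task_correlation(
    subject_run_timecourses: list[list[np.ndarray]],
    generic_regressors: list[np.ndarray] | np.ndarray,
    use_abs: bool = True,
) -> TaskRelevance:
    """Rank components by mean |Pearson r| with the generic task regressor.

    ``subject_run_timecourses[i][r]`` is subject i, run r, frames x C.
    ``generic_regressors`` is either one regressor shared by every run or one
    per run.  Correlations are computed per run (run boundaries never enter a
    single correlation) and averaged over all subject-runs.
    """
    n_comp = subject_run_timecourses[0][0].shape[1]
    sums = np.zeros(n_comp)
    count = 0
    for runs in subject_run_timecourses:
        for r, tc in enumerate(runs):
            reg = (
                generic_regressors[r]
                if isinstance(generic_regressors, list)
                else generic_regressors
            )
            if len(reg) != tc.shape[0]:
                raise ValueError(
                    f"regressor length {len(reg)} != timecourse frames {tc.shape[0]}"
                )
            for c in range(n_comp):
                r_val = _corr(tc[:, c], reg)
                sums[c] += abs(r_val) if use_abs else r_val
            count += 1
    mean_corr = sums / count
    order = np.argsort(mean_corr)[::-1]
    table = pd.DataFrame(
        {
            "component": order,
            "mean_abs_corr": mean_corr[order],
            "retained": mean_corr[order] > RETENTION_THRESHOLD,
        }
    ).reset_index(drop=True)
    return TaskRelevance(table=table)


def retain_task_components(
    correlations: TaskRelevance | np.ndarray, threshold: float = RETENTION_THRESHOLD
) -> np.ndarray:
    """Indices of components whose aggregate |r| strictly exceeds ``threshold``.

    Accepts either a :class:`TaskRelevance` or a raw array of correlation
    magnitudes indexed by component.
    """
    if isinstance(correlations, TaskRelevance):
        tab = correlations.table
        return tab.loc[tab["mean_abs_corr"].abs() > threshold, "component"].to_numpy()
    mags = np.abs(np.asarray(correlations, dtype=float))
    return np.flatnonzero(mags > threshold)


@dataclass
class ConditionBetas:
    """Hit/miss regression coefficients per subject x component.

    ``hit`` and ``miss`` are subjects x components; entries are NaN where a
    condition had no events for that subject (flagged missing, not zero).
    """

    hit: np.ndarray
    miss: np.ndarray
    components: np.ndarray


def condition_betas(
    subject_run_timecourses: list[list[np.ndarray]],
    subject_run_designs: list[list[pd.DataFrame]],
    components: np.ndarray | None = None,
) -> ConditionBetas:
    """OLS hit/miss betas of each component timecourse on the task design.

    Runs are concatenated with per-run intercepts; the hit and miss regressors
    are shared columns across runs.  A condition that is empty for a subject
    (all-zero regressor in every run) is dropped from that subject's design
    and its beta reported as NaN.
    """
    n_subj = len(subject_run_timecourses)
    n_comp = subject_run_timecourses[0][0].shape[1]
    if components is None:
        components = np.arange(n_comp)
    components = np.asarray(components)
    hit = np.full((n_subj, len(components)), np.nan)
    miss = np.full((n_subj, len(components)), np.nan)
    for i, (runs, designs) in enumerate(zip(subject_run_timecourses, subject_run_designs)):
        task_cols = {}
        for cond in ("hit", "miss"):
            col = np.concatenate([np.asarray(d[cond]) for d in designs])
            if np.any(col):
                task_cols[cond] = col
        blocks = []
        offset = 0
        total = sum(tc.shape[0] for tc in runs)
        for tc in runs:
            b = np.zeros(total)
            b[offset : offset + tc.shape[0]] = 1.0
            blocks.append(b)
            offset += tc.shape[0]
        x = np.column_stack(list(task_cols.values()) + blocks)
        y = np.vstack(runs)[:, components]
        beta = np.linalg.pinv(x) @ y
        for j, cond in enumerate(task_cols):
            target = hit if cond == "hit" else miss
            target[i] = beta[j]
    return ConditionBetas(hit=hit, miss=miss, components=components)
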