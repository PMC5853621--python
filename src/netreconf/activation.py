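"""Act / L-Act region identification via a two-level ROI GLM.

Subject level: each ROI's time series is regressed on the task regressor in
every run of the task; the run-averaged slope divided by its standard error
gives a t statistic, converted to a z score by matching upper-tail
probabilities.  Group level: a one-sample t test over subjects' z scores per
ROI, again converted to z, thresholded (default z > 2.32, positive direction
only) to produce the activated (Act) mask; the less-activated (L-Act) set is
its complement, so Act and L-Act always partition the ROI set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Parcellation, RunSeries

__all__ = ["ActivationMap", "subject_glm", "group_activation", "assign_rois"]

logger = logging.getLogger(__name__)

#: group-level activation threshold (z units), positive direction only
DEFAULT_GROUP_Z = 2.32
#: conventional subject-level reporting threshold (z units)
SUBJECT_REPORT_Z = 1.96


@dataclass
class ActivationMap:
    """Group activation result for one task."""

    z_subject: np.ndarray  # n_subjects x N
    z_group: np.ndarray  # length N
    act_mask: np.ndarray  # boolean, length N
    threshold: float
    task: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": np.arange(self.z_group.size),
                "z_group": self.z_group,
                "act": self.act_mask.astype(int),
            }
        )


def _t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Convert t statistics to z scores by matching upper-tail probability.

    Computed on the half-line and mirrored, which stays numerically stable
    for large |t| (survival functions underflow gracefully).
    """
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = -stats.norm.isf(stats.t.sf(-t[~pos], df))
    return np.clip(z, -40, 40)  # isf saturates near 8.2e-17 tail mass


def subject_glm(runs: list[RunSeries], regressor: np.ndarray) -> np.ndarray:
    """Fixed-effects z statistic per ROI for one subject's task runs.

    Each run's columns are regressed on ``[intercept | regressor]``; the
    effect is the run-averaged slope and its variance the averaged slope
    variance, with degrees of freedom pooled over runs.  Zero-variance ROIs
    get z = 0 with a warning.
    """
    if not runs:
        raise ValueError("at least one run is required")
    subj = {(r.subject, r.state) for r in runs}
    if len(subj) != 1:
        raise ValueError("all runs must come from one subject and one task")
    reg = np.asarray(regressor, dtype=float).ravel()
    slopes, variances, df_total = [], [], 0.0
    for run in runs:
        if reg.size != run.n_timepoints:
            raise ValueError("regressor length does not match run length")
        x = np.column_stack([np.ones(reg.size), reg])
        xtx_inv = np.linalg.inv(x.T @ x)
        beta = xtx_inv @ x.T @ run.data
        resid = run.data - x @ beta
        df = reg.size - 2
        sigma2 = (resid**2).sum(axis=0) / df
        slopes.append(beta[1])
        variances.append(sigma2 * xtx_inv[1, 1])
        df_total += df
    effect = np.mean(slopes, axis=0)
    var = np.sum(variances, axis=0) / len(runs) ** 2
    z = np.zeros_like(effect)
    ok = var > 0
    if not ok.all():
        logger.warning("zero-variance ROI(s) in subject GLM: z set to 0")
    t = np.zeros_like(effect)
    t[ok] = effect[ok] / np.sqrt(var[ok])
    z[ok] = _t_to_z(t[ok], df_total)
    return z


def group_activation(
    z_subject: np.ndarray, threshold: float = DEFAULT_GROUP_Z, task: str = "task"
) -> ActivationMap:
    """One-sample group test of subject z scores, thresholded to an Act mask."""
    z_subject = np.atleast_2d(np.asarray(z_subject, dtype=float))
    n_subjects = z_subject.shape[0]
    if n_subjects < 2:
        raise ValueError("group activation needs at least 2 subjects")
    mean = z_subject.mean(axis=0)
    sd = z_subject.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    ok = sd > 0
    t[ok] = mean[ok] / (sd[ok] / np.sqrt(n_subjects))
    z_group = _t_to_z(t, n_subjects - 1)
    act_mask = z_group > threshold
    return ActivationMap(
        z_subject=z_subject,
        z_group=z_group,
        act_mask=act_mask,
        threshold=threshold,
        task=task,
    )


def assign_rois(
    amap_or_mask: ActivationMap | np.ndarray, parcellation: Parcellation
) -> tuple[np.ndarray, np.ndarray]:
    """Split ROI ids into (act_ids, lact_ids) from an activation mask."""
    mask = (
        amap_or_mask.act_mask
        if isinstance(amap_or_mask, ActivationMap)
        else np.asarray(amap_or_mask, dtype=bool)
    )
    if mask.size != parcellation.n_roi:
        raise ValueError("mask length does not match parcellation size")
    ids = np.arange(mask.size)
    return ids[mask], ids[~mask]
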