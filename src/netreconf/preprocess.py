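"""Temporal filtering and nuisance regression of ROI time series.

Stage order contract (enforced by :func:`preprocess_run`): band-pass filter
first, then confound regression, then — for task runs only — regression of
the task-evoked activity before connectivity estimation.  Filtering first
avoids reintroducing stop-band confound energy into the residuals.

No spatial smoothing and no global-signal regression are performed anywhere
in this module; both are deliberately absent from the pipeline.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .containers import ConfoundSet, RunSeries

__all__ = [
    "bandpass_filter",
    "bandpass_vector",
    "regress_confounds",
    "regress_task_activity",
    "preprocess_run",
]

logger = logging.getLogger(__name__)


def bandpass_vector(
    vec: np.ndarray, tr: float, low: float = 0.009, high: float = 0.08
) -> np.ndarray:
    """Band-pass a single regressor with the same zero-phase filter as the
    data, so that filtered data and design stay matched."""
    vec = np.asarray(vec, dtype=float).ravel()
    nyquist = 0.5 / tr
    if not (0 < low < high < nyquist):
        raise ValueError("need 0 < low < high < Nyquist")
    sos = signal.butter(2, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, vec)


def bandpass_filter(run: RunSeries, low: float = 0.009, high: float = 0.08) -> RunSeries:
    """Zero-phase band-pass filter of every ROI column.

    A 2nd-order Butterworth band-pass applied forward-backward
    (``filtfilt``), so the pass band is preserved without temporal shift.
    The default 0.009-0.08 Hz band removes slow scanner drift and
    high-frequency noise while keeping the BOLD fluctuation band.
    """
    nyquist = 0.5 / run.tr
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"high cut {high} Hz is at/above the Nyquist frequency {nyquist:.4f} Hz"
        )
    sos = signal.butter(
        2, [low, high], btype="bandpass", fs=1.0 / run.tr, output="sos"
    )
    filtered = signal.sosfiltfilt(sos, run.data, axis=0)
    return run.with_data(filtered)


def _drop_dependent_columns(x: np.ndarray) -> np.ndarray:
    """Remove linearly dependent columns (rank-revealing QR via pivoted SVD)."""
    if x.shape[1] == 0:
        return x
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    if keep.sum() < x.shape[1]:
        logger.warning(
            "confound matrix rank-deficient: dropping %d dependent column(s)",
            x.shape[1] - keep.sum(),
        )
        x = x[:, keep]
    return x


def _ols_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _confound_design(
    confounds: ConfoundSet, t: int, add_derivatives: bool
) -> np.ndarray:
    cols = confounds.columns
    if cols.size and cols.shape[0] != t:
        raise ValueError(
            f"confound rows ({cols.shape[0]}) do not match run length ({t})"
        )
    design = [np.ones((t, 1))]
    if cols.size:
        design.append(cols)
        if add_derivatives:
            deriv = np.diff(cols, axis=0, prepend=cols[:1])
            deriv[0] = 0.0
            design.append(deriv)
    return _drop_dependent_columns(np.hstack(design))


def regress_confounds(
    run: RunSeries, confounds: ConfoundSet, add_derivatives: bool = True
) -> RunSeries:
    """OLS residuals of every ROI column on the nuisance regressors.

    The design is ``[intercept | confounds | first differences]``; the
    derivative columns (backward differences, first row zero-padded) are
    optional.  Residuals are orthogonal to every retained design column.
    """
    x = _confound_design(confounds, run.n_timepoints, add_derivatives)
    return run.with_data(_ols_residuals(run.data, x))


def regress_task_activity(run: RunSeries, task_regressor: np.ndarray) -> RunSeries:
    """Residualise each ROI column on the mean task activity regressor.

    A no-op (with a warning) on rest runs: there is no task activity to
    remove from the resting state.
    """
    if run.state == "rest":
        logger.warning(
            "regress_task_activity called on a rest run (%s); returning input",
            run.subject,
        )
        return run
    reg = np.asarray(task_regressor, dtype=float).ravel()
    if reg.size != run.n_timepoints:
        raise ValueError("task regressor length does not match run length")
    design = np.column_stack([np.ones(reg.size), reg])
    return run.with_data(_ols_residuals(run.data, design))


def preprocess_run(
    run: RunSeries,
    confounds: ConfoundSet | None = None,
    task_regressor: np.ndarray | None = None,
    low: float = 0.009,
    high: float = 0.08,
    add_derivatives: bool = True,
) -> RunSeries:
    """Full preprocessing of one run in the contracted order.

    Band-pass -> confound regression -> task-activity regression (task runs
    with a regressor supplied).  Columns left with (numerically) zero
    variance are flagged with a warning.
    """
    out = bandpass_filter(run, low=low, high=high)
    if confounds is not None:
        out = regress_confounds(out, confounds, add_derivatives=add_derivatives)
    if task_regressor is not None and run.state != "rest":
        # filter the regressor identically so the regression removes the
        # task component actually present in the filtered data; residualise
        # it against the confound design (Frisch-Waugh) so the sequential
        # regressions equal one joint regression
        reg = bandpass_vector(task_regressor, run.tr, low=low, high=high)
        if confounds is not None:
            x = _confound_design(confounds, run.n_timepoints, add_derivatives)
            reg = _ols_residuals(reg[:, None], x).ravel()
        out = regress_task_activity(out, reg)
    sd = out.data.std(axis=0)
    flat = np.flatnonzero(sd < 1e-12)
    if flat.size:
        logger.warning("ROIs with zero variance after preprocessing: %s", flat)
    return out
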