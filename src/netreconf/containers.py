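"""Core data containers shared across pipeline stages.

The pipeline operates on ROI (region-of-interest) time series: each run is a
T x N matrix (T time points, N ROIs) with acquisition metadata, and a
parcellation table maps every ROI to a functional subnetwork label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["RunSeries", "Parcellation", "ConfoundSet"]


@dataclass
class RunSeries:
    """One scanning run: a T x N ROI time-series matrix plus metadata.

    Parameters
    ----------
    data : ndarray, shape (T, N)
        BOLD-like signal, one row per time point, one column per ROI.
    tr : float
        Repetition time in seconds.
    subject : str
        Subject identifier.
    state : str
        Mental-state label; ``"rest"`` or a task name.
    encoding : str
        Phase-encoding label, ``"LR"`` or ``"RL"``.
    """

    data: np.ndarray
    tr: float
    subject: str
    state: str
    encoding: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("run data must be a 2-D (T x N) matrix")
        t, n = self.data.shape
        if t < 2 or n < 2:
            raise ValueError(f"run needs T >= 2 and N >= 2, got {t} x {n}")
        if not np.isfinite(self.data).all():
            raise ValueError("run data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "RunSeries":
        """Copy of this run with the signal matrix replaced."""
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class ConfoundSet:
    """Nuisance regressors for one run: a T x C matrix with column names."""

    columns: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, dtype=float))
        if self.columns.size == 0:
            self.columns = self.columns.reshape(0, 0)
        if not self.names:
            self.names = [f"conf{i}" for i in range(self.columns.shape[1])]
        if self.columns.shape[1] != len(self.names):
            raise ValueError("confound names do not match column count")

    @property
    def n_columns(self) -> int:
        return self.columns.shape[1] if self.columns.ndim == 2 else 0


@dataclass
class Parcellation:
    """ROI -> subnetwork assignment with per-subnetwork inclusion flags.

    ``subnetwork`` holds one label per ROI; ``included`` marks ROIs whose
    subnetwork takes part in subnetwork-level summaries (some subnetworks
    without a determined functional role are conventionally excluded).
    """

    subnetwork: np.ndarray
    included: np.ndarray

    def __post_init__(self) -> None:
        self.subnetwork = np.asarray(self.subnetwork)
        self.included = np.asarray(self.included, dtype=bool)
        if self.subnetwork.shape != self.included.shape:
            raise ValueError("subnetwork and included must have equal length")
        if self.subnetwork.size == 0:
            raise ValueError("parcellation must contain at least one ROI")

    @property
    def n_roi(self) -> int:
        return self.subnetwork.size

    @property
    def labels(self) -> np.ndarray:
        """Distinct subnetwork labels in first-appearance order."""
        _, idx = np.unique(self.subnetwork, return_index=True)
        return self.subnetwork[np.sort(idx)]

    @property
    def included_labels(self) -> np.ndarray:
        labs = self.labels
        return np.array(
            [lab for lab in labs if self.included[self.subnetwork == lab].all()]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": np.arange(self.n_roi),
                "subnetwork": self.subnetwork,
                "included": self.included.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Parcellation":
        frame = frame.sort_values("roi")
        return cls(
            subnetwork=frame["subnetwork"].to_numpy(),
            included=frame["included"].to_numpy(dtype=bool),
        )

    def integer_labels(self) -> np.ndarray:
        """Subnetwork labels coded as 0..m-1 integers (stable order)."""
        order = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([order[lab] for lab in self.subnetwork], dtype=int)
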