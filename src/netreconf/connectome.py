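"""Functional connectivity network construction.

Per subject and state: Pearson correlation between ROI time series ->
Fisher z transform -> (optionally) averaging of the LR/RL phase-encoding
networks -> zeroing of negative connections -> proportional thresholding
and binarisation at a target edge density.

The canonical "averaged dataset" path is::

    correlation_network(LR), correlation_network(RL)
        -> average_encodings -> zero_negatives -> threshold_density
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import RunSeries

__all__ = [
    "FCNetwork",
    "BinaryNetwork",
    "correlation_network",
    "zero_negatives",
    "average_encodings",
    "threshold_density",
    "build_binary_network",
]

logger = logging.getLogger(__name__)

#: |r| is clipped here before atanh so perfect correlations stay finite
R_CAP = 1.0 - 1e-12

_STAGES = ("raw_z", "averaged_z", "nonneg_z")


@dataclass
class FCNetwork:
    """N x N symmetric Fisher-z connectivity matrix with zero diagonal."""

    weights: np.ndarray
    subject: str
    state: str
    stage: str = "raw_z"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        np.fill_diagonal(w, 0.0)
        if self.stage == "nonneg_z" and (w < 0).any():
            raise ValueError("nonneg_z network contains negative weights")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """Binary adjacency matrix with its realised edge density."""

    adjacency: np.ndarray
    density: float
    subject: str = ""
    state: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        a = (a != 0).astype(np.int8)
        np.fill_diagonal(a, 0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def edge_count(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def correlation_network(run: RunSeries) -> FCNetwork:
    """Pearson correlation of every ROI pair, Fisher z transformed.

    Perfect correlations are clipped to ``1 - 1e-12`` before ``atanh`` so
    the transform stays finite; the diagonal is forced to zero.
    """
    if run.n_timepoints <= 3:
        raise ValueError("need more than 3 time points for correlation")
    sd = run.data.std(axis=0)
    flat = np.flatnonzero(sd < 1e-300)
    if flat.size:
        raise ValueError(f"constant ROI column(s): {flat.tolist()}")
    r = np.corrcoef(run.data, rowvar=False)
    z = np.arctanh(np.clip(r, -R_CAP, R_CAP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return FCNetwork(weights=z, subject=run.subject, state=run.state, stage="raw_z")


def zero_negatives(net: FCNetwork) -> FCNetwork:
    """Set negative connections to 0 (their interpretation is contested)."""
    if net.stage == "nonneg_z":
        raise ValueError("network already non-negative")
    return FCNetwork(
        weights=np.maximum(net.weights, 0.0),
        subject=net.subject,
        state=net.state,
        stage="nonneg_z",
    )


def average_encodings(net_lr: FCNetwork, net_rl: FCNetwork) -> FCNetwork:
    """Entrywise mean of the two phase-encoding networks (Fisher-z units)."""
    if net_lr.weights.shape != net_rl.weights.shape:
        raise ValueError("encoding networks differ in size")
    if (net_lr.subject, net_lr.state) != (net_rl.subject, net_rl.state):
        raise ValueError("encoding networks differ in subject/state metadata")
    if net_lr.stage != "raw_z" or net_rl.stage != "raw_z":
        raise ValueError("encoding averaging expects raw_z networks")
    return FCNetwork(
        weights=(net_lr.weights + net_rl.weights) / 2.0,
        subject=net_lr.subject,
        state=net_lr.state,
        stage="averaged_z",
    )


def threshold_density(net: FCNetwork, density: float) -> BinaryNetwork:
    """Keep the ``floor(density * N(N-1)/2)`` strongest edges, binarised.

    Ties at the cutoff are broken deterministically: weight descending,
    then node-pair lexicographic order.  If fewer positive weights exist
    than requested, only positive-weight edges are kept and the achieved
    density is logged.
    """
    if not (0 < density <= 1):
        raise ValueError("density must lie in (0, 1]")
    if net.stage != "nonneg_z":
        raise ValueError("threshold_density expects a nonneg_z network")
    n = net.n_nodes
    iu, ju = np.triu_indices(n, 1)
    w = net.weights[iu, ju]
    k = int(np.floor(density * n * (n - 1) / 2))
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) lexicographic
    n_pos = int((w > 0).sum())
    if k > n_pos:
        logger.warning(
            "requested %d edges but only %d positive weights; achieved density %.4f",
            k,
            n_pos,
            n_pos / (n * (n - 1) / 2),
        )
        k = n_pos
    sel = order[:k]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[sel], ju[sel]] = 1
    adj += adj.T
    return BinaryNetwork(
        adjacency=adj, density=density, subject=net.subject, state=net.state
    )


def build_binary_network(
    runs: list[RunSeries], density: float, average: bool = True
) -> BinaryNetwork:
    """Convenience composition of the full connectivity path for one state.

    With two runs and ``average=True`` this is the averaged-dataset path;
    with a single run it is the single-encoding path.
    """
    nets = [correlation_network(r) for r in runs]
    if average and len(nets) == 2:
        net = average_encodings(nets[0], nets[1])
    elif len(nets) == 1:
        net = nets[0]
    else:
        raise ValueError("expected one run, or two runs with average=True")
    return threshold_density(zero_negatives(net), density)
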