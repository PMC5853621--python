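"""Graph statistics on binary networks.

Implements the node/region/global measures of the reconfiguration analysis:

* global efficiency  E = (1/(N(N-1))) * sum_{i != j} 1/d_ij  with d_ij the
  shortest hop count (unreachable pairs contribute 0, the Latora-Marchiori
  convention);
* areal efficiency: the same quantity on the subgraph induced by a region
  mask, so paths may not leave the region;
* interaction strength  I = (1/(K*L)) * sum_{i in Act, j in L-Act} A_ij
  between the activated (size K) and less-activated (size L) regions;
* participation coefficient  PC_i = 1 - sum_m (k_im/k_i)^2  over subnetworks
  m (isolated nodes get PC = 0 by convention);
* flexibility  F_k = PC_task,k - PC_rest,k  and its subnetwork averages.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .containers import Parcellation
from .connectome import BinaryNetwork

__all__ = [
    "shortest_path_lengths",
    "global_efficiency",
    "areal_efficiency",
    "interaction_strength",
    "participation_coefficient",
    "flexibility",
    "subnetwork_flexibility",
]

logger = logging.getLogger(__name__)


def _as_adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency
    return np.asarray(net)


def shortest_path_lengths(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """All-pairs minimum hop counts; unreachable pairs are ``inf``."""
    adj = _as_adjacency(net)
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def global_efficiency(net: BinaryNetwork | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs, in [0, 1]."""
    adj = _as_adjacency(net)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("efficiency needs at least 2 nodes")
    d = shortest_path_lengths(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return float(inv.sum() / (n * (n - 1)))


def areal_efficiency(net: BinaryNetwork | np.ndarray, mask: np.ndarray) -> float:
    """Global efficiency of the subgraph induced by ``mask`` members.

    Only connections inside the region are counted; a pair joined solely
    through outside nodes is unreachable within the region.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("areal efficiency needs a region with >= 2 nodes")
    adj = _as_adjacency(net)
    sub = adj[np.ix_(mask, mask)]
    return global_efficiency(sub)


def interaction_strength(
    net: BinaryNetwork | np.ndarray, act: np.ndarray, lact: np.ndarray
) -> float:
    """Cross-region edge density between the Act and L-Act sets.

    ``I = (1/(K*L)) sum_{i in Act, j in L-Act} A_ij``; the K*L factor
    normalises by the number of possible cross pairs, so I lies in [0, 1].
    """
    act = np.asarray(act, dtype=bool)
    lact = np.asarray(lact, dtype=bool)
    if (act & lact).any():
        raise ValueError("Act and L-Act masks must be disjoint")
    k, l = int(act.sum()), int(lact.sum())
    if k == 0 or l == 0:
        raise ValueError("both regions must be nonempty")
    adj = _as_adjacency(net)
    return float(adj[np.ix_(act, lact)].sum() / (k * l))


def participation_coefficient(
    net: BinaryNetwork | np.ndarray, parcellation: Parcellation | np.ndarray
) -> np.ndarray:
    """Participation coefficient of every node over subnetwork modules.

    ``PC_i = 1 - sum_m (k_im / k_i)^2`` where ``k_im`` counts node i's edges
    into subnetwork m and ``k_i`` is its degree.  A node whose edges all stay
    in its own subnetwork scores 0; isolated nodes score 0 by convention.
    """
    adj = _as_adjacency(net)
    labels = (
        parcellation.integer_labels()
        if isinstance(parcellation, Parcellation)
        else np.asarray(parcellation, dtype=int)
    )
    if labels.size != adj.shape[0]:
        raise ValueError("parcellation does not cover all nodes")
    n_modules = labels.max() + 1
    onehot = np.eye(n_modules, dtype=float)[labels]  # N x m
    k_im = adj @ onehot
    k_i = adj.sum(axis=1).astype(float)
    pc = np.zeros(adj.shape[0])
    conn = k_i > 0
    pc[conn] = 1.0 - ((k_im[conn] / k_i[conn, None]) ** 2).sum(axis=1)
    if (~conn).any():
        logger.debug("isolated node(s) assigned PC = 0: %s", np.flatnonzero(~conn))
    return pc


def flexibility(pc_task: np.ndarray, pc_rest: np.ndarray) -> np.ndarray:
    """Node flexibility: task-state PC minus rest-state PC."""
    pc_task = np.asarray(pc_task, dtype=float)
    pc_rest = np.asarray(pc_rest, dtype=float)
    if pc_task.shape != pc_rest.shape:
        raise ValueError("PC vectors differ in length")
    return pc_task - pc_rest


def subnetwork_flexibility(
    flex: np.ndarray, parcellation: Parcellation
) -> dict[str, float]:
    """Mean node flexibility per included subnetwork.

    Excluded subnetworks are omitted; an included subnetwork with no member
    nodes is omitted with a warning.
    """
    flex = np.asarray(flex, dtype=float)
    if flex.size != parcellation.n_roi:
        raise ValueError("flexibility vector does not cover all nodes")
    out: dict[str, float] = {}
    for lab in parcellation.included_labels:
        member = parcellation.subnetwork == lab
        if not member.any():
            logger.warning("included subnetwork %s has no members; omitted", lab)
            continue
        out[str(lab)] = float(flex[member].mean())
    return out
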