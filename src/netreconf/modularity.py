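"""Community structure statistics: modularity, fractional modularity,
partition similarity and consensus (representative) partitions.

Modularity uses the Newman-Girvan form with a resolution parameter::

    Q = (1/2w) * sum_{i,j} [A_ij - gamma * w_i * w_j / (2w)] * delta(g_i, g_j)

where ``w_i`` is the degree (strength) of node i and ``2w`` the total degree.
Community detection is Louvain-family greedy optimisation with randomised
restarts; the restart with maximal Q is kept.

Fractional modularity Q_f restricts the Q summation to node pairs engaging a
region of interest — either pairs with *both* nodes in the region or pairs
with *at least one* node in it — so that the unnormalised Q_f of a region
under the at-least-one rule plus the Q_f of its complement under the
both-nodes rule reconstructs Q exactly (the two pair sets partition all
pairs).  Optional normalisations divide by the eligible-pair count C(k, 2)
or by the eligible-node count k.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectome import BinaryNetwork

__all__ = [
    "Partition",
    "PartitionSimilarity",
    "modularity_value",
    "louvain_best",
    "fractional_modularity",
    "rand_z_score",
    "allegiance_matrix",
    "representative_partition",
]

PAIR_RULES = ("both", "at_least_one")
NORMALIZATIONS = ("none", "pair_count", "region_size")


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities as contiguous 0..k-1 ints by first appearance."""
    labels = np.asarray(labels)
    seen: dict = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in seen:
            seen[lab] = len(seen)
        out[i] = seen[lab]
    return out


@dataclass
class Partition:
    """A community assignment with its modularity and provenance."""

    labels: np.ndarray
    q: float
    gamma: float = 1.0
    restarts: int = 1
    best_of: int = 1

    def __post_init__(self) -> None:
        self.labels = _canonical(self.labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class PartitionSimilarity:
    """z-score of the pair-counting Rand coefficient between two partitions."""

    z_rand: float
    pair: tuple[str, str] = ("", "")


def _as_adjacency(net) -> np.ndarray:
    if isinstance(net, BinaryNetwork):
        return net.adjacency.astype(float)
    return np.asarray(net, dtype=float)


def modularity_value(net, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Evaluate Q for a given community assignment (weighted or binary)."""
    adj = _as_adjacency(net)
    labels = _canonical(labels)
    if labels.size != adj.shape[0]:
        raise ValueError("labels must cover all nodes")
    strengths = adj.sum(axis=1)
    two_w = strengths.sum()
    if two_w <= 0:
        raise ValueError("modularity undefined on an edgeless graph")
    q = 0.0
    for c in range(labels.max() + 1):
        member = labels == c
        a_cc = adj[np.ix_(member, member)].sum()
        deg_c = strengths[member].sum()
        q += a_cc / two_w - gamma * (deg_c / two_w) ** 2
    return float(q)


def louvain_best(
    net,
    gamma: float = 1.0,
    restarts: int = 100,
    seed: int = 0,
) -> Partition:
    """Best-of-``restarts`` Louvain community detection.

    Each restart shuffles the node-visit order through its own seed drawn
    from a generator seeded by ``seed``; the partition with the largest Q
    (ties: first found) is returned.  Deterministic given ``seed``.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    adj = _as_adjacency(net)
    if adj.sum() <= 0:
        raise ValueError("community detection undefined on an edgeless graph")
    graph = nx.from_numpy_array(adj)
    rng = np.random.default_rng(seed)
    best_labels, best_q = None, -np.inf
    for _ in range(restarts):
        restart_seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(
            graph, weight="weight", resolution=gamma, seed=restart_seed
        )
        labels = np.empty(adj.shape[0], dtype=int)
        for c, nodes in enumerate(comms):
            labels[list(nodes)] = c
        q = modularity_value(adj, labels, gamma)
        if q > best_q:
            best_labels, best_q = labels, q
    return Partition(
        labels=best_labels, q=best_q, gamma=gamma, restarts=restarts,
        best_of=restarts,
    )


def fractional_modularity(
    net,
    labels: np.ndarray,
    mask: np.ndarray,
    pair_rule: str = "both",
    normalization: str = "none",
    gamma: float = 1.0,
) -> float:
    """Portion of Q contributed by node pairs engaging a region.

    ``pair_rule="both"`` restricts to pairs with both nodes in ``mask``;
    ``"at_least_one"`` to pairs touching the mask.  The summand keeps the
    degree-null term for every eligible pair (also where A_ij = 0) so that
    the rule-complement decomposition reconstructs Q exactly.
    """
    if pair_rule not in PAIR_RULES:
        raise ValueError(f"pair_rule must be one of {PAIR_RULES}")
    if normalization not in NORMALIZATIONS:
        raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
    adj = _as_adjacency(net)
    labels = _canonical(labels)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != adj.shape[0] or labels.size != adj.shape[0]:
        raise ValueError("mask and labels must cover all nodes")
    if not mask.any():
        raise ValueError("region mask is empty")
    strengths = adj.sum(axis=1)
    two_w = strengths.sum()
    if two_w <= 0:
        raise ValueError("modularity undefined on an edgeless graph")
    if pair_rule == "both":
        eligible = np.outer(mask, mask)
        n_eligible_nodes = int(mask.sum())
    else:
        eligible = np.outer(mask, mask) | np.outer(mask, ~mask) | np.outer(~mask, mask)
        n_eligible_nodes = adj.shape[0]
    delta = labels[:, None] == labels[None, :]
    b = adj - gamma * np.outer(strengths, strengths) / two_w
    qf = float((b * (delta & eligible)).sum() / two_w)
    if normalization == "pair_count":
        factor = n_eligible_nodes * (n_eligible_nodes - 1) / 2
    elif normalization == "region_size":
        factor = n_eligible_nodes
    else:
        factor = 1.0
    if factor == 0:
        raise ValueError("normalization factor is zero")
    return qf / factor


def _pair_stats(labels: np.ndarray) -> tuple[float, float, float]:
    """(M1, T3, T4): same-pair count and falling-factorial group sums."""
    _, sizes = np.unique(labels, return_counts=True)
    s = sizes.astype(float)
    m1 = float((s * (s - 1)).sum() / 2)
    t3 = float((s * (s - 1) * (s - 2)).sum())
    t4 = float((s * (s - 1) * (s - 2) * (s - 3)).sum())
    return m1, t3, t4


def rand_z_score(
    p1: Partition | np.ndarray, p2: Partition | np.ndarray,
    pair: tuple[str, str] = ("", ""),
) -> PartitionSimilarity:
    """z-score of the pair-counting Rand coefficient.

    The statistic w counts node pairs co-classified together in both
    partitions; its mean and variance are exact under the permutation null
    that relabels one partition's nodes uniformly at random while preserving
    both partitions' group sizes.
    """
    l1 = _canonical(p1.labels if isinstance(p1, Partition) else p1)
    l2 = _canonical(p2.labels if isinstance(p2, Partition) else p2)
    if l1.size != l2.size:
        raise ValueError("partitions must cover the same node set")
    n = l1.size
    if n < 4:
        raise ValueError("z-Rand needs at least 4 nodes (null variance)")
    m = n * (n - 1) / 2
    m1, t3_1, _ = _pair_stats(l1)
    m2, t3_2, t4_2 = _pair_stats(l2)
    # observed co-classification count via the contingency table
    cont = np.zeros((l1.max() + 1, l2.max() + 1))
    np.add.at(cont, (l1, l2), 1)
    w = float((cont * (cont - 1)).sum() / 2)
    mean_w = m1 * m2 / m
    # exact permutation-null variance from pair-of-pairs combinatorics:
    # pairs sharing one node need all 3 nodes co-grouped in partition 2,
    # disjoint pairs need both 2-node sets co-grouped (same or different group)
    _, sizes2 = np.unique(l2, return_counts=True)
    s2 = sizes2.astype(float)
    q2 = float(((s2 * (s2 - 1)) ** 2).sum())
    p_share = t3_2 / (n * (n - 1) * (n - 2))
    p_disj = (t4_2 + (2 * m2) ** 2 - q2) / (n * (n - 1) * (n - 2) * (n - 3))
    e_w2 = mean_w + t3_1 * p_share + (m1 * (m1 - 1) - t3_1) * p_disj
    var_w = e_w2 - mean_w**2
    if var_w <= 1e-12:
        raise ValueError("degenerate null variance (trivial partition)")
    return PartitionSimilarity(
        z_rand=float((w - mean_w) / np.sqrt(var_w)), pair=pair
    )


def allegiance_matrix(partitions: list[Partition | np.ndarray]) -> np.ndarray:
    """Co-classification frequency of every node pair across partitions."""
    labels = [
        p.labels if isinstance(p, Partition) else np.asarray(p)
        for p in partitions
    ]
    n = labels[0].size
    alleg = np.zeros((n, n))
    for lab in labels:
        if lab.size != n:
            raise ValueError("partitions must cover the same node set")
        alleg += lab[:, None] == lab[None, :]
    return alleg / len(labels)


def representative_partition(
    partitions: list[Partition | np.ndarray],
    seed: int = 0,
    gamma: float = 1.0,
    restarts: int = 100,
    n_null: int = 1000,
    percentile: float = 95.0,
) -> Partition:
    """Consensus partition across subjects via a null-thresholded allegiance
    matrix.

    The module-allegiance (co-classification) matrix is compared against a
    permutation null built from group-size-preserving random relabelings of
    each subject's partition; entries not exceeding the null's ``percentile``
    are zeroed and the thresholded matrix is clustered with
    :func:`louvain_best`.  Deterministic given ``seed``.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 partitions")
    labels = [
        _canonical(p.labels if isinstance(p, Partition) else p)
        for p in partitions
    ]
    n = labels[0].size
    # all partitions identical: the consensus is that partition itself
    if all(np.array_equal(lab, labels[0]) for lab in labels[1:]):
        lab = labels[0]
        return Partition(labels=lab, q=np.nan, gamma=gamma, restarts=0)
    alleg = allegiance_matrix(labels)
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    null_entries = np.empty((n_null, iu[0].size))
    for b in range(n_null):
        null = np.zeros((n, n))
        for lab in labels:
            perm = rng.permutation(lab)
            null += perm[:, None] == perm[None, :]
        null_entries[b] = null[iu] / len(labels)
    thresh = float(np.percentile(null_entries, percentile))
    pruned = np.where(alleg > thresh, alleg, 0.0)
    np.fill_diagonal(pruned, 0.0)
    if pruned.sum() == 0:
        raise ValueError("thresholded allegiance matrix has no edges")
    part = louvain_best(
        pruned, gamma=gamma, restarts=restarts,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return part
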