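"""Weighted-graph clustering and consensus selection.

Chinese Whispers (CW) is a randomized agglomerative label-propagation
algorithm: every node starts in its own cluster and is iteratively
re-assigned to the label carrying the greatest summed incident edge
weight among its neighbors.  It is fast (linear in node count per pass)
and recovers clusters of very different sizes, which matters when rare
signal types must not be absorbed by dominant ones.  Because the visit
order is random the result varies between runs; consensus across runs is
quantified with normalized mutual information (NMI) and the most
consensual run is kept ("Best of K").
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np

from .similarity import PrunedNetwork

__all__ = ["Partition", "CWConfig", "chinese_whispers", "nmi", "pairwise_nmi_matrix", "best_of_k"]


@dataclass(frozen=True)
class Partition:
    """A node -> cluster labeling of (the non-isolated part of) a network."""

    labels: Mapping[Hashable, int]

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def cluster_sizes(self) -> Counter:
        return Counter(self.labels.values())

    def clusters(self) -> dict:
        """Cluster id -> sorted list of member nodes."""
        out: dict = {}
        for node, lab in self.labels.items():
            out.setdefault(lab, []).append(node)
        for lab in out:
            out[lab].sort()
        return out

    def restrict(self, nodes) -> "Partition":
        """Partition restricted to the given node subset."""
        keep = set(nodes)
        return Partition({v: l for v, l in self.labels.items() if v in keep})

    def drop_small_clusters(self, min_size: int) -> "Partition":
        """Remove clusters below ``min_size``; their members become unlabeled."""
        sizes = self.cluster_sizes()
        return Partition(
            {v: l for v, l in self.labels.items() if sizes[l] >= min_size}
        )

    def as_array(self, nodes) -> np.ndarray:
        return np.array([self.labels[v] for v in nodes])


@dataclass
class CWConfig:
    """Chinese Whispers run parameters."""

    max_iterations: int = 20
    rng_seed: int | None = None
    min_cluster_size: int = 1

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def chinese_whispers(net: PrunedNetwork, config: CWConfig | None = None) -> Partition:
    """Cluster a pruned weighted network with Chinese Whispers.

    Each non-isolated node starts in its own cluster.  Per iteration,
    nodes are visited in a fresh random permutation and each adopts the
    label with the maximum summed incident edge weight among its
    neighbors (asynchronous updates; ties broken uniformly at random
    among the tied labels).  Iteration stops when a full pass makes no
    change, or after ``max_iterations`` passes.  Isolated nodes are
    excluded from the returned partition.
    """
    config = config or CWConfig()
    rng = np.random.default_rng(config.rng_seed)

    ids = np.asarray(net.node_ids)
    connected = np.zeros(len(ids), dtype=bool)
    connected[net.edges_i] = True
    connected[net.edges_j] = True
    conn_idx = np.flatnonzero(connected)
    if conn_idx.size == 0:
        return Partition({})
    remap = -np.ones(len(ids), dtype=int)
    remap[conn_idx] = np.arange(conn_idx.size)

    nc = conn_idx.size
    adj: list[list[tuple[int, float]]] = [[] for _ in range(nc)]
    for i, j, w in zip(remap[net.edges_i], remap[net.edges_j], net.weights):
        w = float(w)
        adj[i].append((j, w))
        adj[j].append((i, w))

    labels = np.arange(nc)
    for _ in range(config.max_iterations):
        changed = False
        for v in rng.permutation(nc):
            tally: dict[int, float] = {}
            for u, w in adj[v]:
                lu = labels[u]
                tally[lu] = tally.get(lu, 0.0) + w
            best = max(tally.values())
            cands = sorted(l for l, s in tally.items() if s == best)
            new = cands[0] if len(cands) == 1 else cands[int(rng.integers(len(cands)))]
            if new != labels[v]:
                labels[v] = new
                changed = True
        if not changed:
            break

    # compress labels to 0..k-1 in order of first appearance over node index
    compress: dict[int, int] = {}
    out: dict = {}
    for local, global_idx in enumerate(conn_idx):
        lab = labels[local]
        if lab not in compress:
            compress[lab] = len(compress)
        out[ids[global_idx]] = compress[lab]
    return Partition(out)


def nmi(pa: Partition, pb: Partition) -> float:
    """Normalized mutual information between two partitions of one node set.

    Computed from the contingency table as
    ``-2 * sum_ij n_ij log(n_ij n / (n_i n_j)) /
    (sum_i n_i log(n_i / n) + sum_j n_j log(n_j / n))``,
    which equals ``2 I(a; b) / (H(a) + H(b))``; the 0/0 form arising when
    both partitions consist of a single cluster is resolved to 1 (two
    trivial partitions agree perfectly).

    Raises ``ValueError`` if the two partitions label different node sets.
    """
    if set(pa.labels) != set(pb.labels):
        raise ValueError("partitions must cover the same node set")
    n = pa.n
    if n == 0:
        return 1.0

    joint: Counter = Counter()
    ca: Counter = Counter()
    cb: Counter = Counter()
    for node, la in pa.labels.items():
        lb = pb.labels[node]
        joint[(la, lb)] += 1
        ca[la] += 1
        cb[lb] += 1

    num = 0.0
    for (la, lb), nij in joint.items():
        num += nij * math.log(nij * n / (ca[la] * cb[lb]))
    den = sum(na * math.log(na / n) for na in ca.values()) + sum(
        nb * math.log(nb / n) for nb in cb.values()
    )
    if den == 0.0:
        return 1.0
    return float(min(1.0, max(0.0, -2.0 * num / den)))


def _nmi_on_common(pa: Partition, pb: Partition) -> float:
    """NMI on the intersection of two (possibly partially labeled) node sets."""
    common = set(pa.labels) & set(pb.labels)
    if not common:
        return 0.0
    return nmi(pa.restrict(common), pb.restrict(common))


def pairwise_nmi_matrix(partitions, restrict_to_common: bool = False) -> np.ndarray:
    """K x K matrix of pairwise NMI values (diagonal = 1)."""
    k = len(partitions)
    m = np.ones((k, k))
    fn = _nmi_on_common if restrict_to_common else nmi
    for a in range(k):
        for b in range(a + 1, k):
            m[a, b] = m[b, a] = fn(partitions[a], partitions[b])
    return m


def best_of_k(partitions, restrict_to_common: bool = False):
    """Select the partition with the highest mean pairwise NMI.

    Ties are broken by the lowest partition index.  Returns
    ``(partition, index, nmi_matrix)``; a single-element input is
    returned unchanged.
    """
    partitions = list(partitions)
    if not partitions:
        raise ValueError("need at least one partition")
    if len(partitions) == 1:
        return partitions[0], 0, np.ones((1, 1))
    m = pairwise_nmi_matrix(partitions, restrict_to_common=restrict_to_common)
    k = len(partitions)
    mean_off = (m.sum(axis=1) - 1.0) / (k - 1)
    idx = int(np.argmax(mean_off))  # argmax returns first (lowest) index on ties
    return partitions[idx], idx, m
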