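"""Canonical partitions and their reduction to scalar modularity coefficients.

A hard partition of a network is fully characterized, as far as modularity is
concerned, by a handful of scalars: the within-community sum of the adjacency
matrix (``a_hat``), the within-community sum of the configuration null model
(``p_hat``), and — for multilayer networks — the within-community sum of the
interlayer coupling (``c_hat``).  With these coefficients the (unnormalized)
modularity of the partition is the affine function

    Q(gamma, omega) = a_hat - gamma * p_hat + omega * c_hat

of the resolution parameter ``gamma`` and the interlayer coupling ``omega``.
All sums run over ordered node pairs (i, j), including i == j, and the
conventional 1/(2m) prefactor is dropped; :func:`normalized_modularity`
restores it for user-facing reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "Network",
    "MultilayerNetwork",
    "Partition",
    "CoefficientRecord",
    "canonicalize",
    "compute_coefficients",
    "compute_multilayer_coefficients",
    "modularity_at",
    "normalized_modularity",
    "deduplicate",
    "permute_nodes",
]


class Network:
    """Weighted undirected network over 0-based contiguous node indices.

    Each edge is stored once and expanded symmetrically.  A self-loop of
    stored weight ``w`` enters the adjacency diagonal as ``A_ii = 2w``
    (counted once in ordered-pair sums) and contributes ``2w`` to the node
    strength, so that ``2m == sum(k_i)`` always holds.

    Parameters
    ----------
    n_nodes
        Number of nodes.
    edges
        Iterable of ``(u, v, weight)`` with ``weight >= 0``.  Duplicate
        listings of the same undirected pair are summed.
    node_labels
        Optional external labels, one per node (kept for I/O round trips).
    """

    def __init__(
        self,
        n_nodes: int,
        edges: Iterable[tuple[int, int, float]],
        node_labels: Sequence[Hashable] | None = None,
    ) -> None:
        if n_nodes <= 0:
            raise ValueError("network must have at least one node")
        merged: dict[tuple[int, int], float] = {}
        for u, v, w in edges:
            u, v = int(u), int(v)
            if not (0 <= u < n_nodes and 0 <= v < n_nodes):
                raise ValueError(f"edge ({u}, {v}) outside node range 0..{n_nodes - 1}")
            w = float(w)
            if w < 0:
                raise ValueError("edge weights must be nonnegative")
            key = (u, v) if u <= v else (v, u)
            merged[key] = merged.get(key, 0.0) + w
        self.n_nodes = int(n_nodes)
        self.edges: list[tuple[int, int, float]] = [
            (u, v, w) for (u, v), w in sorted(merged.items())
        ]
        k = np.zeros(n_nodes)
        m = 0.0
        for u, v, w in self.edges:
            if u == v:
                k[u] += 2.0 * w
            else:
                k[u] += w
                k[v] += w
            m += w
        self.node_strengths = k
        self.total_weight = m
        if node_labels is not None and len(node_labels) != n_nodes:
            raise ValueError("node_labels length must equal n_nodes")
        self.node_labels = list(node_labels) if node_labels is not None else None

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return f"Network(n_nodes={self.n_nodes}, n_edges={len(self.edges)}, m={self.total_weight:g})"


class MultilayerNetwork:
    """Multilayer network in supra-adjacency form.

    State nodes are node-layer pairs indexed 0..n-1.  Intralayer edges join
    state nodes of the same layer; interlayer edges join state nodes of
    different layers.  The null model is block-diagonal: the configuration
    model applied within each layer, ``P_ij = k_i k_j / (2 m_l)`` for i, j in
    layer l, and zero between layers.
    """

    def __init__(
        self,
        intralayer_edges: Iterable[tuple[int, int, float]],
        interlayer_edges: Iterable[tuple[int, int, float]],
        layer_of: Sequence[int],
        node_labels: Sequence[Hashable] | None = None,
    ) -> None:
        self.layer_of = np.asarray(layer_of, dtype=int)
        n = self.layer_of.size
        if n == 0:
            raise ValueError("multilayer network must have at least one state node")
        self.n_state_nodes = int(n)
        self.n_layers = int(self.layer_of.max()) + 1

        def _merge(edges, same_layer: bool):
            merged: dict[tuple[int, int], float] = {}
            for u, v, w in edges:
                u, v = int(u), int(v)
                if not (0 <= u < n and 0 <= v < n):
                    raise ValueError(f"edge ({u}, {v}) refers to unknown state nodes")
                if same_layer and self.layer_of[u] != self.layer_of[v]:
                    raise ValueError(f"intralayer edge ({u}, {v}) spans layers")
                if not same_layer and self.layer_of[u] == self.layer_of[v]:
                    raise ValueError(f"interlayer edge ({u}, {v}) is within a layer")
                w = float(w)
                if w < 0:
                    raise ValueError("edge weights must be nonnegative")
                key = (u, v) if u <= v else (v, u)
                merged[key] = merged.get(key, 0.0) + w
            return [(u, v, w) for (u, v), w in sorted(merged.items())]

        self.intralayer_edges = _merge(intralayer_edges, same_layer=True)
        self.interlayer_edges = _merge(interlayer_edges, same_layer=False)

        k = np.zeros(n)
        twom = np.zeros(self.n_layers)
        for u, v, w in self.intralayer_edges:
            if u == v:
                k[u] += 2.0 * w
            else:
                k[u] += w
                k[v] += w
            twom[self.layer_of[u]] += 2.0 * w
        self.node_strengths = k
        self.layer_two_m = twom
        if node_labels is not None and len(node_labels) != n:
            raise ValueError("node_labels length must equal n_state_nodes")
        self.node_labels = list(node_labels) if node_labels is not None else None

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MultilayerNetwork(n_state_nodes={self.n_state_nodes}, "
            f"n_layers={self.n_layers}, "
            f"n_intra={len(self.intralayer_edges)}, n_inter={len(self.interlayer_edges)})"
        )


@dataclass(frozen=True)
class Partition:
    """Canonical hard partition: labels 0..K-1 in order of first appearance."""

    membership: tuple[int, ...]
    n_communities: int

    def __len__(self) -> int:
        return len(self.membership)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.membership, dtype=int)

    def community_sizes(self) -> np.ndarray:
        return np.bincount(self.as_array(), minlength=self.n_communities)


def canonicalize(raw_membership: Sequence[Hashable]) -> Partition:
    """Relabel a membership vector to canonical form.

    Labels may be arbitrary hashables; they are mapped to 0..K-1 in order of
    first appearance.  The relabeling preserves the co-membership relation
    exactly, is idempotent, and collapses label permutations.
    """
    raw = list(raw_membership)
    if len(raw) == 0:
        raise ValueError("empty partition")
    mapping: dict[Hashable, int] = {}
    out = []
    for lab in raw:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return Partition(membership=tuple(out), n_communities=len(mapping))


@dataclass(frozen=True)
class CoefficientRecord:
    """Scalar coefficients turning a partition into a line/plane in parameter space.

    ``a_hat``/``p_hat``/``c_hat`` are ordered-pair within-community sums of
    adjacency, null model, and interlayer coupling; ``c_hat`` is 0 for
    single-layer networks.  Community counts are carried along because figure
    conventions in the field sometimes report all communities and sometimes
    only those with at least 5 nodes; both are stored.
    """

    a_hat: float
    p_hat: float
    c_hat: float = 0.0
    partition_id: int = 0
    n_communities_total: int = 0
    n_communities_min5: int = 0

    def modularity(self, gamma: float, omega: float = 0.0) -> float:
        return self.a_hat - gamma * self.p_hat + omega * self.c_hat


def _community_counts(part: Partition) -> tuple[int, int]:
    sizes = part.community_sizes()
    return int(sizes.size), int(np.count_nonzero(sizes >= 5))


def compute_coefficients(
    net: Network,
    part: Partition,
    partition_id: int = 0,
    null_model: str = "configuration",
) -> CoefficientRecord:
    """Reduce a single-layer partition to its (a_hat, p_hat) coefficients.

    a_hat = sum over ordered pairs of A_ij within communities;
    p_hat = sum over ordered pairs of k_i k_j / (2m) within communities,
    which collapses to sum over communities of (sum of strengths)^2 / (2m).
    """
    if null_model != "configuration":
        raise ValueError(f"unsupported null model: {null_model!r}")
    if len(part) != net.n_nodes:
        raise ValueError(
            f"partition length {len(part)} does not match n_nodes {net.n_nodes}"
        )
    if net.total_weight <= 0:
        raise ValueError("m = 0: network has no edge weight")
    c = part.as_array()
    a_hat = 0.0
    for u, v, w in net.edges:
        if c[u] == c[v]:
            a_hat += 2.0 * w  # self-loops stored as A_ii = 2w, counted once
    two_m = 2.0 * net.total_weight
    comm_strength = np.bincount(c, weights=net.node_strengths, minlength=part.n_communities)
    p_hat = float(np.sum(comm_strength**2) / two_m)
    n_tot, n_min5 = _community_counts(part)
    return CoefficientRecord(
        a_hat=float(a_hat),
        p_hat=p_hat,
        c_hat=0.0,
        partition_id=partition_id,
        n_communities_total=n_tot,
        n_communities_min5=n_min5,
    )


def compute_multilayer_coefficients(
    mlnet: MultilayerNetwork, part: Partition, partition_id: int = 0
) -> CoefficientRecord:
    """Reduce a multilayer partition to (a_hat, p_hat, c_hat).

    The null-model sum is taken per layer with that layer's configuration
    null k_i k_j / (2 m_l); layers with no intralayer weight contribute 0.
    """
    if len(part) != mlnet.n_state_nodes:
        raise ValueError(
            f"partition length {len(part)} does not match "
            f"n_state_nodes {mlnet.n_state_nodes}"
        )
    c = part.as_array()
    a_hat = 0.0
    for u, v, w in mlnet.intralayer_edges:
        if c[u] == c[v]:
            a_hat += 2.0 * w
    c_hat = 0.0
    for u, v, w in mlnet.interlayer_edges:
        if c[u] == c[v]:
            c_hat += 2.0 * w
    p_hat = 0.0
    K = part.n_communities
    for layer in range(mlnet.n_layers):
        twom = mlnet.layer_two_m[layer]
        if twom <= 0:
            continue
        mask = mlnet.layer_of == layer
        comm_strength = np.bincount(c[mask], weights=mlnet.node_strengths[mask], minlength=K)
        p_hat += float(np.sum(comm_strength**2) / twom)
    n_tot, n_min5 = _community_counts(part)
    return CoefficientRecord(
        a_hat=float(a_hat),
        p_hat=p_hat,
        c_hat=float(c_hat),
        partition_id=partition_id,
        n_communities_total=n_tot,
        n_communities_min5=n_min5,
    )


def modularity_at(rec: CoefficientRecord, gamma: float, omega: float = 0.0) -> float:
    """Evaluate the (unnormalized) modularity plane Q = a_hat - gamma*p_hat + omega*c_hat."""
    return rec.modularity(gamma, omega)


def normalized_modularity(
    rec: CoefficientRecord, net: Network, gamma: float = 1.0
) -> float:
    """Standard modularity with the 1/(2m) prefactor restored (single-layer)."""
    return rec.modularity(gamma) / (2.0 * net.total_weight)


@dataclass
class UniquePartitions:
    """Deduplicated partitions with multiplicities, first-occurrence order."""

    partitions: list[Partition] = field(default_factory=list)
    multiplicities: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.partitions)


def deduplicate(parts: Iterable[Partition | Sequence[Hashable]]) -> UniquePartitions:
    """Collapse a partition list to unique canonical partitions with multiplicities.

    Accepts raw membership vectors or :class:`Partition` objects; all must be
    over the same node set (equal lengths).
    """
    seen: dict[tuple[int, ...], int] = {}
    out = UniquePartitions()
    length: int | None = None
    for p in parts:
        part = p if isinstance(p, Partition) else canonicalize(p)
        if length is None:
            length = len(part)
        elif len(part) != length:
            raise ValueError("partitions have mixed lengths")
        key = part.membership
        if key in seen:
            out.multiplicities[seen[key]] += 1
        else:
            seen[key] = len(out.partitions)
            out.partitions.append(part)
            out.multiplicities.append(1)
    return out


def permute_nodes(
    net: Network | MultilayerNetwork, perm: Sequence[int]
) -> Network | MultilayerNetwork:
    """Return a copy of the network with node ``i`` renamed to ``inv_perm[i]``.

    ``perm`` maps new index -> old index (the convention of
    ``numpy.random.Generator.permutation``); the returned network's node
    ``j`` is the input's node ``perm[j]``.
    """
    perm = np.asarray(perm, dtype=int)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(perm.size)
    if isinstance(net, Network):
        if perm.size != net.n_nodes:
            raise ValueError("permutation length must equal n_nodes")
        edges = [(inv[u], inv[v], w) for u, v, w in net.edges]
        labels = [net.node_labels[p] for p in perm] if net.node_labels else None
        return Network(net.n_nodes, edges, node_labels=labels)
    if perm.size != net.n_state_nodes:
        raise ValueError("permutation length must equal n_state_nodes")
    intra = [(inv[u], inv[v], w) for u, v, w in net.intralayer_edges]
    inter = [(inv[u], inv[v], w) for u, v, w in net.interlayer_edges]
    layer_of = net.layer_of[perm]
    labels = [net.node_labels[p] for p in perm] if net.node_labels else None
    return MultilayerNetwork(intra, inter, layer_of, node_labels=labels)
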