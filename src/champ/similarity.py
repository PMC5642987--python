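"""Partition comparison via adjusted mutual information (AMI).

AMI(X, Y) = (MI - E[MI]) / (max(H(X), H(Y)) - E[MI]), with mutual information
and entropies in natural log and the expectation of MI taken over the
permutation (hypergeometric) model that fixes both sets of community sizes.
The expectation is evaluated with the exact closed-form hypergeometric sum —
no Monte Carlo — and the "max" normalization is the only variant provided.

On top of pairwise AMI sit the ensemble-level summaries used to read a
domain map: the full pairwise matrix in envelope-domain order, the
border-length-weighted average AMI of a domain with its neighbors, and the
per-layer average AMI of a multilayer partition against metadata labels.
"""

from __future__ import annotations

import math
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .champ_2d import DomainMap2D
from .partition_core import Partition, canonicalize

__all__ = [
    "contingency_table",
    "expected_mutual_information",
    "ami",
    "pairwise_ami_matrix",
    "neighbor_averaged_ami",
    "layer_averaged_ami",
]


def _as_canonical(p: Partition | Sequence[Hashable]) -> Partition:
    return p if isinstance(p, Partition) else canonicalize(p)


def contingency_table(
    x: Partition | Sequence[Hashable], y: Partition | Sequence[Hashable]
) -> np.ndarray:
    """Joint label-count matrix n_xy between two partitions of the same nodes."""
    px, py = _as_canonical(x), _as_canonical(y)
    if len(px) != len(py):
        raise ValueError("partitions have different lengths")
    cx, cy = px.as_array(), py.as_array()
    table = np.zeros((px.n_communities, py.n_communities), dtype=np.int64)
    np.add.at(table, (cx, cy), 1)
    return table


def _entropy(sizes: np.ndarray, n: int) -> float:
    p = sizes[sizes > 0] / n
    return float(-np.sum(p * np.log(p)))


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    nz = table > 0
    nij = table[nz].astype(float)
    outer = np.outer(a, b)[nz].astype(float)
    return float(np.sum(nij / n * np.log(n * nij / outer)))


def expected_mutual_information(table: np.ndarray) -> float:
    """Exact E[MI] under the permutation model with fixed marginals.

    For row sums a_i and column sums b_j of an n-node contingency table, the
    joint count N_ij is hypergeometric, and

        E[MI] = sum_ij sum_k (k/n) log(n k / (a_i b_j)) P(N_ij = k),

    with k running from max(1, a_i + b_j - n) to min(a_i, b_j).  Evaluated in
    log space with gammaln for stability.
    """
    a = table.sum(axis=1).astype(np.int64)
    b = table.sum(axis=0).astype(np.int64)
    n = int(table.sum())
    if n == 0:
        raise ValueError("empty contingency table")
    lg = gammaln
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for k in range(lo, hi + 1):
                # log P(N_ij = k), hypergeometric with parameters (n, ai, bj)
                logp = (
                    lg(ai + 1) + lg(bj + 1) + lg(n - ai + 1) + lg(n - bj + 1)
                    - lg(n + 1) - lg(k + 1) - lg(ai - k + 1) - lg(bj - k + 1)
                    - lg(n - ai - bj + k + 1)
                )
                emi += (k / n) * math.log(n * k / (ai * bj)) * math.exp(logp)
    return emi


def ami(
    x: Partition | Sequence[Hashable], y: Partition | Sequence[Hashable]
) -> float:
    """Adjusted mutual information with "max" normalization, in (-inf, 1].

    Returns exactly 1 iff the partitions are identical up to label
    permutation (which covers the degenerate case of two single-community
    partitions).  If exactly one partition is single-community the score is
    <= 0: MI and E[MI] both vanish while max(H) stays positive.
    """
    px, py = _as_canonical(x), _as_canonical(y)
    if len(px) != len(py):
        raise ValueError("partitions have different lengths")
    if px.membership == py.membership:
        return 1.0
    table = contingency_table(px, py)
    n = len(px)
    hx = _entropy(table.sum(axis=1), n)
    hy = _entropy(table.sum(axis=0), n)
    mi = _mutual_information(table)
    emi = expected_mutual_information(table)
    denom = max(hx, hy) - emi
    # denom > 0 unless max(H) = E[MI] = MI, which forces identical partitions
    if abs(denom) < 1e-15:
        return 0.0
    return (mi - emi) / denom


def pairwise_ami_matrix(
    admissible: Sequence[Partition | Sequence[Hashable]],
    order: Sequence[int] | None = None,
) -> np.ndarray:
    """Symmetric AMI matrix over an admissible set, rows in domain order.

    ``order`` gives positional indices into ``admissible`` (e.g. the envelope
    domain order); by default input order is kept.  Diagonal is 1.
    """
    parts = [_as_canonical(p) for p in admissible]
    if not parts:
        raise ValueError("need at least one partition")
    if order is not None:
        parts = [parts[i] for i in order]
    k = len(parts)
    mat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = ami(parts[i], parts[j])
    return mat


def neighbor_averaged_ami(
    dmap: DomainMap2D, partitions: Mapping[int, Partition | Sequence[Hashable]]
) -> dict[int, float | None]:
    """Border-length-weighted average AMI of each domain with its neighbors.

    For domain d with borders e to neighbors: sum(len(e) * AMI(d, nbr)) /
    sum(len(e)).  Domains with no neighbor map to ``None``.
    """
    nbrs: dict[int, list[tuple[int, float]]] = {d.partition_id: [] for d in dmap.domains}
    for (i, j), length in dmap.adjacency.items():
        nbrs[i].append((j, length))
        nbrs[j].append((i, length))
    cache: dict[tuple[int, int], float] = {}

    def _ami(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in cache:
            cache[key] = ami(partitions[i], partitions[j])
        return cache[key]

    out: dict[int, float | None] = {}
    for pid, edges in nbrs.items():
        total = sum(length for _, length in edges)
        if total <= 0:
            out[pid] = None
        else:
            out[pid] = sum(length * _ami(pid, other) for other, length in edges) / total
    return out


def layer_averaged_ami(
    part: Partition | Sequence[Hashable],
    labels: Sequence[Hashable],
    layer_of: Sequence[int],
) -> float:
    """Unweighted mean over layers of per-layer AMI against metadata labels.

    The partition (over state nodes) and the label vector are restricted to
    each layer in turn; the per-layer AMI scores are averaged with equal
    weight per layer.
    """
    p = _as_canonical(part)
    layer_of = np.asarray(layer_of, dtype=int)
    if not (len(p) == len(labels) == layer_of.size):
        raise ValueError("partition, labels and layer vector must have equal lengths")
    labels = list(labels)
    c = p.as_array()
    scores = []
    for layer in range(int(layer_of.max()) + 1):
        idx = np.flatnonzero(layer_of == layer)
        if idx.size == 0:
            raise ValueError(f"empty layer {layer}")
        scores.append(ami(c[idx].tolist(), [labels[i] for i in idx]))
    return float(np.mean(scores))
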