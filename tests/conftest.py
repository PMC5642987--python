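"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's own code paths: coefficients
are recomputed by a literal double loop over ordered node pairs, envelopes
by dense-grid argmax over the raw lines/planes, and expected mutual
information by exhaustive averaging over node permutations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from champ.partition_core import (
    CoefficientRecord,
    MultilayerNetwork,
    Network,
    Partition,
    canonicalize,
)


# ---------------------------------------------------------------------------
# small worked networks
# ---------------------------------------------------------------------------


@pytest.fixture
def k3() -> Network:
    return Network(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])


@pytest.fixture
def star4() -> Network:
    """4-node star, center node 0 with degree 3."""
    return Network(4, [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)])


@pytest.fixture
def two_triangles() -> Network:
    return Network(
        6, [(0, 1, 1), (1, 2, 1), (0, 2, 1), (3, 4, 1), (4, 5, 1), (3, 5, 1)]
    )


@pytest.fixture
def ml_2x2() -> MultilayerNetwork:
    """2 layers x 2 nodes, one intralayer edge per layer, identity coupling."""
    return MultilayerNetwork(
        intralayer_edges=[(0, 1, 1.0), (2, 3, 1.0)],
        interlayer_edges=[(0, 2, 1.0), (1, 3, 1.0)],
        layer_of=[0, 0, 1, 1],
    )


@pytest.fixture
def three_planes() -> list[CoefficientRecord]:
    """The worked 3-plane (gamma, omega) fixture with a triple point at (0, 2)."""
    return [
        CoefficientRecord(6, 6, 0, partition_id=0),
        CoefficientRecord(4, 3, 1, partition_id=1),
        CoefficientRecord(0, 2, 3, partition_id=2),
    ]


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def brute_coefficients(net: Network, part: Partition) -> tuple[float, float]:
    """Literal ordered-pair double loop over the dense adjacency."""
    n = net.n_nodes
    A = np.zeros((n, n))
    for u, v, w in net.edges:
        if u == v:
            A[u, u] += 2.0 * w
        else:
            A[u, v] += w
            A[v, u] += w
    k = A.sum(axis=1)
    two_m = k.sum()
    c = part.as_array()
    a_hat = p_hat = 0.0
    for i in range(n):
        for j in range(n):
            if c[i] == c[j]:
                a_hat += A[i, j]
                p_hat += k[i] * k[j] / two_m
    return a_hat, p_hat


def brute_multilayer_coefficients(
    mlnet: MultilayerNetwork, part: Partition
) -> tuple[float, float, float]:
    """Double loop over ordered state-node pairs with the per-layer null."""
    n = mlnet.n_state_nodes
    A = np.zeros((n, n))
    for u, v, w in mlnet.intralayer_edges:
        if u == v:
            A[u, u] += 2.0 * w
        else:
            A[u, v] += w
            A[v, u] += w
    C = np.zeros((n, n))
    for u, v, w in mlnet.interlayer_edges:
        C[u, v] += w
        C[v, u] += w
    k = A.sum(axis=1)
    lo = mlnet.layer_of
    twom = np.zeros(mlnet.n_layers)
    for i in range(n):
        twom[lo[i]] += k[i]
    c = part.as_array()
    a_hat = p_hat = c_hat = 0.0
    for i in range(n):
        for j in range(n):
            if c[i] == c[j]:
                a_hat += A[i, j]
                c_hat += C[i, j]
                if lo[i] == lo[j] and twom[lo[i]] > 0:
                    p_hat += k[i] * k[j] / twom[lo[i]]
    return a_hat, p_hat, c_hat


def grid_envelope_1d(
    records: list[CoefficientRecord], gammas: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dense-grid max and argmax over the raw lines (ids, not indices)."""
    a = np.array([r.a_hat for r in records])
    p = np.array([r.p_hat for r in records])
    ids = np.array([r.partition_id for r in records])
    Q = a[:, None] - np.outer(p, gammas)
    best = Q.argmax(axis=0)
    return Q.max(axis=0), ids[best]


def grid_argmax_2d(
    records: list[CoefficientRecord], points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Grid argmax over the raw planes at (n, 2) points; returns (ids, margin).

    ``margin`` is the Euclidean distance in (gamma, omega) from each point to
    the nearest border with any other plane — points with a large margin are
    unambiguous.
    """
    a = np.array([r.a_hat for r in records])
    p = np.array([r.p_hat for r in records])
    c = np.array([r.c_hat for r in records])
    ids = np.array([r.partition_id for r in records])
    Q = a[:, None] - np.outer(p, points[:, 0]) + np.outer(c, points[:, 1])
    best = Q.argmax(axis=0)
    qbest = Q[best, np.arange(points.shape[0])]
    margin = np.full(points.shape[0], np.inf)
    for b in np.unique(best):
        sel = best == b
        diff = qbest[sel][None, :] - Q[:, sel]  # >= 0
        norm = np.hypot(p - p[b], c - c[b])
        ok = norm > 0
        if ok.any():
            margin[sel] = (diff[ok] / norm[ok, None]).min(axis=0)
    return ids[best], margin


def mi_natural(x: list[int], y: list[int]) -> float:
    """Plain-python mutual information in nats."""
    n = len(x)
    from collections import Counter

    cx, cy, cxy = Counter(x), Counter(y), Counter(zip(x, y))
    s = 0.0
    for (i, j), nij in cxy.items():
        s += nij / n * math.log(n * nij / (cx[i] * cy[j]))
    return s


def emi_exhaustive(x: list[int], y: list[int]) -> float:
    """E[MI] by averaging over all n! node permutations of y (n <= 8)."""
    vals = [
        mi_natural(x, [y[p] for p in perm])
        for perm in itertools.permutations(range(len(x)))
    ]
    return float(np.mean(vals))


def all_partitions(n: int):
    """Every set partition of n items as a canonical membership vector."""

    def rec(i, labels, k):
        if i == n:
            yield tuple(labels)
            return
        for lab in range(k + 1):
            labels.append(lab)
            yield from rec(i + 1, labels, max(k, lab + 1))
            labels.pop()

    yield from rec(0, [], 0)


def random_records(
    rng: np.random.Generator, n_lines: int, with_coupling: bool = False
) -> list[CoefficientRecord]:
    """Random positive coefficient sets for envelope stress tests."""
    a = rng.uniform(0.1, 100.0, n_lines)
    p = rng.uniform(0.1, 50.0, n_lines)
    c = rng.uniform(0.0, 20.0, n_lines) if with_coupling else np.zeros(n_lines)
    return [
        CoefficientRecord(float(ai), float(pi), float(ci), partition_id=i)
        for i, (ai, pi, ci) in enumerate(zip(a, p, c))
    ]
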