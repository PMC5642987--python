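"""Partition-ensemble production: heuristic sweeps and planted benchmarks.

The pruning stages are agnostic to how their input partitions were found;
this module supplies the standard protocol for producing them — run a
community-detection heuristic many times over a uniform grid of resolution
(and, for multilayer networks, coupling) values, permuting node order per run
so identical parameters can yield different partitions, then deduplicate and
reduce to coefficients.  Any heuristic with the callable signature
``(network, gamma, omega, seed) -> raw membership`` plugs in; a minimal
built-in greedy modularity heuristic (local moves plus community
aggregation, in the style of Louvain) is provided so everything runs with no
external detection package.  Planted-partition generators, single-layer and
temporally coupled multilayer, provide recoverable ground truth for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .partition_core import (
    CoefficientRecord,
    MultilayerNetwork,
    Network,
    Partition,
    canonicalize,
    compute_coefficients,
    compute_multilayer_coefficients,
    permute_nodes,
)

__all__ = [
    "SweepConfig",
    "PlantedConfig",
    "Ensemble",
    "run_sweep",
    "builtin_heuristic",
    "planted_partition_graph",
    "planted_multilayer",
]

Heuristic = Callable[..., Sequence[int]]


@dataclass
class SweepConfig:
    """Grid + repetition + seeding protocol for a heuristic sweep.

    ``gammas`` (and optionally ``omegas``) are uniformly spaced values
    including both endpoints; ``runs_per_point`` independent heuristic runs
    are made at every grid point, each with its own node-order permutation
    and heuristic seed derived reproducibly from ``seed``.
    """

    gammas: np.ndarray
    omegas: np.ndarray | None = None
    runs_per_point: int = 1
    seed: int = 0
    heuristic: Heuristic | None = None  # defaults to builtin_heuristic

    def __post_init__(self) -> None:
        self.gammas = np.asarray(self.gammas, dtype=float)
        if self.gammas.size == 0 or np.any(np.diff(self.gammas) < 0):
            raise ValueError("gamma grid must be nonempty and sorted")
        if self.omegas is not None:
            self.omegas = np.asarray(self.omegas, dtype=float)
            if self.omegas.size == 0 or np.any(np.diff(self.omegas) < 0):
                raise ValueError("omega grid must be nonempty and sorted")
        if self.runs_per_point < 1:
            raise ValueError("runs_per_point must be >= 1")

    def grid(self) -> list[tuple[float, float]]:
        if self.omegas is None:
            return [(float(g), 0.0) for g in self.gammas]
        return [(float(g), float(o)) for g in self.gammas for o in self.omegas]


@dataclass
class PlantedConfig:
    """Planted-partition parameters, single- or multilayer.

    Within-block pairs are edges with probability ``p_in``, between-block
    pairs with ``p_out``.  For multilayer structure, block labels persist
    between consecutive layers with probability ``persistence`` (otherwise
    resampled uniformly), and consecutive appearances of a node are joined by
    identity interlayer edges of weight ``coupling_weight``.
    """

    n_nodes: int
    n_blocks: int
    p_in: float
    p_out: float
    n_layers: int = 1
    persistence: float = 1.0
    coupling_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_blocks < 1 or self.n_nodes < self.n_blocks:
            raise ValueError("need n_nodes >= n_blocks >= 1 (blocks nonempty)")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if not (0.0 <= self.persistence <= 1.0):
            raise ValueError("persistence must be a probability")


@dataclass
class Ensemble:
    """Deduplicated sweep output: unique partitions with coefficients."""

    partitions: list[Partition]
    records: list[CoefficientRecord]
    multiplicities: list[int]
    n_runs: int = 0

    def __len__(self) -> int:
        return len(self.partitions)

    def partition_by_id(self) -> dict[int, Partition]:
        return {r.partition_id: p for r, p in zip(self.records, self.partitions)}


# ---------------------------------------------------------------------------
# built-in greedy modularity heuristic
# ---------------------------------------------------------------------------


class _HeurState:
    """One aggregation level: supernodes with per-layer strengths."""

    def __init__(
        self,
        A: list[dict[int, float]],
        C: list[dict[int, float]],
        klayer: np.ndarray,
        inv_twom: np.ndarray,
    ) -> None:
        self.A = A
        self.C = C
        self.klayer = klayer
        self.inv_twom = inv_twom
        self.size = klayer.shape[0]

    @classmethod
    def from_network(cls, net: Network | MultilayerNetwork) -> "_HeurState":
        if isinstance(net, Network):
            n, n_layers = net.n_nodes, 1
            layer_of = np.zeros(n, dtype=int)
            intra = net.edges
            inter: list[tuple[int, int, float]] = []
            twom = np.array([2.0 * net.total_weight])
        else:
            n, n_layers = net.n_state_nodes, net.n_layers
            layer_of = net.layer_of
            intra = net.intralayer_edges
            inter = net.interlayer_edges
            twom = net.layer_two_m
        A: list[dict[int, float]] = [dict() for _ in range(n)]
        for u, v, w in intra:
            if u != v:  # self-loops never change under moves
                A[u][v] = A[u].get(v, 0.0) + w
                A[v][u] = A[v].get(u, 0.0) + w
        C: list[dict[int, float]] = [dict() for _ in range(n)]
        for u, v, w in inter:
            C[u][v] = C[u].get(v, 0.0) + w
            C[v][u] = C[v].get(u, 0.0) + w
        klayer = np.zeros((n, n_layers))
        if isinstance(net, Network):
            klayer[:, 0] = net.node_strengths
        else:
            klayer[np.arange(n), layer_of] = net.node_strengths
        with np.errstate(divide="ignore"):
            inv_twom = np.where(twom > 0, 1.0 / np.maximum(twom, 1e-300), 0.0)
        return cls(A, C, klayer, inv_twom)

    def aggregate(self, comm: np.ndarray, n_comms: int) -> "_HeurState":
        A: list[dict[int, float]] = [dict() for _ in range(n_comms)]
        C: list[dict[int, float]] = [dict() for _ in range(n_comms)]
        for u in range(self.size):
            cu = comm[u]
            for v, w in self.A[u].items():
                cv = comm[v]
                if cu != cv:
                    A[cu][cv] = A[cu].get(cv, 0.0) + w
            for v, w in self.C[u].items():
                cv = comm[v]
                if cu != cv:
                    C[cu][cv] = C[cu].get(cv, 0.0) + w
        klayer = np.zeros((n_comms, self.klayer.shape[1]))
        np.add.at(klayer, comm, self.klayer)
        return _HeurState(A, C, klayer, self.inv_twom)


def _local_moves(
    state: _HeurState,
    gamma: float,
    omega: float,
    rng: np.random.Generator,
    tol: float = 1e-12,
) -> tuple[np.ndarray, bool]:
    """Greedy node moves until a full pass yields no strictly improving move."""
    M = state.size
    comm = np.arange(M)
    S = state.klayer.copy()  # per-community per-layer strength sums
    moved_any = False
    improved = True
    while improved:
        improved = False
        for u in rng.permutation(M):
            a = comm[u]
            ku = state.klayer[u]
            ku_inv = ku * state.inv_twom
            wA: dict[int, float] = {}
            for v, w in state.A[u].items():
                cv = comm[v]
                wA[cv] = wA.get(cv, 0.0) + w
            wC: dict[int, float] = {}
            if omega != 0.0:
                for v, w in state.C[u].items():
                    cv = comm[v]
                    wC[cv] = wC.get(cv, 0.0) + w
            # score(b) = within-community gain terms of placing u into b
            best, best_score = a, (
                wA.get(a, 0.0)
                + omega * wC.get(a, 0.0)
                - gamma * float(ku_inv @ (S[a] - ku))
            )
            for b in set(wA) | set(wC):
                if b == a:
                    continue
                sc = (
                    wA.get(b, 0.0)
                    + omega * wC.get(b, 0.0)
                    - gamma * float(ku_inv @ S[b])
                )
                if sc > best_score + tol:
                    best, best_score = b, sc
            if best != a:
                comm[u] = best
                S[a] -= ku
                S[best] += ku
                improved = True
                moved_any = True
    # canonical relabel of surviving communities
    uniq, canon = np.unique(comm, return_inverse=True)
    return canon, moved_any


def builtin_heuristic(
    net: Network | MultilayerNetwork,
    gamma: float,
    omega: float = 0.0,
    seed: int = 0,
) -> list[int]:
    """Greedy (multilayer) modularity maximization at fixed (gamma, omega).

    Repeated phases of strictly-improving local moves followed by community
    aggregation, on the unnormalized quality a_hat - gamma*p_hat +
    omega*c_hat with the per-layer configuration null.  Deterministic given
    ``seed`` (which drives the node-visit order); no optimality guarantee.
    """
    state = _HeurState.from_network(net)
    rng = np.random.default_rng(seed)
    membership = np.arange(state.size)
    while True:
        comm, moved = _local_moves(state, gamma, omega, rng)
        membership = comm[membership]
        if not moved:
            break
        state = state.aggregate(comm, int(comm.max()) + 1)
    return membership.tolist()


# ---------------------------------------------------------------------------
# sweep driver
# ---------------------------------------------------------------------------


def _derived_seeds(master: int, grid_idx: int, run_idx: int) -> tuple[int, int]:
    """Splittable per-run seeds: reproducible and parallel-safe."""
    ss = np.random.SeedSequence(entropy=master, spawn_key=(grid_idx, run_idx))
    s1, s2 = ss.generate_state(2)
    return int(s1) & 0x7FFFFFFF, int(s2) & 0x7FFFFFFF


def run_sweep(net: Network | MultilayerNetwork, cfg: SweepConfig) -> Ensemble:
    """Run the heuristic over the grid, deduplicate, compute coefficients.

    For every grid point and run the node order is freshly permuted (with a
    seed derived from the master seed, the grid index and the run index)
    before the heuristic sees the network, and the resulting membership is
    mapped back to the original node order and canonicalized.  The whole
    sweep is reproducible given the config.
    """
    heuristic = cfg.heuristic or builtin_heuristic
    n = net.n_nodes if isinstance(net, Network) else net.n_state_nodes
    multilayer = isinstance(net, MultilayerNetwork)
    seen: dict[tuple[int, ...], int] = {}
    partitions: list[Partition] = []
    multiplicities: list[int] = []
    n_runs = 0
    for gidx, (gamma, omega) in enumerate(cfg.grid()):
        for run in range(cfg.runs_per_point):
            perm_seed, heur_seed = _derived_seeds(cfg.seed, gidx, run)
            perm = np.random.default_rng(perm_seed).permutation(n)
            permuted = permute_nodes(net, perm)
            raw = list(heuristic(permuted, gamma, omega, heur_seed))
            if len(raw) != n:
                raise ValueError(
                    f"heuristic returned membership of length {len(raw)} != {n} "
                    f"at grid point (gamma={gamma}, omega={omega})"
                )
            membership = [None] * n
            for new_idx, old_idx in enumerate(perm):
                membership[old_idx] = raw[new_idx]
            part = canonicalize(membership)
            key = part.membership
            if key in seen:
                multiplicities[seen[key]] += 1
            else:
                seen[key] = len(partitions)
                partitions.append(part)
                multiplicities.append(1)
            n_runs += 1
    records = []
    for pid, part in enumerate(partitions):
        if multilayer:
            records.append(compute_multilayer_coefficients(net, part, partition_id=pid))
        else:
            records.append(compute_coefficients(net, part, partition_id=pid))
    return Ensemble(
        partitions=partitions,
        records=records,
        multiplicities=multiplicities,
        n_runs=n_runs,
    )


# ---------------------------------------------------------------------------
# planted-structure generators
# ---------------------------------------------------------------------------


def _block_labels(n_nodes: int, n_blocks: int) -> np.ndarray:
    sizes = [len(chunk) for chunk in np.array_split(np.arange(n_nodes), n_blocks)]
    return np.repeat(np.arange(n_blocks), sizes)


def _sample_block_edges(
    labels: np.ndarray, p_in: float, p_out: float, rng: np.random.Generator
) -> list[tuple[int, int, float]]:
    n = labels.size
    iu, ju = np.triu_indices(n, k=1)
    prob = np.where(labels[iu] == labels[ju], p_in, p_out)
    mask = rng.random(iu.size) < prob
    return [(int(u), int(v), 1.0) for u, v in zip(iu[mask], ju[mask])]


def planted_partition_graph(
    cfg: PlantedConfig, seed: int = 0
) -> tuple[Network, Partition]:
    """Sample a single-layer planted-partition graph with its ground truth.

    Nodes are split into ``n_blocks`` contiguous near-equal blocks; each
    within-block pair is an (unweighted) edge independently with ``p_in``,
    each between-block pair with ``p_out``.
    """
    rng = np.random.default_rng(seed)
    labels = _block_labels(cfg.n_nodes, cfg.n_blocks)
    edges = _sample_block_edges(labels, cfg.p_in, cfg.p_out, rng)
    return Network(cfg.n_nodes, edges), canonicalize(labels.tolist())


def planted_multilayer(
    cfg: PlantedConfig, seed: int = 0
) -> tuple[MultilayerNetwork, Partition]:
    """Sample temporally coupled multilayer planted structure with ground truth.

    Every layer holds the same ``n_nodes`` nodes (state node ``l*n + i`` is
    node i in layer l).  Block labels carry over from the previous layer with
    probability ``persistence`` (else resampled uniformly), so ground-truth
    communities span layers when persistence is high.  Consecutive
    appearances of each node are joined by identity interlayer edges of
    weight ``coupling_weight`` (omitted entirely if the weight is 0).
    """
    if cfg.n_layers < 2:
        raise ValueError("planted_multilayer needs n_layers >= 2")
    rng = np.random.default_rng(seed)
    n, L = cfg.n_nodes, cfg.n_layers
    labels = np.empty((L, n), dtype=int)
    labels[0] = _block_labels(n, cfg.n_blocks)
    for layer in range(1, L):
        keep = rng.random(n) < cfg.persistence
        resampled = rng.integers(0, cfg.n_blocks, size=n)
        labels[layer] = np.where(keep, labels[layer - 1], resampled)
    intra: list[tuple[int, int, float]] = []
    for layer in range(L):
        off = layer * n
        intra.extend(
            (u + off, v + off, w)
            for u, v, w in _sample_block_edges(labels[layer], cfg.p_in, cfg.p_out, rng)
        )
    inter: list[tuple[int, int, float]] = []
    if cfg.coupling_weight > 0:
        for layer in range(L - 1):
            inter.extend(
                (layer * n + i, (layer + 1) * n + i, cfg.coupling_weight)
                for i in range(n)
            )
    layer_of = np.repeat(np.arange(L), n)
    net = MultilayerNetwork(intra, inter, layer_of)
    return net, canonicalize(labels.reshape(-1).tolist())
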