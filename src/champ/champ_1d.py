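"""Single-layer pruning: upper envelope of partition lines over gamma.

Each partition is the line Q(gamma) = a_hat - gamma * p_hat.  Starting from
the partition optimal at the left end of the analysis range, the algorithm
repeatedly finds the smallest pairwise intersection

    gamma_x = (a1 - a2) / (p1 - p2)

beyond the current transition point and hands optimality to the crossing
line, until no further intersection lies in the range.  The result is the
piecewise-linear maximum Q~(gamma) and, for every admissible partition, its
half-open gamma-domain of optimality [gamma_p, gamma_{p+1}).  Domains are
simply connected, so each admissible partition appears exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .partition_core import CoefficientRecord

__all__ = ["Domain1D", "Envelope1D", "intersection_gamma", "champ_prune_1d", "envelope_value"]

PARALLEL = "parallel"

#: intersections within this absolute gamma tolerance are treated as coincident,
#: and domains narrower than this are dropped as empty.  Coefficients are exact
#: sums of input weights, so crossings are well-conditioned.
GAMMA_TOL = 1e-12


@dataclass(frozen=True)
class Domain1D:
    """A gamma-interval of optimality [gamma_lo, gamma_hi) for one partition."""

    partition_id: int
    gamma_lo: float
    gamma_hi: float  # may be +inf
    record: CoefficientRecord

    @property
    def width(self) -> float:
        return self.gamma_hi - self.gamma_lo


@dataclass
class Envelope1D:
    """Ordered admissible domains tiling [gamma_start, gamma_end).

    Along ``domains`` the transition values strictly increase and both a_hat
    and p_hat strictly decrease (the geometry of an upper envelope of lines).
    ``co_optimal`` maps a retained partition_id to ids of input records with
    identical coefficients (lines of equal merit at every gamma).
    """

    domains: list[Domain1D]
    gamma_start: float
    gamma_end: float
    input_count: int
    pruned_count: int
    co_optimal: dict[int, list[int]] = field(default_factory=dict)

    @property
    def transitions(self) -> list[float]:
        return [d.gamma_lo for d in self.domains[1:]]

    def __len__(self) -> int:
        return len(self.domains)


def intersection_gamma(
    rec1: CoefficientRecord, rec2: CoefficientRecord
) -> float | str:
    """Gamma at which two partition lines cross, or ``"parallel"``.

    Lines with equal p_hat never cross (they coincide if a_hat also agrees);
    parallelism is a value, not an error.
    """
    for r in (rec1, rec2):
        if r.c_hat != 0.0:
            raise ValueError("intersection_gamma requires single-layer records (c_hat = 0)")
    dp = rec1.p_hat - rec2.p_hat
    if dp == 0.0:
        return PARALLEL
    return (rec1.a_hat - rec2.a_hat) / dp


def _collapse_duplicates(
    records: list[CoefficientRecord],
) -> tuple[list[CoefficientRecord], dict[int, list[int]]]:
    """Collapse records with identical coefficients onto the lowest-id one."""
    by_coeff: dict[tuple[float, float, float], CoefficientRecord] = {}
    co: dict[int, list[int]] = {}
    for rec in sorted(records, key=lambda r: r.partition_id):
        key = (rec.a_hat, rec.p_hat, rec.c_hat)
        if key in by_coeff:
            co.setdefault(by_coeff[key].partition_id, []).append(rec.partition_id)
        else:
            by_coeff[key] = rec
    return list(by_coeff.values()), co


def champ_prune_1d(
    records: list[CoefficientRecord],
    gamma_start: float = 0.0,
    gamma_end: float = math.inf,
) -> Envelope1D:
    """Prune an ensemble of single-layer records to its upper envelope.

    Parameters
    ----------
    records
        Coefficient records with c_hat = 0 and finite coefficients.
    gamma_start, gamma_end
        Analysis range; the last domain is capped at ``gamma_end`` (which may
        be infinite).

    Returns
    -------
    Envelope1D
        Domains tiling the range with no gaps or overlaps.  Every input
        record absent from the output lies strictly below the envelope
        somewhere-to-everywhere in the range.  At a transition point the
        incoming (larger-gamma) partition is the optimal one (half-open
        convention); when several lines cross the envelope at the same gamma
        the one with smallest p_hat takes over, ties broken by lowest id.
    """
    if not records:
        raise ValueError("empty record list")
    if gamma_end <= gamma_start:
        raise ValueError("gamma_end must exceed gamma_start")
    for rec in records:
        if not (math.isfinite(rec.a_hat) and math.isfinite(rec.p_hat)):
            raise ValueError(f"non-finite coefficients in record {rec.partition_id}")
        if rec.c_hat != 0.0:
            raise ValueError("champ_prune_1d requires single-layer records (c_hat = 0)")

    uniq, co_optimal = _collapse_duplicates(records)
    a = np.array([r.a_hat for r in uniq])
    p = np.array([r.p_hat for r in uniq])
    ids = np.array([r.partition_id for r in uniq])

    # optimal at gamma_start: max Q, ties -> smaller p_hat, then lower id
    q0 = a - gamma_start * p
    order = np.lexsort((ids, p, -q0))
    cur = int(order[0])

    domains: list[Domain1D] = []
    g = float(gamma_start)
    alive = np.ones(len(uniq), dtype=bool)
    while True:
        alive[cur] = False
        dp = p[cur] - p
        with np.errstate(divide="ignore", invalid="ignore"):
            gx = np.where(dp != 0.0, (a[cur] - a) / dp, -np.inf)
        gx[~alive] = -np.inf
        cand = (gx > g + GAMMA_TOL) & (gx < gamma_end - GAMMA_TOL)
        if not np.any(cand):
            domains.append(Domain1D(int(ids[cur]), g, float(gamma_end), uniq[cur]))
            break
        gmin = float(np.min(gx[cand]))
        at_min = cand & (gx <= gmin + GAMMA_TOL)
        idx = np.flatnonzero(at_min)
        # smallest p_hat takes over; exact ties in p_hat -> lowest id
        nxt = int(idx[np.lexsort((ids[idx], p[idx]))[0]])
        domains.append(Domain1D(int(ids[cur]), g, gmin, uniq[cur]))
        g = gmin
        cur = nxt

    return Envelope1D(
        domains=domains,
        gamma_start=float(gamma_start),
        gamma_end=float(gamma_end),
        input_count=len(records),
        pruned_count=len(records) - len(domains),
        co_optimal=co_optimal,
    )


def envelope_value(env: Envelope1D, gamma: float) -> tuple[float, int]:
    """Evaluate the piecewise-linear envelope Q~(gamma).

    Returns ``(Q, partition_id)`` of the unique domain covering ``gamma``;
    at a transition point the incoming (larger-gamma) domain applies.
    """
    if not (env.gamma_start <= gamma < env.gamma_end):
        raise ValueError(
            f"gamma = {gamma} outside analysis range "
            f"[{env.gamma_start}, {env.gamma_end})"
        )
    los = [d.gamma_lo for d in env.domains]
    i = int(np.searchsorted(los, gamma, side="right")) - 1
    d = env.domains[i]
    return d.record.modularity(gamma), d.partition_id
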