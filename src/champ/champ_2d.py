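"""Multilayer pruning: domains of optimality in the (gamma, omega) plane.

Each multilayer partition is the plane Q(gamma, omega) = a_hat - gamma*p_hat
+ omega*c_hat in (gamma, omega, Q) space.  The admissible subset and its
convex polygonal domains of optimality are obtained by intersecting the
half-spaces above all partition planes — solved as a halfspace-intersection /
dual convex-hull problem (Qhull, via scipy) — with four vertical half-spaces
for the parameter box and a horizontal cap just above the envelope closing
the polyhedron.  The facet of each surviving plane, projected back to
(gamma, omega), is that partition's domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import HalfspaceIntersection, QhullError
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.polygon import orient

from .champ_1d import _collapse_duplicates
from .partition_core import CoefficientRecord

__all__ = [
    "ParameterBox",
    "Domain2D",
    "DomainMap2D",
    "champ_prune_2d",
    "domain_adjacency",
    "assign_point",
    "assign_points",
]

#: vertex-merge / facet-classification tolerance in (gamma, omega)
VERTEX_TOL = 1e-9
#: domains with area below this are dropped as degenerate
AREA_TOL = 1e-9


@dataclass(frozen=True)
class ParameterBox:
    """Axis-aligned rectangle [gamma_lo, gamma_hi] x [omega_lo, omega_hi]."""

    gamma_lo: float
    gamma_hi: float
    omega_lo: float
    omega_hi: float

    def __post_init__(self) -> None:
        if not (self.gamma_lo < self.gamma_hi and self.omega_lo < self.omega_hi):
            raise ValueError("degenerate parameter box")

    @property
    def area(self) -> float:
        return (self.gamma_hi - self.gamma_lo) * (self.omega_hi - self.omega_lo)

    def corners(self) -> np.ndarray:
        return np.array(
            [
                (self.gamma_lo, self.omega_lo),
                (self.gamma_hi, self.omega_lo),
                (self.gamma_hi, self.omega_hi),
                (self.gamma_lo, self.omega_hi),
            ]
        )

    def contains(self, gamma: float, omega: float) -> bool:
        return (
            self.gamma_lo <= gamma <= self.gamma_hi
            and self.omega_lo <= omega <= self.omega_hi
        )


@dataclass
class Domain2D:
    """Convex polygonal (gamma, omega) domain of optimality of one partition."""

    partition_id: int
    polygon: Polygon  # convex, counterclockwise exterior
    record: CoefficientRecord

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def vertices(self) -> list[tuple[float, float]]:
        return list(self.polygon.exterior.coords)


@dataclass
class DomainMap2D:
    """Admissible partitions with their domains inside a parameter box.

    ``out_of_box`` lists partition ids whose domain of optimality lies
    entirely outside the user box but inside a 10x enlarged search box;
    ``adjacency`` maps unordered id pairs to the Euclidean length of the
    shared domain border.
    """

    domains: list[Domain2D]
    box: ParameterBox
    out_of_box: list[int]
    input_count: int
    pruned_count: int
    adjacency: dict[tuple[int, int], float] = field(default_factory=dict)
    co_optimal: dict[int, list[int]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.domains)

    def domain_by_id(self, partition_id: int) -> Domain2D:
        for d in self.domains:
            if d.partition_id == partition_id:
                return d
        raise KeyError(partition_id)


def _envelope_faces(
    a: np.ndarray, p: np.ndarray, c: np.ndarray, box: ParameterBox
) -> dict[int, Polygon]:
    """Polygonal upper-envelope face of each plane inside ``box``.

    Builds the bounded polyhedron {Q >= every plane} ∩ {box sides} ∩
    {Q <= cap} and reads off, for every plane halfspace, the vertices of the
    intersection incident to it (Qhull's dual-facet incidence), projected to
    (gamma, omega).
    """
    n = a.size
    corners = box.corners()
    # cap strictly above the envelope anywhere in the box: affine functions
    # attain their box maximum at a corner
    qcorner = a[:, None] - np.outer(p, corners[:, 0]) + np.outer(c, corners[:, 1])
    qcap = float(qcorner.max()) + 1.0

    halfspaces = np.zeros((n + 5, 4))
    # plane i: Q >= a - gamma p + omega c  <=>  -p*g + c*o - Q + a <= 0
    halfspaces[:n, 0] = -p
    halfspaces[:n, 1] = c
    halfspaces[:n, 2] = -1.0
    halfspaces[:n, 3] = a
    halfspaces[n] = (-1, 0, 0, box.gamma_lo)
    halfspaces[n + 1] = (1, 0, 0, -box.gamma_hi)
    halfspaces[n + 2] = (0, -1, 0, box.omega_lo)
    halfspaces[n + 3] = (0, 1, 0, -box.omega_hi)
    halfspaces[n + 4] = (0, 0, 1, -qcap)

    gc = 0.5 * (box.gamma_lo + box.gamma_hi)
    oc = 0.5 * (box.omega_lo + box.omega_hi)
    qmid = float(np.max(a - gc * p + oc * c))
    interior = np.array([gc, oc, 0.5 * (qmid + qcap)])

    try:
        hs = HalfspaceIntersection(halfspaces, interior, qhull_options="Qt")
    except QhullError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"halfspace intersection failed: {exc}") from exc

    incident: dict[int, list[np.ndarray]] = {i: [] for i in range(n)}
    lo = np.array([box.gamma_lo, box.omega_lo])
    hi = np.array([box.gamma_hi, box.omega_hi])
    for vtx, hs_idx in zip(hs.intersections, hs.dual_facets):
        gw = vtx[:2]
        # snap round-off at the box boundary, then clamp inside
        gw = np.where(np.abs(gw - lo) < VERTEX_TOL, lo, gw)
        gw = np.where(np.abs(gw - hi) < VERTEX_TOL, hi, gw)
        gw = np.clip(gw, lo, hi)
        for i in hs_idx:
            if i < n:
                incident[i].append(gw)

    faces: dict[int, Polygon] = {}
    for i, pts in incident.items():
        if len(pts) < 3:
            continue
        arr = np.array(pts)
        # merge near-duplicate vertices
        keep: list[np.ndarray] = []
        for q in arr:
            if all(np.hypot(*(q - r)) > VERTEX_TOL for r in keep):
                keep.append(q)
        if len(keep) < 3:
            continue
        hull = MultiPoint([tuple(q) for q in keep]).convex_hull
        if not isinstance(hull, Polygon):
            continue
        poly = orient(hull, sign=1.0)
        if poly.area > AREA_TOL:
            faces[i] = poly
    return faces


def champ_prune_2d(
    records: list[CoefficientRecord],
    box: ParameterBox,
    find_out_of_box: bool = True,
) -> DomainMap2D:
    """Prune an ensemble of multilayer records to its (gamma, omega) domains.

    Each returned domain is the convex region of ``box`` where its plane
    attains the pointwise maximum over all input planes.  Planes never
    maximal inside the box but maximal somewhere in a 10x enlarged box
    anchored at the origin are reported in ``out_of_box``; all other planes
    are pruned.  Records with identical coefficients are collapsed onto the
    lowest id (reported in ``co_optimal``).
    """
    if not records:
        raise ValueError("empty record list")
    for rec in records:
        if not all(
            math.isfinite(v) for v in (rec.a_hat, rec.p_hat, rec.c_hat)
        ):
            raise ValueError(f"non-finite coefficients in record {rec.partition_id}")

    uniq, co_optimal = _collapse_duplicates(records)
    a = np.array([r.a_hat for r in uniq])
    p = np.array([r.p_hat for r in uniq])
    c = np.array([r.c_hat for r in uniq])
    by_idx = {i: r for i, r in enumerate(uniq)}

    faces = _envelope_faces(a, p, c, box)
    domains = [
        Domain2D(by_idx[i].partition_id, poly, by_idx[i])
        for i, poly in sorted(faces.items())
    ]
    domains.sort(key=lambda d: d.partition_id)

    out_of_box: list[int] = []
    if find_out_of_box:
        scale = 10.0
        big = ParameterBox(
            min(0.0, box.gamma_lo),
            scale * max(box.gamma_hi, 1e-6),
            min(0.0, box.omega_lo),
            scale * max(box.omega_hi, 1e-6),
        )
        big_faces = _envelope_faces(a, p, c, big)
        in_box = set(faces)
        out_of_box = sorted(
            by_idx[i].partition_id for i in big_faces if i not in in_box
        )

    dmap = DomainMap2D(
        domains=domains,
        box=box,
        out_of_box=out_of_box,
        input_count=len(records),
        pruned_count=len(records) - len(domains),
        co_optimal=co_optimal,
    )
    dmap.adjacency = domain_adjacency(dmap)
    return dmap


def domain_adjacency(dmap: DomainMap2D) -> dict[tuple[int, int], float]:
    """Shared-border lengths between domains.

    Two domains are adjacent iff they share a 1-dimensional border segment;
    the value is its Euclidean length.  Domains meeting only at a point are
    not adjacent.
    """
    adj: dict[tuple[int, int], float] = {}
    ds = dmap.domains
    for i in range(len(ds)):
        for j in range(i + 1, len(ds)):
            inter = ds[i].polygon.intersection(ds[j].polygon)
            length = float(inter.length)
            if length > VERTEX_TOL:
                key = (
                    min(ds[i].partition_id, ds[j].partition_id),
                    max(ds[i].partition_id, ds[j].partition_id),
                )
                adj[key] = length
    return adj


def assign_point(dmap: DomainMap2D, gamma: float, omega: float) -> int:
    """Partition id whose domain contains the point (smaller id wins on borders)."""
    if not dmap.box.contains(gamma, omega):
        raise ValueError(f"point ({gamma}, {omega}) outside the parameter box")
    pt = Point(gamma, omega)
    covering = [d.partition_id for d in dmap.domains if d.polygon.covers(pt)]
    if covering:
        return min(covering)
    # numerical crack between polygons: fall back to the nearest domain
    dists = [(d.polygon.distance(pt), d.partition_id) for d in dmap.domains]
    return min(dists)[1]


def assign_points(dmap: DomainMap2D, points: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_point` for an (n, 2) array of (gamma, omega)."""
    points = np.asarray(points, dtype=float)
    pts = shapely.points(points)
    out = np.full(len(points), -1, dtype=int)
    for d in sorted(dmap.domains, key=lambda d: d.partition_id):
        unassigned = out < 0
        if not unassigned.any():
            break
        mask = shapely.covers(d.polygon, pts[unassigned])
        idx = np.flatnonzero(unassigned)[mask]
        out[idx] = d.partition_id
    for i in np.flatnonzero(out < 0):
        out[i] = assign_point(dmap, points[i, 0], points[i, 1])
    return out
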