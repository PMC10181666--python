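"""Per-leaf phenotype estimation from a single-leaf point cloud.

Four traits are measured on each leaf instance:

inclination (degrees)
    Angle between the leaf's ventral normal and the zenith axis z,
    in [0, 90].  The normal is approximated by the normal ``r`` of the
    total-least-squares plane ``S_leaf`` fitted to the leaf points.
length (cm)
    The midrib is traced as a greedy k-NN walk between the farthest point
    pair (base P, tip Q), projected onto the plane ``S_vein`` (through P
    and Q, perpendicular to ``S_leaf``), and its polyline length summed.
width (cm)
    The widest cross-section starts at M, the point farthest from
    ``S_vein``; L is the nearest midrib point to M.  The walk from M to L
    is projected onto the plane ``S`` (through M, perpendicular to both
    ``S_leaf`` and ``S_vein``); twice its polyline length is the width.
area (cm^2)
    The leaf surface is meshed by local-tangent-plane projection and
    Delaunay triangulation with edge/angle filters, and triangle areas
    are summed with Heron's formula.

All inputs are in meters; reported traits are in degrees / cm / cm^2.
A moving-least-squares smoothing pass precedes estimation, because
multi-station registration and wind leave the raw leaf surface rough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree
from scipy.spatial.distance import cdist

from .cloud import CloudError, LabeledCloud

__all__ = [
    "FittedPlane",
    "MidribPath",
    "TriangleMesh",
    "LeafPhenotype",
    "PhenotypeConfig",
    "PhenotypeError",
    "mls_smooth",
    "fit_plane_ls",
    "leaf_inclination",
    "find_base_tip",
    "midrib_path",
    "build_svein",
    "leaf_length",
    "leaf_width",
    "triangulate_greedy",
    "heron_area",
    "estimate_phenotype",
]

log = logging.getLogger(__name__)


class PhenotypeError(CloudError):
    """Raised when a leaf instance cannot be measured; carries the id."""

    def __init__(self, message: str, instance_id: Optional[int] = None):
        self.instance_id = instance_id
        prefix = f"leaf {instance_id}: " if instance_id is not None else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class FittedPlane:
    """A plane as unit normal + anchor point (meters)."""

    normal: np.ndarray
    anchor: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=np.float64)
        norm = np.linalg.norm(n)
        if not norm > 0:
            raise ValueError("plane normal must be nonzero")
        object.__setattr__(self, "normal", n / norm)
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=np.float64))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.anchor) @ self.normal

    def project(self, points: np.ndarray) -> np.ndarray:
        """Orthogonal projection of points onto the plane."""
        d = self.signed_distance(points)
        return np.asarray(points) - d[:, None] * self.normal


@dataclass
class MidribPath:
    """Ordered point sequence from start to end, optionally projected."""

    points: np.ndarray
    projected: Optional[np.ndarray] = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("path points must be (m, 3)")

    def length(self, projected: bool = False) -> float:
        pts = self.projected if projected and self.projected is not None else self.points
        if pts.shape[0] < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass
class TriangleMesh:
    """Vertices (m x 3, meters) and triangles (t x 3 vertex indices)."""

    vertices: np.ndarray
    triangles: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.size and self.triangles.max() >= self.vertices.shape[0]:
            raise ValueError("triangle index out of range")


@dataclass(frozen=True)
class LeafPhenotype:
    """The four measured traits of one leaf instance."""

    inclination_deg: float
    length_cm: float
    width_cm: float
    area_cm2: float
    n_points: int = 0
    instance_id: int = -1


@dataclass
class PhenotypeConfig:
    """Tunable parameters of the estimation stages (all lengths meters)."""

    mls_radius: float = 0.012        # 4 x the 3 mm voxel size
    mls_order: int = 2
    midrib_k: int = 8                # k-NN window of the midrib walk
    walk_voxel: float = 0.003        # walk operates at this spacing (0 = raw cloud)
    tri_mu: float = 5.0              # edge length limit, x local 6-NN spacing
    tri_max_nn: int = 100
    tri_radius: Optional[float] = None   # None -> 5 x mean 6-NN spacing
    tri_min_angle_deg: float = 0.0
    tri_max_angle_deg: float = 180.0
    tri_max_surface_angle_deg: float = 60.0
    min_points: int = 30


# ----------------------------------------------------------------------
# smoothing

def mls_smooth(points: np.ndarray, search_radius: float = 0.012, poly_order: int = 2) -> np.ndarray:
    """Moving-least-squares resampling (smoothing).

    Each point is projected onto a bivariate polynomial surface of
    ``poly_order`` fitted (in its local tangent frame) to the neighbors
    within ``search_radius``.  Points whose neighborhood is too small for
    the fit pass through unchanged.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 10:
        raise ValueError("mls_smooth needs at least 10 points")
    if poly_order not in (1, 2):
        raise ValueError("poly_order must be 1 or 2")
    nterms = 3 if poly_order == 1 else 6
    min_support = nterms + 2
    tree = cKDTree(pts)
    neighborhoods = tree.query_ball_point(pts, search_radius, workers=-1)
    out = pts.copy()
    skipped = 0
    for i, idx in enumerate(neighborhoods):
        if len(idx) < min_support:
            skipped += 1
            continue
        nb = pts[idx]
        c = nb.mean(axis=0)
        # local tangent frame from the neighborhood covariance
        cov = np.cov((nb - c).T)
        w, v = np.linalg.eigh(cov)
        normal, e1, e2 = v[:, 0], v[:, 1], v[:, 2]
        local = (nb - c) @ np.column_stack([e1, e2, normal])
        u, vv, h = local[:, 0], local[:, 1], local[:, 2]
        if poly_order == 1:
            A = np.column_stack([np.ones_like(u), u, vv])
        else:
            A = np.column_stack([np.ones_like(u), u, vv, u * u, u * vv, vv * vv])
        coef, *_ = np.linalg.lstsq(A, h, rcond=None)
        p_local = (pts[i] - c) @ np.column_stack([e1, e2, normal])
        ui, vi = p_local[0], p_local[1]
        if poly_order == 1:
            hi = coef @ [1.0, ui, vi]
        else:
            hi = coef @ [1.0, ui, vi, ui * ui, ui * vi, vi * vi]
        out[i] = c + ui * e1 + vi * e2 + hi * normal
    if skipped:
        log.warning("mls_smooth: %d points passed through (insufficient support)", skipped)
    return out


# ----------------------------------------------------------------------
# plane fitting and inclination

def fit_plane_ls(points: np.ndarray) -> FittedPlane:
    """Total-least-squares plane fit (orthogonal distance regression).

    The normal is the eigenvector of the point covariance with the
    smallest eigenvalue, sign-fixed to a non-negative z component so the
    inclination angle is well defined.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    w, v = np.linalg.eigh(cov)
    if w[1] <= max(w[2], 1.0) * 1e-12:
        raise ValueError("degenerate (collinear) point set: no unique plane")
    normal = v[:, 0]
    if normal[2] < 0 or (normal[2] == 0 and (normal[0] < 0 or (normal[0] == 0 and normal[1] < 0))):
        normal = -normal
    return FittedPlane(normal=normal, anchor=c)


def leaf_inclination(plane: FittedPlane) -> float:
    """Angle between the plane normal and the zenith axis, degrees in [0, 90]."""
    cos_a = abs(float(plane.normal[2]))
    return float(np.degrees(np.arccos(np.clip(cos_a, 0.0, 1.0))))


# ----------------------------------------------------------------------
# midrib fitting

def find_base_tip(points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """The farthest point pair = leaf base P and tip Q.

    (Which end is the base is irrelevant to the walk.)  Ties are broken
    by the lexicographically smallest ordered pair.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    if pts.shape[0] > 2500:
        # the diameter is realized on the convex hull
        try:
            from scipy.spatial import ConvexHull

            cand = pts[np.unique(ConvexHull(pts, qhull_options="QJ").vertices)]
        except QhullError:
            cand = pts
    else:
        cand = pts
    d = cdist(cand, cand)
    dmax = d.max()
    ii, jj = np.where(d == dmax)
    best = None
    for a, b in zip(ii, jj):
        if a == b:
            continue
        p, q = cand[a], cand[b]
        pair = (tuple(p), tuple(q)) if tuple(p) <= tuple(q) else (tuple(q), tuple(p))
        if best is None or pair < best:
            best = pair
    return np.array(best[0]), np.array(best[1])


def _find_row(points: np.ndarray, target: np.ndarray, tol: float = 1e-9) -> int:
    d = np.linalg.norm(points - target, axis=1)
    i = int(np.argmin(d))
    if d[i] > tol:
        raise ValueError("point is not a member of the cloud")
    return i


def midrib_path(points: np.ndarray, start: np.ndarray, end: np.ndarray, k: int = 8) -> MidribPath:
    """Greedy k-NN walk from ``start`` to ``end`` through the leaf cloud.

    From the current base point b, the k nearest remaining neighbors are
    scored by D = |n - b| + |n - end|; the minimizer becomes the next base
    point and is removed from the working cloud (the end point is never
    removed, so the walk terminates in at most n steps).  Ties on D are
    broken by smaller point index.
    """
    pts = np.asarray(points, dtype=np.float64)
    if k < 1:
        raise ValueError("k must be >= 1")
    i_start = _find_row(pts, np.asarray(start, dtype=np.float64))
    i_end = _find_row(pts, np.asarray(end, dtype=np.float64))
    path = [i_start]
    if i_start == i_end:
        return MidribPath(points=pts[path])
    alive = np.ones(pts.shape[0], dtype=bool)
    alive[i_start] = False
    b = i_start
    d_end_all = np.linalg.norm(pts - pts[i_end], axis=1)
    while b != i_end:
        cand = np.flatnonzero(alive)
        if cand.size == 0:
            raise RuntimeError("candidate set exhausted before reaching the end point")
        d_b = np.linalg.norm(pts[cand] - pts[b], axis=1)
        if cand.size > k:
            sel = np.argpartition(d_b, k - 1)[:k]
            cand, d_b = cand[sel], d_b[sel]
        D = d_b + d_end_all[cand]
        # minimal D, ties -> smaller point index
        winners = cand[D <= D.min() + 1e-15]
        nxt = int(winners.min())
        path.append(nxt)
        if nxt != i_end:
            alive[nxt] = False
        b = nxt
    return MidribPath(points=pts[path])


def build_svein(P: np.ndarray, Q: np.ndarray, s_leaf: FittedPlane) -> FittedPlane:
    """The midrib projection plane: through P and Q, perpendicular to S_leaf."""
    P = np.asarray(P, dtype=np.float64)
    Q = np.asarray(Q, dtype=np.float64)
    v = Q - P
    if np.linalg.norm(v) == 0:
        raise ValueError("P and Q coincide")
    n = np.cross(v, s_leaf.normal)
    if np.linalg.norm(n) < 1e-12 * np.linalg.norm(v):
        raise ValueError("base-tip axis parallel to the leaf normal: S_vein undefined")
    return FittedPlane(normal=n, anchor=P)


def leaf_length(path: MidribPath, s_vein: FittedPlane) -> float:
    """Leaf length in meters: polyline length of the midrib projected onto
    S_vein (projection removes the lateral zigzag of the walk)."""
    if path.points.shape[0] < 2:
        return 0.0
    proj = s_vein.project(path.points)
    path.projected = proj
    return float(np.linalg.norm(np.diff(proj, axis=0), axis=1).sum())


def leaf_width(
    points: np.ndarray,
    midrib: MidribPath,
    s_leaf: FittedPlane,
    s_vein: FittedPlane,
    k: int = 8,
    walk_points: Optional[np.ndarray] = None,
) -> float:
    """Leaf width in meters: twice the projected half-width path length.

    M is the leaf point farthest from S_vein (a boundary point of the
    widest cross-section); L is the point of the *fitted* (S_vein-
    projected) midrib nearest to M, so L sits in the vein plane and the
    half walk spans the full half width.  The walk from M to L is
    projected onto the plane S through M perpendicular to both S_leaf and
    S_vein, and its length is half the leaf width.

    ``walk_points`` optionally supplies a (thinned) cloud for the walk
    itself; M and L are appended to it so the walk endpoints are always
    members.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.shape[0] == 0:
        raise ValueError("empty leaf cloud")
    dist = np.abs(s_vein.signed_distance(pts))
    M = pts[int(np.argmax(dist))]
    fitted = midrib.projected if midrib.projected is not None else s_vein.project(midrib.points)
    d_m = np.linalg.norm(fitted - M, axis=1)
    L = fitted[int(np.argmin(d_m))]
    n_s = np.cross(s_leaf.normal, s_vein.normal)
    if np.linalg.norm(n_s) < 1e-12:
        raise ValueError("degenerate S plane: leaf and vein planes are parallel")
    s_plane = FittedPlane(normal=n_s, anchor=M)
    base = pts if walk_points is None else np.asarray(walk_points, dtype=np.float64)
    half = midrib_path(np.vstack([base, M, L]), M, L, k=k)
    if half.points.shape[0] < 2:
        return 0.0
    proj = s_plane.project(half.points)
    return 2.0 * float(np.linalg.norm(np.diff(proj, axis=0), axis=1).sum())


# ----------------------------------------------------------------------
# surface meshing and area

def _estimate_normals(pts: np.ndarray, tree: cKDTree, k: int) -> np.ndarray:
    k = min(k, pts.shape[0])
    _, idx = tree.query(pts, k=k, workers=-1)
    normals = np.zeros_like(pts)
    for i in range(pts.shape[0]):
        nb = pts[idx[i]]
        cov = np.cov((nb - nb.mean(axis=0)).T)
        _, v = np.linalg.eigh(cov)
        normals[i] = v[:, 0]
    return normals


def triangulate_greedy(
    points: np.ndarray,
    mu: float = 5.0,
    max_nn: int = 100,
    search_radius: Optional[float] = None,
    angle_limits: Tuple[float, float] = (0.0, 180.0),
    max_surface_angle_deg: float = 60.0,
) -> TriangleMesh:
    """Surface triangulation by local tangent-plane projection.

    Each point's neighborhood (within ``search_radius``, at most
    ``max_nn`` points) is projected onto its local tangent plane and
    Delaunay-triangulated; a triangle enters the mesh only when all three
    of its vertices propose it, which keeps the mesh consistent and free
    of overlaps.  Triangles are then filtered by edge length
    (<= ``mu`` x local point spacing), by interior angles
    (``angle_limits``), and by deviation of the triangle normal from the
    local vertex normals (``max_surface_angle_deg``).
    """
    pts = np.asarray(points, dtype=np.float64)
    n = pts.shape[0]
    if n < 3:
        raise ValueError("triangulation needs at least 3 points")
    scale = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    if scale == 0:
        raise ValueError("degenerate cloud")
    # deterministic symmetry-breaking jitter: avoids cocircular ambiguity
    # (e.g. perfect grids) so local Delaunay diagonals agree across patches
    jit = np.random.default_rng(0).normal(scale=1e-7 * scale, size=pts.shape)
    jpts = pts + jit

    tree = cKDTree(jpts)
    # local spacing from the 6-NN ring: for irregular (non-grid) sampling the
    # single nearest neighbor underestimates the typical Delaunay edge length
    kk = min(7, n)
    nn_d, _ = tree.query(jpts, k=kk, workers=-1)
    spacing = nn_d[:, 1:].mean(axis=1)
    if search_radius is None:
        search_radius = 5.0 * float(spacing.mean())
    normals = _estimate_normals(jpts, tree, k=min(20, n))

    proposals: dict = {}
    neighborhoods = tree.query_ball_point(jpts, search_radius, workers=-1)
    for i in range(n):
        idx = neighborhoods[i]
        if len(idx) > max_nn:
            nb_d = np.linalg.norm(jpts[idx] - jpts[i], axis=1)
            idx = [idx[j] for j in np.argsort(nb_d)[:max_nn]]
        if len(idx) < 3:
            continue
        idx = np.asarray(idx)
        nb = jpts[idx]
        # local frame around point i
        normal = normals[i]
        e1 = np.cross(normal, [1.0, 0.0, 0.0])
        if np.linalg.norm(e1) < 1e-8:
            e1 = np.cross(normal, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(normal, e1)
        uv = (nb - jpts[i]) @ np.column_stack([e1, e2])
        try:
            tri2d = Delaunay(uv)
        except QhullError:
            continue
        local_i = int(np.flatnonzero(idx == i)[0])
        for simplex in tri2d.simplices:
            if local_i in simplex:
                key = tuple(sorted(idx[simplex]))
                proposals[key] = proposals.get(key, 0) + 1

    tris = np.array([t for t, c in proposals.items() if c == 3], dtype=np.int64)
    if tris.size == 0:
        raise ValueError("no consistent triangles found; increase search_radius")

    A, B, C = jpts[tris[:, 0]], jpts[tris[:, 1]], jpts[tris[:, 2]]
    e_ab = np.linalg.norm(B - A, axis=1)
    e_bc = np.linalg.norm(C - B, axis=1)
    e_ca = np.linalg.norm(A - C, axis=1)
    local_spacing = spacing[tris].mean(axis=1)
    keep = np.maximum.reduce([e_ab, e_bc, e_ca]) <= mu * local_spacing

    # interior angle limits
    def angle(a, b, c):  # angle at vertex with adjacent sides a, b and opposite c
        cosv = np.clip((a**2 + b**2 - c**2) / (2 * a * b + 1e-300), -1, 1)
        return np.degrees(np.arccos(cosv))

    ang1 = angle(e_ab, e_ca, e_bc)
    ang2 = angle(e_ab, e_bc, e_ca)
    ang3 = 180.0 - ang1 - ang2
    amin, amax = angle_limits
    angs = np.column_stack([ang1, ang2, ang3])
    keep &= (angs.min(axis=1) >= amin) & (angs.max(axis=1) <= amax)

    # surface-angle filter: triangle normal vs mean vertex normal
    tn = np.cross(B - A, C - A)
    tn_norm = np.linalg.norm(tn, axis=1)
    nondegenerate = tn_norm > 1e-14 * scale**2
    keep &= nondegenerate
    vn = normals[tris]
    # vertex normals are sign-ambiguous; align to the triangle normal
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_dev = np.abs(np.einsum("tj,tvj->tv", tn / np.maximum(tn_norm, 1e-300)[:, None], vn))
    keep &= np.degrees(np.arccos(np.clip(cos_dev, 0, 1))).max(axis=1) <= max_surface_angle_deg

    tris = tris[keep]
    used = np.unique(tris)
    if used.size < n:
        log.debug("triangulate_greedy: %d of %d points unreferenced", n - used.size, n)
    return TriangleMesh(vertices=pts, triangles=tris)


def heron_area(mesh: TriangleMesh) -> float:
    """Total mesh area (m^2) by Heron's formula.

    For each triangle with sides a, b, c and half-perimeter
    p = (a + b + c) / 2, the area is sqrt(p (p-a) (p-b) (p-c)); tiny
    negative radicands from float noise are clamped to zero.
    """
    if mesh.triangles.size == 0:
        return 0.0
    V = mesh.vertices
    T = mesh.triangles
    a = np.linalg.norm(V[T[:, 1]] - V[T[:, 0]], axis=1)
    b = np.linalg.norm(V[T[:, 2]] - V[T[:, 1]], axis=1)
    c = np.linalg.norm(V[T[:, 0]] - V[T[:, 2]], axis=1)
    p = 0.5 * (a + b + c)
    radicand = p * (p - a) * (p - b) * (p - c)
    return float(np.sqrt(np.clip(radicand, 0.0, None)).sum())


# ----------------------------------------------------------------------
# end-to-end single-leaf estimation

def estimate_phenotype(
    leaf_points,
    config: Optional[PhenotypeConfig] = None,
    instance_id: int = -1,
) -> LeafPhenotype:
    """Measure inclination, length, width and area of one leaf instance.

    ``leaf_points`` is an (n, 3) array or :class:`LabeledCloud` in
    original (denormalized) meters.  Stages: MLS smoothing -> plane fit
    (inclination) -> farthest pair -> midrib walk -> S_vein projection
    (length) -> widest-cross-section walk (width) -> triangulation +
    Heron (area).
    """
    cfg = config or PhenotypeConfig()
    pts = leaf_points.coords if isinstance(leaf_points, LabeledCloud) else np.asarray(leaf_points, dtype=np.float64)
    if pts.shape[0] < cfg.min_points:
        raise PhenotypeError(
            f"needs at least {cfg.min_points} points, got {pts.shape[0]}", instance_id
        )
    try:
        smooth = mls_smooth(pts, search_radius=cfg.mls_radius, poly_order=cfg.mls_order)
        s_leaf = fit_plane_ls(smooth)
        alpha = leaf_inclination(s_leaf)
        P, Q = find_base_tip(smooth)
        # the greedy walk assumes ~3 mm neighbor spacing (its k-NN window is
        # sized for the voxel grid), so it runs on a thinned copy; P and Q
        # are appended so the endpoints are always members
        if cfg.walk_voxel and cfg.walk_voxel > 0:
            from .preprocess import voxel_thin

            walk_pts = np.vstack(
                [voxel_thin(LabeledCloud(smooth), voxel=cfg.walk_voxel).coords, P, Q]
            )
        else:
            walk_pts = smooth
        path = midrib_path(walk_pts, P, Q, k=cfg.midrib_k)
        s_vein = build_svein(P, Q, s_leaf)
        length_m = leaf_length(path, s_vein)
        width_m = leaf_width(
            smooth, path, s_leaf, s_vein, k=cfg.midrib_k, walk_points=walk_pts
        )
        mesh = triangulate_greedy(
            smooth,
            mu=cfg.tri_mu,
            max_nn=cfg.tri_max_nn,
            search_radius=cfg.tri_radius,
            angle_limits=(cfg.tri_min_angle_deg, cfg.tri_max_angle_deg),
            max_surface_angle_deg=cfg.tri_max_surface_angle_deg,
        )
        area_m2 = heron_area(mesh)
    except PhenotypeError:
        raise
    except (ValueError, RuntimeError) as exc:
        raise PhenotypeError(str(exc), instance_id) from exc
    return LeafPhenotype(
        inclination_deg=alpha,
        length_cm=length_m * 100.0,
        width_cm=width_m * 100.0,
        area_cm2=area_m2 * 1e4,
        n_points=int(pts.shape[0]),
        instance_id=instance_id,
    )
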