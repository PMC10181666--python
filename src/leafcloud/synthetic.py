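"""Synthetic branch + leaf point clouds with analytic ground truth.

The generator emulates a terrestrial-lidar branch sample at pear-tree
scale so that every stage of the pipeline can be tested without scan
data.  A leaf is a ruled surface over a quadratic Bezier midrib (drooping
out of the leaf plane) with a smooth width profile that vanishes at the
base and tip and peaks at a configurable arc position — an ovate,
pear-like silhouette.  Ground truth is recorded per leaf:

* length — arc length of the midrib (fine quadrature);
* width — the maximum of the width profile;
* area — surface quadrature on a fine parameter grid;
* inclination — from the total-least-squares plane of a dense,
  area-uniform deterministic sampling of the posed surface.

Branches are slightly bent cylinders with leaves attached along the axis
in a phyllotaxis-like spiral.  All randomness flows through a single
seed; output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .cloud import CloudError, LabeledCloud
from .phenotype import fit_plane_ls, leaf_inclination

__all__ = [
    "LeafSpec",
    "BranchSpec",
    "LeafTruth",
    "make_leaf",
    "make_branch",
    "perturb",
    "min_centroid_separation",
]


@dataclass(frozen=True)
class LeafSpec:
    """Parametric single-leaf description (lengths in meters).

    The midrib is the quadratic Bezier through (0,0,0) and (chord,0,0)
    with the middle control point lifted by ``droop * chord``; the width
    profile is ``width_max * sin(pi * s**q) ** width_power`` with ``q``
    chosen so the peak sits at arc position ``s_mid``.
    """

    chord: float = 0.08          # base-to-tip straight distance
    droop: float = 0.12          # out-of-plane bow, fraction of chord
    width_max: float = 0.045     # maximum blade width
    width_power: float = 0.9
    s_mid: float = 0.4           # arc position of the widest section
    fold_angle_deg: float = 0.0  # dihedral fold about the midrib
    tilt_deg: float = 0.0        # leaf plane tilt from horizontal
    yaw_deg: float = 0.0
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    sampling_density: float = 25.0  # points per cm^2 (~2 mm spacing)
    noise_sigma: float = 0.0     # isotropic jitter, meters
    dropout: float = 0.0         # fraction of a random cap removed

    def __post_init__(self):
        if not (self.chord > 0 and self.width_max > 0):
            raise ValueError("chord and width_max must be positive")
        if not (0 < self.s_mid < 1):
            raise ValueError("s_mid must lie strictly inside (0, 1)")


@dataclass(frozen=True)
class LeafTruth:
    """Analytic ground truth of one generated leaf."""

    instance_id: int
    inclination_deg: float
    length_cm: float
    width_cm: float
    area_cm2: float
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass(frozen=True)
class BranchSpec:
    """Branch sample description (lengths in meters).

    Defaults mirror observed pear-branch statistics: branch length within
    0.25–1.13 m, 8–26 leaves, leaf blades 4–12 cm long and 2–7 cm wide.
    """

    length: float = 0.7
    radius: float = 0.004
    bend: float = 0.08             # sagitta of the axis, fraction of length
    n_leaves: int = 14
    leaf_chord_range: Tuple[float, float] = (0.04, 0.12)
    width_ratio_range: Tuple[float, float] = (0.45, 0.62)
    width_clip: Tuple[float, float] = (0.02, 0.07)
    droop_range: Tuple[float, float] = (0.05, 0.18)
    tilt_range_deg: Tuple[float, float] = (10.0, 80.0)
    petiole: float = 0.012
    min_separation: float = 0.0    # enforced pairwise centroid distance (0 = report only)
    point_spacing: float = 0.003   # branch surface sampling (~voxel grid)
    sampling_density: float = 25.0
    max_retries: int = 50

    def __post_init__(self):
        if not (0.1 <= self.length <= 2.0):
            raise ValueError("branch length out of plausible range")
        if self.n_leaves < 0:
            raise ValueError("n_leaves must be non-negative")


# ----------------------------------------------------------------------
# midrib geometry

def _bezier(spec: LeafSpec, s: np.ndarray) -> np.ndarray:
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([spec.chord / 2.0, 0.0, spec.droop * spec.chord])
    p2 = np.array([spec.chord, 0.0, 0.0])
    s = np.asarray(s, dtype=np.float64)[:, None]
    return (1 - s) ** 2 * p0 + 2 * (1 - s) * s * p1 + s**2 * p2


def _bezier_deriv(spec: LeafSpec, s: np.ndarray) -> np.ndarray:
    p0 = np.array([0.0, 0.0, 0.0])
    p1 = np.array([spec.chord / 2.0, 0.0, spec.droop * spec.chord])
    p2 = np.array([spec.chord, 0.0, 0.0])
    s = np.asarray(s, dtype=np.float64)[:, None]
    return 2 * (1 - s) * (p1 - p0) + 2 * s * (p2 - p1)


def _width_profile(spec: LeafSpec, s: np.ndarray) -> np.ndarray:
    q = math.log(0.5) / math.log(spec.s_mid)
    s = np.clip(np.asarray(s, dtype=np.float64), 0.0, 1.0)
    return spec.width_max * np.sin(np.pi * s**q) ** spec.width_power


def _pose_matrix(spec: LeafSpec) -> np.ndarray:
    ty = math.radians(spec.tilt_deg)
    tz = math.radians(spec.yaw_deg)
    ry = np.array([
        [math.cos(ty), 0, math.sin(ty)],
        [0, 1, 0],
        [-math.sin(ty), 0, math.cos(ty)],
    ])
    rz = np.array([
        [math.cos(tz), -math.sin(tz), 0],
        [math.sin(tz), math.cos(tz), 0],
        [0, 0, 1],
    ])
    return rz @ ry


def _surface_points(spec: LeafSpec, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Map parameters (s in [0,1], v in [-w(s)/2, w(s)/2]) to canonical 3D."""
    c = _bezier(spec, s)
    if spec.fold_angle_deg == 0.0:
        pts = c.copy()
        pts[:, 1] += v
        return pts
    # fold: rotate the lateral offset about the local midrib tangent
    t = _bezier_deriv(spec, s)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    phi = np.sign(v) * math.radians(spec.fold_angle_deg) / 2.0
    y = np.zeros_like(c)
    y[:, 1] = 1.0
    cosp, sinp = np.cos(phi)[:, None], np.sin(phi)[:, None]
    # Rodrigues rotation of y-hat about t
    rot = (
        y * cosp
        + np.cross(t, y) * sinp
        + t * (np.sum(t * y, axis=1, keepdims=True)) * (1 - cosp)
    )
    return c + v[:, None] * rot


def _posed(spec: LeafSpec, pts: np.ndarray) -> np.ndarray:
    return pts @ _pose_matrix(spec).T + np.asarray(spec.origin)


# ----------------------------------------------------------------------
# analytic / quadrature ground truth

def midrib_arc_length(spec: LeafSpec, n: int = 4096) -> float:
    """Arc length of the Bezier midrib by composite midpoint quadrature."""
    s = (np.arange(n) + 0.5) / n
    return float(np.linalg.norm(_bezier_deriv(spec, s), axis=1).sum() / n)


def leaf_area_quadrature(spec: LeafSpec, ns: int = 800, nv: int = 120) -> float:
    """Surface area by triangulating a fine (s, v) parameter grid."""
    s = np.linspace(0.0, 1.0, ns)
    frac = np.linspace(-0.5, 0.5, nv)
    S, F = np.meshgrid(s, frac, indexing="ij")
    V = F * _width_profile(spec, s)[:, None]
    pts = _surface_points(spec, S.ravel(), V.ravel()).reshape(ns, nv, 3)
    # sum the two triangles of every grid quad
    a = pts[:-1, :-1]
    b = pts[1:, :-1]
    c = pts[1:, 1:]
    d = pts[:-1, 1:]
    t1 = 0.5 * np.linalg.norm(np.cross(b - a, d - a), axis=-1)
    t2 = 0.5 * np.linalg.norm(np.cross(b - c, d - c), axis=-1)
    return float(t1.sum() + t2.sum())


def _dense_uniform_sampling(spec: LeafSpec, ns: int = 200, nv: int = 60) -> np.ndarray:
    """Deterministic, approximately area-uniform surface grid (posed)."""
    grid = np.linspace(0, 1, 2049)
    dens = _width_profile(spec, grid) * np.linalg.norm(_bezier_deriv(spec, grid), axis=1)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    s_mid = np.interp((np.arange(ns) + 0.5) / ns, cdf, grid)
    frac = (np.arange(nv) + 0.5) / nv - 0.5
    S = np.repeat(s_mid, nv)
    V = np.tile(frac, ns) * _width_profile(spec, S)
    return _posed(spec, _surface_points(spec, S, V))


def leaf_truth(spec: LeafSpec, instance_id: int = 0) -> LeafTruth:
    """Ground-truth record for a spec (independent of any sampled cloud)."""
    dense = _dense_uniform_sampling(spec)
    incl = leaf_inclination(fit_plane_ls(dense))
    return LeafTruth(
        instance_id=instance_id,
        inclination_deg=incl,
        length_cm=midrib_arc_length(spec) * 100.0,
        width_cm=spec.width_max * 100.0,
        area_cm2=leaf_area_quadrature(spec) * 1e4,
        centroid=dense.mean(axis=0),
    )


# ----------------------------------------------------------------------
# sampling

def make_leaf(spec: LeafSpec, seed: int = 0, instance_id: int = 0) -> Tuple[LabeledCloud, LeafTruth]:
    """Sample a leaf surface (semantic = 1) and return its ground truth.

    Points are drawn area-uniformly: the arc position s follows the
    density w(s)|c'(s)| via inverse-CDF sampling and the lateral offset is
    uniform across the local width.  The truth record depends only on the
    spec, never on the seed.
    """
    truth = leaf_truth(spec, instance_id)
    n = int(round(spec.sampling_density * truth.area_cm2))
    if n < 30:
        raise CloudError(
            f"sampling density too low: {n} points for a {truth.area_cm2:.1f} cm^2 leaf"
        )
    rng = np.random.default_rng(seed)
    grid = np.linspace(0, 1, 2049)
    dens = _width_profile(spec, grid) * np.linalg.norm(_bezier_deriv(spec, grid), axis=1)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    s = np.interp(rng.random(n), cdf, grid)
    v = (rng.random(n) - 0.5) * _width_profile(spec, s)
    pts = _posed(spec, _surface_points(spec, s, v))
    cloud = LabeledCloud(
        coords=pts,
        semantic=np.ones(n, dtype=np.int64),
        instance=np.full(n, instance_id, dtype=np.int64),
    )
    if spec.noise_sigma > 0 or spec.dropout > 0:
        cloud = perturb(cloud, spec.noise_sigma, spec.dropout, seed=int(rng.integers(2**31)))
    return cloud, truth


def _branch_axis(spec: BranchSpec, u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=np.float64)
    return np.column_stack([
        u * spec.length,
        np.zeros_like(u),
        spec.bend * spec.length * 4.0 * u * (1 - u),
    ])


def _sample_branch_surface(spec: BranchSpec, rng: np.random.Generator) -> np.ndarray:
    n_rings = max(2, int(spec.length / spec.point_spacing))
    u = np.linspace(0, 1, n_rings)
    axis = _branch_axis(spec, u)
    tangent = np.gradient(axis, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    ref = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(tangent, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(tangent, e1)
    n_around = max(3, int(round(2 * np.pi * spec.radius / spec.point_spacing)))
    theta = 2 * np.pi * (np.arange(n_around) / n_around)
    pts = (
        axis[:, None, :]
        + spec.radius * np.cos(theta)[None, :, None] * e1[:, None, :]
        + spec.radius * np.sin(theta)[None, :, None] * e2[:, None, :]
    ).reshape(-1, 3)
    return pts + rng.normal(scale=spec.point_spacing * 0.05, size=pts.shape)


def make_branch(spec: BranchSpec, seed: int = 0) -> Tuple[LabeledCloud, List[LeafTruth]]:
    """Generate a branch cylinder plus posed leaves with unique instance ids.

    Leaf placement is retried (with fresh jitter) until all pairwise leaf
    centroids are at least ``spec.min_separation`` apart; each truth
    record carries the posed leaf centroid so tests can verify the
    separation when choosing clustering radii
    (see :func:`min_centroid_separation`).
    """
    rng = np.random.default_rng(seed)
    branch_pts = _sample_branch_surface(spec, rng)
    if spec.n_leaves == 0:
        n = branch_pts.shape[0]
        return (
            LabeledCloud(branch_pts, np.zeros(n, dtype=np.int64), np.full(n, -1, dtype=np.int64)),
            [],
        )

    for _ in range(spec.max_retries):
        trial = np.random.default_rng(rng.integers(2**31))
        clouds, truths = _place_leaves(spec, trial)
        if (
            spec.n_leaves < 2
            or spec.min_separation <= 0
            or min_centroid_separation(truths) >= spec.min_separation
        ):
            break
    else:
        raise CloudError(
            f"could not place {spec.n_leaves} leaves with centroid separation "
            f">= {spec.min_separation} m after {spec.max_retries} retries"
        )

    nb = branch_pts.shape[0]
    coords = np.vstack([branch_pts] + [c.coords for c in clouds])
    semantic = np.concatenate(
        [np.zeros(nb, dtype=np.int64)] + [c.semantic for c in clouds]
    )
    instance = np.concatenate(
        [np.full(nb, -1, dtype=np.int64)] + [c.instance for c in clouds]
    )
    return LabeledCloud(coords, semantic, instance), truths


def _place_leaves(spec: BranchSpec, rng: np.random.Generator):
    n = spec.n_leaves
    u = np.linspace(0.08, 0.95, n) + rng.uniform(-0.01, 0.01, n)
    attach = _branch_axis(spec, np.clip(u, 0, 1))
    clouds, truths = [], []
    for i in range(n):
        chord = rng.uniform(*spec.leaf_chord_range)
        width = float(np.clip(chord * rng.uniform(*spec.width_ratio_range), *spec.width_clip))
        # leaves fan out sideways, alternating left/right along the shoot;
        # they never point down the axis into their neighbors
        yaw = (90.0 + 180.0 * (i % 2) + rng.uniform(-40, 40)) % 360.0
        leaf_spec = LeafSpec(
            chord=chord,
            droop=rng.uniform(*spec.droop_range),
            width_max=width,
            tilt_deg=rng.uniform(*spec.tilt_range_deg),
            yaw_deg=yaw,
            origin=tuple(attach[i]),
            sampling_density=spec.sampling_density,
        )
        # push the blade off the branch axis along its own midrib direction
        direction = _pose_matrix(leaf_spec) @ np.array([1.0, 0.0, 0.0])
        leaf_spec = replace(leaf_spec, origin=tuple(attach[i] + spec.petiole * direction))
        cloud, truth = make_leaf(leaf_spec, seed=int(rng.integers(2**31)), instance_id=i)
        clouds.append(cloud)
        truths.append(truth)
    return clouds, truths


def min_centroid_separation(truths: List[LeafTruth]) -> float:
    """Minimum pairwise distance between leaf centroids (inf for < 2 leaves)."""
    if len(truths) < 2:
        return float("inf")
    c = np.array([t.centroid for t in truths])
    d = np.linalg.norm(c[:, None] - c[None, :], axis=2)
    return float(d[np.triu_indices(len(truths), k=1)].min())


def perturb(
    cloud: LabeledCloud,
    noise_sigma: float = 0.0,
    dropout: float = 0.0,
    seed: int = 0,
) -> LabeledCloud:
    """Add isotropic Gaussian jitter and remove a random spherical cap of
    ``dropout`` fraction from each leaf instance (labels preserved).

    Emulates registration noise and the occasional incompleteness of
    occluded leaves in multi-station scans.
    """
    if not 0.0 <= dropout < 1.0:
        raise ValueError("dropout must be in [0, 1)")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    coords = cloud.coords.copy()
    if noise_sigma > 0:
        coords = coords + rng.normal(scale=noise_sigma, size=coords.shape)
    out = cloud.with_coords(coords)
    if dropout == 0.0:
        return out
    if cloud.instance is not None:
        groups = [np.flatnonzero(cloud.instance == i) for i in np.unique(cloud.instance) if i >= 0]
    else:
        groups = [np.arange(cloud.n)]
    drop_mask = np.zeros(cloud.n, dtype=bool)
    for idx in groups:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        proj = out.coords[idx] @ direction
        k = int(round(dropout * idx.size))
        if k > 0:
            drop_mask[idx[np.argsort(-proj)[:k]]] = True
    return out.select(~drop_mask)
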