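"""Geometry primitives on sets of spheres.

Everything downstream (exposure radii, beta-shape boundaries, ligand shape
descriptors) reduces to a handful of operations on balls in 3-space:

* the minimum enclosing sphere of a set of balls,
* PCA bounding-box extents,
* the volume of a union of balls and its equal-volume radius,
* centers of probe spheres externally tangent to three given atoms.

All coordinates and radii are in Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

__all__ = [
    "Sphere",
    "BoxExtents",
    "minimum_enclosing_sphere",
    "pca_box_extents",
    "union_volume",
    "equal_volume_radius",
    "tangent_probe_centers",
]


class DegenerateInputError(ValueError):
    """Raised when sphere centers are coincident/collinear where that is fatal."""


@dataclass(frozen=True)
class Sphere:
    """A ball: center (3-vector, A) and radius (A, >= 0)."""

    center: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"center must be a finite 3-vector, got {self.center!r}")
        if not np.isfinite(self.radius) or self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius!r}")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "radius", float(self.radius))


@dataclass(frozen=True)
class BoxExtents:
    """Principal-axis bounding-box edge lengths, sorted L1 >= L2 >= L3 >= 0."""

    L1: float
    L2: float
    L3: float

    def __post_init__(self) -> None:
        if not (self.L1 >= self.L2 >= self.L3 >= -1e-12):
            raise ValueError(f"extents must satisfy L1 >= L2 >= L3 >= 0: {self}")


def _as_arrays(spheres: Sequence[Sphere]) -> tuple[np.ndarray, np.ndarray]:
    centers = np.array([s.center for s in spheres], dtype=float)
    radii = np.array([s.radius for s in spheres], dtype=float)
    return centers, radii


def minimum_enclosing_sphere(spheres: Sequence[Sphere], tol: float = 1e-6) -> Sphere:
    """Smallest sphere containing every input ball entirely.

    Solved as the convex program  min_{c,R} R  s.t.  |c - c_i| + r_i <= R,
    i.e. the minimax of the ball support function.  The returned sphere
    satisfies the containment constraints to within ``tol``.
    """
    spheres = list(spheres)
    if not spheres:
        raise ValueError("minimum_enclosing_sphere requires at least one sphere")
    centers, radii = _as_arrays(spheres)
    if len(spheres) == 1:
        return Sphere(centers[0], radii[0])

    def support(c: np.ndarray) -> np.ndarray:
        # distance from c to the far side of each ball; eps guards the
        # gradient when c coincides with a center
        d = np.sqrt(np.sum((centers - c) ** 2, axis=1) + 1e-30)
        return d + radii

    # start from the midpoint of the farthest support pair
    c0 = centers.mean(axis=0)
    x0 = np.concatenate([c0, [support(c0).max()]])

    def objective(x):
        return x[3]

    def obj_grad(x):
        return np.array([0.0, 0.0, 0.0, 1.0])

    def cons(x):
        return x[3] - support(x[:3])

    def cons_jac(x):
        d = np.sqrt(np.sum((centers - x[:3]) ** 2, axis=1) + 1e-30)
        jac = np.empty((len(centers), 4))
        jac[:, :3] = (centers - x[:3]) / d[:, None]
        jac[:, 3] = 1.0
        return jac

    res = optimize.minimize(
        objective,
        x0,
        jac=obj_grad,
        constraints=[{"type": "ineq", "fun": cons, "jac": cons_jac}],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    c = res.x[:3]
    # R is set by the active constraints, never below the support max
    R = float(support(c).max())
    return Sphere(c, R)


def pca_box_extents(
    spheres: Sequence[Sphere], include_radii: bool = True
) -> BoxExtents:
    """Edge lengths of the PCA-aligned bounding box of a set of balls.

    Principal axes come from the (unweighted) covariance of the centers; the
    extent along each axis is ``max(proj + r) - min(proj - r)`` when
    ``include_radii`` is set, else the bare center extent.  Degenerate inputs
    (single atom, collinear centers) yield zero center-variance along the
    missing axes, so radii-inclusive extents stay positive (2r).
    """
    spheres = list(spheres)
    if not spheres:
        raise ValueError("pca_box_extents requires at least one sphere")
    centers, radii = _as_arrays(spheres)
    centered = centers - centers.mean(axis=0)
    cov = centered.T @ centered / max(len(spheres), 1)
    _, axes = np.linalg.eigh(cov)  # columns are principal axes
    proj = centered @ axes
    r = radii[:, None] if include_radii else 0.0
    extents = np.sort((proj + r).max(axis=0) - (proj - r).min(axis=0))[::-1]
    return BoxExtents(*[float(v) for v in extents])


def union_volume(
    spheres: Sequence[Sphere],
    method: Literal["grid", "montecarlo"] = "grid",
    resolution: float = 0.2,
    samples: int = 200_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Volume (A^3) of the union of balls, with an error estimate.

    grid:
        counts cell centers of a regular grid with spacing ``resolution``
        inside the union; deterministic.  The error estimate is the
        Richardson-style difference against a grid twice as coarse.
    montecarlo:
        uniform rejection sampling over the bounding box; the second return
        value is the binomial standard error.
    """
    spheres = list(spheres)
    if not spheres:
        raise ValueError("union_volume requires at least one sphere")
    centers, radii = _as_arrays(spheres)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)

    if method == "grid":
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        v = _grid_count(centers, radii, lo, hi, resolution)
        v_coarse = _grid_count(centers, radii, lo, hi, 2.0 * resolution)
        return v, abs(v - v_coarse)
    if method == "montecarlo":
        if samples <= 0:
            raise ValueError("samples must be positive")
        rng = np.random.default_rng(seed)
        pts = rng.uniform(lo, hi, size=(samples, 3))
        inside = _inside_union(pts, centers, radii)
        box = float(np.prod(hi - lo))
        p = inside.mean()
        se = box * float(np.sqrt(max(p * (1.0 - p), 0.0) / samples))
        return box * float(p), se
    raise ValueError(f"unknown method {method!r}")


def _grid_count(centers, radii, lo, hi, h: float) -> float:
    axes = [np.arange(lo[k] + h / 2.0, hi[k], h) for k in range(3)]
    nx, ny, nz = (len(a) for a in axes)
    occupied = np.zeros((nx, ny, nz), dtype=bool)
    # mark per ball inside its own sub-box; avoids a full n_points x n_balls matrix
    for c, r in zip(centers, radii):
        idx = [
            np.searchsorted(axes[k], [c[k] - r, c[k] + r]) for k in range(3)
        ]
        sub = [axes[k][idx[k][0] : idx[k][1]] for k in range(3)]
        if any(len(s) == 0 for s in sub):
            continue
        dx2 = (sub[0] - c[0]) ** 2
        dy2 = (sub[1] - c[1]) ** 2
        dz2 = (sub[2] - c[2]) ** 2
        mask = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :] <= r * r
        occupied[
            idx[0][0] : idx[0][1], idx[1][0] : idx[1][1], idx[2][0] : idx[2][1]
        ] |= mask
    return float(occupied.sum()) * h**3


def _inside_union(pts: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    tree = cKDTree(centers)
    rmax = radii.max()
    inside = np.zeros(len(pts), dtype=bool)
    neighbors = tree.query_ball_point(pts, rmax)
    for i, nbr in enumerate(neighbors):
        if not nbr:
            continue
        d2 = np.sum((centers[nbr] - pts[i]) ** 2, axis=1)
        inside[i] = bool(np.any(d2 <= radii[nbr] ** 2))
    return inside


def equal_volume_radius(volume: float) -> float:
    """Radius of the sphere with the given volume: (3V / 4 pi)^(1/3)."""
    if volume < 0:
        raise ValueError(f"volume must be >= 0, got {volume}")
    return float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))


def tangent_probe_centers(
    s1: Sphere, s2: Sphere, s3: Sphere, beta: float, tol: float = 1e-9
) -> list[np.ndarray]:
    """Centers of probe spheres of radius ``beta`` externally tangent to three atoms.

    Solves |c - c_k| = r_k + beta for k = 1..3.  Generic configurations give 0
    or 2 solutions (mirror images through the plane of the centers); a
    discriminant within ``tol`` of zero gives the single grazing solution.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    a = np.array([s1.center, s2.center, s3.center], dtype=float)
    R = np.array([s1.radius, s2.radius, s3.radius], dtype=float) + beta

    u = a[1] - a[0]
    v = a[2] - a[0]
    n = np.cross(u, v)
    n_norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(u), np.linalg.norm(v), 1.0)
    if n_norm < 1e-12 * scale * scale:
        raise DegenerateInputError("sphere centers are collinear or coincident")
    n = n / n_norm

    # subtracting the tangency equations pairwise gives two planes whose
    # intersection is the axis line p + t*n
    A = np.array([2.0 * u, 2.0 * v])
    b = np.array(
        [
            np.dot(a[1], a[1]) - np.dot(a[0], a[0]) - (R[1] ** 2 - R[0] ** 2),
            np.dot(a[2], a[2]) - np.dot(a[0], a[0]) - (R[2] ** 2 - R[0] ** 2),
        ]
    )
    # particular solution in the plane spanned by u, v
    M = A @ np.stack([u, v], axis=1)
    coeff = np.linalg.solve(M, b - A @ a[0])
    p = a[0] + coeff[0] * u + coeff[1] * v

    # |p + t n - a0|^2 = R0^2, with n unit and (p - a0) . n == 0 up to roundoff
    w = p - a[0]
    t2 = R[0] ** 2 - np.dot(w, w) + np.dot(w, n) ** 2
    if t2 < -tol:
        return []
    if t2 <= tol:
        return [p - np.dot(w, n) * n]
    t = np.sqrt(t2)
    base = p - np.dot(w, n) * n
    return [base + t * n, base - t * n]
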