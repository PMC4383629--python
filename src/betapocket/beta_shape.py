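"""Per-atom probe-exposure radii and the beta-shape boundary.

An atom is *exposed* to a spherical probe of radius beta when some probe
tangent externally to the atom overlaps no other atom.  Each boundary atom
carries an exposure interval [0, beta_i]: it can be touched by any probe up to
its exposure radius beta_i and by none larger (the single-interval model).
The beta-shape boundary at probe radius beta is the set of still-exposed atoms
together with the triangles of atom triples that admit an empty tangent probe;
straightening the rolling-probe (Connolly) surface onto the atom centers gives
a polyhedral surface whose volume is computed by the divergence theorem.

Exposure is decided by sampled tangency directions (a deterministic Fibonacci
sphere) rather than by the exact Voronoi diagram of balls; with the same
direction set the sampled test is exactly monotone in beta, because a smaller
probe tangent along the same direction is contained in the larger one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .sphere_geometry import DegenerateInputError, Sphere, tangent_probe_centers
from .structure_io import MolecularModel

__all__ = [
    "ExposureProfile",
    "BetaBoundary",
    "TopologyError",
    "fibonacci_directions",
    "is_exposed",
    "exposure_radius",
    "compute_exposure_profile",
    "boundary_atoms",
    "beta_boundary",
    "beta_triangles",
    "beta_shape_volume",
    "boundary_adjacency",
    "export_mesh_obj",
    "export_profile_csv",
]

DEFAULT_DIRECTIONS = 512
DEFAULT_TOL = 0.01  # bisection tolerance on beta, A
EMPTY_TOL = 1e-6  # clearance tolerance for "probe overlaps no atom", A


class TopologyError(ValueError):
    """The boundary triangles do not form a closed orientable surface."""

    def __init__(self, message: str, open_edges: Sequence[tuple[int, int]] = ()):
        super().__init__(message)
        self.open_edges = list(open_edges)


@dataclass(frozen=True)
class ExposureProfile:
    """Maximal touchable probe radius per atom (np.inf = exposed at any size)."""

    beta: np.ndarray  # shape (n_atoms,), beta_i >= 0 or +inf
    beta_cap: float
    tol: float

    def __post_init__(self) -> None:
        b = np.asarray(self.beta, dtype=float)
        if np.any(b < 0):
            raise ValueError("exposure radii must be >= 0")
        object.__setattr__(self, "beta", b)

    def boundary_at(self, beta: float) -> set[int]:
        return set(np.nonzero(self.beta >= beta)[0].tolist())


@dataclass(frozen=True)
class BetaBoundary:
    """Boundary atoms, triangles and adjacency of the beta-shape at one beta."""

    beta: float
    boundary_atom_ids: frozenset[int]
    triangles: tuple[tuple[int, int, int], ...]
    adjacency: nx.Graph

    def __post_init__(self) -> None:
        for tri in self.triangles:
            if not set(tri) <= self.boundary_atom_ids:
                raise ValueError(f"triangle {tri} has non-boundary vertices")


def fibonacci_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the sphere (deterministic)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)


class _ExposureEngine:
    """Caches the KD-tree and direction set for repeated exposure queries."""

    def __init__(
        self,
        model: MolecularModel,
        n_directions: int = DEFAULT_DIRECTIONS,
        seed: int | None = None,
        tol: float = EMPTY_TOL,
    ):
        self.centers = model.centers
        self.radii = model.radii
        if np.any(self.radii <= 0):
            raise ValueError("all atoms need positive radii (run assign_radii first)")
        self.tree = cKDTree(self.centers)
        self.rmax = float(self.radii.max())
        self.tol = tol
        dirs = fibonacci_directions(n_directions)
        if seed is not None:
            # optional random rotation of the whole direction set
            rng = np.random.default_rng(seed)
            q = rng.normal(size=(3, 3))
            Q, _ = np.linalg.qr(q)
            dirs = dirs @ Q.T
        self.dirs = dirs

    def is_exposed(self, atom_id: int, beta: float) -> bool:
        if beta < 0:
            raise ValueError("beta must be >= 0")
        c = self.centers[atom_id]
        r = self.radii[atom_id]
        cand = c + (r + beta) * self.dirs  # candidate probe centers
        # atoms that could overlap any candidate probe
        nbr = self.tree.query_ball_point(c, r + 2.0 * beta + self.rmax + self.tol)
        nbr = [j for j in nbr if j != atom_id]
        if not nbr:
            return True
        bc = self.centers[nbr]
        br = self.radii[nbr]
        # candidate is free when it clears every blocker
        d2 = np.sum((cand[:, None, :] - bc[None, :, :]) ** 2, axis=2)
        limit = (br + beta - self.tol) ** 2
        return bool(np.any(np.all(d2 >= limit[None, :], axis=1)))

    def exposed_mask(self, beta: float, subset: Iterable[int] | None = None) -> np.ndarray:
        ids = range(len(self.centers)) if subset is None else subset
        mask = np.zeros(len(self.centers), dtype=bool)
        for i in ids:
            mask[i] = self.is_exposed(i, beta)
        return mask

    def exposure_radius(self, atom_id: int, beta_cap: float, tol: float) -> float:
        if beta_cap <= 0:
            raise ValueError("beta_cap must be positive")
        if self.is_exposed(atom_id, beta_cap):
            return float("inf")
        if not self.is_exposed(atom_id, 0.0):
            return 0.0
        lo, hi = 0.0, beta_cap  # exposed at lo, blocked at hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if self.is_exposed(atom_id, mid):
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)


def _default_cap(model: MolecularModel) -> float:
    c, r = model.centers, model.radii
    span = (c + r[:, None]).max(axis=0) - (c - r[:, None]).min(axis=0)
    return float(np.linalg.norm(span))


def is_exposed(
    model: MolecularModel,
    atom_id: int,
    beta: float,
    n_directions: int = DEFAULT_DIRECTIONS,
    seed: int | None = None,
) -> bool:
    """True if some probe of radius ``beta`` tangent to the atom is empty."""
    return _ExposureEngine(model, n_directions, seed).is_exposed(atom_id, beta)


def exposure_radius(
    model: MolecularModel,
    atom_id: int,
    beta_cap: float | None = None,
    tol: float = DEFAULT_TOL,
    n_directions: int = DEFAULT_DIRECTIONS,
    seed: int | None = None,
) -> float:
    """Upper end beta_i of the atom's exposure interval, by bisection.

    Returns +inf when the atom is still exposed at ``beta_cap`` (default: the
    model diameter).
    """
    cap = beta_cap if beta_cap is not None else _default_cap(model)
    return _ExposureEngine(model, n_directions, seed).exposure_radius(atom_id, cap, tol)


def compute_exposure_profile(
    model: MolecularModel,
    beta_cap: float | None = None,
    tol: float = DEFAULT_TOL,
    n_directions: int = DEFAULT_DIRECTIONS,
    seed: int | None = None,
) -> ExposureProfile:
    """Exposure radii for every atom of the model."""
    cap = beta_cap if beta_cap is not None else _default_cap(model)
    engine = _ExposureEngine(model, n_directions, seed)
    beta = np.array(
        [engine.exposure_radius(i, cap, tol) for i in range(len(model))]
    )
    return ExposureProfile(beta, cap, tol)


def boundary_atoms(
    model: MolecularModel,
    beta: float,
    n_directions: int = DEFAULT_DIRECTIONS,
    seed: int | None = None,
    profile: ExposureProfile | None = None,
) -> set[int]:
    """Atoms on the beta-shape boundary at probe radius ``beta``.

    Equivalent to ``{i : beta_i >= beta}``; computed directly from the
    tangency test (one probe evaluation per atom) unless a precomputed
    profile is supplied.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if profile is not None:
        return profile.boundary_at(beta)
    engine = _ExposureEngine(model, n_directions, seed)
    return set(np.nonzero(engine.exposed_mask(beta))[0].tolist())


def _empty_tangent_centers(
    model: MolecularModel,
    tree: cKDTree,
    tri: tuple[int, int, int],
    beta: float,
    tol: float = EMPTY_TOL,
) -> list[np.ndarray]:
    """Tangent-probe centers for a triple whose probe overlaps no other atom."""
    c, r = model.centers, model.radii
    i, j, k = tri
    try:
        sols = tangent_probe_centers(
            Sphere(c[i], r[i]), Sphere(c[j], r[j]), Sphere(c[k], r[k]), beta
        )
    except DegenerateInputError:
        return []
    rmax = float(r.max())
    empty = []
    for p in sols:
        nbr = tree.query_ball_point(p, beta + rmax + tol)
        nbr = [m for m in nbr if m not in tri]
        if nbr:
            d = np.linalg.norm(c[nbr] - p, axis=1)
            if np.any(d < r[nbr] + beta - tol):
                continue
        empty.append(p)
    return empty


def _oriented_triangles(
    model: MolecularModel, beta: float
) -> list[tuple[int, int, int]]:
    """One oriented triangle per empty tangent probe, normal toward the probe."""
    if beta <= 0:
        raise ValueError("beta must be positive")
    c, r = model.centers, model.radii
    tree = cKDTree(c)
    cutoff = 2.0 * float(r.max()) + 2.0 * beta
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    nbrs: dict[int, set[int]] = {i: set() for i in range(len(model))}
    for a, b in pairs:
        if np.linalg.norm(c[a] - c[b]) <= r[a] + r[b] + 2.0 * beta:
            nbrs[int(a)].add(int(b))
            nbrs[int(b)].add(int(a))
    oriented: list[tuple[int, int, int]] = []
    for i in range(len(model)):
        for j in sorted(nbrs[i]):
            if j <= i:
                continue
            for k in sorted(nbrs[i] & nbrs[j]):
                if k <= j:
                    continue
                for p in _empty_tangent_centers(model, tree, (i, j, k), beta):
                    v1, v2, v3 = c[i], c[j], c[k]
                    n = np.cross(v2 - v1, v3 - v1)
                    centroid = (v1 + v2 + v3) / 3.0
                    if np.dot(n, p - centroid) >= 0:
                        oriented.append((i, j, k))
                    else:
                        oriented.append((i, k, j))
    return oriented


def beta_triangles(model: MolecularModel, beta: float) -> list[tuple[int, int, int]]:
    """Atom triples admitting an empty tangent probe of radius ``beta``.

    Each triple is reported once (sorted ids) even if both mirror probes are
    empty.  Candidate triples are pruned by pairwise center distance
    ``|c_i - c_j| <= r_i + r_j + 2 beta``.
    """
    seen: set[tuple[int, int, int]] = set()
    out: list[tuple[int, int, int]] = []
    for tri in _oriented_triangles(model, beta):
        key = tuple(sorted(tri))
        if key not in seen:
            seen.add(key)
            out.append(key)  # type: ignore[arg-type]
    return out


def beta_shape_volume(model: MolecularModel, beta: float) -> float:
    """Volume (A^3) of the beta-shape from its triangulated boundary.

    The boundary triangles (vertices at atom centers, normals oriented toward
    their empty probes, i.e. outward) must form a closed orientable surface:
    every undirected edge in exactly two triangles with opposite directions.
    The signed divergence-theorem sum then gives the enclosed volume.
    """
    oriented = _oriented_triangles(model, beta)
    if not oriented:
        raise TopologyError("no boundary triangles: surface is not closed")
    edge_count: dict[tuple[int, int], int] = {}
    for a, b, cc in oriented:
        for e in ((a, b), (b, cc), (cc, a)):
            edge_count[e] = edge_count.get(e, 0) + 1
    bad = [
        e
        for e in edge_count
        if edge_count[e] != 1 or edge_count.get((e[1], e[0]), 0) != 1
    ]
    if bad:
        raise TopologyError(
            f"boundary is not a closed orientable surface; offending edges: "
            f"{sorted(set(tuple(sorted(e)) for e in bad))[:20]}",
            open_edges=bad,
        )
    c = model.centers
    vol = 0.0
    for a, b, cc in oriented:
        vol += float(np.linalg.det(np.stack([c[a], c[b], c[cc]])))
    vol /= 6.0
    if vol < 0:
        raise TopologyError(f"negative enclosed volume ({vol:.3f}); orientation broken")
    return vol


def beta_boundary(
    model: MolecularModel,
    beta: float,
    n_directions: int = DEFAULT_DIRECTIONS,
) -> BetaBoundary:
    """Assemble the full boundary description at one probe radius.

    The boundary atom set is the union of the sampled tangency test and the
    triangle vertices: an empty tangent probe of a triangle is a constructive
    witness that its vertices are exposed, even when the direction grid
    misses that tangency.
    """
    tris = beta_triangles(model, beta)
    atoms = boundary_atoms(model, beta, n_directions=n_directions)
    atoms |= {v for tri in tris for v in tri}
    return BetaBoundary(
        beta=beta,
        boundary_atom_ids=frozenset(atoms),
        triangles=tuple(tris),
        adjacency=boundary_adjacency(model, beta, atom_ids=atoms),
    )


def boundary_adjacency(
    model: MolecularModel,
    beta: float,
    atom_ids: Iterable[int] | None = None,
) -> nx.Graph:
    """Graph on the given atoms; edge (i, j) iff |c_i - c_j| <= r_i + r_j + 2 beta.

    Two atoms are connected when a probe of radius ``beta`` bridging them can
    touch both, which is the connectivity used to cluster pocket atoms into
    components.
    """
    ids = sorted(set(range(len(model)) if atom_ids is None else atom_ids))
    g = nx.Graph()
    g.add_nodes_from(ids)
    if len(ids) < 2:
        return g
    c, r = model.centers, model.radii
    sub = np.array(ids)
    tree = cKDTree(c[sub])
    cutoff = 2.0 * float(r[sub].max()) + 2.0 * beta
    for a, b in tree.query_pairs(cutoff, output_type="ndarray"):
        i, j = int(sub[a]), int(sub[b])
        if np.linalg.norm(c[i] - c[j]) <= r[i] + r[j] + 2.0 * beta:
            g.add_edge(i, j)
    return g


def export_mesh_obj(model: MolecularModel, beta: float, path) -> None:
    """Write the oriented boundary triangulation as a Wavefront OBJ mesh."""
    oriented = _oriented_triangles(model, beta)
    c = model.centers
    used = sorted({v for tri in oriented for v in tri})
    remap = {v: n + 1 for n, v in enumerate(used)}
    lines = [f"v {c[v][0]:.4f} {c[v][1]:.4f} {c[v][2]:.4f}" for v in used]
    lines += [f"f {remap[a]} {remap[b]} {remap[cc]}" for a, b, cc in oriented]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def export_profile_csv(profile: ExposureProfile, path) -> None:
    """Write the exposure profile as CSV (atom_id, beta_i)."""
    with open(path, "w") as fh:
        fh.write("atom_id,beta_i\n")
        for i, b in enumerate(profile.beta):
            fh.write(f"{i},{'inf' if np.isinf(b) else f'{b:.4f}'}\n")
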