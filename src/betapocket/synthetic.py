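"""Synthetic receptors, ligands and bound complexes with known ground truth.

Real benchmark data (protein-ligand complexes) cannot ship with the test
suite, so every stage of the pipeline is exercised on constructions whose
answer is known by design:

* lattice *slab receptors* with spherical cavities carved out of them, where
  the planted pocket lining is recorded at construction time;
* *random drug-like ligands* built as self-avoiding random walks at bonded
  distances, matching the 20-70 atom range of drug-like compounds;
* *bound complexes* made by placing a ligand inside a cavity without
  interpenetration.

All generators are deterministic under a fixed seed.  These fixtures emulate
the geometry of pockets (depressions with a constriction) but none of the
chemistry of real proteins: no residue identity, no realistic packing, no
hydrogen-bond geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import MolecularModel

__all__ = [
    "CavitySlabSpec",
    "SlabSpecError",
    "GenerationError",
    "PlacementError",
    "make_cavity_slab",
    "make_random_ligand",
    "make_bound_complex",
    "flask_slab_spec",
    "flask_throat_radius",
]


class SlabSpecError(ValueError):
    """The cavity specification destroys the slab or violates its invariants."""


class GenerationError(RuntimeError):
    """Random-walk ligand generation failed after bounded retries."""


class PlacementError(RuntimeError):
    """The ligand cannot be placed in the cavity without clashes."""


@dataclass(frozen=True)
class CavitySlabSpec:
    """A lattice slab with spherical cavities.

    The slab occupies a cubic lattice with ``nx x ny x nz`` atoms at
    ``spacing`` A; the top face lies in the plane z = 0 and layers extend
    downward (z = 0, -spacing, ...).  Cavity centers are absolute coordinates
    in that frame.  ``jitter`` is the s.d. (A) of the Gaussian positional
    noise applied to every coordinate, seeded.
    """

    nx: int = 9
    ny: int = 9
    nz: int = 4
    spacing: float = 3.0
    atom_radius: float = 1.7
    cavities: tuple[tuple[tuple[float, float, float], float], ...] = ()
    seed: int = 0
    jitter: float = 0.1

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise SlabSpecError("slab needs at least one atom per side")
        if self.spacing < 0.8 * 2.0 * self.atom_radius:
            raise SlabSpecError(
                "lattice spacing must be >= 0.8 x atom diameter "
                f"({self.spacing} < {0.8 * 2 * self.atom_radius})"
            )
        for _, r in self.cavities:
            if r <= self.atom_radius:
                raise SlabSpecError("cavity radius must exceed the atom radius")


def make_cavity_slab(spec: CavitySlabSpec) -> tuple[MolecularModel, set[int]]:
    """Build the slab receptor and the planted cavity-lining atom set.

    Atoms with centers inside any cavity ball are removed; the planted lining
    is the retained atoms whose centers lie within one lattice spacing of a
    cavity ball surface.  Deterministic given the spec.
    """
    s = spec.spacing
    xs = (np.arange(spec.nx) - (spec.nx - 1) / 2.0) * s
    ys = (np.arange(spec.ny) - (spec.ny - 1) / 2.0) * s
    zs = -np.arange(spec.nz) * s  # top face at z = 0
    grid = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)
    rng = np.random.default_rng(spec.seed)
    if spec.jitter > 0:
        grid = grid + rng.normal(0.0, spec.jitter, size=grid.shape)

    keep = np.ones(len(grid), dtype=bool)
    for center, radius in spec.cavities:
        d = np.linalg.norm(grid - np.asarray(center, dtype=float), axis=1)
        keep &= d >= radius
    if not np.any(keep):
        raise SlabSpecError("cavities removed every slab atom")
    centers = grid[keep]

    lining_mask = np.zeros(len(centers), dtype=bool)
    for center, radius in spec.cavities:
        d = np.linalg.norm(centers - np.asarray(center, dtype=float), axis=1)
        lining_mask |= np.abs(d - radius) <= s
    receptor = MolecularModel.from_arrays(
        centers,
        spec.atom_radius,
        "C",
        role="receptor",
        name=f"slab_seed{spec.seed}",
    )
    return receptor, set(np.nonzero(lining_mask)[0].tolist())


def flask_slab_spec(
    seed: int = 0,
    nx: int = 11,
    ny: int = 11,
    nz: int = 7,
    spacing: float = 3.0,
    atom_radius: float = 1.7,
    cavity_radius: float = 7.5,
    cavity_depth: float = 6.0,
) -> CavitySlabSpec:
    """A slab with one flask-shaped cavity opening through the top face.

    The cavity ball is submerged ``cavity_depth`` A below the face, giving a
    bowl with a constricted mouth.  The largest empty probe the cavity admits
    is its inscribed void radius (cavity_radius - atom_radius, the *throat*):
    water reaches the lining through the mouth, but any probe beyond the
    throat cannot touch it, which is what makes the planted pocket
    recognizable at a ligand-sized threshold (see
    :func:`flask_throat_radius`).
    """
    return CavitySlabSpec(
        nx=nx,
        ny=ny,
        nz=nz,
        spacing=spacing,
        atom_radius=atom_radius,
        cavities=(((0.0, 0.0, -cavity_depth), cavity_radius),),
        seed=seed,
    )


def flask_throat_radius(spec: CavitySlabSpec, cavity_id: int = 0) -> float:
    """Radius of the largest empty probe the cavity admits (A).

    For a spherical cavity carved from atoms of radius r_a this is the
    inscribed void radius ``cavity_radius - atom_radius``: lining atoms sit on
    the cavity sphere, so a probe centered at the cavity center clears them
    exactly up to that radius.  A recognition threshold just above the throat
    separates the lining (blocked) from flat boundary atoms (still exposed).
    """
    _, radius = spec.cavities[cavity_id]
    return radius - spec.atom_radius


def make_random_ligand(
    n_atoms: int,
    bond_length: float = 1.5,
    radii_range: tuple[float, float] = (1.2, 1.8),
    seed: int = 0,
    compactness: float = 0.6,
    max_retries: int = 200,
) -> MolecularModel:
    """Self-avoiding random-walk ligand with ``n_atoms`` atoms.

    Consecutive centers are ``bond_length`` apart; any pair closer than
    0.8 x bond_length is rejected.  Radii are sampled uniformly in
    ``radii_range``.  ``compactness`` biases each step toward the running
    centroid (0 = pure random walk), giving the globular shapes typical of
    drug-like compounds, which ordinarily span 20-70 atoms.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    min_sep = 0.8 * bond_length
    for _ in range(max_retries):
        pts = [np.zeros(3)]
        ok = True
        while len(pts) < n_atoms:
            centroid = np.mean(pts, axis=0)
            for _ in range(max_retries):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                pull = centroid - pts[-1]
                norm = np.linalg.norm(pull)
                if norm > 1e-9:
                    u = u + compactness * pull / norm
                    u /= np.linalg.norm(u)
                cand = pts[-1] + bond_length * u
                d = np.linalg.norm(np.array(pts[:-1]) - cand, axis=1) if len(pts) > 1 else np.array([np.inf])
                if np.all(d >= min_sep):
                    pts.append(cand)
                    break
            else:
                ok = False
                break
        if ok:
            centers = np.array(pts)
            radii = rng.uniform(*radii_range, size=n_atoms)
            return MolecularModel.from_arrays(
                centers, radii, "C", role="ligand", name=f"ligand_seed{seed}"
            )
    raise GenerationError(f"could not place {n_atoms} atoms after {max_retries} restarts")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_bound_complex(
    receptor_spec: CavitySlabSpec,
    ligand_spec: dict | None = None,
    cavity_id: int = 0,
    overlap_tol: float = 0.4,
    max_attempts: int = 200,
) -> tuple[MolecularModel, MolecularModel, set[int]]:
    """Place a random ligand inside a slab cavity without interpenetration.

    The ligand is centered at the cavity center and rotated / nudged (seeded)
    until no receptor-ligand atom pair interpenetrates beyond ``overlap_tol``
    A.  Returns (receptor, placed ligand, planted lining atom ids).
    """
    if cavity_id >= len(receptor_spec.cavities):
        raise ValueError(f"slab has no cavity {cavity_id}")
    ligand_spec = dict(ligand_spec or {})
    ligand_spec.setdefault("n_atoms", 30)
    ligand_spec.setdefault("compactness", 0.8)
    ligand_spec.setdefault("seed", receptor_spec.seed + 1000)
    receptor, lining = make_cavity_slab(receptor_spec)
    ligand = make_random_ligand(**ligand_spec)
    cav_center, cav_radius = receptor_spec.cavities[cavity_id]
    cav_center = np.asarray(cav_center, dtype=float)

    lc = ligand.centers - ligand.centers.mean(axis=0)
    lr = ligand.radii
    rc, rr = receptor.centers, receptor.radii
    tree = cKDTree(rc)
    rng = np.random.default_rng(receptor_spec.seed + 7 * (cavity_id + 1))

    for attempt in range(max_attempts):
        rot = _random_rotation(rng) if attempt else np.eye(3)
        nudge = rng.normal(0.0, 0.3, size=3) if attempt else np.zeros(3)
        placed = lc @ rot.T + cav_center + nudge
        clash = False
        for k, p in enumerate(placed):
            nbr = tree.query_ball_point(p, lr[k] + rr.max())
            if nbr:
                d = np.linalg.norm(rc[nbr] - p, axis=1)
                if np.any(d < rr[nbr] + lr[k] - overlap_tol):
                    clash = True
                    break
        if not clash:
            placed_ligand = MolecularModel.from_arrays(
                placed, lr, "C", role="ligand", name=ligand.name + "_bound"
            )
            return receptor, placed_ligand, lining
    raise PlacementError(
        f"ligand does not fit in cavity {cavity_id} after {max_attempts} attempts"
    )
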