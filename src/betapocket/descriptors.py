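"""The six ligand shape descriptors (L-descriptors).

Each descriptor is a single length (A) summarizing the ligand's shape, used
directly as the pocket-recognition threshold beta_theta:

* ``beta_mes``  - radius of the minimum enclosing sphere of the ligand balls,
* ``beta_pc1/2/3`` - edge lengths of the PCA-aligned bounding box (radii
  inclusive by default), sorted descending,
* ``beta_vdw``  - radius of the sphere whose volume equals the van der Waals
  (union-of-balls) volume,
* ``beta_beta`` - radius of the sphere whose volume equals the beta-shape
  volume at the water probe (1.4 A).

``beta_vdw`` depends only on the occupied volume, so it is invariant under
conformational changes that preserve the pairwise atom overlaps, while
``beta_mes`` and the PC descriptors track the spatial extent and move with
every torsion swing.  ``beta_beta`` is undefined (reported as None) when the
beta-shape boundary is not a closed surface, e.g. for one or two atoms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .beta_shape import TopologyError, beta_shape_volume
from .sphere_geometry import (
    Sphere,
    equal_volume_radius,
    minimum_enclosing_sphere,
    pca_box_extents,
    union_volume,
)
from .structure_io import MolecularModel

log = logging.getLogger(__name__)

__all__ = ["LDescriptorSet", "DESCRIPTOR_NAMES", "compute_descriptors", "conformation_delta"]

DESCRIPTOR_NAMES = ("beta_mes", "beta_pc1", "beta_pc2", "beta_pc3", "beta_vdw", "beta_beta")

WATER_PROBE = 1.4  # A


class ConformerMismatchError(ValueError):
    """Two conformers do not share the same atoms."""


@dataclass(frozen=True)
class LDescriptorSet:
    """The six shape descriptors (A) of one ligand conformer."""

    beta_mes: float
    beta_pc1: float
    beta_pc2: float
    beta_pc3: float
    beta_vdw: float
    beta_beta: float | None  # None when the beta-shape volume is undefined
    probe_radius: float = WATER_PROBE
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.beta_pc1 >= self.beta_pc2 >= self.beta_pc3 >= 0):
            raise ValueError("PC extents must be sorted descending and non-negative")
        # exact containment gives beta_vdw <= beta_mes; allow grid-estimator noise
        if self.beta_vdw > self.beta_mes * (1.0 + 0.02) + 1e-9:
            raise ValueError("beta_vdw cannot exceed beta_mes")
        if self.beta_beta is not None and self.beta_beta < 0:
            raise ValueError("beta_beta must be >= 0")

    def get(self, which: str) -> float | None:
        if which not in DESCRIPTOR_NAMES:
            raise KeyError(f"unknown descriptor {which!r}; choose from {DESCRIPTOR_NAMES}")
        return getattr(self, which)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}


def _spheres(model: MolecularModel) -> list[Sphere]:
    return [Sphere(a.center, a.radius) for a in model.atoms]


def compute_descriptors(
    ligand: MolecularModel,
    probe: float = WATER_PROBE,
    include_radii: bool = True,
    grid_resolution: float = 0.1,
) -> LDescriptorSet:
    """All six L-descriptors of a ligand conformer.

    ``grid_resolution`` controls the union-volume grid.  A beta-shape topology
    failure (no closed boundary at the probe radius) downgrades ``beta_beta``
    to None with a warning; the remaining descriptors are still returned.
    """
    if any(a.radius <= 0 for a in ligand.atoms):
        raise ValueError("ligand atoms need positive radii (run assign_radii first)")
    spheres = _spheres(ligand)
    mes = minimum_enclosing_sphere(spheres)
    box = pca_box_extents(spheres, include_radii=include_radii)
    vol, _ = union_volume(spheres, method="grid", resolution=grid_resolution)
    try:
        beta_beta = equal_volume_radius(beta_shape_volume(ligand, probe))
    except TopologyError as exc:
        log.warning("beta_beta undefined for %r: %s", ligand.name, exc)
        beta_beta = None
    return LDescriptorSet(
        beta_mes=mes.radius,
        beta_pc1=box.L1,
        beta_pc2=box.L2,
        beta_pc3=box.L3,
        beta_vdw=equal_volume_radius(vol),
        beta_beta=beta_beta,
        probe_radius=probe,
        name=ligand.name,
    )


def conformation_delta(
    bound: MolecularModel,
    optimized: MolecularModel,
    which: str,
    probe: float = WATER_PROBE,
) -> float:
    """Descriptor difference (bound conformer) - (energy-minimized conformer).

    Both conformers must have the same atom count and element sequence.
    """
    if which not in DESCRIPTOR_NAMES:
        raise KeyError(f"unknown descriptor {which!r}")
    if len(bound) != len(optimized) or bound.elements != optimized.elements:
        raise ConformerMismatchError(
            "conformers differ in atom count or element sequence"
        )
    a = compute_descriptors(bound, probe=probe).get(which)
    b = compute_descriptors(optimized, probe=probe).get(which)
    if a is None or b is None:
        raise ValueError(f"descriptor {which} undefined for one of the conformers")
    return float(a - b)
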