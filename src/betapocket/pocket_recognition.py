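"""Ligand-aware pocket recognition from exposure radii.

A pocket is a depressed region of the receptor boundary: atoms that a water
probe can touch but a larger, ligand-sized probe cannot.  Concretely, with B
the set of water-accessible boundary atoms (beta_i >= water probe), the raw
pocket atoms at threshold beta_theta are {i in B : beta_i < beta_theta}.  The
threshold is taken directly from a ligand shape descriptor (beta_vdw by
default), which makes the recognized pockets specific to the ligand being
screened.  Raw atoms are clustered into topologically connected components of
the boundary adjacency at the water probe, ranked by size, and the top
candidates are returned.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from . import beta_shape
from .beta_shape import _ExposureEngine, boundary_adjacency
from .descriptors import DESCRIPTOR_NAMES, compute_descriptors
from .structure_io import MolecularModel

log = logging.getLogger(__name__)

__all__ = ["Pocket", "recognize_pockets", "threshold_from_ligand", "best_matched_component"]

WATER_PROBE = 1.4  # A


@dataclass(frozen=True)
class Pocket:
    """One recognized pocket candidate."""

    atom_ids: frozenset[int]
    rank: int  # 1-based, by descending atom count
    beta_theta: float

    def __post_init__(self) -> None:
        if not self.atom_ids:
            raise ValueError("pocket cannot be empty")
        if self.rank < 1:
            raise ValueError("rank is 1-based")

    @property
    def size(self) -> int:
        return len(self.atom_ids)

    def as_dict(self) -> dict:
        return {
            "rank": self.rank,
            "size": self.size,
            "beta_theta": self.beta_theta,
            "atom_ids": sorted(self.atom_ids),
        }


def recognize_pockets(
    receptor: MolecularModel,
    beta_theta: float,
    water_probe: float = WATER_PROBE,
    top_k: int = 5,
    n_directions: int = beta_shape.DEFAULT_DIRECTIONS,
    exposure_tol: float = beta_shape.DEFAULT_TOL,
) -> list[Pocket]:
    """Recognize up to ``top_k`` pocket candidates at threshold ``beta_theta``.

    Candidates are connected components of the raw pocket atom set
    {i in B : beta_i < beta_theta} under the boundary adjacency at the water
    probe, sorted by atom count (ties: larger summed exposure deficit
    sum(beta_theta - beta_i), then lowest minimum atom id).  An empty raw set
    yields an empty list.
    """
    if beta_theta <= water_probe:
        raise ValueError(
            f"beta_theta ({beta_theta}) must exceed the water probe ({water_probe}); "
            "no atom can be water-accessible yet blocked for a smaller probe"
        )
    engine = _ExposureEngine(receptor, n_directions)
    in_b = engine.exposed_mask(water_probe)
    b_ids = np.nonzero(in_b)[0]
    # raw pocket atoms: water-accessible but blocked at beta_theta; by
    # monotonicity of the sampled test this equals {i in B : beta_i < beta_theta}
    raw = [int(i) for i in b_ids if not engine.is_exposed(int(i), beta_theta)]
    if not raw:
        return []
    # exposure radii only needed for the tie-break deficit, so only on raw atoms
    deficits = {
        i: beta_theta - min(engine.exposure_radius(i, beta_theta, exposure_tol), beta_theta)
        for i in raw
    }
    graph = boundary_adjacency(receptor, water_probe, atom_ids=raw)
    components = [frozenset(comp) for comp in nx.connected_components(graph)]
    components.sort(
        key=lambda comp: (
            -len(comp),
            -sum(deficits[i] for i in comp),
            min(comp),
        )
    )
    return [
        Pocket(atom_ids=comp, rank=r + 1, beta_theta=beta_theta)
        for r, comp in enumerate(components[:top_k])
    ]


def threshold_from_ligand(
    ligand: MolecularModel,
    which: str = "beta_vdw",
    probe: float = WATER_PROBE,
) -> float:
    """beta_theta from a ligand: the named descriptor's value, used as-is."""
    if which not in DESCRIPTOR_NAMES:
        raise KeyError(f"unknown descriptor {which!r}; choose from {DESCRIPTOR_NAMES}")
    value = compute_descriptors(ligand, probe=probe).get(which)
    if value is None:
        raise ValueError(
            f"descriptor {which!r} is undefined for this ligand; "
            f"fall back to one of {[d for d in DESCRIPTOR_NAMES if d != which]}"
        )
    return float(value)


def best_matched_component(
    candidates: list[Pocket], reference: set[int] | frozenset[int]
) -> Pocket:
    """Candidate maximizing overlap with the reference atom set.

    Ties broken by larger Jaccard index, then lower rank.  If no candidate
    intersects the reference at all, the rank-1 candidate is returned with a
    warning.
    """
    if not candidates:
        raise ValueError("no candidates")
    reference = set(reference)

    def score(p: Pocket) -> tuple:
        inter = len(p.atom_ids & reference)
        union = len(p.atom_ids | reference)
        jaccard = inter / union if union else 0.0
        return (inter, jaccard, -p.rank)

    best = max(candidates, key=score)
    if not best.atom_ids & reference:
        log.warning(
            "no candidate intersects the reference pocket; returning rank-1"
        )
        return min(candidates, key=lambda p: p.rank)
    return best


def pockets_to_json(candidates: list[Pocket], receptor: MolecularModel) -> str:
    """Serialize candidates with residue annotations."""
    out = []
    for p in candidates:
        residues = sorted(
            {
                f"{receptor.atoms[i].meta.get('chain', '')}/"
                f"{receptor.atoms[i].meta.get('resname', '?')}"
                f"{receptor.atoms[i].meta.get('resseq', '?')}"
                for i in p.atom_ids
            }
        )
        entry = p.as_dict()
        entry["residues"] = residues
        out.append(entry)
    return json.dumps(out, indent=2)
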