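"""Reading, writing and preparing molecular structures.

Receptors and ligands are plain lists of spheres with element / residue
metadata.  PDB files are handled through gemmi, mol2 files through RDKit
(without sanitization, so atoms are taken exactly as recorded).  Radii are a
separate, explicit assignment step so the van der Waals table in use is always
documented and overridable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "MolecularModel",
    "RadiiTable",
    "BONDI_RADII",
    "read_structure",
    "write_structure",
    "assign_radii",
    "split_complex",
]

#: Bondi-style van der Waals radii (A).  The default fallback for elements not
#: listed is RadiiTable.default.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "NA": 2.27,
    "K": 2.75,
    "FE": 1.63,
    "MN": 1.61,
    "CU": 1.40,
}

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}


class EmptyModelError(ValueError):
    """A structure contained no atoms after filtering."""


class SelectionError(ValueError):
    """A ligand selector matched no atoms."""


@dataclass(frozen=True)
class Atom:
    """One spherical atom: index, element, center (A) and vdW radius (A).

    ``radius == 0.0`` is the sentinel for "not yet assigned" (see
    :func:`assign_radii`).  ``meta`` carries residue name/number, chain, atom
    name, occupancy and altloc when the source format provides them.
    """

    id: int
    element: str
    center: np.ndarray
    radius: float = 0.0
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError(f"atom center must be a finite 3-vector: {self.center!r}")
        if self.radius < 0:
            raise ValueError(f"atom radius must be >= 0: {self.radius}")
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "element", str(self.element).upper())


@dataclass(frozen=True)
class MolecularModel:
    """An ordered, contiguously indexed set of atoms with a role tag."""

    atoms: tuple[Atom, ...]
    role: Literal["receptor", "ligand", "complex"] = "complex"
    name: str = ""

    def __post_init__(self) -> None:
        atoms = tuple(self.atoms)
        if not atoms:
            raise EmptyModelError(f"model {self.name!r} has no atoms")
        if [a.id for a in atoms] != list(range(len(atoms))):
            raise ValueError("atom ids must be unique and contiguous from 0")
        object.__setattr__(self, "atoms", atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def centers(self) -> np.ndarray:
        return np.array([a.center for a in self.atoms])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @classmethod
    def from_arrays(
        cls,
        centers: np.ndarray,
        radii: np.ndarray | float,
        elements: Sequence[str] | str = "C",
        role: str = "complex",
        name: str = "",
        metas: Sequence[Mapping[str, object]] | None = None,
    ) -> "MolecularModel":
        centers = np.asarray(centers, dtype=float)
        n = len(centers)
        radii = np.broadcast_to(np.asarray(radii, dtype=float), (n,))
        if isinstance(elements, str):
            elements = [elements] * n
        metas = metas or [{}] * n
        atoms = tuple(
            Atom(i, elements[i], centers[i], float(radii[i]), dict(metas[i]))
            for i in range(n)
        )
        return cls(atoms, role, name)  # type: ignore[arg-type]

    def reindexed(self, role: str | None = None, name: str | None = None) -> "MolecularModel":
        atoms = tuple(
            replace(a, id=i) for i, a in enumerate(self.atoms)
        )
        return MolecularModel(
            atoms,
            role if role is not None else self.role,  # type: ignore[arg-type]
            name if name is not None else self.name,
        )


@dataclass(frozen=True)
class RadiiTable:
    """Element -> vdW radius (A) with a default for unknown elements."""

    radii: Mapping[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default: float = 1.50

    def __post_init__(self) -> None:
        radii = {str(k).upper(): float(v) for k, v in self.radii.items()}
        if self.default <= 0 or any(v <= 0 for v in radii.values()):
            raise ValueError("all radii (and the default) must be positive")
        object.__setattr__(self, "radii", radii)

    def lookup(self, element: str) -> tuple[float, bool]:
        """Radius for an element plus a flag telling whether the default was used."""
        el = element.upper()
        if el in self.radii:
            return self.radii[el], False
        return self.default, True

    @classmethod
    def from_file(cls, path: str | Path) -> "RadiiTable":
        """Load a JSON table: either ``{"C": 1.7, ...}`` or
        ``{"radii": {...}, "default": 1.5}``."""
        data = json.loads(Path(path).read_text())
        if "radii" in data:
            return cls(radii=data["radii"], default=float(data.get("default", 1.50)))
        return cls(radii=data)


# ---------------------------------------------------------------------------
# reading


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mol2", "auto"] = "auto",
    drop_waters: bool = True,
    drop_hydrogens: bool = False,
) -> MolecularModel:
    """Read a PDB or mol2 file into a :class:`MolecularModel`.

    Radii are left unassigned (0.0 sentinel); call :func:`assign_radii`.
    PDB altlocs keep the highest-occupancy record (ties: first in file);
    water residues are dropped unless ``drop_waters`` is False.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = "mol2" if path.suffix.lower() == ".mol2" else "pdb"
    if format == "pdb":
        atoms = _read_pdb(path)
    elif format == "mol2":
        atoms = _read_mol2(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    kept = []
    for el, center, meta in atoms:
        if drop_waters and str(meta.get("resname", "")).upper() in WATER_RESIDUES:
            continue
        if drop_hydrogens and el.upper() in ("H", "D"):
            continue
        kept.append((el, center, meta))
    if not kept:
        raise EmptyModelError(f"{path}: no atoms left after filtering")
    return MolecularModel(
        tuple(Atom(i, el, c, 0.0, meta) for i, (el, c, meta) in enumerate(kept)),
        "complex",
        path.stem,
    )


def _read_pdb(path: Path) -> list[tuple[str, np.ndarray, dict]]:
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    records: list[tuple[str, np.ndarray, dict]] = []
    # (chain, seqid, resname, atom name) -> index into records, for altloc pick
    best: dict[tuple, tuple[int, float]] = {}
    if len(st) == 0:
        raise EmptyModelError(f"{path}: structure has no models")
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                el = atom.element.name if atom.element else atom.name[:1]
                meta = {
                    "resname": res.name,
                    "resseq": res.seqid.num,
                    "chain": chain.name,
                    "atom_name": atom.name,
                    "occupancy": float(atom.occ),
                    "altloc": atom.altloc or "",
                    "het": res.het_flag == "H",
                }
                key = (chain.name, res.seqid.num, res.name, atom.name)
                entry = (el, np.array([atom.pos.x, atom.pos.y, atom.pos.z]), meta)
                if key in best:
                    idx, occ = best[key]
                    if float(atom.occ) > occ:  # strict: ties keep first in file
                        records[idx] = entry
                        best[key] = (idx, float(atom.occ))
                else:
                    best[key] = (len(records), float(atom.occ))
                    records.append(entry)
    return records


def _read_mol2(path: Path) -> list[tuple[str, np.ndarray, dict]]:
    from rdkit import Chem

    mol = Chem.MolFromMol2File(str(path), sanitize=False, removeHs=False)
    if mol is None:
        raise IOError(f"RDKit could not parse mol2 file {path}")
    conf = mol.GetConformer()
    records = []
    for atom in mol.GetAtoms():
        pos = conf.GetAtomPosition(atom.GetIdx())
        info = atom.GetPDBResidueInfo()
        meta = {
            "resname": info.GetResidueName().strip() if info else "LIG",
            "resseq": info.GetResidueNumber() if info else 1,
            "chain": "",
            "atom_name": info.GetName().strip() if info else atom.GetSymbol(),
            "occupancy": 1.0,
            "altloc": "",
            "het": True,
        }
        records.append((atom.GetSymbol(), np.array([pos.x, pos.y, pos.z]), meta))
    return records


# ---------------------------------------------------------------------------
# writing


def write_structure(model: MolecularModel, path: str | Path) -> None:
    """Write a model as a PDB file (coordinates rounded to 10^-3 A)."""
    import gemmi

    st = gemmi.Structure()
    st.name = model.name or "model"
    gm = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    for atom in model.atoms:
        meta = atom.meta
        chain_name = str(meta.get("chain", "") or "A")
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        chain = chains[chain_name]
        resname = str(meta.get("resname", "UNK"))
        resseq = int(meta.get("resseq", atom.id + 1))
        if (
            not chain
            or chain[-1].name != resname
            or chain[-1].seqid.num != resseq
        ):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resseq, " ")
            res.het_flag = "H" if meta.get("het") else "A"
            chain.add_residue(res)
        res = chain[-1]
        ga = gemmi.Atom()
        ga.name = str(meta.get("atom_name", atom.element))
        ga.element = gemmi.Element(atom.element.capitalize())
        ga.pos = gemmi.Position(*[round(float(x), 3) for x in atom.center])
        ga.occ = float(meta.get("occupancy", 1.0))
        res.add_atom(ga)
    for chain in chains.values():
        gm.add_chain(chain)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# preparation


def assign_radii(model: MolecularModel, table: RadiiTable | None = None) -> MolecularModel:
    """Return a copy of the model with vdW radii set from the table.

    Unknown elements receive ``table.default`` and are logged once per element.
    """
    table = table or RadiiTable()
    warned: set[str] = set()
    atoms = []
    for atom in model.atoms:
        r, fallback = table.lookup(atom.element)
        if fallback and atom.element not in warned:
            warned.add(atom.element)
            log.warning(
                "element %r not in radii table; using default %.2f A",
                atom.element,
                table.default,
            )
        atoms.append(replace(atom, radius=r))
    return MolecularModel(tuple(atoms), model.role, model.name)


def split_complex(
    model: MolecularModel,
    ligand_selector: str,
) -> tuple[MolecularModel, MolecularModel]:
    """Partition a complex into (receptor, ligand) by a selector query.

    The selector is ``"RESNAME"`` or ``"RESNAME/CHAIN"`` or
    ``"RESNAME/CHAIN/RESSEQ"`` (empty fields match anything).
    Receptor and ligand are re-indexed from 0; together they partition the
    input atom set.
    """
    parts = (ligand_selector.split("/") + ["", ""])[:3]
    want_res, want_chain, want_seq = [p.strip() for p in parts]

    def matches(atom: Atom) -> bool:
        meta = atom.meta
        if want_res and str(meta.get("resname", "")).upper() != want_res.upper():
            return False
        if want_chain and str(meta.get("chain", "")) != want_chain:
            return False
        if want_seq and str(meta.get("resseq", "")) != want_seq:
            return False
        return True

    lig = [a for a in model.atoms if matches(a)]
    rec = [a for a in model.atoms if not matches(a)]
    if not lig:
        raise SelectionError(f"selector {ligand_selector!r} matched no atoms")
    if not rec:
        raise SelectionError(f"selector {ligand_selector!r} matched every atom")
    receptor = MolecularModel(
        tuple(replace(a, id=i) for i, a in enumerate(rec)),
        "receptor",
        f"{model.name}:receptor",
    )
    ligand = MolecularModel(
        tuple(replace(a, id=i) for i, a in enumerate(lig)),
        "ligand",
        f"{model.name}:ligand",
    )
    return receptor, ligand
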