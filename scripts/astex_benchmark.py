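"""Benchmark run over the Astex Diverse Set (85 protein-ligand complexes).

The dataset is an external download and is not redistributed here.  Expected
layout, one directory per complex:

    data/astex/<pdb_id>/protein.pdb
    data/astex/<pdb_id>/ligand.mol2

For every complex the script computes the six L-descriptors of the native
ligand, extracts the optimal pocket from the bound complex, recognizes
pockets on the apo receptor at the beta_vdw threshold, and scores the best
matched component (plus a size-matched random baseline) with the full metric
suite.  Outputs: a per-ligand descriptor table, the descriptor averages, and
a per-complex metric table for manual comparison.

Usage:
    python scripts/astex_benchmark.py --data data/astex --out results/astex
"""

from __future__ import annotations

import argparse
import csv
import json
from pathlib import Path

import numpy as np

from betapocket import (
    RadiiTable,
    all_metrics,
    assign_radii,
    compute_descriptors,
    confusion_from_sets,
    optimal_pocket_atoms,
    random_baseline,
    read_structure,
    recognize_pockets,
    sample_iif,
    threshold_from_ligand,
)
from betapocket.beta_shape import _ExposureEngine
from betapocket.descriptors import DESCRIPTOR_NAMES
from betapocket.evaluation import _METRIC_FIELDS
from betapocket.pocket_recognition import best_matched_component


def iter_complexes(data_dir: Path):
    for entry in sorted(data_dir.iterdir()):
        protein = entry / "protein.pdb"
        ligand = entry / "ligand.mol2"
        if protein.exists() and ligand.exists():
            yield entry.name, protein, ligand


def descriptor_means(data_dir: Path, table: RadiiTable | None = None) -> dict[str, float]:
    """Average L-descriptors over the native ligands of the set."""
    table = table or RadiiTable()
    values: dict[str, list[float]] = {name: [] for name in DESCRIPTOR_NAMES}
    for name, _, ligand_path in iter_complexes(data_dir):
        ligand = assign_radii(read_structure(ligand_path), table)
        d = compute_descriptors(ligand)
        for key, v in d.as_dict().items():
            if v is not None:
                values[key].append(v)
    return {k: float(np.mean(v)) for k, v in values.items() if v}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, required=True)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--descriptor", default="beta_vdw", choices=DESCRIPTOR_NAMES)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    table = RadiiTable()

    desc_rows = []
    metric_rows = []
    for name, protein_path, ligand_path in iter_complexes(args.data):
        receptor = assign_radii(read_structure(protein_path), table)
        ligand = assign_radii(read_structure(ligand_path), table)
        d = compute_descriptors(ligand)
        desc_rows.append({"complex": name, "n_atoms": len(ligand), **{
            k: ("" if v is None else f"{v:.4f}") for k, v in d.as_dict().items()
        }})
        try:
            optimal = optimal_pocket_atoms(receptor, sample_iif(receptor, ligand)).atom_ids
            bt = threshold_from_ligand(ligand, which=args.descriptor)
            engine = _ExposureEngine(receptor, 512)
            boundary = set(np.nonzero(engine.exposed_mask(1.4))[0].tolist())
            candidates = recognize_pockets(receptor, bt)
            best = (
                set(best_matched_component(candidates, optimal).atom_ids)
                if candidates else set()
            )
            rand = random_baseline(boundary, len(best), seed=args.seed)
            for label, atoms in (("best_component", best), ("random", rand)):
                c = confusion_from_sets(optimal & boundary, atoms & boundary, boundary)
                m = all_metrics(c)
                metric_rows.append({"complex": name, "set": label, **{
                    k: f"{v:.4f}" for k, v in m.as_dict().items() if v is not None
                }})
        except Exception as exc:  # record and continue the batch
            metric_rows.append({"complex": name, "set": f"error: {exc}"})

    with (args.out / "descriptors.csv").open("w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["complex", "n_atoms", *DESCRIPTOR_NAMES])
        w.writeheader()
        w.writerows(desc_rows)
    with (args.out / "metrics.csv").open("w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["complex", "set", *_METRIC_FIELDS], extrasaction="ignore"
        )
        w.writeheader()
        w.writerows(metric_rows)
    (args.out / "descriptor_means.json").write_text(
        json.dumps(descriptor_means(args.data, table), indent=2)
    )
    print(f"wrote {len(desc_rows)} descriptor rows and {len(metric_rows)} metric rows")


if __name__ == "__main__":
    main()
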