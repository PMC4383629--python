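# Methods

## The model

A molecule is a union of van der Waals balls: atoms `σ_i` with centers `c_i`
(Å) and radii `r_i` (Å).  A spherical probe of radius `β` *touches* an atom
when some sphere of radius `β`, externally tangent to that atom, overlaps no
other atom of the molecule.  Because a smaller probe tangent along the same
direction is contained in the larger one, touchability is monotone in `β`:
each atom carries an **exposure interval** `[0, β_i]`, where `β_i` is the
largest probe that can still touch it (`β_i = ∞` for atoms in convex
position).  The atoms with `β_i ≥ β` are the boundary atoms of the
**beta-shape** at probe radius `β` — the polyhedral straightening of the
rolling-probe (Connolly) surface onto the atom centers.

A **pocket** is a depression: atoms that water (probe 1.4 Å) can reach but a
ligand-sized probe cannot.  Given a threshold `β_θ`, the raw pocket atoms are

```
{ i ∈ B : β_i < β_θ },    B = { i : β_i ≥ 1.4 Å }
```

clustered into connected components of the boundary adjacency
(`|c_i − c_j| ≤ r_i + r_j + 2β` at the water probe) and ranked by atom count.
The threshold is taken from one of six **ligand shape descriptors** (Å):

| descriptor | definition |
|---|---|
| `β_mes`   | radius of the minimum enclosing sphere of the ligand balls |
| `β_PC1–3` | edge lengths of the PCA-aligned bounding box (radii-inclusive), sorted |
| `β_vdW`   | radius of the sphere whose volume equals the union-of-balls volume |
| `β_beta`  | radius of the sphere whose volume equals the beta-shape volume at 1.4 Å |

`β_vdW` depends only on occupied volume, so it is stable under conformational
change that preserves atom overlaps; the extent-based descriptors are not.
That stability, and its intermediate size, is why `β_vdW` is the default
threshold choice.

The reference ("optimal") pocket of a bound complex is derived from the
**interaction interface (IIF)**: the locus of points equidistant from the
receptor and ligand vdW surfaces, trimmed to where the receptor surface is
within one water radius (`d(q, receptor) ≤ 1.4 Å`, and `≥ 0`, i.e. outside
both molecules).  The optimal pocket Π is the set of receptor atoms that
realize the nearest-surface distance for at least one retained interface
point.  Recognized pockets are scored against Π over the boundary set B with
a full confusion-matrix suite: the primary rates (TPR/FPR/P/SP/AC), the
normalized mutual information `NMI = (H(x) − H(x|y))/H(x)` and the
G-statistic likelihood ratio `LR = 2 Σ O ln(O/E)` (both insensitive to the
strong pocket/non-pocket class imbalance), and eleven secondary metrics
(BA, G2, ED, YI, F, G1, PSI, NPV, γ, τ_b, τ_c).

## Numerical realization

**Exposure by sampled tangency.**  Instead of the exact Voronoi diagram of
balls (the structure behind true beta-shapes), exposure is decided by testing
candidate probe centers `c_i + (r_i + β)·u` over a deterministic Fibonacci
sphere of unit directions (default 512) and `β_i` is found by bisection
(default tolerance 0.01 Å, cap = model diameter).  With a fixed direction
set the test is exactly monotone in `β`, so thresholding and bisection are
consistent.  Direction sampling can only *miss* free probes, never invent
them: `β_i` estimates are one-sided (under-estimates).  Near-grazing exposure
boundaries — an almost-convex atom whose largest free probe survives only in
a thin angular sliver — are resolved only as finely as the direction grid;
the tests therefore check strict oracle agreement (against a 10⁴-direction
brute force) on fixtures with interior-maximum throats and the one-sided
bound everywhere else.  At the water/ligand scales that drive pocket
recognition (β ≤ ~8 Å) 256–512 directions are ample.

**Single-interval model.**  True beta-shapes can expose an atom over several
disjoint `β` intervals; this implementation keeps one interval per atom.
Probes are required to be empty but not to be reachable from infinity, so a
sealed interior void still counts as exposure — for a cavity this means the
*effective throat* is the inscribed void radius, not the mouth.

**Beta-shape boundary and volume.**  Boundary triangles are atom triples
admitting an empty tangent probe (solved in closed form from the three-sphere
tangency system; candidate triples pruned by
`|c_i − c_j| ≤ r_i + r_j + 2β` through a KD-tree).  Each empty probe
orients its triangle outward; the volume is the divergence-theorem sum over
the oriented triangulation, accepted only if every undirected edge lies in
exactly two opposite-oriented triangles.  Elongated, sparsely overlapping
molecules (chain ligands) often have no closed 3-tangency surface at the
water probe; `β_beta` is then reported as missing rather than 0.

**Other primitives.**  The minimum enclosing sphere of balls solves the
convex program `min R s.t. |c − c_i| + r_i ≤ R` with SLSQP (verified against
a multi-resolution grid search).  Union volumes use grid counting (default
spacing 0.2 Å for screening; 0.05–0.1 Å where closed-form accuracy is
asserted — cell-center counting overestimates a unit ball by ~5% at 0.2 Å,
~0.1% at 0.05 Å) with a Monte-Carlo cross-check.  The IIF is sampled on a
grid anchored to absolute multiples of its spacing (default 0.5 Å, band
half-width ε = 0.25 Å), which makes sampling deterministic and lets symmetric
configurations hit the mid-plane exactly; Π is consequently exactly invariant
under joint grid-aligned motions and only approximately under arbitrary ones.
Entropies use base-2 logs, the likelihood ratio natural logs (χ²-comparable);
`0·log 0 = 0`; degenerate denominators yield 0 and are flagged.  Ties in
pocket ranking break by larger summed exposure deficit `Σ(β_θ − β_i)`, then
lowest atom id; ties in nearest-atom assignment within 10⁻⁶ Å include all
tied atoms.

## Synthetic fixtures

Real benchmark complexes cannot ship with the tests, so ground truth is
planted:

* **Cavity slabs** — cubic lattices (default 11×11×7 atoms, spacing 3 Å,
  atom radius 1.7 Å, Gaussian jitter 0.1 Å) with spherical cavities carved
  out; the planted lining is the retained atoms within one lattice spacing of
  a cavity surface.  The recovery suite uses a *flask*: a cavity ball of
  radius 7.5 Å submerged 6 Å below the top face, whose inscribed void radius
  (7.5 − 1.7 = 5.8 Å) is the effective throat; recognition uses
  `β_θ = throat + 0.7 Å`.  Mean top-1 Jaccard against the planted lining is
  ≈ 0.75 over 20 seeds.  The ceiling is ≈ 0.8, not 1.0: the lining shell
  necessarily includes a ring of flat-face rim atoms (convex-exposed,
  `β_i = ∞`, never recognizable) and a few buried outer-shell atoms (not
  water-accessible).  This is a property of the lining bookkeeping, not of
  the recognizer.
* **Random ligands** — self-avoiding random walks at bonded distances
  (1.5 Å steps, pairwise separation ≥ 0.8×bond, radii uniform in
  1.2–1.8 Å, 20–70 atoms as for drug-like compounds), with a tunable bias of
  each step toward the running centroid (default 0.6) to produce globular
  rather than fully extended shapes.
* **Bound complexes** — a compact ligand (default 30 atoms, bias 0.8) rotated
  and nudged into a snugger flask (cavity 6 Å, submerged 4.5 Å) until no
  atom pair interpenetrates beyond 0.4 Å.  The interface-derived Π then
  overlaps the planted lining with mean Jaccard ≈ 0.58 (each seed > 0.45):
  the ligand cannot reach the rim/outer parts of the lining shell, which
  bounds this number for the same bookkeeping reasons as above.

What these fixtures do **not** emulate: real packing density and secondary
structure, residue chemistry, hydrogens vs heavy-atom-only structures,
multiple binding sites of realistic shape, or crystallographic noise.
Passing tests demonstrate the geometric and statistical machinery is correct
on constructions with known answers; they do not certify recognition rates on
real proteins.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| water probe | 1.4 Å | boundary definition, `β_beta`, IIF trim |
| exposure directions | 512 (256 for slab-scale tests) | angular resolution of the tangency test |
| exposure tolerance | 0.01 Å | bisection width for `β_i` |
| empty-tangency tolerance | 10⁻⁶ Å | clearance slack; degenerate quadruple tangencies count as empty |
| union-volume grid | 0.2 Å (0.05–0.1 Å in tests) | volume accuracy vs cost |
| IIF spacing / ε / trim | 0.5 / 0.25 / 1.4 Å | interface sampling density, band width, water cutter |
| top_k | 5 | pocket candidates returned |
| descriptor choice | `β_vdW` | recognition threshold source |
| vdW radii | Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 …), default 1.50 | overridable via JSON |

## Known limitations

* Single-interval exposure; interior voids count as exposure (no
  reachability test).
* `β_beta` is frequently undefined for sparse chain molecules (no closed
  3-tangency surface); callers must handle the missing value.
* PCA box extents are arbitrary for PCA-isotropic atom sets (degenerate
  covariance eigenvalues): extents are then not stable under rotation.
* The published average descriptor values for the external benchmark
  depend on the (unpublished) vdW radii set and hydrogen policy of the
  original implementation, and their printed PC averages are mutually
  consistent with mes only if interpreted as half-edge lengths; this package
  uses full radii-inclusive edges.  Expect systematic offsets when
  reproducing those averages.
* The exact Voronoi/quasi-triangulation construction, multi-interval beta
  spans, docking, and binormal-smoothed ROC fitting are out of scope; ROC/PR
  areas are empirical trapezoids over operating points.
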