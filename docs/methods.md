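# Methods

This note documents the models, conventions and design choices behind
`vsfunnel`, what the synthetic generators do and do not emulate, and the
numerical details a user would need to reproduce or modify the behaviour.

## Shape model

Molecular shape is a sum of atom-centred spherical Gaussians over heavy
atoms only, `ρ(x) = Σᵢ p·exp(−αᵢ‖x − xᵢ‖²)` with a fixed amplitude
`p = 2.7`.  The width `αᵢ = π(3p/(4πrᵢ³))^{2/3}` makes the isolated-atom
integral equal the hard-sphere volume for the element's van der Waals radius
(C 1.70, N 1.55, O 1.52, F 1.47, S/P 1.80, Cl 1.75, Br 1.85, I 1.98 Å;
unknown elements fall back to 1.70 Å).  Hydrogens are implicit and carry no
volume.

The overlap `V_AB` is the first-order pairwise product integral only — no
higher-order intersection corrections.  This is the standard approximation
for Gaussian shape comparison; it is accurate to a few percent, and the
Shape-Tanimoto ratio `V_AB/(V_AA + V_BB − V_AB)` is provably in [0, 1] for
it (Cauchy–Schwarz on the density inner product), which the test suite
exercises as a property.  Only shape is scored; there is no chemistry
("color") term, so the ranking is purely geometric.

Overlay optimization centres the candidate on the query centroid and runs a
local maximization of `V_AB` over rotation (rotation-vector parameters) and
translation from four starting orientations: the proper principal-axes
alignments (covariance eigenvectors, the four sign combinations with
determinant +1).  The local search is L-BFGS with numerical gradients,
capped at 200 iterations; the best converged placement is returned and is
never worse than its starting orientation.  Collinear molecules pose no
problem because the covariance eigendecomposition always yields an
orthonormal frame.  Ranking ties are broken lexicographically by compound id
for reproducibility.  The query conformer is used exactly as read — no
re-minimization — mirroring the use of a crystallographic reference
conformation.

## Property conventions

- HBD = number of N/O atoms bearing ≥ 1 hydrogen; HBA = count of N plus O
  atoms (the classic rule-of-five conventions).
- Rotatable bond = non-ring single bond between heavy atoms of degree ≥ 2,
  excluding amide C–N; rigid bonds are the remaining heavy-atom bonds.
- Ring systems merge fused rings sharing at least one atom.
- TPSA is the Ertl fragment-contribution sum and clogP the Crippen
  atom-contribution estimate (both via RDKit).  Vendor-computed clogP/TPSA
  values in input SD tags are treated as annotations and are *not* expected
  to match these estimates; the packaged property-table fixture carries
  vendor values and is used only for formula/mass checks and worked
  examples.
- Molecular weights use IUPAC conventional atomic weights; the packaged
  table's printed masses mix rounding conventions, so the agreement
  tolerance is ±0.02 g/mol.

## Drug-likeness rule set

The exact thresholds of the commercial "blockbuster" filter are proprietary;
the shipped defaults are this package's own, chosen to be of the same kind
(MW 130–781, clogP ≤ 6.85, HBD ≤ 6, HBA ≤ 10, rotatable ≤ 14, ring systems
≤ 6, chiral centers ≤ 10, TPSA ≤ 205 Å²) and fully overridable in config.
The rule-of-five secondary filter allows up to three violations by default.
Structural alerts are named SMARTS patterns; the aggregator check is an
exact-graph (canonical SMILES) match against a small illustrative list.
Solubility is accepted only as an input annotation — no prediction is made.
The artifact's contract is the rule engine, not any vendor's numbers.

## Interaction detection

Thresholds follow the published conventions of geometric interaction
profilers (all configurable via `GeometryParams`):

| type | rule |
|------|------|
| hydrophobic (HD) | apolar carbon pair ≤ 4.0 Å (apolar: C bonded only to C/H/S) |
| hydrogen bond (HB) | donor–acceptor heavy distance ≤ 3.5 Å; with explicit polar H, ≤ 3.6 Å and D–H···A ≥ 120° |
| salt bridge (SB) | opposite charged-group centroids ≤ 5.5 Å |
| π-stacking (PIPI) | ring centroids ≤ 5.5 Å, interplanar ≤ 30° (parallel) or 60–90° (T-shaped), in-plane offset ≤ 2.0 Å |
| π-cation (PICAT) | cation to ring centroid ≤ 6.0 Å (either partner may supply the ring) |

Protein protonation assumes pH 7.4: K/R positive, D/E negative, H neutral.
Protein hydrogens are implicit, so protein-donor H-bonds use the
distance-only rule.  One record is emitted per (residue, type) with the
closest qualifying geometry; detection is restricted to a configured site
(default: all residues).  Detection uses only pairwise distances and angles,
hence is invariant under rigid motion of protein and pose together — tested
as a property.  Residues are displayed as one-letter code + author
numbering with the chain (subunit) letter, e.g. `F95:A`; numbering is taken
verbatim from the input file.

The RMSD utility implements the mass-weighted deviation
`√((1/M)Σmᵢ‖rᵢ−rᵢ′‖²)` with `M = Σmᵢ` and performs **no** superposition; it
is a pure per-atom deviation metric, provided standalone (no trajectory
machinery).

## Pose acceptance criteria

Criterion (i) counts distinct (chain, residue, type) records.  Criterion
(ii) counts key residues with a qualifying record; the key set and allowed
types are configurable, defaulting to hydrophobic contacts at
F88/F95/F103/M105/F108/Y295/I310, H-bond/salt bridge at D92, and
H-bond/hydrophobic at Y298 *from the adjacent subunit*.  Two deliberate
interpretation choices, each behind a switch:

- π-stacking counts toward the hydrophobic slot of aromatic key residues
  (default on) — published grids mix HD and π-π at the same
  phenylalanines/tyrosines.
- Criterion (iii), "one more polar interaction with any *other* residue", is
  read by default as a polar record not consumed by a key slot; the strict
  alternative (the residue must not be a key residue at all) is available as
  `strict_other_residue`.  The default reading is the one under which all
  eight packaged worked-example grids pass, matching the study outcome those
  grids came from.

"Adjacent subunit" is judged against a configured primary chain (default A)
rather than inferred from the record set, so that adding records can never
flip a passing verdict — monotonicity is a tested property.  The subjective
parts of visual inspection (shape complementarity, pose reproducibility,
steric strain) are surfaced as manual-review flags in the report, never
auto-decided.

Score-table orientation (higher- vs lower-is-better) is always declared
explicitly in the table, never inferred from the score sign.  Consensus is
the order-preserving union of the two top-N lists.

## Synthetic data

The generators produce detector- and filter-facing realism, not physics:

- **Libraries** are assembled from a fragment grammar (aromatic/aliphatic
  scaffolds plus small substituents joined at free-valence atoms) and
  embedded with RDKit's distance-geometry conformer generator, up to 50
  conformers per compound as in typical multi-conformer database
  preparation.  Planted drug-likeness violations append a long flexible
  chain, which guarantees breaking the rotatable-bond and MW ranges; clean
  draws are verified against the default rule set at generation time, so the
  violation labels are exact ground truth.
- **The pocket** places pseudo-residues (minimal atom sets: aromatic rings
  for F/Y/W/H, charged termini for D/E/K/R, apolar carbons elsewhere, plus a
  four-atom backbone) on a 16 Å sphere around a cavity, side chains pointing
  inward, chains A/B/C as in the site inventory.  Aromatic rings face the
  cavity so stacking partners placed along the ring normal head into the
  pocket.  There is no fold, no sequence connectivity and no energetics.
- **Poses** are planted at threshold − margin (default margin 0.4 Å) for
  each requested contact and threshold + margin for decoys; π-stacks are
  placed at 4.5 Å face-to-face so the ring atoms stay outside the 4.0 Å
  hydrophobic cutoff.  Every planted pose is verified against the default
  detector at construction; an infeasible request raises with the clash.
- **Score tables** realize an exact top-N overlap `k` between two programs
  on realistic scales (higher-is-better ~86–108; lower-is-better ~−12.2 to
  −10.6).

All randomness flows from one seed; identical seeds give byte-identical
SDF/PDB/TSV outputs (tested).  Because the pocket and poses are pseudo-
geometries, passing tests demonstrate the correctness of the decision logic
and geometry rules — not performance on real receptors, real conformational
ensembles, or real docking poses.

## Problem sizes and numerics

The test suite and acceptance script run at desk scale by design: libraries
of 8–60 compounds with 1–3 conformers, a 32-residue pocket, 20 overlay pairs
plus self-overlays for the score-bound check.  Oracles are kept independent
of the code paths they check: overlap volumes against 3-D grid quadrature
(0.15 Å spacing, 1% tolerance), overlays against a 10°-step exhaustive Euler
grid with local polish (1e−3 tolerance on the score), interaction detection
against a plain all-pairs enumeration, ranking against a full re-sort.
Self-overlay scores equal 1 up to ~1e−15 round-off, which is clamped to
exactly 1 when within 1e−9.

## Known limitations

- SMILES support is RDKit's; stereo bonds are accepted but not required,
  and chiral centers are counted including unassigned ones.
- Multi-conformer SDF grouping is by shared title; files mixing identical
  titles for genuinely different compounds will be mis-grouped.
- The H-bond rule is distance-only whenever explicit polar hydrogens are
  absent, which over-detects at grazing geometries relative to a full
  angular model.
- The printed interaction grids are transcriptions merged from two external
  profilers with no stated precedence; they are treated as data fixtures for
  the criteria engine, not as ground truth for this package's detector.
- One printed grid cell inventory contains a residue label ("Y293" on
  subunit B) that appears once and is kept verbatim in the fixture; the
  default pocket uses F293 on that chain.
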