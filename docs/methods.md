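# Methods

This note documents the models and procedures `ringscan` implements, the
parameters that matter, what the synthetic generators do and do not emulate,
and the numerical choices made where the published descriptions of these
analyses leave the design open.

## Coordinate and sequence model

Structures are parsed from PDB coordinate text (via gemmi) into a plain
Atom/Residue/Chain/Structure hierarchy: first model only, ATOM records only
(waters and heteroatoms excluded), and for altloc duplicates the
highest-occupancy conformer with ties resolved toward altloc `A`.  This
yields a deterministic single-conformer geometry for all distance math.
Residue identity is author numbering plus insertion code; non-standard
residues map to one-letter `X`, are excluded from class-based sequence
scoring, but keep their atoms for geometry.  All coordinates in the package
are 1-based and inclusive (alignment columns, residue indices, domain
intervals).  Coordinates are written at the PDB's 3-decimal precision, so a
parse→write→parse cycle is a fixed point.

## RING-type classification

The classifier is a two-step procedure: a spacing-constrained scan for the
eight metal-ligand positions, then a deterministic rule table on the eight
letters found.

**Spacing model.** Published type inventories name the ligand letters but
not a spacing; the default gap ranges `(1,3), (8,40), (1,4), (1,4), (1,3),
(3,50), (1,3)` bracket the canonical RING spacing (the long second and sixth
linkers accommodate the variable loop and helix insertions seen across the
superfamily) and are fully configurable.  Positions 1, 3 and 7 are invariant
Cys in every named type, so their scan alphabet is `{C}`; positions 2 and 6
admit `{C,S,T}` (the Ser/Thr-substituted variant), position 4 `{C,H}`,
position 5 `{C,H,G,D}` and position 8 `{C,D}`.

**Rule table.** With positions 4/5 as the drivers: (4=H, 5=C) is the C3HC4
family — C3HC4 when the rest are Cys, C3HC3D when position 8 is Asp;
(4=H, 5=H) → C3H2C3; (4=C, 5=H) → C4HC3; (4=H, 5=G) → C3HGC3; Asp at
position 5 → RING-D; Ser/Thr at positions 2 and/or 6 → RING-S/T; eight
cysteines → C4C4.  Letter combinations the inventory does not name are
returned as `unclassified` rather than forced into the nearest label, so
unexpected patterns fail loudly.  The function is total and deterministic
over the ligand alphabet `{C,H,D,G,S,T}`⁸ (verified exhaustively against an
independently coded pattern dictionary).

When a sequence yields several candidates, the one with fewest substitutions
from the C3HC4 reference wins, ties going to the leftmost.  A sequence with
no candidate is assigned U-box only on an explicit upstream annotation hint,
since U-box domains share the fold while lacking the metal-chelating
residues — there is nothing for a ligand scan to find.

**Three-zinc types.** No ligand order is established for the third zinc site
of the 12-ligand C6H3C2D type, so its detection is a composition test (three
His, the rest Cys, one optional Asp restricted to positions 8 or 12) over a
permissive 12-position scan, disabled by default and clearly flagged as
composition-based in the output.

## Consensus and conservation

A column's consensus is a single letter when one standard letter reaches the
level threshold (default 0.8) over the non-gap entries, otherwise the most
specific residue class whose aggregate fraction does.  Specificity order:
identity, then aliphatic/aromatic/alcohol/tiny/negative/positive, then
charged, hydrophobic, small, polar, bulky — so a pure `{I,V,L}` column reads
aliphatic (`l`) rather than hydrophobic (`h`) although both qualify.  Gaps
are excluded from the denominator; columns with more than half gaps are
flagged low-support.

The conservation index is a reimplementation choice: the surveys this
package follows used an alignment program's 0–9 indices without publishing a
formula, so we define `index = round(9 · (1 − H/ln 20))` with H the Shannon
entropy of the standard-letter frequencies, clamped to 0–9.  A pure column
scores 9, a uniform one 0, and the published "> 4" conservation rule is kept
verbatim.  Note that the plug-in entropy estimate is biased low at small
row counts (with 4 rows even four distinct letters score 5), so the scoring
rule is only meaningful at realistic alignment depths (tens of rows).

Conserved-column calling restricts to SCR columns when segments are given
and reports the zinc-ligand columns separately — the six "equivalent
residues" are by definition the conserved columns *besides* the Cys/His
ligands.  Role assignment maps hydrophobic-consensus columns to hydro1
(N-loop), hydro2/hydro3 (βα region, in column order) and hydro4 (C-loop),
and polar-consensus columns to polar1 (βα helix) and polar2 (C-loop).  An
identity consensus of Pro is accepted for the hydro4 role (that position is
dominated by Pro in real RING sets) and the positive class for polar roles
(polar2 is typically Arg).  Surplus or missing columns become diagnostics,
never silent drops.

## Superposition, column RMSD and SCR detection

Superposition is the Kabsch least-squares fit (SVD with the reflection
excluded; determinant +1 enforced to 1e-8).  Fewer than three pairs or
collinear points raise an error rather than returning a silent NaN.  The
implementation is cross-checked in the tests against an independent Horn
quaternion method to 1e-9.

For an ensemble, every structure is superposed onto a reference (the first
by default) over their mutually ungapped C-alpha pairs; ensembles already
deposited in a common frame can skip the refit (`superpose=False` — the
refit would absorb part of any localized deviation into the rigid fit, which
matters for closed-form checks).  Each gap-free column then scores the RMSD
of the equivalent C-alpha atoms from their centroid,
`sqrt(mean ‖x_i − x̄‖²)`; a column missing a C-alpha anywhere is treated as
a gap and logged.

**SCR scan.**  Defaults: window w = 3, threshold 3.0 Å, minimum length 3,
with 2.0 Å available as the stricter preset used for per-region averages.
Scanning left to right, a seed is w consecutive gap-free columns with mean
RMSD ≤ threshold (boundary inclusive: a window averaging exactly 3.0 Å
qualifies).  The published description of the extension step is ambiguous
("extended until the mean did not rise above" the threshold, which reads
both ways); this package extends one column at a time while (i) the
extension is gap-free, (ii) the trailing w-column mean stays within the
threshold, and (iii) the whole segment's mean stays within the threshold.
The trailing-window condition is what stops extension at the edge of a
high-deviation run — under a pure whole-segment-mean rule, accumulated
low-RMSD columns dilute the mean and the segment absorbs entire
high-deviation spacers, which contradicts the intended behaviour of
recovering distinct conserved regions.  A final merge pass joins adjacent
or overlapping segments whose union still qualifies; segments shorter than
min_len are dropped.  The scan is deterministic; its output is verified
against a direct quadratic enumeration of the same semantics on random
profiles.

Threshold monotonicity (tightening never lengthens a segment, loosening
never shortens one) holds in the regime the survey operates in — low-RMSD
regions well below threshold separated by spacers well above — but is not a
theorem for greedy windowed scans in general: near-threshold profiles exist
where loosening merges an earlier segment past a would-be seed start and
shifts a boundary the other way.  The tests assert the property in the
separated regime only.

## SASA, buried core and the hydrophobic patch

SASA is Shrake–Rupley sphere-point quadrature, written in-package: each
heavy atom's van der Waals sphere (C 1.70, N 1.55, O 1.52, S 1.80 Å, carbon
default for unlisted elements) is inflated by the 1.4 Å water-probe radius
and sampled with a deterministic golden-spiral set of 960 points; points
inside any neighbour's inflated sphere are buried.  The point count keeps
the isolated-sphere quadrature error well under the 2% documented tolerance.
Relative SASA divides by the theoretical extended-tripeptide maxima (Tien et
al. 2013); values above 1.2 are clamped and flagged.  Burial is relative
SASA < 0.10 by default.  All of method, probe, point count, burial threshold
and reference table are configurable, since none is fixed by the analyses
being reproduced.

Hydrophobic-neighbour search returns hydrophobic-class residues whose
minimum heavy-atom distance to the query is ≤ 4.0 Å, excluding the query
and its covalent sequence neighbours (author-numbering offset ±1) so bonded
contacts do not count; the published analyses do not state whether all-atom,
side-chain-only or C-beta distances were used, and all-heavy-atom is chosen
here.  Patch validation checks that hydro1, hydro3 and hydro4 each approach
hydro2 — the central hydrophobic residue, taken from its role rather than
re-derived geometrically — within 4 Å (strict).

## Interface contacts

Contacts are cross-selection residue pairs with minimum heavy-atom distance
≤ 4.0 Å; the ≤ 3.5 Å subset is the close-approach tier (both boundaries
inclusive, and close records are a subset of contact records by
construction).  Crystal structures generally lack hydrogens, so backbone
hydrogen bonds are approximated as cross-chain backbone N···O pairs within
3.5 Å with no angle criterion, the backbone N standing in for the amino
hydrogen donor.  Contact residues map through the alignment to SCR regions
I (N-loop), II (α-helix of the βα region) and III (C-loop); unmappable
residues are labelled `none` with a diagnostic.  For real complexes the
RING-domain residue range is derived from the classifier's ligand span plus
a 2-residue flank on each side (`interfaces.ring_selection`), since the
published boundary convention is not stated; the flank is configurable.
Exact-cutoff pairs are knife-edge by nature: a pair at exactly 4.0 Å is a
contact, but floating-point rigid motions can move it across the boundary,
so reproducibility claims at the cutoffs assume a fixed frame.

## Orthology and architectures

Best hits rank by bit score, then lower e-value, then higher percent
identity, then lexicographic subject id — the published definition is just
"reciprocal best hits", so the conventional ordering is stated explicitly
for determinism; self-hits are removed before ranking.  RBBH pairs are those
where each side is the other's best hit.  Hit tables are consumed, not
computed: the original database searches are era-specific and not
reproducible, so BLAST tabular TSV is an input format.

Architecture comparison is on ordered domain-name lists via longest common
subsequence: `identical` (equal lists), `insertion`/`deletion` (one list a
strict subsequence of the other; positions reported 1-based on the longer
list), `rearrangement` (same multiset, different order) and `other`.  The
finer labels beyond identical-vs-insertion aid reuse.

## Synthetic data: what it emulates and what it does not

All generators route randomness through one seeded numpy Generator;
identical specs give byte-identical outputs, and each generator ships a
direct truth checker that validates the emitted data against its planted
ground truth before tests rely on it.

- **Sequences** plant one canonical ligand pattern per sequence at random
  admissible spacings; flanks and gap fillers draw only from letters that
  can never occupy a ligand position, so the planted pattern is provably the
  unique scan candidate.  Real sequences contain distracting Cys/His, which
  this deliberately avoids — recovery rates on these data measure the
  scanner's correctness, not its specificity on real proteomes.
- **Ensembles** are C-alpha traces (3.8 Å self-avoiding steps, minimum
  3.0 Å non-adjacent separation, one dummy side-chain atom per residue)
  with per-region isotropic Gaussian noise; the default region plan —
  low-noise regions of lengths 9/7/13/6 at σ = 0.3 Å among σ = 4.0 Å
  spacers — mirrors the four conserved-region lengths reported for real
  RING ensembles (N-loop 9, β 7, βα 13, C-loop 6 residues).  A column of n
  members at noise σ has expected centroid RMSD ≈ σ·sqrt(3(n−1)/n) (≈0.5 Å
  vs ≈6.4 Å for the two levels at n = 10), comfortably separated by the
  3.0 Å threshold.  No secondary structure, side-chain packing or
  correlated backbone motion is modelled.
- **Complexes** place each planned cross-chain atom pair at exactly its
  planned distance (axis-aligned so the 3-decimal coordinate format keeps
  tier boundaries sharp) with all other atoms ≥ 8 Å from the partner chain.
- **Alignments** sample planted columns to a target class level ±0.05 with
  one dominant member (85% of class picks) and restricted off-class
  letters, emulating the single-residue dominance of real conserved
  columns; unplanted columns are uniform over the 20 letters, which is far
  noisier than real homologous columns.
- **Hit tables** give planted pairs 150–300 bits and decoys strictly lower
  (20–140), with optional constructed ties (equal bit score, worse e-value)
  to exercise the tie-break.

Because every condition is planted and separations are generous, passing
the closed-loop tests demonstrates algorithmic correctness under the stated
conditions — not performance on real, noisy data where regions blur into
spacers and conservation is marginal.

## Pipeline

Stages run in dependency order (classify → SCR → conservation → interface →
orthology → architecture diff) from a YAML config; each stage's output is
cached under a content hash of its input files and parameters, so partial
reruns are cheap and a rerun with identical inputs is byte-identical
(reports are written with sorted keys and floats rounded to 4 decimals).  A
stage failure is recorded in the report and halts its dependents while
independent stages still run.  Percentages are reported to one decimal.

## Scope and limitations

- The headline counts of the original fly-genome survey (139 proteins, 118
  orthologs, per-type tables) depend on era-specific databases and searches
  and are not recomputable here; the package reproduces the machinery, with
  the seeded generators defining the test conditions.
- The printed close-residue counts for the c-Cbl/UbcH7 (6) and CNOT4/UbcH5B
  (20) cocrystals require the corresponding PDB entries; the computation is
  implemented (`ring_selection` + `extract_contacts` +
  `count_close_e3_residues`) and the comparison runs whenever the files are
  placed under `data/cocrystals/`, but the coordinates are not bundled and
  the corresponding check fails when they are absent.
- Alignment construction, structure database searching, homology modelling,
  secondary-structure prediction, pocket detection and subcellular
  localization are out of scope; alignments, hit tables and coordinates are
  inputs.
- Problem sizes in the test suite and acceptance script (100 ensembles of
  10×51 residues, 300×300 proteomes, 200 random contact systems, 1000
  random profiles) were chosen as comfortable desk-scale conditions for the
  statistics being measured.
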