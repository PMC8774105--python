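# Methods

## The motif and the detection model

Methionine's thioether ([-CH₂-S-CH₃]) interacts attractively with aromatic
π systems through a mixture of S–π, S-lone-pair–π and CH–π contributions.
An *n-bridge cluster* is one Met residue whose side chain has n or more
aromatic residues (Phe, Tyr, Trp) within a distance criterion; the 3-bridge
is the motif this package surveys.

Detection is purely geometric. A Met–aromatic pair is a contact when the
configured distance is **≤ 6.0 Å (inclusive)**. The long cutoff is
deliberate so that weaker interactions are still captured; no angular
criterion is applied by default (the angle cutoff is 360°, i.e. disabled).
The Met-side reference point is the SD sulfur; the aromatic-side reference
is configurable:

- `sd_to_nearest_midpoint` (default): minimum distance from SD to the
  midpoints of the ring bonds. This follows the earlier Met-aromatic
  screening convention the survey builds on.
- `sd_to_centroid`: distance from SD to the unweighted mean of the ring
  heavy atoms.

Both values, plus the angles between the SD→reference vector and two
estimated sulfur lone-pair directions, are recorded on every contact so the
convention never has to be guessed from the output. The lone-pair estimate
places both vectors opposite the CG-SD-CE wedge, displaced symmetrically
out of its plane; it is reported, never filtered on by default.

Clusters are enumerated on a bipartite residue interaction graph (Met
nodes vs aromatic nodes, one edge per contact). A Met with aromatic degree
≥ n yields **one maximal cluster** carrying all its partners; a
combinatorial mode expanding every n-subset exists for sensitivity
analysis, because published counts do not fix which convention was used
when a Met has more than n partners.

## The canonical Met frame (two quaternions)

Each cluster is reduced to six 3-tuples — CG, SD, CE and the partner ring
centroids — and mapped to a standard pose:

1. translate all points by −SD, so the sulfur is at the origin;
2. with α = arccos of the direction cosine between SD→CE and the x-axis,
   rotate by quaternion **Q1** about cross(SD→CE, x̂) so the SD–CE bond is
   collinear with +x (when the cross product vanishes the pose is already
   on the axis; the antiparallel case uses a fixed 180° rotation about ẑ);
3. with β = atan2(CG_z, CG_y) after step 2, rotate by quaternion **Q2**
   about x̂ through −β, bringing CG into the x,y-plane with CG_y ≥ 0 (the
   CH₂ arm points along +y).

Centroids are carried by the composition Q2·Q1 applied after the
translation. Quaternions are unit, scalar-first (w, x, y, z), right-handed
and act as active rotations v′ = q v q*; the hand-rolled algebra is
cross-checked against `scipy.spatial.transform.Rotation` in the tests.
Both steps are proper rotations, so the mapping is a rigid motion: local
coordinates are invariant under any proper rigid motion of the structure
(verified to 1e-9 Å over 10⁴ random poses) and a mirror image flips
exactly the z-coordinates — improper motions are not silently absorbed.
Scaffolds within 1° of collinear CG-SD-CE are rejected by name rather than
mapped through an unstable frame.

## Parsing conventions

- **Model selection**: model 1 only, the X-ray survey convention;
  multi-model files draw a warning.
- **Altlocs**: per (residue, atom name) the highest-occupancy conformer is
  kept; ties resolve toward altloc "A"; a warning records the choice.
- **Hydrogens** are ignored throughout (detection uses heavy atoms only).
- **Selenomethionine** (MSE, SE in place of SD) is excluded by default and
  included via `include_mse`, since its treatment materially affects counts
  and a strict reading of "Met" excludes it.
- **Trp centroid**: mean of all 9 indole heavy atoms by default; a
  6-membered-ring-only option exists. Trp ring-bond midpoints follow the 10
  bonds of the fused bicycle with the shared CD2–CE2 bond counted once.
- **EC numbers** come from COMPND `EC:` records (PDB) or `_entity.pdbx_ec`
  (mmCIF); absent or malformed entries are "unclassified". The primary
  class is the first digit of the first listed EC number.
- Only PHE/TYR/TRP amino-acid residues qualify as aromatic sites; het
  ligands never do. Incomplete scaffolds and rings are skipped with
  warnings, never errors.
- Inter-chain contacts count by default (a flag restricts to intra-chain).

## Survey statistics

- **Composition tally**: counts over the 10 unordered {Phe,Tyr,Trp}
  triples; clusters with more than 3 partners are tallied by their 3
  nearest partners (a skip mode exists) — the reporting convention for
  oversize clusters is otherwise underdetermined.
- **EC breakdown**: per-structure primary class over cluster-bearing
  structures; counts and percentages (zeros kept so breakdowns always sum
  to 100%).
- **Distance histogram**: half-open bins [lo, hi) from 0, left-closed so
  boundary values are unambiguous; counts conserve totals.
- **B-factor context**: cluster mean B over all atoms of the Met plus
  partner residues, compared to the distribution of per-residue mean B of
  the whole protein; the percentile uses mid-rank tie handling, so a
  uniform B column sits at exactly 50 and the statistic is invariant to
  affine rescaling B → aB + b (a > 0). An all-zero B column is flagged
  uninformative.
- **survey_run** sorts inputs by path and results by structure ID, so the
  summary is byte-identical across runs and independent of scan order;
  unparseable entries are isolated, logged, counted as failed, and removed
  from denominators.

## The synthetic-data generator

Fixtures are assembled in the canonical Met frame, where planting is
exact: partner ring centroids at chosen spherical coordinates (r, θ polar
from +z, φ azimuth from +x), ring orientation as a random normal plus
spin, decoy residues (ALA and out-of-range aromatics) kept at least 9 Å
from the Met SD and planted centroids so they can never create contacts
under either metric. A seeded random rigid motion then moves every atom so
no fixture sits in the canonical frame by accident, and the structure is
written as fixed-column PDB.

Geometry conventions (fixture conventions, configurable — not claims
about real proteins): |CG−SD| = 1.81 Å, |SD−CE| = 1.79 Å, wedge 100°;
Phe/Tyr rings are regular hexagons of circumradius 1.39 Å; Trp an
idealized planar fused pentagon+hexagon with 1.40 Å bonds. Aromatic
residues carry ring + CB atoms and Met carries CB-CG-SD-CE — the minimum
the pipeline reads.

Because PDB coordinates are quantized to 1e-3 Å, plain rounding could move
a planted distance by up to ~9e-4 Å in either direction — enough to push a
centroid planted exactly at the cutoff to the wrong side. The writer
therefore converges each partner ring onto the coordinate grid so the
*written* SD–centroid distance lies within (r − 5e-4, r]: realized
distances are accurate to better than the file precision and a distance
planted at exactly 6.000 Å is always inside the inclusive boundary.

Survey-scale generation allocates cluster-bearing structures
deterministically — `round(rate × n)` planted entries, compositions
apportioned by largest remainder — so small surveys hit requested rates
exactly (200 structures at rate 0.12 → exactly 24). The default planting
rate of 0.12 mirrors the survey-wide fraction of cluster-bearing
structures in the non-redundant X-ray dataset; planted radii span
3.8–5.4 Å, inside the observed 2–4 Å peak region plus margin, and
non-planted structures receive 0–2 sub-threshold partners so negatives are
non-trivial. Defect fixtures (altloc pairs, missing ring atoms, MSE,
multi-model, waters-only) exercise each parser decision on purpose.

**What passing tests show — and what they do not.** The generator emulates
coordinate bookkeeping, geometry, quantization, annotations and defects; it
does not emulate crystallographic noise, alternate side-chain rotamer
distributions, crystal contacts, or realistic packing density. Perfect
precision/recall on fixtures validates the pipeline's logic, not the
biological prevalence of the motif; real-survey numbers require the real
coordinate files (the `--fetch`-enabled scan and
`analysis/05_worked_examples.py` cover that path).

## Problem sizes

The shipped analysis and the acceptance script use a 200-structure
synthetic survey (≈50 atoms per structure), 100+100 random structures for
the brute-force detector cross-check, 10⁴ (tests) / 10³ (script) random
poses for the frame contract — sizes chosen so the full suite completes in
well under a minute while every property is exercised at scale.

## Known limitations

- Only Phe/Tyr/Trp partners; His and het-group aromatics are out of scope.
- Cys–aromatic, aromatic–aromatic stacking and cation–π detection are not
  implemented.
- No assembly/symmetry expansion: contacts across crystallographic copies
  that are not in the deposited coordinates are invisible.
- The lone-pair directions are a geometric estimate on an idealized
  thioether, adequate for reporting angles but not a substitute for
  electronic-structure analysis.
- Kernel-density or angular-correlation statistics over the local-frame
  point cloud are not included; the exported CSV is the intended input for
  such downstream analysis.
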