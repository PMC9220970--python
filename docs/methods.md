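# Methods

## Problem and model

Given only the ordered Cα coordinates of a protein chain, assign each
residue one of three secondary-structure states: H (α-helix), E (β-strand),
C (coil). The assigner is a sliding-window classifier: for every contiguous
fragment of N residues (N odd, 5–13) a feature vector is computed and a
feed-forward network predicts the class of the fragment's middle residue.

The network has an input layer of width equal to the feature vector, two
sigmoid hidden layers (128 neurons each by default), and a 3-neuron softmax
output. Weights are Glorot-uniform initialized from a seed, biases start at
zero, and training is plain mini-batch SGD on categorical cross-entropy with
one-hot targets. Input features are standardized (z-score) using statistics
of the training rows only; the statistics travel with the model. A literal
sigmoid applied to raw Å-scale distances would saturate immediately, so
"activating" the input layer is realized as this standardization step.

Defaults: learning rate 0.01, batch size 32, 3500 epochs, 80/20
train/validation split. The split is over rows by default; passing per-row
group identifiers (chain names) switches to a group-level split so that
correlated windows of one chain never straddle the split — all whole-corpus
results quoted in this repository use the chain-level split. Training is
bit-reproducible for a fixed seed.

## Features

All features are functions of interatomic distances and triple products, so
they are exactly invariant under rigid motion of the chain. For a window of
N residues:

1. **Local distances** (3N−9 values): all r(i,i+2) (N−2), signed r\*(i,i+3)
   (N−3) and r(i,i+4) (N−4) within the window. r\*(i,i+3) carries the sign
   of the triple product (v₀×v₁)·v₂ of the three consecutive pseudo-bond
   vectors between atoms i..i+3 — positive for right-handed (α-helical)
   geometry, negative for its mirror image. An exactly planar quadruplet has
   triple product zero and is signed +1; planar conformations are
   measure-zero in real data, so the tie-break only matters for idealized
   synthetic strands.
2. **Neighbor counts** (4N values): for each window residue, the number of
   chain Cα atoms within 4.0, 4.5, 5.0 and 6.0 Å, counting only partners
   with |i−j| ≥ 3 along the sequence. Counts are computed within the query
   chain; tightly packed core residues (regular secondary structure) score
   high, exposed loops low.
3. **CG hydrogen-bond counts** (N values in {0, 1, 2}), described below.

Feature order within a row is fixed — r2 block, r3s block, r4 block,
neighbor counts residue-major with cutoffs ascending, hbond counts — and a
column-name manifest is stored in every model file. Windows that span a
chain break (consecutive Cα distance outside [2.5, 4.3] Å — the range admits
trans ≈ 3.8 Å and cis ≈ 2.9 Å peptides) are dropped during training;
at inference the affected residues are assigned C, as are the (N−1)/2
windowless residues at each terminus (the safest prior). For N = 7 with all
blocks the row length is 12 + 28 + 7 = 47.

## Coarse-grained hydrogen bonds

Every three consecutive Cα atoms define a triangle: centroid plus unit
normal from the cross product of the two bond vectors. Two triangles are
declared hydrogen-bonded when

* their centroid distance lies in [4.0, 6.0] Å,
* |cos| of the angle between their normals ≥ 0.7 (unsigned, so parallel and
  antiparallel sheets both qualify),
* the unit centroid displacement has |cos| ≥ 0.5 against **both** normals
  (the partner sits above or below the triangle face, not beside it), and
* the residues are ≥ 3 apart along the sequence.

Requiring the displacement gate against both normals makes the relation
symmetric: (a,b) bonded iff (b,a) bonded. Each residue offers two sides
(along/against its normal); at most one partner occupies a side (nearest
centroid wins, ties to the lower residue index), so per-residue counts are
structurally bounded by 2 — the saturation value reached by interior
residues of the middle strand of a three-stranded sheet. The four thresholds
are detector parameters, chosen so the gates fire on cross-strand geometry
at the canonical ~4.8 Å inter-strand spacing and stay silent inside an
isolated strand or helix (where the closest eligible triangle pairs are
either too far or fail the orientation gates). They are stored in the model
file and overridable via config keys `hbond.dist_min`, `hbond.dist_max`,
`hbond.normal_cos`, `hbond.disp_cos`, `hbond.min_sep`, so a trained model
is always self-consistent between training and inference.

## Synthetic structures

The generator produces labeled chains with the geometric signatures the
classifier must separate; it is the package's training corpus and its test
bed.

* **Helix**: p_i = (r·cos(iθ), r·sin(iθ), i·rise) with textbook Cα values
  rise 1.5 Å, radius 2.3 Å, θ = 100°/residue (right-handed by default).
  Consecutive distance 3.83 Å; characteristic chords 5.43 / +5.05 / 6.20 Å.
* **Strand**: planar zigzag along x with axial step 3.3 Å and alternating
  z = ±0.942 Å, giving a 3.80 Å bond and chords 6.60 / 10.08 / 13.20 Å; an
  optional slow twist rotates the zigzag plane about the strand axis.
* **Sheet**: strands stacked at 4.8 Å along the strand-triangle normal
  (antiparallel by default), joined by deterministic equal-chord circular
  arcs (step 3.8 Å) that bulge out of the sheet plane; strand residues are
  labeled E, loop residues C, and the assembled trace contains no chain
  break. Parallel sheets need loops long enough to bridge strand ends
  ((loop_len+1)·3.8 Å ≥ the end-to-start distance); shorter requests fail
  loudly rather than stretch bonds.
* **Coil**: seeded self-avoiding random walk, step 3.8 Å, pseudo-bond angle
  uniform in [60°, 180°], uniform dihedral, minimum non-adjacent (|i−j| ≥ 2)
  approach 4.0 Å with bounded resampling. The angle range favors expanded
  conformations, so coil neighbor counts stay low.
* **Mixed topologies**: H/E/C segments generated in their ideal local
  geometry and concatenated by seeded rigid placement (junction bond 3.8 Å,
  no |i−j| ≥ 2 pair closer than 3.5 Å, retried until clash-free).
* **Mirror**: reflection through the xy-plane, used to test chirality:
  it negates every signed r\*(i,i+3) and changes no other feature.

The standard corpus (`make_dataset`) draws chain topologies from a fixed
menu — pure helices, helix–coil–helix, helix–coil, 2- and 3-stranded
antiparallel sheets, pure coils — with randomized segment lengths
(helices 8–25, strands 6–12, coils 4–30 residues). E residues come almost
exclusively from sheets so that the hydrogen-bond signal exists for the E
class, mirroring the observation that extended coil and β-strand geometry
are locally similar and are separated by bonding pattern, not by local
distances.

What the generator does **not** emulate: Ramachandran-statistics backbone
variation, bent/kinked helices, β-bulges, π/3₁₀ helices, twisted sheets,
packing of multiple domains, or experimental coordinate noise. Passing the
recovery tests therefore demonstrates that the pipeline is self-consistent
and that the features separate idealized classes cleanly; it does not
certify accuracy on deposited structures, which depends on training against
reference assignments of real chains.

## Problem sizes and numerical choices

Whole-corpus results in this repository use 600 synthetic chains
(≈ 15,000 residues, ≈ 9,400 windows at N = 11), the full feature set,
128×128 hidden layers, learning rate 0.01, batch 32 and 150 epochs — the
loss plateaus two orders of magnitude below its start well within that
budget on this corpus, so longer schedules change nothing but runtime.
Under a chain-level 80/20 split this yields held-out Q3 ≈ 0.98 with H/E
recall ≥ 0.97 (recomputed by the test suite on every run).

Other fixed choices: prediction ties break H > E > C; zero-variance feature
columns store std 1; probabilities are clipped at 1e−12 inside the loss;
model files are JSON text whose floats round-trip exactly, carry a format
version tag, and are validated (shape consistency, positive std, input
width vs feature configuration) on load. Altloc CA records resolve to the
highest occupancy (first on tie); CA atoms whose element is not carbon
(calcium ions) are ignored; HETATM CA (e.g. selenomethionine) is accepted.

## Limitations

* Whole-chain Q3 on short chains is dominated by the windowless termini
  (10 forced-C residues per chain at N = 11); windowed-residue Q3 is the
  meaningful recovery metric and is what the training log reports.
* The CG hydrogen-bond thresholds were set geometrically, not fitted to PDB
  statistics; models trained with different criteria are not interchangeable
  (the model file enforces this).
* Isolated strands outside sheets carry no bond signal and remain the
  hardest class boundary, as expected from the feature design.
* Eight-state reference labels are reduced H,G,I→H; E,B→E; others→C — the
  common convention; other reductions would shift class boundaries.
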