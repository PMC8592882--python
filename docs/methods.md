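# Methods

This note documents the models and procedures implemented in `nacgeo`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical choices that affect results.

## Near-attack-conformation statistics

The S\_N2 methyl transfer from AdoMet to a substrate arginine is
geometrically characterised per frame by the attack distance d between the
nucleophilic guanidino nitrogen (Nη1 or Nη2) and the AdoMet methyl carbon,
and the attack angle θ = N···CH₃···S with the vertex at the methyl carbon
(the angle subtended by the nucleophile and the sulfur leaving group). A
frame is a NAC when d ≤ 3.2 Å and |180° − θ| ≤ 15°, both bounds inclusive
so boundary frames count. The scalar coordinate

r = d + 0.5·cos θ   (Å)

folds the angle into the distance: θ = 180° rewards d by −0.5 Å, θ = 90°
leaves it unchanged, θ < 90° penalises. r is strictly decreasing in θ at
fixed d and bounded by d ± 0.5.

Distributions of r are probability densities over bins of 0.1 Å by
default, with the bin grid anchored at multiples of the bin width and
truncated at r_max = 10 Å. Peak heights are density values and therefore
scale with the bin width; every summary carries its bin width so heights
from different runs are comparable. Frames beyond r_max are excluded from
the density (all frames beyond r_max is an error, since it means the
wrong atoms were selected). Both Nη1 and Nη2 triplets can be analysed and
are reported separately rather than pooled; pooling is a caller decision.

## Hydrogen-bond occupancy

A bond is scored per frame on (i) donor-heavy-atom to acceptor-heavy-atom
distance ≤ 3.0 Å and (ii) donor–H···acceptor angle at the hydrogen
≥ 135°. The distance is deliberately D···A, not H···A: 3.0 Å is a
heavy-atom separation (an H···A criterion at 3.0 Å would be far too
permissive), and this is the convention of the standard trajectory
tooling this module mirrors. Chemically equivalent atoms are declared as
groups — carboxylate OE1+OE2, guanidino HH21+HH22 — and a frame satisfies
the grouped bond if *any* donor/hydrogen/acceptor combination does. This
union semantics matches reporting one percentage per grouped row:
occupancy of a group is the union of per-member frame sets, never the sum
of percentages (the implementation and tests include an overlap case
where the union is 50% while naive addition would claim 80%). Occupancy
is monotone under loosening either cutoff and under growing any group.

Hydrogens must be present in the topology; the module refuses structures
without explicit protons (crystal structures) rather than inferring
positions, because an inferred proton would silently change the angle
criterion.

## Clustering

The trajectory is clustered on pairwise best-fit (Kabsch) RMSD over a
selection, default `protein and not hydrogen` — heavy atoms, since
including fast-librating protons adds noise to a coordinate metric and
default topologies differ in proton naming. The pipeline is
cpptraj-faithful:

1. sieve: every s-th frame (systematic, deterministic; default s = 10);
2. average-linkage agglomeration of the sieved pairwise RMSD matrix down
   to k clusters (default k = 10, top 3 reported) — at each step the two
   clusters with the smallest unweighted mean cross-pair distance merge.
   The implementation delegates the agglomeration to
   `scipy.cluster.hierarchy.linkage(method="average")` with a
   `cut_tree` at k; the test suite verifies it against a naive cubic
   re-scan oracle on hundreds of random instances;
3. restore: every non-sieved frame joins the cluster whose
   *representative* it is nearest to by best-fit RMSD (representatives,
   not centroids, keep the assignment inside the metric);
4. populations are percentages of *all* frames and sum to 100;
5. the representative of a cluster is the sieved member minimising mean
   RMSD to its sieved co-members;
6. the averaged structure is the arithmetic mean of member coordinates
   after superposing each member onto the representative. Coordinate
   averaging can produce non-physical local geometry (it is an ensemble
   mean, not a conformer); the representative frame is always available
   alongside.

Termination is a fixed cluster count k rather than a distance epsilon
because population percentages of the top clusters are the quantity of
interest, and k with top-n reporting reproduces that table shape
directly. Cluster ids are relabelled by descending population.

RMSD is mass-unweighted (uniform weights), the common default for
coordinate RMSD. The Kabsch solution enforces det(R) = +1 (proper
rotation; mirror pairs are fit without reflection), and the RMSD is
computed from the actual post-rotation residuals rather than the
singular-value identity E₀ − 2Σσ, which cancels catastrophically near
zero and limits accuracy to ~10⁻⁷ Å where the residual form gives ~10⁻¹⁴.

## SASA and interface decomposition

SASA uses the Shrake–Rupley construction: each atom's solvent-expanded
sphere (r_vdw + 1.4 Å probe) is sampled at 960 deterministic points from
a golden-angle Fibonacci spiral; the accessible fraction of points times
the expanded-sphere area is the atom's SASA. The point sphere is fixed in
the laboratory frame, so SASA is rotation-invariant only to within the
sampling error (< 0.5% at 960 points; deviations from analytic
sphere/cap values shrink as the point count grows). Radii: C 1.70, N
1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å, fallback 1.70 Å (strict mode
errors on unknown elements instead).

Interface burial of a two-chain-group complex is
SASA(A) + SASA(B) − SASA(AB), decomposed per residue as
ΔSASA = isolated − in-complex (clamped at zero; the unclamped per-atom
sum equals the total exactly by construction). A residue is an interface
residue when it buries > 0.1 Ų — any real burial counts, the threshold
only suppresses point-sampling noise. Per-residue "per dimer" values sum
the two chains' copies of a residue position.

Cross-chain contacts are heavy-atom-only (crystal structures carry no
hydrogens): hydrogen bonds are donor-capable N/O to acceptor-capable N/O
pairs within 3.5 Å, with capability assigned from residue-template tables
(backbone N donor / O acceptor; side-chain donors Arg NE/NH1/NH2, Lys NZ,
His ND1/NE2, Trp NE1, Asn ND2, Gln NE2, Ser/Thr/Tyr hydroxyls; acceptors
carboxylates, amide oxygens, hydroxyls, His nitrogens, Met SD). Salt
bridges are Arg/Lys/His basic nitrogens to Asp/Glu carboxylate oxygens
within 4.0 Å. Within each category, multiple atom pairs between the same
residue pair collapse to the shortest contact, and residue pairs counted
as salt bridges are excluded from the H-bond list so a charged contact is
not double-counted. These cutoffs reproduce what interface servers can
observe on crystal structures; since published interface counts depend on
each tool's unprinted criteria and radii, comparisons against published
per-residue burials and contact counts are tolerance checks (±15%, ±2
contacts), not exact ones.

## Structures, trajectories, selections

Trajectories are multi-model PDB files: MODEL/ENDMDL blocks are frames,
atom identities must be constant across frames (a mismatch is a hard
error naming the offending MODEL; an unparseable coordinate reports its
line number). HETATM records are kept and flagged, and the default
`protein` selection excludes them. Duplicated altlocs keep the
highest-occupancy record, first on tie — deterministic. Residue numbers
are taken verbatim from the file; the rat↔human PRMT1 numbering offset
(+18, W197↔W215) is an exported constant, not auto-detected. Parsing and
writing are backed by biotite; a one-frame trajectory is written without
MODEL records by default (flag to force them). Coordinates survive a
write/read roundtrip to the PDB's three printed decimals.

## Synthetic generators: what they emulate, and what not

The generators reproduce the *statistical structure* each analysis
assumes, with truth planted as exact counts (`round(f·n)` frames) so
recovery is exact rather than within binomial noise; an `iid` mode exists
for tolerance-style tests. Defaults are the study conditions used
throughout the tests: NAC mixture fraction 0.3 over 1000 frames
(NAC-forming frames d ~ U(2.8, 3.2) Å, θ ~ U(168°, 180°); non-forming
d ~ N(6, 1) truncated ≥ 3.5 Å, θ ~ U(60°, 180°)); H-bond occupancy 0.247
over 1000 frames (bound D–A 2.8 Å at 175°, unbound 5.0 Å); conformer
mixture 60/25/15% over 500 frames of a 20-atom chain with 8 Å
inter-conformer RMSD and σ = 0.3 Å isotropic noise (references are
rejected if their separation is below 10σ). Every frame receives a random
rigid motion, so the analyses must genuinely superpose; all randomness
comes from one seeded generator per call and identical seeds give
bit-identical output.

What they do *not* emulate: force-field energetics, correlated frame-to-
frame dynamics, aMD boost statistics, solvent, or realistic protein
topology. Passing recovery tests therefore demonstrates that the
*measurement machinery* is correct — that a planted signal of realistic
magnitude is recovered exactly — not that any particular enzyme ensemble
has a given NAC fraction or cluster structure. Conclusions about real
systems require real trajectories, which this package reads but does not
produce.

## Problem sizes

The validation suite uses 1000-frame three-atom trajectories for the NAC
and H-bond recoveries, 500 frames × 20 atoms for clustering (sieve 1 and
5, i.e. up to 124,750 superpositions per matrix, batched), 10⁵ samples
for distribution-peak checks, 200 random ≤ 20-item instances for the
linkage oracle, and 960-point spheres for SASA. These sizes give exact or
sub-percent agreement with the planted/analytic answers while keeping the
full suite around a minute on one CPU.

## Known limitations

* The selection language covers chain/residue/name/element predicates,
  not distance-based or within-style selections.
* SASA is O(N·points·neighbours) pure NumPy per atom; adequate for
  crystal-structure dimers (minutes at worst), not tuned for
  thousands-of-frames SASA time series.
* H-bond occupancy requires explicit hydrogens; crystal structures must
  be protonated upstream.
* Interface contact typing covers the 20 standard amino acids; modified
  residues participate only through backbone atoms.
* mmCIF is not parsed; convert to PDB first.
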