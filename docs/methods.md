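# Methods

This note documents the models implemented in `ecdkit`, the defaults and
why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions a user should know before trusting
a number.

## Essential collective dynamics

The covariance matrix of mean-centered Cartesian displacements is
accumulated per trajectory segment and diagonalized. Conventions:

* **Segmenting.** Default segment length 0.2 ns, contiguous and
  non-overlapping; a trailing remainder is dropped with a logged
  warning. Frame spacing comes from the trajectory's times; when a
  format without times is read (plain PDB), 1 ps/frame is assumed with a
  warning. Descriptors are computed per segment and arithmetically
  averaged; the across-segment standard deviation is reported as the
  error bar.
* **Covariance.** Mean-centering uses the segment mean; normalization is
  1/n_frames (so the trace equals the mean-square displacement exactly,
  which the tests assert to 1e-6 relative). No mass weighting anywhere —
  superposition, PCA and RMSD share one unweighted convention.
* **Truncation.** K = max(20, smallest count reaching 80% of the total
  displacement), capped at 3N. This honors both truncation statements
  (a fixed top-20 set and an at-least-80% displacement fraction)
  simultaneously; for small synthetic systems the 3N cap is the binding
  constraint.
* **Mode weighting.** The per-atom essential coordinates scale each
  atom's slice of mode k by √λᵏ, so dominant modes dominate distances in
  the 3K-space; an unweighted variant is available
  (`weighting="unweighted"`). The √λ scaling is the package default
  because the correlation descriptor is meant to measure *dynamic*
  coupling: without it, near-zero-amplitude modes would contribute to d
  on equal footing with the dominant motions.
* **Superposition check.** PCA on an unsuperposed segment is detected by
  a least-squares linear trend of the centroid against time (net drift
  above 1 Å warns). A trend separates genuine drift from stationary
  fluctuation, which legitimately moves the centroid frame to frame.

Flexibility F is the distance of a Cα atom's essential coordinates from
the Cα centroid; the correlation descriptor d(i,j) is the Euclidean
distance between two atoms' essential coordinates and is a true metric
(zero self-distance, symmetry, triangle inequality — property-tested).
Per DNA residue the *minimum* d over its atoms is reported: the plotted
quantity is the strongest coupling to that residue.

## Clustering

* Frames are fitted once on a stable selection (Cα by default) to a
  common reference; the RMSD matrix over the interface selection is then
  plain coordinate RMSD — no per-pair refitting. After a shared fit,
  pair RMSD equals Euclidean distance in frame space divided by √m, so
  the matrix is a genuine Euclidean metric and the pairwise form of the
  within-cluster sum of squares is exact; SSR/SST is then provably
  non-decreasing along the nested UPGMA cut sequence.
* Average linkage is scipy's UPGMA; labels are renumbered by first
  appearance, making the whole path deterministic. An exhaustive
  merge-loop oracle cross-checks it in the tests.
* The Davies–Bouldin index uses **medoids** as cluster centers, since
  only a distance matrix is guaranteed; coincident medoids yield DBI =
  ∞ rather than an error. Lower DBI is better and selection happens at
  local minima. (One narrative sentence in the source literature claims
  high DBI indicates good clustering; that contradicts both the index's
  definition and the minima-based selection actually used, so the
  standard convention is implemented.)
* The elbow plateau is the smallest count after which every marginal
  gain in explained variance is below 1 percentage point (configurable).
  The selected count is the **largest** DBI local minimum strictly
  beyond the plateau, falling back to the global minimum with a warning.
  The "largest qualifying minimum" reading reproduces the published
  worked example (minima {7,12,15,17}, plateau 14 → 17) but is one of
  several defensible readings of a narrative rule.

## Hydrogen bonds

Donors are N/O atoms carrying a covalent hydrogen (H within 1.25 Å);
acceptors are all N/O (sulfur optional, off by default). The criterion
is D–A distance ≤ 3.5 Å and deviation from linearity below 50°, with the
angle vertex at the hydrogen (∠DHA > 130°). Same-residue pairs are
excluded — backbone-to-backbone bonds between different residues are
kept. Only single-water bridges are reported; multi-water chains are not
traversed. Detection is meant for representative (centroid) structures;
occupancy statistics over trajectories are out of scope.

Groove classification: phosphate = {P, OP1/O1P, OP2/O2P, O3′, O5′};
sugar atoms line the minor groove by convention; base atoms follow
canonical edge tables (e.g. G O6/N7 major, G N3/N2 minor, T O4/C N4
major, C/T O2 minor). Watson–Crick edge atoms that face neither groove
squarely are assigned by convention (purine N1 with the minor-groove C2
side, pyrimidine N3 with the major-groove C4 side); unknown names return
"unclassified" with a warning rather than guessing.

## Binding energies

Single-trajectory convention: receptor and ligand conformations come
from the same complex trajectory, so intramolecular terms cancel exactly
and only cross pairs are computed — electrostatics k q_i q_j/(ε r) with
k = 332.0637 kcal·Å/(mol·e²) and ε = 1 (both configurable), plus
12-6 Lennard-Jones with Lorentz–Berthelot combining, over all pairs with
no cutoff. Cross-pair distances below 0.1 Å are treated as clashes and
rejected.

The nonpolar solvation term is γ·ΔSASA with γ = 0.00542 kcal/mol/Å²,
probe 1.4 Å, Shrake–Rupley sampling on a deterministic Fibonacci point
set (960 points; single-sphere quadrature error < 1% and monotonically
decreasing in the point count). The offset b = 0.92 kcal/mol belongs to
absolute single-structure estimates only; it cancels in binding
differences, which is what makes the estimate vanish exactly at infinite
separation. γ and b are common MM-PBSA defaults exposed in the model
config — the source protocol does not print its values. Exactly
coincident atoms are deduplicated before the surface calculation
(keeping the larger radius) so overlapping duplicates expose one atom's
surface, not two.

Per-residue decomposition attributes each cross pair in full to the
residue on each side, so receptor-side rows and ligand-side rows each
sum exactly to the total pairwise energy (asserted at 1e-6 relative).
The surface term is not pairwise: each residue carries the buried area
of its own atoms and the two sides together sum to γ·ΔSASA. Tables can
be re-based against a named reference run (e.g. wild type at the lowest
temperature) and filtered at the ±1 kcal/mol reporting threshold while
retaining the full table.

**Not implemented:** the finite-difference Poisson–Boltzmann polar
solvation term and normal-mode entropy. Both are projects of their own;
the pipeline accepts externally computed per-frame polar values and a
scalar −TΔS and otherwise reports the MM + nonpolar-SASA estimate,
labeled as such in every output.

## Synthetic data: what it emulates, what it does not

* **Planted-mode trajectories** sample frame displacements as
  Σₖ √λₖ aₖ(t) Mₖ plus isotropic Gaussian noise with aₖ(t) i.i.d.
  standard normal. The covariance analysis only sees second moments, so
  no temporal autocorrelation is generated; a green recovery test
  establishes that the PCA machinery recovers a known covariance, not
  that real MD kinetics are reproduced.
* **Conformation mixtures** draw frames from discrete structures with
  Gaussian jitter — the idealization behind conformational clustering.
  A precondition enforces pairwise conformation RMSD ≥ 5× the jitter so
  planted labels are well defined.
* **Toy complexes** are geometric, not physical: serine-like protein
  residues, an exaggerated acceptor-only DNA ladder (12 Å rise, 16 Å
  strand separation, hydrogens omitted from DNA) and explicitly placed
  bridge waters. Requested bonds are realized by rigidly placing donor
  residues along clash-checked approach directions; the builder re-runs
  the detector and refuses to emit a structure whose detected edge set
  differs from the request, so the fixture's ground truth is exact by
  construction. Toy charges are plausible but not force-field accurate:
  protein residues net 0 e, nucleotides net −1 e, TIP3P-like waters.
* Random generator worlds for recovery tests use a rigid core plus a
  localized mobile "loop", with fitting on the core — mirroring the
  fit-on-Cα / cluster-on-interface protocol. Fully random per-atom
  deformations are avoided because they amplify per-frame fit jitter and
  blur the elbow plateau, a property of the fixture rather than of the
  clustering code.

## Statistical design of the recovery checks

Eigenvalue estimates from a single 2000-frame segment carry an
irreducible sampling error of about √(2/2000) ≈ 3.2% (1σ), plus a small
upward repulsion bias ≈ γσ²/λ with γ = 3N/n_frames from the noise bulk.
The eigenvalue-recovery acceptance test therefore compares the mean over
five replicate trajectories against the finite-sample expectation
(λ+σ²)(1+γσ²/λ) at the 5% tolerance, and asserts eigenvector overlap
> 0.95 per replicate. Comparing a single trajectory's estimate to the
bare planted amplitude would test Monte-Carlo convergence, not the
estimator.

The separation-limit check (binding estimate → 0 at 500 Å) is run with
charges zeroed: with charges on, a neutral-protein/anionic-DNA system
retains a ~10⁻² kcal/mol multipole tail at 500 Å that no pairwise
implementation can remove; that variant is asserted small (< 0.05
kcal/mol) rather than zero.

## Known limitations

* No binary trajectory formats (DCD/XTC); multi-model PDB and XYZ only.
  PDB precision truncates coordinates to 10⁻³ Å and drops frame times.
* No periodic-boundary re-imaging; inputs are assumed whole and
  re-imaged.
* H-bond detection has no occupancy mode; it is per-structure.
* The energy model trusts the topology TSV's charges and LJ parameters;
  it performs no parameter assignment or validation beyond presence.
* Groove classification is name-based; non-standard nucleotide atom
  names fall back to "unclassified".
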