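# Methods

This note records the statistical definitions, parameter choices, and design
decisions behind `slimdock`, and what the synthetic data do and do not
establish about real inputs.

## Conservation profile

The conservation statistic is the per-column Shannon entropy in bits,
`H_j = −Σ_a p_a(j) log₂ p_a(j)`, maximal at log₂ 20 ≈ 4.32 for a uniform
residue distribution.  Two gap policies are exposed because docking-site
alignments are gap-rich and the choice materially changes the profile:

- `exclude` (default): probabilities are renormalised over non-gap residues;
  the gap fraction and effective count are reported per column; an all-gap
  column yields NaN.  This reads the profile as *residue* variability.
- `as_symbol`: the gap is a 21st symbol, so columns that are variable mainly
  through indels also score as variable.

The `X` ambiguity code is treated as gap-equivalent under both policies (and
in p-distances), since no residue distribution can be defended for it.

Logo matrices use information content `R_j = log₂ 20 − H_j` without
small-sample correction by default; the standard bias term
`19 / (2 ln 2 · n_eff)` is available as an option.  Rendering is left to
plotting packages; the export is the per-column probability matrix.

Region extraction is anchored on a named reference sequence in *ungapped*
1-based coordinates (the convention in which "D-site = residues 1–32" is
stated) and maps through the gapped reference to an alignment column span,
keeping internal gap columns.  Sequences entirely gapped within the span are
dropped and counted — the same exclusion logic used when N-terminal regions
are missing from ortholog sets.

## Divergence and grouping

Pairwise distance is the p-distance over pairwise-complete columns (both
sequences non-gap), matching the "distance < 0.2 ⇔ ≥ 80% identity" reading;
pairs with no comparable column are NaN and never form network edges.  The
similarity-network edge rule is strictly `d < threshold`.

K-means needs vectors, so "cluster the similarity network with K-means" is
made concrete as follows: each sequence is embedded as its row of the
distance matrix (distance-profile embedding) and clustered with k-means++
initialisation, 10 restarts, and a fixed seed.  With `k="auto"` the k in
2..8 maximising the mean silhouette is selected (ties go to the smaller k)
and silhouettes for every examined k are reported.  A spectral alternative
(top-k eigenvectors of the symmetrically normalised adjacency with
self-loops, row-normalised) sits behind `embedding="spectral"`.  When even
the best silhouette is below 0.1 the assignment is flagged `degenerate`:
the data do not support real group structure, though labels are still
returned with k forced ≥ 2.

## Motif grammar

The consensus docking motif is `K/R–X–K/R–X₂₋₃–Φ–X–Φ–X₄₋₅–D/E` with five
constrained positions.  Φ defaults to {L, I, V, M}: the motif's hydrophobics
are usually Leu or Ile, and Val/Met are the conservative extensions; the
strict {L, I} reading is one argument away.  The scanner enumerates all
start offsets and wildcard expansions and deduplicates by the key-position
tuple, keeping the shortest span — no "best match" ranking is invented.
Spans are counted inclusively: the grammar covers 13–15 residues
(e.g. positions 3–16 on human MEK1, a 14-residue span with the
X₂₋₃ element at 3 and X₄₋₅ at 4).

## Contact maps and confidence

A residue pair is in contact when any pair of non-hydrogen atoms lies within
the cutoff, read inclusively as ≤ 4.0 Å (the standard contact convention;
the boundary case is tested).  Hydrogens are identified by element, with an
atom-name heuristic fallback for files lacking element columns — predicted
models rarely contain hydrogens but MD-derived frames do.  Residues are
keyed by (chain, author number); insertion codes are rejected with a clear
error (AlphaFold-convention models have none); for altloc atoms the
highest-occupancy conformer is kept.  The implementation vectorises the
all-pairs minimum; tests verify equivalence with a pure-Python brute-force
oracle.

Per-residue confidence is the Cα B-factor (AlphaFold writes identical pLDDT
on all atoms of a residue, so the representative choice is observationally
neutral on conforming files; the mean over atoms is the fallback), binned as
disordered < 50, well-ordered > 70, intermediate otherwise.  Values outside
[0, 100] trigger a warning that the file is not confidence-annotated.

Occupancy maps from trajectories use the same rule per frame; a single-frame
occupancy map equals the binary map of that frame by construction, which is
asserted in tests.

## Dissociation kinetics

The binding order parameter is the distance between the centers of mass of
two selections — by default the backbone atoms ({N, CA, C, O}; O included by
standard convention, configurable) of the D-site keys {3, 5, 9, 11, 16} and
the DRS set {15, 81, 114, 119, 159, 162, 318, 321}.  COM weighting defaults
to atomic masses; a geometric option exists because minimal topologies may
lack masses, and for backbone atoms the two differ negligibly.

`t_D` is the time of the first frame with distance strictly > 15 Å; a single
frame suffices (the definition is the *earliest* crossing; no dwell-time
filter).  `η_i(t)` is 0 before and 1 from `t_D` on; `F(t)` is the average of
the indicators on a shared grid (default: the union of all frame times),
right-continuous so that a trajectory counts as dissociated at its own
`t_D`.  `F` is non-decreasing with values in {k/N} and plateaus below 1 when
some runs never dissociate.

Subdomain RMSD against frame 0 follows
`RMSD(t) = sqrt((1/M) Σ_m ||r_m(t) − r_m(0)||²)`.  The literal formula has
no fit term, but without removing global tumbling it measures diffusion
rather than flexibility, so the recommended mode superposes each frame onto
frame 0 (Kabsch, via SVD-based rotation alignment) using a declared stable
core before evaluation; both modes are implemented and labelled in the
output, and the anchor must have ≥ 3 non-collinear atoms.  Times are ns
internally; readers convert ps-native containers.

## Synthetic data: what it emulates, and what it does not

`generate_group_msa` defaults to four distinct 20-mer consensi, each carrying
one motif instance at keys {3, 5, 9, 11, 16}, 50 sequences per group, 5%
i.i.d. substitution per position (uniform over the other 19 residues).
Under these conditions within-group p-distance is ≈ 0.1 and between-group
distance > 0.5, the planted-partition regime in which network + K-means
recovery should be exact.  An optional indel mode inserts a variable linker
segment with deterministic left-justified gap padding.  The generator does
not model phylogenetic correlation, rate heterogeneity, or alignment error —
so exact recovery here shows the clustering machinery is correct, not that
real ortholog sets split this cleanly.

`generate_trajectory` holds a receptor pseudo-cluster fixed (mass-weighted
COM exactly at the origin) and moves a ligand cluster along x with a
truncated discrete Ornstein–Uhlenbeck separation: stationary mean 7.5 Å, sd
0.8 Å (inside the 5–10 Å band of a stably bound motif), relaxation time
5 ns, clipped at ±4 sd, 1000 frames at 1 ns emulating a 1 μs run.  In escape
mode the separation switches at a planted time (default 300 ns) to a
deterministic outward drift at 0.5 Å/ns, giving an exactly known
first-crossing time for recovery tests; atoms get 0.02 Å Gaussian jitter, so
the measured crossing can shift by at most one frame.  Escape is a planted
switch rather than a sampled barrier crossing precisely so that ground truth
is exact; nothing about force fields, solvent, or thermal ensembles is
represented.

`generate_interface_structure` spaces receptor residues 18 Å apart and
places each planted docking residue ~3 Å from its partner, enforcing the
realizability margins (planted pairs ≤ cutoff − jitter, decoys ≥ cutoff +
jitter) and verifying after construction that the realized map equals the
planted one — geometrically impossible pair sets (e.g. one residue planted
against two receptor residues 18 Å apart) raise a construction error rather
than silently degrade.

## Numerical choices and degenerate inputs

- Entropy/probability code guards all-gap columns (NaN / zero rows) and
  never takes log 0.
- Distance-matrix NaNs (no comparable columns) are excluded from edges and
  mapped to the maximal distance 1.0 in the clustering embedding.
- Strict inequalities: network threshold (`< 0.2`) and dissociation
  threshold (`> 15 Å`); inclusive contact cutoff (`≤ 4.0 Å`).
- K-means ties across k resolve to the smaller k; cluster labels are
  relabelled by first appearance so runs are bit-for-bit reproducible.
- The plain-text frames format requires uniform frame spacing; NaN
  coordinates, ragged atom counts, and mid-stream atom-identity changes are
  hard errors.

## Problem sizes

Default test and reproduction runs use 4 × 50 sequences of length 20, 100
random structures of ≤ 100 atoms for oracle checks, and 50 + 8 trajectories
of 1000 frames × 52 atoms — sizes chosen so the planted effects are
unambiguous while the full suite runs in seconds.

## Known limitations

- Sequence generation is i.i.d. per site; no tree-structured evolution.
- The similarity network feeds clustering only through the distance matrix;
  graph-native community detection is not implemented.
- Contact maps use all non-hydrogen atoms; a sidechain-only variant is not
  exposed.
- No binding free energies, kinetic models, or rate constants are estimated;
  `F(t)` is a descriptive statistic of the supplied trajectories.
- Real MD containers are read through mdtraj; exotic topologies (multiple
  models, insertion codes) are rejected rather than guessed at.
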