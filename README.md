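# slimdock

Analysis toolkit for **short linear docking motifs (SLiMs) at kinase
interfaces**, built around the MEK–ERK system: MEK's intrinsically disordered
N-terminal docking site (D-site) binds the conserved D-recruitment site (DRS)
groove on ERK.  The D-site diverges rapidly across taxa while staying
conserved within lineages, and a handful of key residues carry the binding —
a pattern that calls for joint analysis of sequence conservation, interface
structure, and binding dynamics.  `slimdock` implements that analysis for
anyone studying docking-motif coevolution: computational biologists working
with alignments of kinase orthologs, AlphaFold-predicted complexes, and
molecular-dynamics trajectories.

## What it computes

**Sequence layer** (`conservation`, `divergence`, `motif`)

- Per-column Shannon entropy of a gapped alignment,
  `H_j = −Σ_a p_a log₂ p_a` (bits), with explicit gap policy and gap-aware,
  reference-anchored extraction of a domain such as "residues 1–32".
- Pairwise p-distance over pairwise-complete columns; a similarity network
  connecting sequences with distance < 0.2 (≥ 80% identity); K-means groups
  on the distance-profile embedding with silhouette-selected k.
- The docking-motif grammar `K/R–X–K/R–X₂₋₃–Φ–X–Φ–X₄₋₅–D/E`
  (Φ = {L, I, V, M}) with a scanner that enumerates every wildcard
  expansion.  On human MEK1 the five key positions are 3, 5, 9, 11 and 16.

**Structure layer** (`contacts`)

- Binary interchain contact maps: residue pairs with any non-hydrogen atom
  pair within 4.0 Å, optionally restricted to declared subsets (the five
  D-site residues × eight DRS residues).
- pLDDT disorder classification from the B-factor column (AlphaFold
  convention): disordered < 50, well-ordered > 70.

**Dynamics layer** (`kinetics`)

- Center-of-mass distance between backbone-atom selections; the dissociation
  time `t_D` as the first frame exceeding 15 Å; the indicator `η_i(t)` and
  the pooled cumulative fraction dissociated `F(t) = (1/N) Σ η_i(t)`.
- Contact occupancy over frames and subdomain RMSD against frame 0, with or
  without Kabsch superposition on a stable core.

**Synthetic layer** (`synth`)

Seeded generators for every input class — grouped motif-bearing alignments,
planted-contact two-chain complexes, and bound/escape trajectories with an
exactly known dissociation time — so the whole pipeline is testable without
alignment programs, structure predictors, or MD engines.

## Worked example

```sh
slimdock demo --seed 17 --outdir demo_run
```

runs the full synthetic pipeline and prints (abridged):

```json
{
  "cluster_k": 4,
  "cluster_ari_vs_planted": 1.0,
  "cluster_silhouette": {"2": 0.528429, "3": 0.728568, "4": 0.937037, "5": 0.844799},
  "motif_key_position_count": 5,
  "planted_contacts_recovered": true,
  "bound_fraction_dissociated_end": 0.0,
  "escape_fraction_dissociated_end": 1.0,
  "config_hash": "158164e21ecbc890",
  "summary_hash": "9f2e45ded9772360"
}
```

Reading the numbers: silhouette peaks at k = 4, so the four planted sequence
groups are found with perfect agreement (ARI 1.0); the scanner constrains
exactly five key residues; the contact map recovered from the written PDB
equals the planted ground truth; bound-mode trajectories never cross the
15 Å threshold (`F(end) = 0`) while every escape-mode trajectory does
(`F(end) = 1`).  Rerunning with the same seed reproduces the identical
`summary_hash`.

Individual stages are available as subcommands, e.g.

```sh
slimdock entropy --msa aln.fasta --gap-policy exclude --out entropy.tsv
slimdock cluster --msa dsite.fasta --threshold 0.2 --k auto --seed 17 --outdir out/
slimdock scan --fasta seqs.fasta --pattern default
slimdock contacts --structure complex.pdb --chains A,B --cutoff 4.0 \
    --subset-a 3,5,9,11,16 --subset-b 15,81,114,119,159,162,318,321 --out cmap.tsv
slimdock dissociation --traj run1.xyzt --traj run2.xyzt \
    --sel-a 'MEK:3,5,9,11,16:backbone' \
    --sel-b 'ERK:15,81,114,119,159,162,318,321:backbone' --threshold 15 --outdir out/
```

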