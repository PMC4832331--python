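# Methods

This note records the models, conventions and design choices behind
`ldcsig`, in the order the pipeline uses them.

## Genetic-environment classification

Two rules, applied in priority order to a gene's flanking-gene record:

1. **ldcI-like** — a cadB-family antiporter gene is adjacent, on the
   same strand, and flagged as belonging to the same operon;
2. **ldcC-like** — the gene is flanked by an accA-family gene and a
   yaeR-family gene, in either order.

Gene families are matched by case-insensitive synonym lists
(configurable; defaults `cadB`, `accA`, `yaeR`). Operon membership is
an input flag, never inferred from intergenic distance — no distance
cutoff is defensible from annotation tables alone. If both rules fire
the call is `unknown` with evidence `ambiguous`; partial contexts
(e.g. accA present, yaeR absent) are `unknown` rather than guessed.
The audit flags a conflict whenever the stated annotation (`ldcI`,
`cadA` → ldcI-like; `ldcC` → ldcC-like) maps to the opposite group of
the rule-based call.

## Alignment

Pairwise global alignment is Needleman–Wunsch with affine gaps,
BLOSUM62, gap open 10, gap extend 0.5; a gap of length L costs
open + (L−1)·extend. **Percent identity** counts identical non-gap
pairs over all columns except double-gap columns (so gap-vs-residue
columns count in the denominator); **percent similarity** additionally
counts residue pairs with a positive BLOSUM62 score. These conventions
are stated because reported identity values are meaningless without
them; under a local-alignment or gaps-excluded convention the numbers
shift by a few points.

The multiple aligner is a deliberately minimal progressive scheme:
k-mer (k = 3) distances, a UPGMA guide tree, and profile–profile
Needleman–Wunsch merged leaf-to-root, with profile columns scored as
the expectation of BLOSUM62 over the two frequency vectors (gap
fractions score zero; gap penalties live in the DP states). It is not
an iterative-refinement aligner and does not try to replicate any
specific MSA package; for the ~70%-identical, indel-poor families this
package targets, a single progressive pass aligns the signature
regions correctly, which the tests verify against planted ground
truth. Column indices are 0-based internally, 1-based in reports;
residue numbering is 1-based throughout, and signature positions in
non-reference sequences are always located through the alignment to
the reference sequence (cross-species numbering drifts).

## Consensus, signature and chimeras

Per-column residue frequencies are observed counts (X spread uniformly
over the 20 residues); conservation defaults to the majority-residue
relative frequency in [0, 1], with an information-content mode
(log2 20 − H, bits) available. Polarity classes are a fixed table:
acidic {D, E}, basic {K, R, H}, hydrophilic {S, T, N, Q, C, G, Y},
hydrophobic {A, V, L, I, P, F, M, W}. Assigning tyrosine to the
hydrophilic class is a judgement call (its aromatic ring argues the
other way); the table is fixed so that outputs are reproducible.

The signature is the concatenation of the two β-strand regions,
631–640 and 697 to the C-terminus (E. coli LdcI numbering; reference
length 715). Classification is a two-group log-odds sum over non-gap
signature positions with pseudocount 0.5 per position (spread over the
20 residues) against a uniform 1/20 background; gapped positions carry
no evidence, an all-gap signature returns `unknown`, and a
configurable margin (default 0) can force `unknown` for near-ties.
Discriminating positions are reported data-driven as the positions
whose per-group majority residue sets are disjoint; the Y697/K697
dimorphism is the one externally fixed expectation and is planted in
the synthetic generator's defaults.

Chimera design swaps the aligned donor segment into the backbone
inside each signature region (donor insertions strictly inside a
region are carried along; everything outside is byte-identical to the
backbone) and emits a junction table with the backbone and donor
coordinate spans of each swap. A donor that is entirely gapped across
a region is an error, not a silent empty swap.

## Phylogeny

Distances: p-distance; Poisson correction −ln(1−p), capped at 5.0
substitutions/site once p ≥ 0.85 (capped pairs are flagged as
saturated); or WAG maximum-likelihood, the branch length t maximising
Σ_sites log(π_a P_ab(t)) by bounded 1-D optimisation (t ∈ [1e−8, 5],
xatol 1e−8) using the published WAG exchangeabilities and stationary
frequencies embedded as constants (eigendecomposition of the
π-symmetrised rate matrix, normalised to one expected substitution per
site; printed frequencies are renormalised to sum to exactly 1). No
rate heterogeneity (+Γ) is modelled. Gapped columns are excluded
pairwise.

Trees are Saitou–Nei neighbor joining. Q-matrix ties break to the
lexicographically smallest pair of current node indices; negative
branch lengths are clamped to zero with a warning. The tree is
reported unrooted. The choice of NJ on WAG-ML pairwise distances —
rather than a full maximum-likelihood topology search — keeps both
named model components while staying a distance method; full ML search
is out of scope. Bootstrap supports come from column resampling with a
seeded PRNG: support of an internal edge is the percentage of
replicate NJ trees containing its bipartition. The two-group question
is answered exactly: a tree separates groups A and B iff some internal
edge induces precisely that leaf bipartition; the pipeline reports
tree-group membership only in that case, and "not separable"
otherwise, rather than fabricating a grouping.

## Structural comparison

Models are Cα-only, keyed by (chain, residue number); PDB and mmCIF
are read with gemmi, altlocs resolve to the highest-occupancy
conformer (ties to 'A'), and insertion codes are rejected outright.
The five-domain partition is wing 1–129, linker 130–183, PLP-SD
184–417, subdomain 4 418–563, CTD 564–715 (core = linker + PLP-SD +
subdomain 4).

Superposition is least-squares rigid-body with proper rotations only;
near-collinear point sets (second singular value < 1e−8 of the
largest) are rejected as degenerate. **In-context RMSD** of a domain
is computed after a single global superposition — whole-decamer by
default, per-monomer optionally, since published protocols often leave
this unstated — with no per-domain refit; **RMSD_min** refits each
domain optimally, so RMSD_min ≤ in-context holds for every cell and is
asserted on every report. Cross-protein model pairs are paired
per-chain by global sequence alignment (gapped columns dropped);
same-protein states pair by residue number. Summaries report min and
max over the ten monomers, matching the range phrasing used for such
assemblies. Segment centroid shifts are reported both as Euclidean
displacement and as the radial component relative to the 5-fold axis,
which is estimated as the unique principal-inertia direction of the
decamer when not supplied.

## Synthetic data: what it emulates, and what it does not

The family generator mirrors the natural study conditions: 11 taxa per
group by default (22 total), 715-residue proteins, signature regions
631–640 and 697–715, disjoint group-specific residues at every
signature position with (Y, K) pinned at 697, tree height 0.5 and
between-group separation 0.5 expected substitutions/site. Topologies
are random sequential joins with exponential edge lengths scaled so
root-to-tip paths average the requested height; background columns
evolve by per-branch transition matrices (a uniform 20-state
exchange model by default — group separation, not evolutionary
realism, is what the fixtures need — with WAG optional); signature
columns are drawn per leaf from the group's allowed set and are
indel-protected. Indels default off so reference numbering is trivial;
when enabled they are leaf-wise deletions only. Everything is
determined by the seed, and outputs are byte-identical across runs.

Toy decamers are five Gaussian point clouds (σ = 3 Å, distinct
centroids, guaranteeing non-degenerate superpositions) per monomer,
ten copies placed with exact D5 symmetry; the "moved" copy applies a
stated rigid swing (rotation about an axis through the CTD centroid)
and stretch (radial translation) to the CTD in each monomer's local
frame. Because the displacement field commutes with the D5 group, the
optimal global superposition is the identity, so a stretch of d Å
reads back exactly as CTD in-context RMSD = d with RMSD_min = 0 —
that is the parameter-recovery oracle.

What passing on synthetic data does **not** show: real families have
rate heterogeneity, correlated sites, partial operon annotations and
ambiguous contexts; real decamers deform non-rigidly and their maps
limit model accuracy. The synthetic results validate the machinery,
not the biology; the reference-data checks (E. coli sequence pair,
deposited decamer models) exist for the latter and require the user to
supply the public files listed in the README.

## Numerical conventions and edge cases

* Superposition tolerances: rotations are proper to 1e−9 in the
  determinant; identity-case RMSDs are treated as zero below 1e−6
  (SVD noise floor).
* Distance saturation: Poisson cap 5.0 at p ≥ 0.85; WAG-ML upper
  bound 5.0, hits flagged.
* NJ ties: first (lowest-index) minimum of the Q matrix; this makes
  trees reproducible across runs and platforms.
* Alignment traceback prefers the diagonal move, then horizontal,
  then vertical, at equal score.
* Degenerate inputs raise typed errors (`AlignmentError`,
  `PhyloError`, `SignatureError`, `StructureError`, `SyntheticError`,
  `ContextError`, `PipelineError`) rather than returning silent
  defaults.
* Problem sizes in the test suite and acceptance script (20+20-taxon
  families, 100 bootstrap replicates, 50 seeds for the concordance
  sweep, 1000 superposition oracle instances) were chosen as the
  smallest sizes at which the checked properties are sharp; all run in
  about a minute on one CPU.

## Known limitations

* The progressive MSA has no iterative refinement; very gappy or
  low-identity families may misalign signature regions.
* WAG-ML distances are pairwise composite likelihoods, not a joint
  tree likelihood; branch supports are NJ-bootstrap, not ML.
* The context classifier trusts the input operon flag and synonym
  lists; it does not predict operons or detect genes.
* Chimera design assumes the backbone/donor alignment is locally
  correct inside the swap regions; junctions are reported so users can
  inspect them instead of relying on asserted construct lengths.
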