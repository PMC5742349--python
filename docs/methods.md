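# Methods

This note documents the models, conventions, and numerical choices behind
each analysis stage, what the synthetic-family generator does and does not
emulate, and the known limitations of the toolkit.

## Scope and design stance

The toolkit analyses SWEET/SemiSWEET-like membrane transporter families at
the sequence level: screening candidate records, building sequence
similarity networks (SSNs), classifying repeat-unit architecture, profiling
conservation and coevolution on multiple alignments, building
distance-based trees, and doing the arithmetic of MM/PBSA binding-energy
decompositions. Several stages are deliberately transparent stand-ins for
heavyweight externals a large-scale study would use (an HMM topology
predictor, BLAST-based all-vs-all search, ClustalW, MISTIC, maximum
likelihood tree inference): each stand-in is a simple, deterministic,
oracle-testable algorithm with the same interface role, not a re-creation
of the external tool's numerics. Where that matters per stage, it is noted
below.

## Synthetic families (module `synthetic`)

The generator emulates the statistical structure the pipeline assumes,
with planted ground truth for every feature a stage is supposed to recover.

**Geometry.** The ancestral repeat unit is loop–helix–loop–helix–loop–
helix–loop: three hydrophobic blocks (drawn from {L,I,V,F,A,M}) of 28
residues separated by hydrophilic loops (drawn from {K,R,E,D,N,Q,S,T,G,P})
of 12 residues. A PQ dipeptide replaces the last two residues of the first
loop, just upstream of the first helix; the motif-bearing loop carries no
other proline, so the planted PQ is unambiguous. Architectures are built
by concatenating units and single-helix linkers (one 28-residue block plus
a 12-residue loop): 3 TMH = one unit; 7 TMH = unit–linker–unit; 15 TMH =
four units with three linkers; other counts expand by the same greedy rule
the architecture stage uses. The block length of 28 gives the hydropathy
predictor (window 19, threshold 1.6, minimum run 15) a detection margin of
roughly two windows per block edge, so each block is called as exactly one
helix even under substitution noise; shorter blocks (≈21) sit on the
detection boundary and were rejected for that reason.

**Divergence.** Each family member is drawn independently from the family
ancestor: every site mutates with probability `substitution_rate` and is
resampled uniformly within its hydropathy class (hydrophobic ↔
hydrophobic, loop ↔ loop). This decouples mutation noise from topology
truth: divergence never destroys a planted helix. There are no indels
(fragments aside), so full-length family members share the ancestral
coordinate system and align gap-free.

**Planted features.**

- *Invariant columns* are never mutated. The generator writes a distinctive
  tryptophan at each planted invariant site (configurable via
  `invariant_residue`): W belongs to neither mutable class and carries the
  highest BLOSUM62 self-score, which both mirrors the real family — whose
  single most conserved position is an aromatic — and makes planted-truth
  recovery identifiable. An invariant alanine would be genuinely
  indistinguishable, under a sum-of-pairs conservation score, from a
  90%-conserved proline column; that is a property of the score, not a
  bug. The PQ motif positions are additionally kept unmutated (the screen
  stage filters on the motif); they are reported separately in the family
  truth table (`pq_columns`).
- *Covarying pairs* only ever hold state combinations from an explicit
  table (default E/K ↔ K/E, drawn 50/50 per sequence), the idealised limit
  of compensatory charge swaps. `demo_scenario` places both invariant and
  covarying sites in loop regions so the planted residues cannot perturb
  helix detection.
- *Fragments* truncate a record to a uniformly random 20–45% contiguous
  window — guaranteed to fail the fragment filter at its default 50%
  cutoff. *Duplicates* are byte-identical copies under fresh, lexically
  later accessions, so the dedupe rule retains the original.
  Injection counts are deterministic (`round(rate × n)`), with the victims
  chosen by the seeded stream; this makes statements like "exactly 3
  duplicates among 20 records" constructible.

**Truth tables.** Per sequence: family, TMH count, architecture class,
element spans, fragment flag, duplicate source. Element spans are cut at
the midpoints of the hydrophilic gaps between consecutive elements'
hydrophobic blocks — the same loop-midpoint convention the architecture
stage uses — so decomposition output is directly comparable to truth.
Per family: ancestral length, plan, invariant columns, PQ columns,
covarying pairs. One integer seed drives a single `numpy` Generator; equal
inputs give byte-identical FASTA and truth output.

**What is not emulated.** No indel evolution, no rate heterogeneity, no
phylogenetic correlation structure within a family (members are i.i.d.
draws from the ancestor), no codon-level process, no compositional bias
beyond the two-class alphabet. Tests passing on these families show the
pipeline recovers planted signal under the stated noise model; they do not
certify behaviour on real families with indels, long-branch structure, or
heterotachy.

## Screening (module `screen`)

Filters run in a fixed order — dedupe → fragment → motif → TMH count — and
each removed record gets the first failing reason only.

- *Dedupe* removes byte-identical sequences, keeping the lexicographically
  smallest accession (deterministic, input-order independent). Note that a
  zero-divergence family is itself collapsed by this rule; screening
  recovery tests therefore run at non-zero substitution rates.
- *Fragment* means length < 0.5 × median length of the post-dedupe set
  (the threshold fraction is configurable). The definition is relative
  because absolute length cutoffs do not transfer across families with 3-
  vs 25-TMH architectures.
- *Motif*: a dipeptide scan for PQ (`strict_PQ`) or P alone (`relaxed_P`)
  within the first predicted helix extended by a 10-residue flank. The
  relaxed mode exists because the glutamine of the dipeptide is conserved
  only in part of the family. This is a literal scan, not a profile/HMM
  domain search.
- *TMH count*: sliding-window Kyte–Doolittle hydropathy. A position is a
  helix candidate iff the mean hydropathy of the 19-residue window centred
  on it is ≥ 1.6; candidate runs separated by gaps shorter than 3 are
  merged; merged runs of length ≥ 15 are helices. Window, threshold,
  minimum length and merge gap are all configurable. Positions closer than
  half a window to either terminus are never candidates (no partial
  windows). This is a transparent stand-in for HMM topology prediction:
  adequate for strongly amphipathic sequences, it will undercall helices
  with charged faces and has no concept of membrane orientation.

## Similarity network (module `ssn`)

All-vs-all exact Smith–Waterman local alignment (BLOSUM62; gap of length g
costs 11 + (g−1)·1) via Biopython's `PairwiseAligner`, converted to
Karlin–Altschul statistics: bitscore = (λS − ln K)/ln 2 with gapped
constants λ = 0.267, K = 0.041 (configurable — the constants of any
particular BLAST build are compile-dependent), and e-value = m·n·2^(−bit)
with m the query length and n the total residue count of the input set
(BLAST-like search-space convention, made explicit). Percent identity is
counted over the columns of one optimal alignment, including internal gap
columns; an all-negative pairing is the empty alignment — raw score 0,
identity 0. Edges with e-value ≤ the cutoff (default 1e−55) are kept;
clusters are connected components; components of ≥ 10 members are labelled
1, 2, … by decreasing size with ties broken by smallest member accession,
and each labelled cluster gets a taxon-composition table (fractions
summing to 1). Exact alignment rather than a seeded heuristic keeps the
stage deterministic and oracle-testable at desk scale; an optional k-mer
prefilter exists for larger inputs but is off by default.

## Architecture (module `architecture`)

Class is a pure function of helix count: {3,4} semiSWEET, {6,7} SWEET,
{14,15} extraSWEET, ≥ 18 superSWEET, else atypical. The bins are
configuration, not code constants, because the 14/15 and ≥18 anchors come
from a handful of reported proteins. Decomposition is greedy left-to-right:
a triplet of helices, then a single-helix linker whenever at least one more
triplet follows; a single trailing helix is a linker (giving the canonical
3/4/7/15 plans); a trailing pair is marked unresolved. 25 helices therefore
decompose to 6 triplets + 5 linkers + 2 unresolved — counts with no exact
plan are handled rather than rejected, since 18- and 23-TMH proteins exist
without a published decomposition rule. Residue spans are cut at the
midpoints of inter-helix loops so each unit carries its flanking context
(fusion evidence compares whole repeat units, not bare helices). Fusion
evidence aligns each triplet unit's span against every reference sequence
(same scoring as the SSN stage) and flags units whose best identity is
≥ 70%.

## Alignment and conservation (module `msa`)

Progressive alignment: 3-mer multiset distance → UPGMA guide tree (ties in
joins broken by smallest member accession) → profile–profile global
alignment under BLOSUM62 with affine gaps (open 10, extend 0.5; a gap of
length g costs open + g·extend), with fixed DP tie preference
(match > gap-in-second > gap-in-first). Everything is deterministic, unlike
typical aligner builds; there is no iterative refinement. Ungapping any
output row reproduces its input sequence exactly (tested invariant).

Column conservation is a weighted sum of normalised pairs:
raw(c) = Σ_{i<j} w_i w_j · s_norm(a_i, a_j) over rows without a gap in c,
where s_norm is BLOSUM62 min–max normalised to [0,1] and w are sequence
weights (uniform, or inverse-cluster-size after single-linkage clustering
at 62% identity). The profile is rescaled so the best column reads exactly
100 — the convention of setting the highest conserved amino acid to 100 —
and columns that are mostly gaps (> 50%) are scored but excluded from the
normalisation maximum, so alignment artifacts cannot claim the anchor.
The underlying per-column score is this package's own declared definition;
it is not ClustalW's (unpublished) formula, and numeric conservation
values are not comparable across scoring schemes — only the normalised
ranking is meant to be.

Logo matrices use information content log2(20) − H(c) from non-gap
frequencies, without small-sample correction, with per-residue heights
f_a·bits. The reference map sends alignment columns to reference residue
numbers (strictly increasing over mapped columns) for reporting positions
in a chosen numbering such as a structural reference.

## Coevolution (module `coevolution`)

Raw MI (natural log) between column pairs from weighted, optionally
pseudocounted joint frequencies over pairwise-complete rows (gap-as-21st-
symbol available by flag); pairs where either column has fewer than 5
usable rows are skipped. Because raw MI scales with entropy and sample
size, significance uses an explicit shuffle null: the second column's rows
are permuted n times (≥ 20; default 100) from one seeded stream, and
mi_z = (MI − null mean)/null sd (sd floored at 1e−12). The significance
threshold (default 6.5) is interpreted on this standardised scale — a
declared convention of this package, since the provenance of the published
threshold's scale is ambiguous; the shuffle null gives it a defined
meaning here. Significant edges are ranked by raw MI and coloured: top 5%
(ceiling) red, down to the 70th percentile (floor of 25%) black, the
remaining ~70% gray. cMI(c) sums raw MI over significant pairs containing
c; proximity MI averages cMI over residues within a radius (default 5 Å)
of each residue, excluding itself, using representative-atom coordinates
(Cα by convention) keyed by reference numbering. Z-scoring all O(L²) pairs
is quadratic in columns times shuffles; the pipeline stage therefore
z-scores only the top pairs by raw MI (default 200, configurable).

## Phylogeny (module `phylo`)

Distances between aligned rows: p-distance (1 − fraction identical over
pairwise non-gap columns) or Poisson-corrected −ln(identity), capped at
10.0 for saturated pairs. Trees are canonical neighbor joining on the
Q-criterion with ties broken by smallest accession pair; negative branch
lengths are clamped to zero with the deficit moved to the sibling edge, a
standard NJ repair that preserves path lengths through the joined pair.
Bootstrap resamples columns with replacement per replicate (seeded);
support of an internal bipartition of the point-estimate tree is the
percentage of replicate trees containing it. NJ + bootstrap is a
deliberate desk-scale stand-in for likelihood-based inference: adequate
for clade-recovery questions on strongly separated synthetic families, it
makes no claim to reproduce ML topologies, branch lengths, or likelihoods
on real data. Newick output carries supports as internal-node labels and
round-trips through the package's parser (lengths to 1e−9).

## Energetics (module `energetics`)

Pure bookkeeping over per-residue component tables exported from an MD
package: E_MM = E_ele + E_vdw; G_sol = G_polar + G_np; G_total = E_MM +
G_sol − TΔS. The nonpolar term is linear in solvent-accessible surface
area, G_np = γ·SASA + β, defaults γ = 0.0054 kcal/mol/Å², β = 0.92
kcal/mol. TΔS is an input constant defaulting to 0 — entropy estimation is
noisy and commonly omitted when comparing residues within one
receptor–ligand series — so the identity stays complete without
pretending to compute entropy. A residue is flagged favorable iff
G_total < 0 (ties unfavorable by convention). All energies kcal/mol, SASA
in Å²; no Poisson–Boltzmann solving, SASA computation, docking, or
trajectory analysis happens here.

## Pipeline and fixtures (module `pipeline`)

`run_all` executes generate → screen → ssn → architecture → msa_profile →
coevolution → phylo in order (energetics independently, from a supplied
component table), writing each stage's tables under one output directory
and a JSON run report recording parameters, seeds, output paths and row
counts; the report is checked against a packaged structural schema
(required keys and types; the validator is in-package and minimal).
Configurations reject unknown keys by name. Reruns with equal
configuration are byte-identical.

The packaged mutation-outcome table transcribes the 19 most conserved
family positions with their tested substitutions and phenotypes
(13 abolish / 2 reduce / 4 no effect), joined to a residue-region
annotation (extrafacial gate, binding pocket, intrafacial gate). The
region assignment is shipped annotation used for labelling output; the
spatial clustering itself is not computed here.

## Problem sizes and tolerances

Synthetic studies in the tests and the acceptance script use 1–2 families
of 8–50 members (7-TMH ancestors ≈ 300 residues), chosen as the smallest
sizes at which the planted effects are statistically unambiguous: 25
members at substitution rate 0.3 for conservation recall (at 25 members
the probability that any unplanted column stays near-invariant by chance
is ≪ 1 per alignment), 50 members for MI significance (planted-pair
z-scores land near 30–50 against a 6.5 threshold), 8–10 members per
family for network separation and bootstrap support. Numerical
tolerances: alignment-score and MI oracle agreement to 1e−9; energy
additivity to 1e−9; conservation's top column is exactly 100 by
construction. Unit-boundary recovery is asserted to ≤ 2 residues at zero
noise and ≤ 3 under 5% substitution: the hydropathy detector's run edges
carry a residue or two of jitter, so exact boundary equality is not a
meaningful target even noise-free.

## Known limitations

- The TMH predictor, aligner, MI pipeline and NJ trees are transparent
  stand-ins; none reproduces the numerics of the external tools a
  large-scale survey would use, and results on real data will differ in
  detail (helix edge placement, alignment of low-identity pairs, MI
  values, deep-branch topology).
- Conservation values are score-definition-dependent; only the
  rank/normalised profile is interpretable.
- The e-value model uses fixed Karlin–Altschul constants; absolute
  e-values shift with the constants, so network comparisons should hold
  the parameter set fixed.
- The generator's i.i.d.-from-ancestor model understates the correlation
  structure of real families; recovery rates measured here are upper
  bounds relative to data with phylogenetic structure.
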