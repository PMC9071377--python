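# Methods

This note documents the models, rules and numerical choices behind
`bhlhkit`, and what the synthetic validation does and does not show.

## Domain model and search

The bHLH domain is represented as a 51-column frequency profile
(basic region columns 0–13, helix 1 to 28, loop to 36, helix 2 to 51)
built from a packaged **synthetic** seed alignment
(`synthetic_seed_profile.py`): eight constructed sequences around a
single consensus with the canonical bHLH architecture.  It is a
constructed reference, not a transcription of a curated HLH profile;
its purpose is a fully specified, testable profile whose rule-relevant
columns are known exactly.  Column scores are log2-odds
`log2(((f + 0.2/20) / (occupancy + 0.2)) / (1/20))` with a flat 1/20
background; `X` scores 0.

Search is a semi-global affine-gap dynamic program (gap open 5, extend
1 in score units): the whole profile must be consumed while the protein
flanks are free, so a hit is a placement of the complete domain.  Ties
at the optimum resolve to the first (leftmost) placement and, within
the traceback, to match over deletion over insertion.  The acceptance
threshold is the 99th percentile of scores over 1,000 residue shuffles
of the consensus (seed 0); the calibrated value (0.3066) is frozen in
the package and reproducible with `calibrate_score_threshold`.

## Binding cascade and intron patterns

DNA-binding classification follows a fixed cascade on the located
domain: (1) fewer than 6 residues from {K, R, H} in the basic region →
non-binding ("more than five basic residues" read literally as ≥ 6;
both the residue set and the threshold are configurable); (2) E-box
binding requires E at the E-2 column and R at R-4; (3) E-box binders
with H or K at H/K-1, E at E-2 and R at R-5 are G-box binders.  A
gapped rule column fails its requirement.  The four rule columns ship
as profile metadata (columns 3, 6, 10, 12 of the packaged profile) and
can be overridden together with a custom profile.

Introns are mapped from gene models into CDS coordinates and kept when
they fall inside `[3·domain_start, 3·domain_end)`; phase is position
mod 3.  Three canonical positions (domain offsets 39, 93, 129 nt —
basic/helix-1 junction, loop, helix 2) with a ±6 nt tolerance define an
occupancy signature; the twelve pattern codes are a packaged, editable
table over (occupied subset, any-non-canonical): I = {1,2,3}, IX = {2},
XI = ∅ are fixed; II–VIII and X cover the remaining signatures and O is
the fallback.  Two introns hitting one canonical position demote it to
non-canonical occupancy.

## Synteny and tandem duplication

Collinear blocks are maximal-score chains of homology anchors per
chromosome pair and orientation: anchors sorted by gene rank, chain
score = Σ match − Σ 0.05·(rank gaps), strict rank monotonicity on both
sides (decreasing second side for inverted blocks), per-side gap cap of
25 ranks, minimum 5 anchors per block, match score 1 — the defaults of
the standard collinearity tools, all exposed as parameters.  The best
chain is extracted repeatedly (ties: smaller starting rank), each
anchor joining at most one block.  Ortholog pairs are family anchors
inside inter-genomic blocks; OGs are connected components of those
pairs, with unpaired family genes forming species-specific OGs (merged
with same-species homologs only via supplied tandem co-membership
pairs).  Whether OGs must be supported in all pairwise species
comparisons or any single one is not fixed by the underlying
literature; this implementation uses "any".  Tandem clusters are
connected runs of same-chromosome homologs within ≤ 1 intervening gene
(configurable), named T1, T2, … per species in coordinate order.

## Substitution rates

Ka/Ks uses Nei–Gojobori (1986) counting: per-codon synonymous site
fractions enumerate all nine single-nucleotide changes, with changes to
stop codons counted as nonsynonymous, so S + N = 3 × codons exactly;
observed differences average with equal weight over all minimal
mutational pathways whose intermediates avoid stops (if every pathway
crosses a stop, all pathways are used); Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p); pS ≥ 3/4 or pN ≥ 3/4 flags saturation and
leaves the corrected value undefined.  The protein aligner behind the
codon alignment is global Needleman–Wunsch–Gotoh (BLOSUM62, open −10,
extend −0.5).  The method choice is recorded in the output
(`method="NG86"`), as the classic counting mode of the usual Ka/Ks
calculators.

## Trees, clades, expansions

Protein distances use partial deletion (columns with < 80 % non-gap
coverage removed) and either p-distance or the Poisson correction
−ln(1−p); maximum-likelihood JTT distances are deliberately not
implemented — at the divergences involved here topology-level
conclusions are insensitive to that choice, and the Poisson correction
keeps the dependency surface small.  Neighbor joining follows
Saitou–Nei with the Q-criterion, lexicographic tie-breaks and negative
branch estimates clamped to zero (flagged).  Bootstrap resamples
columns with replacement, seed-deterministically; support is the
fraction of replicate trees containing each reference bipartition.

Clade assignment without anchors cuts the leaf metric at its k−1
deepest splits by single-linkage agglomeration (closest groups merged
first, ties by smallest label pair).  This is the robust reading of
"cut the deepest divergences": selecting the k−1 longest internal
edges directly proved fragile under among-lineage rate variation,
occasionally isolating a fast-evolving ortholog instead of separating
the ancient duplicates.  With anchors, leaves join the nearest anchor
group by path length and the groups must form connected subtrees.

For the regulator cluster, the tree is built from a reference-anchored
full-CDS codon alignment rather than the 51-column domain alignment:
cluster members are close homologs, and the ~6× larger column count is
what makes clade assignment stable (the star alignment is exact for
indel-free families and an approximation otherwise).  The ancestral
copy number of the cluster is the number of clades containing
main-cluster genes.  Expansion calls: within a clade, a species with
≥ 2 genes is a post-speciation expansion iff max intra-species Ks <
min inter-species Ks; absence is a loss; saturated pairs are excluded
with a warning.  Ks < 0.32 additionally marks a duplication as recent
(the empirical post-divergence cutoff; configurable).

## Expression

FPKM matrices are transformed elementwise as log2(FPKM+1) (missing
samples stay missing).  "Predominant expression" is operationalized —
the source analyses never quantify it — as: the tissue attains the
unique row maximum, the maximum is ≥ 1 FPKM, and exceeds the runner-up
≥ 2-fold on the linear scale; both thresholds are configurable.  *Brp*
candidates are the root-predominant members of the OG paralogous to the
tandem-bearing regulator OG, restricted to the clade holding most such
genes.

## Synthetic pangenome generator

The simulator emulates the comparative setting the pipeline targets: a
clade of diploid genomes (default 3 taxa, root 18 MYA; a 7-taxon tree
with a recent WGD on one deep lineage is also packaged) sharing an
ancient tetraploidization at 90 MYA.  Defaults, chosen once as
field-realistic values: 24 ancestral genes on 2 chromosomes, 110
codons per gene, segmental retention 0.4 after the shared polyploidy
(retained copies appended, in order, to the other chromosome — which
is what makes WGD siblings recoverable from intra-genomic collinear
blocks), per-branch gene-loss probability 0.03, tandem rate 0.03
duplications/gene/branch with children inserted adjacent to parents,
proposal mutation rate 0.006 substitutions/site/MY (mid-range for
plant nuclear genes) and dN/dS 0.2 on every branch (purifying
selection).  Divergence times are configurable constants, not
estimates.

Codon evolution is a proposal–acceptance process: point mutations
proposed at the branch's expected rate with an HKY-like transition
bias (kappa default 1.0, i.e. uniform proposals — this keeps the
equal-rate NG86 site counting an unbiased reader of the simulated
omega; raise kappa to study that bias), accepted with probability 1 if
synonymous and omega if nonsynonymous, so realized dN/dS equals omega.
Proposals creating stops are redrawn among the remaining targets,
which slightly depresses realized rates at stop-adjacent codons.

Each gene carries a planted domain drawn from the packaged consensus
with category-realizing residue edits, and introns realizing a chosen
pattern (mixes default to a realistic skew: IX 40 %, I 25 %, XI 15 %,
the rest spread over the minor codes).  The 13 basic-region codons are
frozen during evolution, modelling the near-absolute conservation of
the DNA-contacting residues; helices, loop and flanks evolve freely.
Consequences: planted binding categories and intron patterns are
exactly recoverable, and the recovery tests therefore validate the
classification *machinery*, not its robustness to domain erosion.

A regulator-cluster architecture is planted by default: one
mid-chromosome family is forcibly retained through the tetraploidy
(with two flanking neighbors on each side, so the duplicated segment
chains into a block), its primary lineage expands to three tandem
copies at 50 MYA (the main cluster), its polyploid sibling to two
copies at 70 MYA (the paralogous cluster), one paralogous-cluster gene
per species gets root-biased expression (the *Brp* analog, 6-fold bias,
log2-noise sd 0.3), and the second taxon receives a two-copy tandem
expansion of the cluster at 2 MYA (the post-speciation expansion the
Ks rule must detect).

Homology anchors are emitted inter-genomically only between genes of
the same post-polyploidy lineage and intra-genomically between all
same-family genes.  This emulates a similarity-thresholded anchor
list: after ~90 MY the cross-species out-paralog similarity falls
below a sensible anchor cutoff while orthologs and within-genome
duplicates remain above it.  It also makes the ground-truth ortholog
groups well defined.  Real anchor tables will contain out-paralog
anchors, and on such inputs OG recovery depends on the anchor cutoff
chosen upstream — a limitation of what the synthetic validation shows.

Other features of real data the generator does not emulate: indels,
annotation errors and split/merged gene models, unplaced scaffolds,
nucleotide composition bias, intron gain/loss, gene conversion between
tandem copies, and expression batch structure.

## Problem sizes and runtime choices

The packaged validation runs at deliberately modest sizes — 3 species,
~110 genes total, 110-codon genes, 100-replicate bootstraps in the
pipeline default (the `bootstrap_support` function itself defaults to
1,000), 100 Monte-Carlo replicates per omega in the recovery check,
500 random chaining instances and 200 random additive matrices in the
oracle comparisons — chosen so the whole suite and the acceptance
script complete in seconds while every check retains clear
discriminating power.

## Known limitations

* The NG86 estimator is the classic counting method; it ignores
  transition/transversion bias and codon-frequency effects, and its
  Ka/Ks is noisy for short genes (the per-pair variance at 110 codons
  is visible in the paralog summaries — the median, not the maximum,
  is the stable statistic).
* The domain profile is synthetic; applying the pipeline to real
  proteomes calls for building the profile from a curated domain
  alignment via `build_domain_profile` and recalibrating the
  threshold.
* Single-linkage clade cutting assumes clade divergences are deeper
  than within-clade divergences; heavily rate-heterogeneous families
  should use anchor-guided assignment.
* The star codon MSA is exact only for indel-free clusters; for
  indel-rich families an external MSA can be supplied to the distance
  and bootstrap functions directly.
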