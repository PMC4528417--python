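# Methods

## The problem

Antibody heavy chains are assembled by V(D)J recombination: one germline V,
D and J segment are joined with exonuclease trimming and non-templated
(N-)nucleotide addition, then diversified by somatic hypermutation.
Recovering which germline alleles produced an observed read is the first
step of repertoire analysis.  Germline V genes are phylogenetically
structured — families form clades — so this package treats assignment as a
*phylogenetic placement* problem rather than a best-hit search: the read's
V and J segments are attached to fixed reference trees under a substitution
model, and the uncertainty of the assignment is quantified by model
averaging instead of being hidden behind a single hit.

## Reference construction

IMGT-dialect germline FASTA files are parsed (numbering periods stripped;
pseudogenes excluded by default, included with a flag), and sequence-
identical alleles are collapsed with a synonym map so downstream evaluation
treats them as interchangeable.  V and J alignments are kept separate and
joined only at scoring time; V alignments are codon alignments (length a
multiple of 3) carrying FR1–3/CDR1–3 column boundaries, J alignments carry
the column of the conserved tryptophan and of the `[FW]G.G` joining motif,
located by scanning reading frames for a motif position shared by ≥80% of
rows.

Reference trees may be imported as newick.  The built-in fallback is
neighbor joining on pairwise maximum-likelihood distances, rooted on the
longest internal branch that renders all families monophyletic (midpoint
otherwise), followed by a GTR + branch-length fit on the fixed topology.
Topology search beyond NJ is deliberately out of scope: placement accuracy
depends mainly on branch lengths and labels, not on fine topology.

Internal nodes are labelled by two rules: a node with a child at zero
branch length (tolerance 1e-9 substitutions/site) inherits that child's
label, because a zero-length branch implies an identical sequence; any
other node receives the most resolved level of the allele > gene > family >
region hierarchy shared by all its descendant leaves.  Ancestral sequences
for every internal node are reconstructed by joint maximum likelihood
(max-product dynamic programming with traceback), ties broken by the fixed
nucleotide order A < C < G < T; a node is gapped only where its whole clade
is gapped.  The substitution model throughout is nucleotide GTR with
empirical base frequencies, exchangeabilities fitted by coordinate ascent
(branch-length Brent sweeps alternating with Nelder–Mead on log
exchangeabilities; the log-likelihood trace is non-decreasing by
construction).  A codon model would change ancestral reconstructions only
marginally at the divergences involved and would cost two orders of
magnitude more per query.

## Query mapping

Each read is locally aligned — affine gaps, both strands — against the
reconstructed V+J MRCA concatenation and every primary (*01) V × *01 J
concatenation; the best-scoring mapping transfers reference columns onto
query positions.  Scoring is nucleotide-level (match 5, mismatch −4, gap
open 10, gap extend 1), with the reading frame carried over from the
template's codon structure rather than re-derived by protein-level DP: the
queries this tool targets are substitution-dominated, the templates are
codon-clean, and the junction logic only needs a frame anchor (the FW3
cysteine codon).  Orientation is settled once against the MRCA template and
the panel is scanned on that strand, unless the two strand scores are
within 10% of each other, in which case every template is tried on both
strands.  Reads are declared unmappable when their best score falls below a
self-calibrated floor: mean + 3 SD of the scores of dinucleotide-shuffled
copies of the first query (30 shuffles, seeded), computed once per run.

The junction runs from the FW3 3′-cysteine codon (last codon of the FR3
reference block) to the first `[FW]G.G` motif on the cysteine-anchored
codon grid within the J region; when the motif has been mutated away, it
ends at the alignment-mapped column of the conserved tryptophan.  CDR3 is
reported as the junction interior (exclusive of the cysteine codon and the
motif).  A read is productive when the junction is in frame and the mapped
translation is stop-free.  Ambiguity codes are treated as missing data in
both alignment and likelihood.

## Placement and model averaging

A rearrangement hypothesis is (V branch, J branch, breakpoint): query
positions 5′ of the breakpoint are scored in the V tree, the rest in the J
tree.  Attaching a query mid-branch and re-optimising only the three
adjacent branch lengths is a three-taxon problem by time reversibility.
The branch endpoints are represented by the inside and outside
partial-likelihood messages of the reference tree — not by point ancestral
sequence estimates — so the three-taxon computation *equals* the full-tree
attachment likelihood exactly (the test suite asserts the identity to
1e-6 against grafting the query onto the tree and running full pruning).
In the GTR eigenbasis the likelihood profile along any single branch length
is `sum_k W_k exp(lambda_k t)`, so each line search costs a 4-term
exponential per column; Brent line searches over (t_q, t_p, t_c), each
clamped to [0, 10], are cycled until the log-likelihood improves by less
than 1e-6 (max 50 cycles).  The kernels are numba-compiled.

Fitness is AIC_c = −2 logL + 2k + 2k(k+1)/(n−k−1) with k = 7 — six branch
lengths plus the breakpoint; GTR parameters are fitted once per bundle and
shared by all models, so they cancel in model comparison — and n the number
of reference columns covered by the query (fixed per query, so AIC_c
ranking equals likelihood ranking across that query's models).  Every
distinct model evaluated during the search receives an Akaike weight
`exp(−0.5 ΔAIC_c)` normalised over the evaluated set.

The search is a CHC genetic algorithm on a bitstring genome (binary-encoded
branch indices and breakpoint grid index; out-of-range decodings wrap):
population 32, elitist truncation of the merged parent+child pool, HUX
uniform crossover that swaps half the differing bits, incest prevention via
a Hamming-distance threshold (genome length / 4) decremented on stagnation,
and cataclysmic restarts that rebuild the population by flipping each elite
bit with probability 0.35.  The search stops after 3 consecutive restarts
without improving the best AIC_c, and is reproducible given its seed.  The
breakpoint domain is a 1-nt grid from 30 nt 5′ of the mapped FW3 cysteine
to the first J-aligned position (3-nt grid for the exhaustive oracle, which
scores every model and is used in tests and as a fallback on small
references).

Weights are summed by (V label, J label) of the attachment branches; the
top pair is the call and every pair at ≥0.01 joins the credible set
(marginal per-region supports are reported alongside).  One geometric
subtlety: a model whose fitted parent-side length is zero places the query
*exactly at the parent node*, the same point reached from every branch
meeting there.  Such models are labelled by the parent node — the same
identical-sequence reasoning that underlies zero-branch label propagation —
otherwise a single placement splits its weight across sibling-branch
labels and can push the true allele's support below 0.5 on even unmutated
reads.

D alleles are outside the phylogenetic machinery: every dictionary entry
(forward and reverse complement) is Smith–Waterman-aligned (affine gaps;
match 5, mismatch −4, open 10, extend 1) to the junction nucleotides; all
alleles tied at the maximum score are reported as equally likely, and
scores below 15 (three matched codons) yield "no D assigned".  Low D
accuracy under trimming and mutation is an expected property of short,
eroded D segments, not a defect; the evaluation tables document it.

## Simulation (ground truth)

`simulate_simple` emits the Cartesian product of *01 V × D × J
concatenations.  `simulate_rearrangement` samples alleles with inverse
alleles-per-gene weights (genes equiprobable), draws the four deletion
lengths and the two N lengths independently, fills N regions from a base
composition vector, and keeps a draw only if the read is stop-free,
contains a CDR3 matching a configurable pattern (default `C[A-Z]{2,32}W`),
and has an in-frame J with the `[FW]G.G` and `TVSS` motifs.  Hypermutation
follows the S5F scheme: position weights are 5-mer mutabilities (terminal
two positions immutable) recomputed after every substitution so newly
created contexts matter, and the replacement base is drawn from the 5-mer's
substitution profile.  Already-mutated positions are excluded from later
draws, so the Hamming distance to the parent is exactly the requested
mutation count.  Clonal families share one rearrangement and are mutated
independently.

Published deletion/N-length and S5F tables are not shipped; loaders accept
them as TSV (`load_length_table`, `S5FModel.from_tsv`).  The defaults are
explicit synthetic stand-ins: geometric deletion lengths (mean 1 for V3′,
2 for both D ends and J5′), geometric N lengths (mean 4), uniform N
composition and a flat S5F.  Checks that depend on these defaults are
therefore directional (V/J stay high while D degrades), not numeric.

## Synthetic reference generator

The generator emits a reduced-scale analogue of a heavy-chain locus:
4 V families × 3 genes × 2 alleles (98 codons; family ancestors ~7%
diverged, genes ~3%, alleles 1–2 nt; conserved FR3-terminal cysteine; one
family carries a one-codon CDR1 deletion so the alignment is genuinely
gapped), 10 short D genes in 3 families whose members differ by only a few
bases (the realistic source of D ambiguity), and 3 J genes × 2 alleles
(7 variable codons + WGQG motif + TTVTVSS tail).  Everything derives from
one integer seed.  What this does **not** emulate: sequencing error,
indel hypermutation, allele-frequency skew, primer effects, and the sheer
allele density of the real locus — so passing tests demonstrate algorithmic
correctness and the published accuracy *pattern* at reduced scale, not
real-data performance figures.

## Evaluation conventions

Per region, reads are tallied as correct_top (true allele has the highest
model-averaged support, synonyms allowed), correct_in_credible (true allele
present but outweighed), ancestral (an internal gene/family label that is
an ancestor of the true allele — reported in its own column rather than
silently counted either way), wrong (with the wrong-gene subset), and
no_assignment; the headline `correct` column is correct_top +
correct_in_credible, matching the usual benchmarking convention.  D calls
count correct when the true allele is in the tied top-score set.  Clonal
clustering joins reads whose credible sets share a (V, J) pair and takes
connected components (the relation is symmetric, so strongly connected
components reduce to ordinary ones); clone aggregation reports the
unweighted mean of per-read pair supports (a sum variant is available).

## Problem sizes and numerical choices

The shipped experiments (test suite and `scripts/acceptance.py`) use 150
reads per evaluation dataset, 12 clones × 15 members, a 100-query
GA-vs-exhaustive oracle comparison, and the synthetic reference above —
sizes chosen so the full exhaustive oracle stays tractable and the whole
evaluation reruns in minutes on one core.  Percentage thresholds in tests
follow a three-binomial-SE band at the n actually used.  Branch lengths are
clamped to [0, 10] substitutions/site; likelihoods are scaled per column to
avoid underflow; Brent tolerance is 1e-5 on lengths and 1e-6 on logL;
ties everywhere (labels, templates, argmax sets) break lexicographically or
by fixed nucleotide order for determinism.  Queries are independent: any
execution order, including process-parallel maps, yields identical
per-read output.

## Known limitations

* D assignment is a deliberately simple alignment heuristic; its accuracy
  collapses under trimming and mutation.
* The GA is stochastic; rare failures to reach the global AIC_c optimum are
  expected (the oracle-comparison rate is itself a reported quantity).
* Akaike weights are conditional on the reference set: missing alleles
  inflate support for their nearest present relatives.
* Gapped J alignments are not supported by the motif scanner; J references
  must be ungapped (true of the real locus' J set).
* No chimera detection, UMI handling, paired-end merging or quality use.
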