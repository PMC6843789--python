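# Methods

This note records the models, parameter choices and known limitations of
`epsclust` in one place. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Homology model

Pairwise protein comparison is local Smith–Waterman under BLOSUM62 with
affine gaps costing `open + k·extend` for a gap of length k (open 11,
extend 1 — the familiar protein-BLAST defaults). The ambiguity letter X
scores 0 against everything. Percent identity is matches over alignment
columns (gap columns included); coverage is the aligned fraction of each
sequence's full length, times 100. Because local alignment is symmetric,
one alignment yields both "directions" of a reciprocal test: the a-side
and b-side coverages are evaluated separately and both must pass. Ties on
score resolve to the traceback with the most alignment columns, then the
lowest end cell, making results independent of input order.

The kernel is a numba-compiled Gotoh DP (score, traceback and
identity/coverage bookkeeping in one pass). The test suite checks it
against an independently written plain-Python DP on short sequences, and
checks score symmetry and identity monotonicity under mutation ladders.

No E-values are computed anywhere: E-values need database-size statistics
that have no meaning in a self-contained run. Reference-library searches
(seeds, neighbourhood expansion, role assignment) filter on identity
> 30%, coverage ≥ 50% and raw score ≥ 100 — the score floor plays the
role of a stringent E-value cut-off, since chance local alignments
between unrelated proteins of these lengths rarely exceed score ~60
while genuine homologs clearing the identity/coverage bar score
several-fold higher. The family graph filters on identity ≥ 50%/35%
with coverage ≥ 50% on both sides, where reciprocal full-length coverage
already makes chance hits vanishingly unlikely. Coverage for seed and
role assignment is taken on the gene-product (query) side: a genuinely
truncated cluster gene aligns over its whole remaining length and still
receives a role (and a truncation flag), while short spurious local
matches cannot clear half of a full-length query. An all-vs-all pair is
skipped without aligning only when the length ratio alone proves the
longer sequence's coverage cannot reach the threshold — a bound that is
exact, so the shortcut can never drop a passing pair.

## Cluster detection

Seeds are CDS matching any EpsA–EpsE reference. From each seed the walk
proceeds over the record's feature order (annotation adjacency, not
base-pair distance — robust to annotation density); a neighbour is
EPS-related if it aligns to any reference-library protein at the
neighbour threshold or its product text matches a curated keyword list
(glycosyltransferase, polysaccharide, flippase, polymerase, epimerase,
mutase, dehydratase, transposase, acetyltransferase). More than `max_gap`
(default 2) consecutive unrelated genes end the walk, and trailing
unrelated genes are trimmed, so interior insertions (hypothetical genes,
mobile elements) are spanned but flanking housekeeping genes are not
absorbed. Pseudogenes stay out of all alignment stages; inside a
neighbourhood they can still join a cluster through their annotation
text. Clusters sharing a feature merge; a cluster needs at least two
genes. Clusters with no seed-role gene at all are not discoverable — a
documented limitation shared by any seed-anchored search.

`max_gap` formalises what is otherwise a manual judgement about where a
cluster ends; it is exposed in the run configuration.

## Roles, GT families, topology

Each cluster gene receives exactly one role: best reference hit first,
annotation keyword as fallback, `Other` last. Flippase/polymerase calls
must be consistent with a polytopic membrane topology (≥ 8 predicted
helices) or they fall to `Other`. A protein shorter than half the median
length of its role's references is flagged truncated (the cut-off is a
package choice; truncation marks likely non-functional products).

GT family labels follow a two-method agreement rule: (1) the family of
the best-scoring reference alignment, and (2) the family whose
concatenated reference 4-mers contain the largest fraction of the query's
4-mers (containment ≥ 0.2, and the top family must clear the runner-up by
more than 0.05 to count as a vote). A family is reported only when both
methods name the same one; everything else is `unknown`. The margin rule
exists because a near-equal split (e.g. a two-family chimera) should not
produce a confident label from either method. This preserves the
conservatism of multi-tool CAZyme annotation without external binaries or
trained models.

Transmembrane helices come from Kyte–Doolittle hydropathy: every
19-residue window with mean ≥ 1.6 is a candidate; candidates are accepted
greedily by descending mean, keeping ≥ 3 loop residues between helices.
Orientation uses the positive-inside rule (K+R summed over alternate
loops under both topologies; ties default to an inside N-terminus), so
the C-terminus side follows from the N-side and helix-count parity. This
is a deliberately simple, self-contained stand-in for HMM-based topology
predictors: adequate for counting helices in strongly polytopic
transporters and for terminus calls, with no per-residue posteriors and
no signal-peptide discrimination.

## Architecture classification

Clusters whose majority strand is "−" are reversed before order checks,
so every cluster reads from its regulatory 5′ end. A cluster is *generic*
iff its first five non-transposase genes are EpsA, EpsB, EpsC, EpsD,
EpsE in exactly that order; transposases are skipped because mobile
elements are insertions, not architecture. Completeness is the set
difference between the essential checklist {epsE, gt, wzx, wzy, epsC,
epsB} (and dispensable {epsA, epsD}) and the roles present as non-pseudo,
non-truncated genes; whether truncated-but-present genes count as present
is a flag (`count_truncated_as_missing`, default true). GC deviation is
pooled per-role gene GC minus whole-record GC (N excluded from both
numerator and denominator). Transposase adjacency is immediate
feature-order neighbourhood or span nesting; run-level proportions are
adjacent genes over all genes of the role.

## Protein families and diversity

The similarity graph is clustered with Markov clustering implemented on a
dense column-stochastic matrix: identity-weighted edges, self-loops at
each node's maximum incident weight (1 for isolated nodes), alternating
expansion (matrix squaring) and inflation (elementwise power +
renormalisation), pruning entries < 1e-5, until the maximum elementwise
change is < 1e-8 or 200 iterations (non-convergence warns and interprets
the current matrix). Clusters are attractor systems with overlapping
systems merged; family ids derive from the lexicographically smallest
member, so the partition is invariant to input order.

Families are two-level: loose families from edges at identity ≥ 35%
(inflation 1.5), strict families from the ≥ 50% edge subset clustered
independently inside each loose family (inflation 2.0) — strict ⊂ loose
holds by construction. The two thresholds play the role of genus-level
versus cross-genus family granularities in pan-genome family systems;
they are an analog, not a reproduction, of any external family
assignment. Inflation defaults were chosen so that families planted at
the 50%-identity edge threshold are recovered (the synthetic
family-recovery experiment in the tests); both are configurable.

Per-role diversity statistics (protein counts, families at both levels,
proteins per strict family, strict per loose, % singleton families,
multicopy copy/family means) are computed over non-pseudo cluster genes
only, with ratios rounded to one decimal.

## Comparison and habitat analysis

The presence/absence matrix is binary over (family, cluster); rows and
columns are sorted for determinism. Hierarchical clustering uses Jaccard
distance on the 1-entries with average linkage — a standard choice for
sparse binary profiles; both are configurable and recorded in the run
manifest, and the group count k at which the tree is cut is a user
parameter (no automatic selection). Identical columns merge at height 0.
The dendrogram is exported as Newick.

Habitat sharing places each role's families into one of 7 Venn regions
by the set of habitats of the strains contributing members; singleton
families are tallied separately from multi-member families, and
unknown-habitat material is excluded (counted, not silently dropped).
Strain habitat resolves through a strain → (species, habitat) table with
species fallback; unknown strains resolve to `unknown`, never an error,
and are excluded from sharing analysis.

## Synthetic data: what it emulates, what it does not

The generator's defaults define the benchmark conditions. Per-strain
cluster counts are drawn from {1, 2, 3, 4} with probabilities
0.65/0.25/0.09/0.01 — the proportions observed among complete
*Lactobacillus* genomes — with a rare plasmid-borne cluster (p = 0.03).
Habitat proportions are 0.5/0.35/0.15 host-adapted/nomadic/free-living.
Generic layouts occur with probability 0.65 in host-adapted strains, 0.5
in free-living, and 0 in nomadic strains, whose clusters lack *epsA*
entirely; non-generic layouts arise by per-gene dropout (highest for
*wzy*, 0.25, and *epsD*, 0.20) or relocation of one 5′ gene. Genes for
*gt*/*wzx*/*wzy* are back-translated 8 GC points below the 0.45 genome
background; transposases are inserted in 35% of clusters, 60% of the time
immediately beside *wzx*. Family pools are per-habitat: each role has a
per-habitat ancestor with two strict branches (ancestor identity 0.76,
giving sister-family member identities of roughly 40% — inside the loose
threshold, outside the strict one), and members mutate from their strict
reference at 85% identity with BLOSUM62-biased substitutions and exact
substitution counts. Wzx families carry 10–14 planted helices (mode 14),
Wzy 8–12 (mode 10). Pseudogene and truncation probabilities are 0.06 and
0.05. Housekeeping filler genes come from an unrelated random pool that
demonstrably never reaches the seed thresholds, so spurious seeds are
impossible by construction.

GC targeting is composition control, not a codon-usage model: codons are
sampled with per-base probabilities matching the target and then
greedily swapped until the realised GC is within ~0.15 GC points of the
closest achievable value. Back-translated genes always start with ATG
(the initial methionine is never mutated).

Precursor-enzyme and transposase pools are global by default — these
genes travel between lineages, so sharing them across habitats is the
realistic choice — and one common ancestor is kept per CAZy-style GT
family, so occasional cross-habitat family joins can occur, as they do in
real repertoires. With `disjoint_habitat_pools=True` every pool (GT,
precursor, transposase included) gets independent per-habitat ancestors,
making the habitats fully unrelated at the family level; that is the
configuration used for the habitat-recovery checks (dendrogram cut at
k = 3 versus habitat labels; zero cross-habitat families).

What the generator does **not** emulate: nucleotide-level evolution (no
indels by default, no dN/dS, no recombination), realistic codon usage,
operon-internal regulatory structure, annotation errors, or genome-scale
gene content (synthetic replicons are tens of kilobases, tens of genes —
sizes chosen so the full benchmark runs in about a minute on one CPU).
Passing the synthetic benchmarks therefore demonstrates the pipeline's
internal correctness — recovery of exactly the structure the generator
planted under the stated noise — not performance on real annotation
quality or real evolutionary divergence patterns.

## Numerical and degenerate-input choices

GC of an all-ambiguous interval is NaN, never 0. An empty sequence is an
alignment error; a zero-score alignment reports identity/coverage 0. MCL
inflation is validated to [1.2, 6]. Group cutting validates 1 ≤ k ≤
number of leaves. Jaccard distance between two all-zero columns (both
clusters lacking every family, impossible in practice since families come
from cluster proteins) is treated as 0. GenBank parsing uses /translation
verbatim when present, else translates the spanned sequence with
bacterial table 11 honouring /codon_start, warning on a missing start
codon; compound (join) locations are out of scope. Coordinates are
0-based half-open internally, converted at the I/O boundary.
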