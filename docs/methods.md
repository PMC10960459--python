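# Methods

## Scope and model

`mitorearr` analyses the order of the 37 genes (13 protein-coding genes, 2
rRNAs, 22 tRNAs) on circular mitochondrial genomes. A genome is a signed
circular permutation: each gene carries an orientation, `+` for the
reference transcription strand and `-` for the opposite strand. Two physical
readings of one molecule — any rotation, and the strand-flipped reading in
which the sequence is reversed and every orientation toggled — describe the
same arrangement. The package makes that equivalence explicit instead of
relying on manual pattern comparison.

### Canonical form and arrangement patterns

Canonicalization rotates the order so that `cox1` comes first and, if `cox1`
lies on the minus strand, reflects the whole order first so that `cox1` is
always `+`. The anchor choice is pragmatic: `cox1` is single-copy and
present in every usable mitogenome, and anchoring makes pattern identity a
plain tuple comparison. Canonicalization is idempotent and constant on each
rotation/reflection orbit (property-tested on 1000+ random orbit elements).
Arrangement patterns are the equivalence classes of canonical forms;
pattern ids are assigned in first-seen input order from 1.

Genomes with missing or duplicated genes are rejected outright: the analysis
assumes exactly one copy of each of the 37 genes, and no partial-content
distance variant is provided. Non-coding regions (e.g. the control region)
do not participate.

### Breakpoint distance

An adjacency is an ordered pair of neighbouring signed genes; reading the
circle from the other strand maps `(a, b)` to `(-b, -a)`, and the two forms
are identified. For two genomes of identical gene content the breakpoint
distance is `Bp = n - |shared adjacencies|`, counting the wrap-around
adjacency because the molecules are circular (with 37 genes, `Bp` can reach
37). This is the breakpoint statistic produced by gene-order comparison
tools for circular mitogenomes; rearrangement-scenario inference, common
intervals, signed inversion distance and DCJ are deliberately out of scope.

Exact single-event laws hold under this convention and are asserted in the
tests: one inversion changes `Bp` against the pre-event order by exactly 2;
one transposition or inverted transposition by exactly 3 (segment length at
most `n - 2`, destination distinct from the origin).

### Gene clusters and synapomorphies

A gene cluster is an ordered, oriented run of at least two genes. A genome
contains the cluster if its genes occur contiguously, in sequence and
orientation, in either reading direction (`(a, b, c)` also matches
`(-c, -b, -a)`). A bounded number of intervening genes may be tolerated
(`max_insertions`, default 0), which formalizes variants such as a two-gene
cluster interrupted by a single translocated tRNA in a few taxa. Because
each gene occurs exactly once, the minimal insertion count for a reading is
determined by gene positions alone.

A cluster is a synapomorphy candidate for a taxon set when every member
contains it, and neither the ancestral arrangement nor any outgroup or
non-member does. "Derived" is always judged against the hypothetical
ancestral arthropod arrangement, which matches the gene order of the
horseshoe crab *Limulus polyphemus* (identical to the fruit-fly order except
that `trnL2` sits next to `trnL1` between `nad1` and `rrnL`); the fixture is
packaged and immutable.

Maximal exactly-shared clusters are found through conserved adjacencies:
a run is shared by a set of genomes iff each of its internal adjacencies is
conserved in all of them (each gene being unique, pairwise adjacency
conservation forces contiguity), so maximal shared clusters are maximal
paths of conserved adjacencies — an O(n · taxa) computation verified in the
tests against a brute-force window scan.

### Cladogram assembly

Clade hypotheses are taxon sets with supporting clusters. Three sources are
supported:

* **named clusters** (config-driven): each named cluster, with its own
  insertion tolerance, defines the set of taxa matching it — this is how
  published groupings with explicitly listed cluster variants are
  reproduced and audited;
* **candidate clades**: explicit taxon sets, supported by their exclusive
  derived clusters;
* **greedy default**: the atomic derived characters. Every adjacency absent
  from the ancestor defines the set of taxa carrying it; the set is then
  corroborated by the longer maximal clusters (up to `max_len`, default 8)
  its members share exclusively. Defining sets by adjacencies rather than by
  arbitrary longer windows is deliberate: a longer window can combine a
  derived junction with an ancestral adjacency that a nested clade
  subsequently destroyed, producing a taxon set that is not a clade; the
  adjacency characters are the standard encoding for gene-order parsimony
  and are exact when junctions are not reused.

Accepted hypotheses must form a laminar family (any two nested or
disjoint) — exactly the sets representable as one rooted tree. Conflicts
are resolved in a fixed order: more supporting clusters wins, then the
larger taxon set, then the set with the lexicographically smallest member
id. Every rejection is logged, never silent. Unplaced taxa attach as
polytomies at the deepest compatible node; an empty cluster set yields a
star tree. Newick output labels internal nodes with their supporting
clusters (hyphen-joined, `~` marking minus-strand genes).

## NG86 Ka/Ks

Synonymous and nonsynonymous rates are computed with the Nei–Gojobori
(1986) counting method under the invertebrate mitochondrial genetic code
(translation table 5; configurable). Per codon, each position contributes
the fraction of its three possible point mutations that are synonymous;
mutations that would create a stop codon count as nonsynonymous, so
`S + N = 3 × codons` holds exactly. Pairwise differences are classified
along all substitution pathways with equal weights (2 pathways for two
changed positions, 6 for three); pathways passing through a stop codon are
excluded, and in the degenerate case where every pathway is blocked all
pathways are used. Sites are averaged across the two sequences; codons with
gaps or ambiguity codes are excluded pairwise; an internal stop codon is an
error naming the offending codon. Proportions are Jukes–Cantor corrected,
`K = -(3/4)·ln(1 - (4/3)·p)`; `p ≥ 3/4` is past saturation and sets the
`Ks_saturated` flag (or yields an undefined `Ka`). The implementation
agrees with an explicit enumeration oracle to 1e-12 and is exercised
against simulated pairs with known rates.

The breakpoint–rate correlation is a plain Pearson coefficient with
`df = n - 2` and a two-sided p-value from `t = r·sqrt(df/(1 - r²))`.
Maximum-likelihood dN/dS and site-rate heterogeneity are out of scope.

## Simulation and study conditions

The rearrangement simulator evolves a gene order along a rooted tree.
Events per edge are Poisson with mean `rate × branch length` per kind
(inversion, transposition, inverted transposition — the three kinds
observed in mitogenome rearrangement; tandem duplication–random loss is not
modelled because the data the package targets contain no duplicated genes).
Segment lengths are geometric (default `p = 0.5`, capped at `n - 2`):
short segments dominate observed mitochondrial rearrangements. A single
seed governs all draws; per-edge streams derive deterministically from
(seed, edge id) so subtree draws are stable under edits elsewhere. The
event log is complete: replaying it from the root reproduces every tip
bit-exactly, which the tests assert.

`simulate_clade_markers` produces the regime in which synapomorphy logic is
exact: one event per internal edge, rejection-sampled so that created
adjacencies are globally novel and are never broken on descendant edges,
with a post-hoc presence/absence verification. Under these conditions every
derived adjacency marks exactly one clade, and cladogram recovery is exact;
the acceptance measurements run 100 replicates at 8–16 taxa. Deeply
pectinate trees with many nested events can exhaust the 37-gene alphabet
and trigger the rejection-budget error, which is reported rather than
worked around.

`simulate_codon_pair` generates ground truth for the NG86 estimator. The
ancestor is uniform over stop-free codons; the descendant receives at most
one substitution per codon, with per-codon probabilities `pS*·S_c` and
`pN*·N_c`, where `pS*`/`pN*` are the Jukes–Cantor forward-mapped targets
and `S_c`/`N_c` the codon's site fractions. A nonsynonymous draw whose
sampled target would be a stop is realized as a different nonsynonymous
non-stop change in the same codon, so the expected counted differences stay
on target while both sequences remain translatable. Restricting to one
change per codon keeps pathway averaging out of the expectation, making the
estimator's recovery property sharp (mean estimate within sampling error of
the target; measured at true Ka = 0.3 with 3000 codons × 100 replicates).
Targets implying a per-codon substitution probability above 1 are rejected
as beyond saturation.

### The fig1_mini fixture

A 12-taxon engineered fixture carries scaled-down analogues of published
eriophyoid synapomorphy clusters: `nad6-trnT-cob` shared by all taxa,
`trnR-trnI` marking one two-taxon clade, `nad2-trnM` marking a seven-taxon
clade with one member carrying the 1-insertion variant `nad2-trnC-trnM`,
`trnS1-trnI` marking a nested five-taxon clade and the rRNA block
`trnY-trnQ-trnV-trnL2-rrnS-rrnL` marking the innermost three taxa. Run with
its named-cluster config (per-cluster tolerances), the cladogram reproduces
the intended 5-clade nested topology with the variant taxon placed
correctly and no conflicts.

## What the synthetic data do and do not show

The simulator emulates the combinatorics of gene-order evolution: event
kinds, Poisson counts along branches, clade-defining junctions, and codon
pairs with controlled rates. It does not emulate nucleotide-level realism
(no indels, no compositional bias, no tRNA structure), gene duplication or
loss, control-region rearrangement, or rate variation among lineages.
Passing tests therefore certify the correctness of the distance, matching,
grouping and counting machinery under known ground truth — not that any
particular empirical data set will be free of homoplasy or junction reuse.
On real genomes, reused junctions will surface as logged cladogram
conflicts, which is the intended behaviour.

## Numerical and degenerate-input choices

* Adjacency and cluster identity use a deterministic lexicographic
  representative of the two reading directions, so equivalent forms collide
  in hashed sets.
* Cluster matching rejects tolerant matches whose walk would lap the whole
  circle (span bounded by `n`).
* Orders identical up to rotation/reflection share the whole circle as a
  single cluster.
* Unknown gene names fail loudly; the synonym table is packaged data and
  extendable at run time (`register_synonym`), and leucine/serine tRNAs
  without an anticodon family are errors, never guesses.
* Pearson correlation requires `n ≥ 3`, finite values and nonzero variance.
* All tables are TSV; trees are newick; the pipeline stamps outputs with
  the package version and a hash of the analysis-determining config fields.

## Problem sizes used in the shipped measurements

Oracle-agreement checks use 1000 random circle pairs (n = 4–12) and 200
random 100-codon pairs; orbit invariance uses 1000 orbit elements;
synapomorphy and cladogram recovery use 100 replicates each at 6–16 taxa;
Ka recovery uses 100 replicates of 3000 codons. These sizes give the
properties sharp expected values (rates of exactly 1, RF of exactly 0)
while keeping the whole measurement suite under a minute on one CPU.
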