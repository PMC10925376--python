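# Methods

## Graph model

A pangenome gene graph has one vertex per gene and one bidirected edge per
observed adjacency.  Orientation matters: an oriented gene is `>v` or `<v`,
and the reverse complement of an adjacency `x -> y` is `ȳ -> x̄`.  Edges are
stored once under a canonical key (the lexicographically smaller of
`(x, y)` and `(ȳ, x̄)`) with both directed views synthesized on access, so
skew symmetry is unviolable by construction.  Multi-edges are disallowed —
edge identity is the ordered oriented pair, and repeated contig support
accumulates in the edge's support set — while self edges (`>B -> >B`, the
signature of a tandem duplication) are allowed and handled by every
traversal.  Genes appear in the graph only by appearing in a walk; edges
only arise from walks.

Edge scores: `S(x|y)` is the arithmetic mean, over the contigs supporting
`x -> y`, of the alignment score of `x`'s placed occurrence in that
adjacency (occurrences repeated on one contig are averaged within the
contig first).  `S(x|y)` and `S(ȳ|x̄)` are stored separately; they are
generally unequal because they average scores of different genes.

## Annotation and selection

Inputs are per-genome PAF records of protein-to-genome alignments.  A
protein named `<GeneID>:<ProteinID>` belongs to gene `<GeneID>`; when a
gene has several proteins, the one maximizing the summed per-genome
best-hit score is kept.  Hits without splicing are suppressed when the gene
has a spliced hit elsewhere (likely processed pseudogenes); a strict mode
additionally drops genes that are never spliced, and `off` disables the
filter (appropriate for bacteria).

Redundant (orthologous) input genes are collapsed by the `b(v)`
competition: `b(v)` counts genomes where `v`'s best hit beats every
overlapping best hit of another gene (overlap = same contig and
intersection >= 50% of the shorter interval, configurable down to 1 bp;
score ties are broken by the 64-bit FNV-1a hash of the gene name so runs
are reproducible across platforms).  Genes are then accepted greedily in
descending *current* `b(v)` — a lazy-deletion max-heap re-verifies the key
at pop time — and each acceptance decrements, once per genome, the `b` of
every overlapping higher-scoring competitor, floored at zero.  Genes popped
at `b = 0` are rejected.  Orthologs at one locus collapse to a single
representative; paralogs at distinct loci survive.

Per-contig annotation then places hits of selected genes greedily by
score, skipping hits that overlap an already placed one; every placed,
coordinate-sorted contig becomes a walk.

## Graph adjustments

Two heuristics repair systematic mis-annotation, in this order:

1. **False edges** (ratio `r1`, default 0.95).  `x -> y` is false when some
   alternative `x -> z` exists with gene(y) and gene(z) on different
   contigs in *every* genome carrying both (genomes carrying at most one
   are ignored; genes that ever share a contig are exempt) and
   `S(x|y) < S(x|z) * r1`.  Placed hits of gene(x) realizing a false
   adjacency are deleted and the walks re-joined.  This repairs, e.g., a
   genome that lacks a chromosome entirely, whose genes would otherwise
   map onto a paralogous locus of another chromosome and create spurious
   cross-chromosome edges.  The pass is idempotent on simulator output.
2. **Low-priority edges** (ratio `r2`, default 0.98).  When the competing
   far genes *do* co-occur on a contig, the weaker adjacency's gene
   occurrences are only demoted: they inherit a low-priority mark, and at a
   single global re-annotation pass an unmarked competing gene wins the
   locus even at a slightly lower score.  This resolves the
   longer-paralog-wins artifact at paralogous loci that have lost one copy.

Operational filters follow, in a fixed order: genes with more than 10
bidirected edges; genes placed at more than 3 distant loci (placed-hit
clusters per contig, gaps <= 100 kb merged — the locus notion is
coordinate-based, one of the genuinely open design points); genes present
in < 5% of genomes (set `--min-freq 0.001` to disable); optionally genes
with no spliced alignment; and finally edges supported by fewer than
`--min-edge-support` contigs.  Removing a gene elides its walk steps and
re-joins the flanks, creating merged-support edges, so pruning cannot
fragment chromosomes; removing an *edge*, by contrast, splits the walks at
that adjacency — the alternative (walk step pairs without a backing edge)
would break the graph's core invariant.

## Generalized bibubbles

`U(x, y)` is the set of genes reachable from `x` without passing through
`x`, `x̄` or `y`; passage through `ȳ` is allowed, contributes gene(y), and
expansion continues through it (this asymmetry is what rejects
orientation-crossed pairs such as the deletion toy's `(>A, <C)`).
A pair `(x, y)` is a generalized bibubble when:

1. `U(x, y) = U(ȳ, x̄)` and is non-empty;
2. every interior gene lies on some `x -> y` walk (some orientation of it
   is reachable from `x` and reaches `y`);
3. *minimality*: no oriented gene `z` over the interior satisfies
   `U(x, z) = U(z̄, x̄) != ∅` or `U(z, y) = U(ȳ, z̄) != ∅`;
4. the enclosed region is not a bare chain: the number of distinct
   bidirected edges among interior plus boundary genes exceeds `|U| + 1`;
5. gene(x) and gene(y) are cycle equivalent in the net graph (below).

Conditions 4 and 5 deserve comment, because the design space here was
genuinely open.  Requiring the *inner* pair's `U` to be non-empty in
condition 3 is what lets a pure tandem copy-number bubble
(`>A [>B >B] >C`, interior `{B}`) survive minimality — with the empty-set
equality admitted as a veto, the direct successor of the entrance would
veto every such bubble, and copy-number changes are precisely the kind of
variation a gene graph should expose.  But the non-empty variant alone
over-accepts: on an unvarying linear stretch `>a >b >c`, the flanks of any
sub-chain satisfy conditions 1–3 vacuously.  Condition 4 restores the
obvious requirement that a bubble encloses *variation*: a region whose
edge count equals `|U| + 1` is a single path with a single traversal.
Condition 5 is, for the empty-veto variant of the definition, a provable
consequence (entrance and exit of a bubble form a 2-edge cut-set of the
net graph); under the non-empty variant a counterexample exists — a
duplicated *exit* gene sits alone in its self-loop class while conditions
1–4 hold — so the property is imposed explicitly.  That keeps the
definition exactly aligned with the class-pruned search, and matches the
behaviour of the enumeration strategy this implements, which only ever
tests co-classed exits.  All five conditions are applied identically in
the fast path and in the brute-force oracle.

For every reported bubble the package asserts (in tests) the structural
theorems: twin symmetry, the separator property (removing entrance and
exit genes disconnects the interior from everything else), entrance/exit
co-classing, nesting of intersecting interiors, and at most one bubble per
entrance.

## Net graph and cycle equivalence

Each gene contributes a start and an end port; each directed edge adds an
undirected link between head(x) and tail(y) (head of `>v` is `(v, e)`, of
`<v` is `(v, s)`; tails are the opposites), and both skew views contract
the same unordered port pair.  Contracting all links (union-find) yields
the net graph: port components are vertices, genes are edges, self-loops
and parallel edges included.

Two net edges are cycle equivalent when every cycle through one passes the
other.  All bridges are vacuously equivalent and share one designated
acyclic class — exactly what co-classes the flanks of a bubble embedded in
a linear chromosome.  For non-bridges, cycle equivalence coincides with
forming a 2-edge cut-set (the cut-set characterization is itself
cross-checked in tests for non-bridge pairs; it deliberately does not hold
for bridge pairs, whose removal yields three components).

The classes are computed by a deterministic XOR-labelling over a spanning
forest: every non-tree edge receives a distinct 64-bit label derived from
FNV-1a of the gene name; every tree edge receives the XOR of the labels of
the non-tree edges whose fundamental cycle covers it (accumulated in one
subtree pass).  Equal non-zero labels correspond to identical covering
sets, hence to 2-edge cut-sets, hence to cycle equivalence; label zero
marks bridges.  A spanning tree always contains at least one edge of any
2-cut, so two non-tree edges are never equivalent and the labelling is
exact up to 64-bit XOR collisions (probability ~ |E|^2 / 2^64, negligible
at any realistic graph size; the exhaustive oracle agrees on 100% of 200
random multigraphs in the acceptance run).  The pass is near-linear and
handles 20,000-gene graphs in well under a second.

The exhaustive oracle enumerates simple cycles as edge subsets that are
connected with all vertex degrees exactly 2 (a self-loop alone is a
cycle), groups edges by identical cycle-membership sets, and is guarded to
<= 14 edges.

## Enumeration

From every oriented gene (the `branching` option restricts entrances to
out-degree >= 2 at the cost of missing bubbles entered through a plain
adjacency, e.g. a duplication flank), a BFS visits up to `m = 100` distinct
genes; oriented genes co-classed with the entrance become candidate exits
and are not traversed beyond; candidates are tested in discovery order and
the first success wins (an entrance heads at most one bubble).  Skew twins
are deduplicated by keeping the twin whose entrance label has the smaller
FNV-1a hash; output is sorted by entrance hash.  On chain-like stretches
the direct successor is itself co-classed, so the search degenerates to a
constant-time check per entrance — this is what keeps whole-pangenome runs
(20k genes, 10 genomes) in the tens of seconds on one core, end to end.
The brute-force scan tests all ordered oriented pairs and is guarded to 60
genes; it exists purely as the independent oracle.

## Synthetic pangenomes

The generator emulates, at the alignment level, the variation classes the
graph is meant to capture.  An ancestral order of `n_genes` genes (split
over `n_chromosomes` contigs) is mutated independently per genome by
per-gene events: deletions (p = 0.02), inversions of 1–3 genes (p = 0.01)
and tandem duplications adding 1–2 extra copies (p = 0.01).  Genes are
placed every 5 kb with 1 kb gene bodies (plus a 200 bp intron for spliced
genes); alignment scores are 500 with 1% Gaussian noise — small enough
that the 95%/98% ratio thresholds behave deterministically — and paralog
family members produce cross-hits at each other's loci at 93% of the true
score, deliberately below `r1` so the false-edge filter resolves
chromosome-loss scenarios.  All randomness flows from a single seed; PAF
emission is byte-deterministic.

With `min_event_spacing = 3` (the default) events keep at least three
unaffected genes between one another — across all genomes — and away from
chromosome ends.  Under that regime the expected-bubble list is exhaustive:
an event on span `S` flanked by unaffected `a, b` surfaces as exactly the
bubble `(>a, >b)` with interior `S`, and the full pipeline recovers 100% of
expected bubbles with no extras over 20 seeds, with the presence matrix
equal to the true copy table.  Setting `min_event_spacing = None` allows
clustered, interacting events; those graphs are used for the
oracle-equivalence checks, where truth is the brute-force scan rather than
the event list.

What the generator does *not* model — and hence what passing tests do not
establish about real data: alignment errors beyond score noise, assembly
gaps and fragmented contigs, partial-gene hits, exon gain/loss and gene
fusion, recurrent events at one locus in several genomes, and sequence-level
paralogy beyond the fixed family score ratio.  Real inputs also depend on
the upstream aligner's handling of frameshifts and in-frame stops, which is
invisible at this level.

## Numerical and tie-break conventions

All orderings that affect output (protein choice, best hits, greedy
selection, placement, bubble canonicalization and sort order) break ties
with the 64-bit FNV-1a hash of the relevant identifier, never with Python's
salted `hash`.  Coordinates are 0-based half-open throughout.  Scores are
kept as floats; the score-ratio comparisons are strict inequalities, so a
ratio exactly at the threshold keeps the edge.  Degenerate inputs — empty
graphs, single-gene contigs, genes in zero walks after filtering, walks
split to fragments — are exercised in the test suite.

## Problem sizes used in the shipped checks

The acceptance script and test suite run at desk scale, chosen to finish in
minutes on one core: 200 random event graphs of 6–25 genes for bubble
oracle equivalence, 200 random multigraphs of <= 12 edges for the cycle
classes, 20 seeds of 10 genomes x 200 genes for end-to-end recovery, and
one 20,000-gene x 10-genome run as a whole-pangenome-scale smoke test.

## Known limitations

* The locus-count filter is coordinate-based (100 kb cluster merging); a
  graph-distance notion would behave differently for genes on short
  fragmented contigs.
* Low-priority re-annotation is a single pass, not a fixpoint iteration;
  pathological chains of marks could in principle need more passes.
* The cycle-class labelling is Monte-Carlo-exact (64-bit XOR collisions);
  the brute-force oracle is exact but exponential.
* An alternative enumeration via single-entry single-exit regions of the
  net graph (with a dummy anchor vertex) is deliberately not implemented:
  anchor placement is heuristic and the plain class-pruned search is both
  exact against the oracle and fast enough.
* Bubbles are local by construction; chromosome-scale rearrangements
  (translocations, large inversions spanning a bubble boundary) are out of
  scope and will instead distort or merge nearby bubbles.
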