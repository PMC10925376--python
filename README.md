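# genegraph

Pangenome **gene graphs** and **generalized bibubbles**: build a bidirected
graph of gene adjacencies from protein-to-genome alignments of multiple
assemblies, encode every contig as a walk of oriented genes, and detect gene
order, gene copy-number and gene orientation differences between the
genomes as bubbles of that graph.

## Who this is for

Groups comparing many high-quality assemblies of one species (or close
relatives) — human haplotype collections, bacterial strain panels — who want
a gene-level, rather than base-level, view of structural variation: which
genes are core vs accessory, where a haplotype carries an extra tandem copy,
which gene spans are inverted, which loci swap gene content.

The input is one PAF file per assembly from a spliced protein-to-genome
aligner (miniprot-style tags: `AS:i` score, `cg:Z` CIGAR with `N`/`U`/`V`
intron operators). No sequence is ever read.

## The model

Let `V` be the gene set and `X = V x {>, <}` the oriented genes; `>v` is
gene `v` read forward, `<v` reversed, and `x̄` flips an orientation.  Each
contig is a walk over `X`; a pair `(x, y)` supported by a contig (y directly
follows x, or `x̄` follows `ȳ` on the other strand) becomes a directed edge
`x -> y`, with the twin `ȳ -> x̄` implied — the edge set is *skew
symmetric*.  Edges carry the mean alignment score of each endpoint over
their supporting contigs, `S(x|y)`.

Annotation is made consistent across genomes before the graph is built:
one protein per gene; per gene the count `b(v)` of genomes where `v`'s best
hit beats every overlapping competitor; then a greedy pass in descending
current `b(v)` that selects one representative per orthologous locus while
keeping paralogs at distinct loci.  Two score-ratio heuristics clean the
result: cross-contig *false edges* (`r1 = 0.95`) delete misplaced paralogous
hits, and same-contig *low-priority edges* (`r2 = 0.98`) demote a gene so a
competing unmarked gene wins its locus on re-annotation.

A **generalized bibubble** is a pair of oriented genes `(x, y)` minimally
enclosing a non-empty interior `U(x, y)` — the genes reachable from `x`
without passing `x`, `x̄` or `y` — with `U(x, y) = U(ȳ, x̄)`, every interior
gene on some `x -> y` walk, and no smaller enclosed pair inside.  Bubbles
capture deletions, tandem copy-number changes and inversions in one
framework.  Enumeration is pruned by *cycle equivalence* on the *net graph*
(split genes into start/end ports, contract adjacency links; genes become
edges of an undirected multigraph): entrance and exit of a bubble are always
cycle equivalent, so a bounded BFS from each entrance only tests co-classed
exits.  A brute-force definition scan is available as an independent
cross-check (`--brute-force`).

## Worked example

Simulate a small pangenome with known events, build the graph, call
bubbles, classify core genes:

```sh
genegraph simulate -o demo --genes 50 --genomes 4 --seed 5
genegraph build demo/genome0{1,2,3,4}.paf -o graph.gfa
genegraph bubbles graph.gfa -o bubbles.tsv
genegraph stats graph.gfa -o presence.tsv
```

The log reports the pipeline stages:

```
[INFO] simulated 4 genomes x 50 genes, 3 events, 3 expected bubbles
[INFO] selection: 50 genes in, 50 selected
[INFO] initial graph: 50 genes, 54 edges, 4 walks
[INFO] wrote graph.gfa: 50 genes, 54 edges, 4 walks
[INFO] 3 generalized bibubbles
```

and `bubbles.tsv` contains exactly the three simulated events:

```
bubble_id  entrance  exit      n_interior_genes  interior_genes           has_inversion  n_distinct_walk_paths
bb1        >g00045   >g00047   1                 g00046                   true           2
bb2        >g00004   >g00006   1                 g00005                   false          2
bb3        >g00009   >g00013   3                 g00010,g00011,g00012     true           2
```

Row `bb2` is a tandem duplication of `g00005` (two copies in one genome,
flagged with no inversion); `bb1` and `bb3` are inversions of one and three
genes, each flanked by its two unaffected neighbours.  Every row names the
entrance/exit oriented genes, the interior gene set, and how many distinct
interior traversals the walks realize.  `presence.tsv` holds the gene x
genome copy-number table with a final `core`/`accessory` column (presence in
>= 99% of genomes by default).

The graph itself is GFA 1.1: `S` lines are genes (`CN:i` = number of
genomes carrying the gene), `L` lines adjacencies (`NS:i` = supporting
contigs, `SC:f`/`S2:f` = the two directed mean scores), `W` lines the
per-contig walks.

## Library use

```python
from genegraph import read_paf, build_pangenome_graph, find_bibubbles

hits = [h for g, p in [("hap1", "hap1.paf"), ("hap2", "hap2.paf")]
        for h in read_paf(p, g)]
graph = build_pangenome_graph(hits)
for bub in find_bibubbles(graph):
    print(bub.entrance.label(), bub.exit.label(), sorted(bub.interior))
```

## Scope and limits

Vertices are genes, never nucleotide segments; there is no coordinate
liftover, no protein clustering (consume a pre-clustered protein set), and
no chromosome-scale rearrangement calling.  See `docs/methods.md` for the
model details, parameter defaults and known limitations.
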