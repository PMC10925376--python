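"""Core domain types for bidirected gene graphs.

A pangenome gene graph has one vertex per gene.  An *oriented gene* is a gene
read on a particular strand, written ``>v`` (forward) or ``<v`` (reverse).
Each input contig contributes a *walk* — the ordered sequence of oriented
genes annotated on it — and every adjacent pair ``(x, y)`` on a walk becomes
a directed edge ``x -> y``.  Because DNA is double stranded, the reverse
complement adjacency ``flip(y) -> flip(x)`` is implied by ``x -> y``; this is
the *skew symmetry* of the edge set.

Edges are stored once, in a canonical orientation (the lexicographically
smaller of ``(x, y)`` and ``(flip(y), flip(x))``), so skew symmetry cannot be
violated by construction.  Both directed views are synthesized on access.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

FORWARD = ">"
REVERSE = "<"

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = 0xFFFFFFFFFFFFFFFF


def fnv1a64(data: str | bytes) -> int:
    """64-bit FNV-1a hash, used for platform-stable tie-breaking."""
    if isinstance(data, str):
        data = data.encode("utf-8")
    h = _FNV_OFFSET
    for b in data:
        h ^= b
        h = (h * _FNV_PRIME) & _MASK64
    return h


class OrientedGene(NamedTuple):
    """A gene together with a reading direction ('>' forward, '<' reverse)."""

    gene: str
    orient: str

    def flip(self) -> "OrientedGene":
        return OrientedGene(self.gene, REVERSE if self.orient == FORWARD else FORWARD)

    def label(self) -> str:
        return f"{self.orient}{self.gene}"


def flip(x: OrientedGene) -> OrientedGene:
    """Reverse complement of an oriented gene; an involution."""
    return x.flip()


def og(text: str) -> OrientedGene:
    """Parse ``'>A'`` / ``'<A'`` (a bare name means forward)."""
    if text and text[0] in (FORWARD, REVERSE):
        return OrientedGene(text[1:], text[0])
    return OrientedGene(text, FORWARD)


class WalkStep(NamedTuple):
    og: OrientedGene
    start: int
    end: int


@dataclass
class Walk:
    """The ordered, coordinate-sorted gene content of one contig (fragment)."""

    genome: str
    contig: str
    steps: list[WalkStep]

    def oriented_genes(self) -> list[OrientedGene]:
        return [s.og for s in self.steps]

    def walk_string(self) -> str:
        return "".join(s.og.label() for s in self.steps)


def _canonical(x: OrientedGene, y: OrientedGene) -> tuple[OrientedGene, OrientedGene, bool]:
    """Return the canonical key for edge {x->y, flip(y)->flip(x)}.

    The boolean is True when (x, y) itself is the canonical view.
    """
    tx, ty = y.flip(), x.flip()
    if (x, y) <= (tx, ty):
        return x, y, True
    return tx, ty, False


@dataclass
class EdgeData:
    """Payload of one canonical edge.

    ``src_scores`` / ``dst_scores`` hold, per supporting (genome, contig),
    the alignment scores of the source / destination gene occurrences that
    realize the adjacency; their per-contig means average into S(x|y) and
    S(y_flipped|x_flipped) respectively.
    """

    support: set[tuple[str, str]] = field(default_factory=set)
    src_scores: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    dst_scores: dict[tuple[str, str], list[float]] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    # triggers of the false/low-priority marks: oriented source genes whose
    # incident placed hits are to be penalised
    false_sources: set[OrientedGene] = field(default_factory=set)
    low_priority_sources: set[OrientedGene] = field(default_factory=set)
    # hints used when a graph is loaded from GFA without walks
    n_support_hint: int | None = None
    score_src_hint: float | None = None
    score_dst_hint: float | None = None

    def _mean(self, per_contig: dict[tuple[str, str], list[float]], hint: float | None) -> float:
        if not per_contig:
            if hint is not None:
                return hint
            raise ValueError("edge has no supporting scores")
        means = [sum(v) / len(v) for v in per_contig.values()]
        return sum(means) / len(means)

    def score_src(self) -> float:
        return self._mean(self.src_scores, self.score_src_hint)

    def score_dst(self) -> float:
        return self._mean(self.dst_scores, self.score_dst_hint)

    def n_support(self) -> int:
        if self.support:
            return len(self.support)
        return self.n_support_hint or 0


class UnknownGeneError(KeyError):
    pass


class PangeneGraph:
    """Bidirected gene graph with per-contig walks.

    Vertices are genes; edges are skew-symmetric pairs of directed views over
    oriented genes.  Multi-edges are not allowed (repeated contig support
    accumulates in the edge's support set); self edges such as ``>B -> >B``
    from tandem duplications are allowed.
    """

    def __init__(self) -> None:
        self.genes: set[str] = set()
        self.walks: list[Walk] = []
        self.meta: dict = {}
        self._edges: dict[tuple[OrientedGene, OrientedGene], EdgeData] = {}
        self._adj: dict[OrientedGene, set[OrientedGene]] = {}
        self._incident: dict[str, set[tuple[OrientedGene, OrientedGene]]] = {}

    # -- construction -----------------------------------------------------

    def add_gene(self, gene: str) -> None:
        self.genes.add(gene)

    def add_edge(
        self,
        x: OrientedGene,
        y: OrientedGene,
        support: tuple[str, str] | None = None,
        score_x: float | None = None,
        score_y: float | None = None,
    ) -> EdgeData:
        """Add (or reinforce) edge x->y together with its skew twin."""
        self.genes.add(x.gene)
        self.genes.add(y.gene)
        cx, cy, is_canon = _canonical(x, y)
        data = self._edges.get((cx, cy))
        if data is None:
            data = EdgeData()
            self._edges[(cx, cy)] = data
            self._adj.setdefault(cx, set()).add(cy)
            self._adj.setdefault(cy.flip(), set()).add(cx.flip())
            self._incident.setdefault(cx.gene, set()).add((cx, cy))
            self._incident.setdefault(cy.gene, set()).add((cx, cy))
        if support is not None:
            data.support.add(support)
            if score_x is not None:
                tgt = data.src_scores if is_canon else data.dst_scores
                tgt.setdefault(support, []).append(score_x)
            if score_y is not None:
                tgt = data.dst_scores if is_canon else data.src_scores
                tgt.setdefault(support, []).append(score_y)
        return data

    def remove_edge(self, x: OrientedGene, y: OrientedGene) -> None:
        cx, cy, _ = _canonical(x, y)
        if (cx, cy) not in self._edges:
            raise KeyError(f"no edge {x.label()} -> {y.label()}")
        del self._edges[(cx, cy)]
        self._adj[cx].discard(cy)
        self._adj[cy.flip()].discard(cx.flip())
        for g in {cx.gene, cy.gene}:
            self._incident[g].discard((cx, cy))

    def remove_gene(self, gene: str) -> None:
        """Remove a gene and all incident edges.  Walks are the caller's duty."""
        for key in list(self._incident.get(gene, ())):
            self.remove_edge(*key)
        self._incident.pop(gene, None)
        self._adj.pop(OrientedGene(gene, FORWARD), None)
        self._adj.pop(OrientedGene(gene, REVERSE), None)
        self.genes.discard(gene)

    # -- accessors ---------------------------------------------------------

    def has_edge(self, x: OrientedGene, y: OrientedGene) -> bool:
        cx, cy, _ = _canonical(x, y)
        return (cx, cy) in self._edges

    def edge_data(self, x: OrientedGene, y: OrientedGene) -> EdgeData:
        cx, cy, _ = _canonical(x, y)
        try:
            return self._edges[(cx, cy)]
        except KeyError:
            raise KeyError(f"no edge {x.label()} -> {y.label()}") from None

    def score(self, x: OrientedGene, y: OrientedGene) -> float:
        """S(x|y): mean alignment score of x over contigs supporting x->y."""
        cx, cy, is_canon = _canonical(x, y)
        data = self._edges[(cx, cy)]
        return data.score_src() if is_canon else data.score_dst()

    def canonical_edges(self) -> Iterator[tuple[OrientedGene, OrientedGene, EdgeData]]:
        for (cx, cy), data in self._edges.items():
            yield cx, cy, data

    def directed_edges(self) -> Iterator[tuple[OrientedGene, OrientedGene]]:
        """Both skew-symmetric views of every edge (twins counted separately)."""
        for cx, cy in self._edges:
            yield cx, cy
            if (cy.flip(), cx.flip()) != (cx, cy):
                yield cy.flip(), cx.flip()

    def n_edges(self) -> int:
        return len(self._edges)

    def gene_degree(self, gene: str) -> int:
        """Number of distinct bidirected edges incident to the gene."""
        return len(self._incident.get(gene, ()))

    def out_neighbors(self, x: OrientedGene) -> set[OrientedGene]:
        if x.gene not in self.genes:
            raise UnknownGeneError(x.gene)
        return set(self._adj.get(x, ()))

    def _successors(self, x: OrientedGene) -> set[OrientedGene]:
        return self._adj.get(x, set())

    # -- traversal ---------------------------------------------------------

    def _bfs(self, start: OrientedGene, banned: frozenset | set = frozenset()) -> set[OrientedGene]:
        """Oriented genes visitable from ``start`` without entering ``banned``.

        ``start`` itself is never entered (and never part of the result) even
        when a cycle returns to it.
        """
        visited: set[OrientedGene] = set()
        queue = deque([start])
        adj = self._adj
        no_entry = set(banned)
        no_entry.add(start)
        while queue:
            cur = queue.popleft()
            for nxt in adj.get(cur, ()):
                if nxt in no_entry or nxt in visited:
                    continue
                visited.add(nxt)
                queue.append(nxt)
        return visited

    def reachable(self, start: OrientedGene, avoid: Iterable[OrientedGene] = ()) -> set[OrientedGene]:
        """All oriented genes reachable from ``start`` along out-edges while
        never entering a member of ``avoid``; excludes ``start`` itself."""
        return self._bfs(start, frozenset(avoid))

    def is_inversion(self, gene: str) -> bool:
        """True when some oriented gene reaches both orientations of ``gene``."""
        if gene not in self.genes:
            raise UnknownGeneError(gene)
        fwd = OrientedGene(gene, FORWARD)
        rev = OrientedGene(gene, REVERSE)
        for z in list(self._adj):
            r = self._bfs(z)
            if fwd in r and rev in r:
                return True
        return False

    # -- walks -------------------------------------------------------------

    def add_walk(self, walk: Walk) -> None:
        for s in walk.steps:
            self.genes.add(s.og.gene)
        self.walks.append(walk)

    def genomes(self) -> list[str]:
        declared = self.meta.get("genomes")
        if declared:
            return list(declared)
        return sorted({w.genome for w in self.walks})

    def gene_genomes(self) -> dict[str, set[str]]:
        """Genomes containing each gene (from walks)."""
        out: dict[str, set[str]] = {g: set() for g in self.genes}
        for w in self.walks:
            for s in w.steps:
                out[s.og.gene].add(w.genome)
        return out

    def check_invariants(self) -> None:
        """Assert skew symmetry and walk/edge consistency (testing aid)."""
        views = set(self.directed_edges())
        for x, y in views:
            assert (y.flip(), x.flip()) in views, f"skew symmetry broken at {x.label()}->{y.label()}"
        for w in self.walks:
            genes_sorted = all(
                w.steps[i].start <= w.steps[i + 1].start for i in range(len(w.steps) - 1)
            )
            assert genes_sorted, f"walk {w.genome}/{w.contig} not sorted"
            for a, b in zip(w.steps, w.steps[1:]):
                assert self.has_edge(a.og, b.og), (
                    f"walk step pair {a.og.label()}->{b.og.label()} has no edge"
                )


def from_walks(
    walk_specs: Sequence[tuple[str, str, Sequence[str | OrientedGene]]],
    score: float = 500.0,
    step_span: int = 1000,
    gap: int = 1000,
) -> PangeneGraph:
    """Build a graph directly from oriented-gene walks (fixtures, simulations).

    ``walk_specs`` is a sequence of (genome, contig, [">A", ">B", ...]).
    All steps get the same synthetic alignment score.
    """
    g = PangeneGraph()
    genomes: list[str] = []
    for genome, contig, items in walk_specs:
        if genome not in genomes:
            genomes.append(genome)
        steps = []
        pos = 0
        for it in items:
            x = og(it) if isinstance(it, str) else it
            steps.append(WalkStep(x, pos, pos + step_span))
            pos += step_span + gap
        walk = Walk(genome, contig, steps)
        g.add_walk(walk)
        for a, b in zip(steps, steps[1:]):
            g.add_edge(a.og, b.og, support=(genome, contig), score_x=score, score_y=score)
    g.meta["genomes"] = genomes
    return g
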