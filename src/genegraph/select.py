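"""Consistent multi-genome annotation from raw protein-to-genome hits.

The central problem: the input protein set may contain redundant
(orthologous) entries.  If genes v and w are orthologs, their best hits fall
on the same locus in each genome, and naive per-locus best-score annotation
would make both look accessory.  The remedy is a greedy competition on
b(v) — the number of genomes where v's best hit beats every overlapping
competitor — that selects one representative per orthologous locus while
keeping paralogs at distinct loci.

All tie-breaks use the 64-bit FNV-1a hash of identifiers so results are
identical across platforms and runs.
"""

from __future__ import annotations

import heapq
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .core import fnv1a64
from .io import AlignmentHit

DEFAULT_OVERLAP_MIN = 0.5


def intervals_overlap(
    astart: int, aend: int, bstart: int, bend: int, overlap_min: float = DEFAULT_OVERLAP_MIN
) -> bool:
    """Overlap test: intersection >= overlap_min of the shorter interval.

    ``overlap_min <= 0`` degenerates to a 1-bp overlap criterion.
    """
    inter = min(aend, bend) - max(astart, bstart)
    if overlap_min <= 0:
        return inter > 0
    shorter = min(aend - astart, bend - bstart)
    return inter >= overlap_min * shorter and inter > 0


def hits_overlap(a: AlignmentHit, b: AlignmentHit, overlap_min: float = DEFAULT_OVERLAP_MIN) -> bool:
    if a.genome != b.genome or a.contig != b.contig:
        return False
    return intervals_overlap(a.tstart, a.tend, b.tstart, b.tend, overlap_min)


def _beats(a: AlignmentHit, b: AlignmentHit) -> bool:
    """Deterministic strict total order on competing hits: higher score wins,
    ties broken by the gene-name hash."""
    if a.score != b.score:
        return a.score > b.score
    return fnv1a64(a.gene) < fnv1a64(b.gene)


class _ContigIndex:
    """Sorted-interval index for overlap queries on one contig."""

    def __init__(self, hits: Sequence[AlignmentHit]) -> None:
        self.hits = sorted(hits, key=lambda h: h.tstart)
        self.starts = [h.tstart for h in self.hits]
        self.maxlen = max((h.tend - h.tstart for h in self.hits), default=0)

    def overlapping(
        self, tstart: int, tend: int, overlap_min: float
    ) -> Iterator[AlignmentHit]:
        lo = bisect_left(self.starts, tstart - self.maxlen)
        hi = bisect_right(self.starts, tend)
        for h in self.hits[lo:hi]:
            if intervals_overlap(tstart, tend, h.tstart, h.tend, overlap_min):
                yield h


@dataclass
class SelectionState:
    b: dict[str, int] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)
    best_hit: dict[tuple[str, str], AlignmentHit] = field(default_factory=dict)
    genomes: list[str] = field(default_factory=list)


def filter_pseudogene_hits(
    hits: Sequence[AlignmentHit], mode: str = "default"
) -> list[AlignmentHit]:
    """Suppress likely processed-pseudogene alignments.

    default: drop unspliced hits of genes that have a spliced hit somewhere.
    strict:  additionally drop genes with no spliced hit in any genome.
    off:     identity.
    """
    if mode == "off":
        return list(hits)
    if mode not in ("default", "strict"):
        raise ValueError(f"unknown pseudogene filter mode {mode!r}")
    spliced = {h.gene for h in hits if h.n_introns >= 1}
    out = []
    for h in hits:
        if h.gene in spliced:
            if h.n_introns >= 1:
                out.append(h)
        elif mode == "default":
            out.append(h)
        # strict: genes without any spliced hit are dropped entirely
    return out


def choose_protein_per_gene(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Keep exactly one protein per gene: the one maximizing the sum over
    genomes of its best-hit score (ties by protein-name hash)."""
    per_gene: dict[str, dict[str, dict[str, float]]] = {}
    for h in hits:
        scores = per_gene.setdefault(h.gene, {}).setdefault(h.protein, {})
        if h.score > scores.get(h.genome, float("-inf")):
            scores[h.genome] = h.score
    chosen: dict[str, str] = {}
    for gene, proteins in per_gene.items():
        chosen[gene] = min(
            proteins,
            key=lambda p: (-sum(proteins[p].values()), fnv1a64(p)),
        )
    return [h for h in hits if h.protein == chosen[h.gene]]


def best_hits(hits: Sequence[AlignmentHit]) -> dict[tuple[str, str], AlignmentHit]:
    """Per (gene, genome): the highest-scoring hit, deterministic under ties."""
    best: dict[tuple[str, str], AlignmentHit] = {}
    for h in hits:
        key = (h.gene, h.genome)
        cur = best.get(key)
        if cur is None:
            best[key] = h
        elif h.score > cur.score or (
            h.score == cur.score
            and fnv1a64(f"{h.gene}\t{h.contig}\t{h.tstart}")
            < fnv1a64(f"{cur.gene}\t{cur.contig}\t{cur.tstart}")
        ):
            best[key] = h
    return best


def _best_hit_indexes(
    state: SelectionState,
) -> dict[tuple[str, str], _ContigIndex]:
    by_loc: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in state.best_hit.values():
        by_loc.setdefault((h.genome, h.contig), []).append(h)
    return {k: _ContigIndex(v) for k, v in by_loc.items()}


def compute_b(
    state: SelectionState, overlap_min: float = DEFAULT_OVERLAP_MIN
) -> dict[str, int]:
    """b(v) = number of genomes where v's best hit beats every overlapping
    best hit of another gene."""
    indexes = _best_hit_indexes(state)
    b = {g: 0 for (g, _) in state.best_hit}
    for (gene, genome), h in state.best_hit.items():
        idx = indexes[(h.genome, h.contig)]
        wins = True
        for other in idx.overlapping(h.tstart, h.tend, overlap_min):
            if other.gene != gene and _beats(other, h):
                wins = False
                break
        if wins:
            b[gene] += 1
    state.b = b
    return b


def select_genes(
    state: SelectionState, overlap_min: float = DEFAULT_OVERLAP_MIN
) -> list[str]:
    """Greedy non-orthologous gene selection on descending current b(v).

    Pop the gene with the largest current b (lazy-deletion max-heap, ties by
    gene-name hash); accept it if b > 0; then, for every gene w whose best
    mapping overlaps the accepted gene's best mapping in some genome while
    scoring higher there, decrement b(w) by one (floored at zero).
    """
    b = dict(state.b)
    heap = [(-n, fnv1a64(g), g) for g, n in b.items()]
    heapq.heapify(heap)
    indexes = _best_hit_indexes(state)
    selected: list[str] = []
    done: set[str] = set()
    while heap:
        negb, _, gene = heapq.heappop(heap)
        if gene in done:
            continue
        if -negb != b[gene]:
            heapq.heappush(heap, (-b[gene], fnv1a64(gene), gene))
            continue
        done.add(gene)
        if b[gene] <= 0:
            continue
        selected.append(gene)
        for genome in state.genomes:
            h = state.best_hit.get((gene, genome))
            if h is None:
                continue
            idx = indexes.get((h.genome, h.contig))
            if idx is None:
                continue
            for other in idx.overlapping(h.tstart, h.tend, overlap_min):
                if other.genome != genome or other.gene == gene:
                    continue
                if _beats(other, h) and b[other.gene] > 0:
                    b[other.gene] -= 1
        state.b = b
    state.selected = selected
    return selected


def build_selection_state(
    hits: Sequence[AlignmentHit], genomes: Iterable[str] | None = None
) -> SelectionState:
    state = SelectionState()
    state.best_hit = best_hits(hits)
    if genomes is None:
        state.genomes = sorted({h.genome for h in hits})
    else:
        state.genomes = list(genomes)
    return state


@dataclass
class PlacedGene:
    """One placed occurrence of a selected gene on a contig."""

    hit: AlignmentHit

    @property
    def gene(self) -> str:
        return self.hit.gene

    @property
    def tstart(self) -> int:
        return self.hit.tstart

    @property
    def tend(self) -> int:
        return self.hit.tend


def place_annotations(
    hits: Sequence[AlignmentHit],
    selected: Iterable[str],
    overlap_min: float = DEFAULT_OVERLAP_MIN,
) -> dict[tuple[str, str], list[PlacedGene]]:
    """Per-contig annotation of the selected genes.

    Greedy by score over every hit of a selected gene: place a hit unless it
    overlaps an already placed, preferred hit.  Hits carrying the
    low-priority mark sort after all unmarked hits regardless of score.
    """
    sel = set(selected)
    by_contig: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        if h.gene in sel:
            by_contig.setdefault((h.genome, h.contig), []).append(h)
    placements: dict[tuple[str, str], list[PlacedGene]] = {}
    for key, bucket in by_contig.items():
        bucket.sort(
            key=lambda h: (h.low_priority, -h.score,
                           fnv1a64(f"{h.gene}\t{h.contig}\t{h.tstart}"))
        )
        maxlen = max(h.tend - h.tstart for h in bucket)
        placed_starts: list[int] = []
        placed: list[PlacedGene] = []
        for h in bucket:
            lo = bisect_left(placed_starts, h.tstart - maxlen)
            hi = bisect_right(placed_starts, h.tend)
            if any(
                intervals_overlap(h.tstart, h.tend, p.tstart, p.tend, overlap_min)
                for p in placed[lo:hi]
            ):
                continue
            at = bisect_left(placed_starts, h.tstart)
            placed_starts.insert(at, h.tstart)
            placed.insert(at, PlacedGene(h))
        placements[key] = placed
    return placements
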